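"""Independent brute-force statistical oracles (enumeration at tiny n)."""

import itertools
import math

import numpy as np
from scipy import stats as sps



def spearman_exact_oracle(x, y):
    """Two-sided exact Spearman p by full enumeration over rank pairings."""
    rx = sps.rankdata(x).astype(int)
    ry = sps.rankdata(y).astype(int)
    n = len(x)
    denom = n * (n * n - 1)

    def rho_num(perm):  # 6 * sum d^2, integer-exact for distinct ranks
        return 6 * sum((a - b) ** 2 for a, b in zip(rx, perm))

    # rho = 1 - rho_num/denom, so |rho| compares via |rho_num - denom| (integer-exact)
    obs_dist = abs(rho_num(ry) - denom)
    count = sum(1 for p in itertools.permutations(ry)
                if abs(rho_num(p) - denom) >= obs_dist)
    import math
    return count / math.factorial(n)


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n2 = len(b)
    mid = n1 * n2 / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    return np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12)


def kruskal_exact_oracle(groups):
    """Exact permutation distribution of H over all equal-size assignments."""
    values = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    N = len(values)
    ranks = sps.rankdata(values)

    def h_of(assign_ranks):
        h = 0.0
        start = 0
        for m in sizes:
            h += sum(assign_ranks[start:start + m]) ** 2 / m
            start += m
        return 12.0 / (N * (N + 1)) * h - 3 * (N + 1)

    h_obs = h_of(ranks)
    count = total = 0
    idx_all = set(range(N))

    def rec(remaining, chosen, gi):
        nonlocal count, total
        if gi == len(sizes) - 1:
            assign = chosen + [sorted(remaining)]
            r = [ranks[i] for grp in assign for i in grp]
            total += 1
            if h_of(r) >= h_obs - 1e-12:
                count += 1
            return
        rem = sorted(remaining)
        for comb in itertools.combinations(rem, sizes[gi]):
            rec(remaining - set(comb), chosen + [list(comb)], gi + 1)

    rec(idx_all, [], 0)
    return count / total


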