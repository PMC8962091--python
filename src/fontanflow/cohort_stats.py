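"""Descriptive and inferential statistics for patient cohort tables.

Implements the statistical layer of the cohort analysis: Shapiro–Wilk-driven
presentation (mean±SD vs median/IQR), Pearson/Spearman correlation with the
conventional strength bands (weak 0.3–0.5, moderate 0.5–0.7, strong 0.7–0.9,
excellent > 0.9), Kruskal–Wallis segment comparison with Bonferroni-adjusted
pairwise Mann–Whitney tests, and two-group differences.  All tests are
two-sided at α = 0.05.

Small-sample p-values are exact: the Spearman null is enumerated over all
rank permutations for n ≤ 9, Mann–Whitney uses the exact U distribution
where scipy provides it, and the Kruskal–Wallis omnibus for small samples
uses a seeded Monte-Carlo permutation of the rank statistic H.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError

log = logging.getLogger(__name__)

ALPHA = 0.05
SPEARMAN_EXACT_MAX_N = 9


def strength_label(r: float) -> str:
    """Correlation strength by |r|: weak/moderate/strong/excellent bands."""
    a = abs(r)
    if a > 0.9:
        return "excellent"
    if a >= 0.7:
        return "strong"
    if a >= 0.5:
        return "moderate"
    if a >= 0.3:
        return "weak"
    return "negligible"


def _shapiro_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """True when Shapiro–Wilk does not reject normality (inapplicable -> False)."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= alpha


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def describe(table: pd.DataFrame, variables: Sequence[str] | None = None
             ) -> pd.DataFrame:
    """Per-variable summary with normality-driven presentation choice.

    Returns one row per variable with n, mean, SD, median, IQR, the
    Shapiro–Wilk p and the chosen presentation (``mean_sd`` when normality is
    not rejected at α = 0.05, else ``median_iqr``; degenerate columns are
    flagged).  Missing values are excluded per variable.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    rows = []
    for var in variables:
        x = pd.to_numeric(table[var], errors="coerce").dropna().to_numpy()
        if len(x) == 0:
            log.warning("variable %s is all-missing; skipped", var)
            continue
        if len(x) < 3:
            raise ContractError(f"variable {var} has fewer than 3 non-missing values")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        if np.ptp(x) == 0:
            rows.append(dict(variable=var, n=len(x), mean=x[0], sd=0.0, median=med,
                             iqr=0.0, shapiro_p=np.nan, presentation="constant"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_p = sps.shapiro(x).pvalue
        rows.append(dict(
            variable=var, n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)),
            median=float(med), iqr=float(q3 - q1), shapiro_p=float(sw_p),
            presentation="mean_sd" if sw_p >= ALPHA else "median_iqr"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    method: str       # "pearson" | "spearman"
    estimate: float
    p: float
    n: int
    label: str

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with the exact permutation p over all n! rank pairings."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    obs = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    r_all = ((ry_perm * rx).mean(axis=1) - rx.mean() * ry.mean()) / (sx * sy)
    p = float(np.mean(np.abs(r_all) >= abs(obs) - 1e-12))
    return obs, p


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Correlation with two-sided p and a strength label.

    ``auto`` picks Pearson when both variables pass Shapiro–Wilk (α = 0.05),
    Spearman otherwise.  Spearman p is exact (full rank-permutation null)
    for n ≤ 9, asymptotic otherwise; Pearson p uses the t transform.
    Missing values are excluded pairwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ContractError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("correlation undefined: zero variance in x or y")
    if method == "auto":
        method = "pearson" if (_shapiro_normal(x) and _shapiro_normal(y)) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        if n <= SPEARMAN_EXACT_MAX_N:
            r, p = _spearman_exact(x, y)
        else:
            r, p = sps.spearmanr(x, y)
    else:
        raise ContractError(f"unknown correlation method {method!r}")
    return CorrelationResult(method=method, estimate=float(r), p=float(p), n=n,
                             label=strength_label(float(r)))


def correlation_table(table: pd.DataFrame, pairs: Sequence[tuple[str, str]],
                      method: str = "auto") -> pd.DataFrame:
    """Long-format correlation results for variable pairs of a cohort table."""
    rows = []
    for a, b in pairs:
        res = correlate(table[a], table[b], method=method)
        rows.append(dict(variable_pair=f"{a}~{b}", method=res.method, n=res.n,
                         estimate=res.estimate, p=res.p, label=res.label))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _kruskal_h(ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    N = len(ranks)
    h = 0.0
    start = 0
    for m in sizes:
        h += ranks[start:start + m].sum() ** 2 / m
        start += m
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_factor if tie_factor > 0 else np.nan


@dataclasses.dataclass
class SegmentComparison:
    h: float
    p: float
    omnibus_method: str            # "asymptotic" | "permutation"
    pairwise_raw: pd.DataFrame
    pairwise_adjusted: pd.DataFrame
    n_pairs: int
    groups_used: tuple[str, ...]


def compare_segments(groups: Mapping[str, Sequence[float]],
                     omnibus: str = "auto", n_resamples: int = 10000,
                     seed: int = 0) -> SegmentComparison:
    """Kruskal–Wallis omnibus + Bonferroni-adjusted pairwise Mann–Whitney.

    Groups with n < 2 are excluded with a warning.  The omnibus p is the
    chi-square asymptotic for comfortable sample sizes and a seeded
    Monte-Carlo permutation of H when any group has n ≤ 5 (``omnibus`` can
    force either).  Pairwise two-sided Mann–Whitney p-values are multiplied
    by the number of pairs and capped at 1.
    """
    used = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= 2}
    for k in set(groups) - set(used):
        log.warning("group %s has n < 2; excluded from comparison", k)
    if len(used) < 2:
        raise ContractError("need at least 2 groups with n >= 2")
    names = list(used)
    values = [used[k] for k in names]
    pooled = np.concatenate(values)
    sizes = [len(v) for v in values]

    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
        method = "degenerate"
    else:
        ranks = sps.rankdata(pooled)
        _, tie_counts = np.unique(pooled, return_counts=True)
        N = len(pooled)
        tie_factor = 1.0 - np.sum(tie_counts**3 - tie_counts) / (N**3 - N)
        h = _kruskal_h(ranks, sizes, tie_factor)
        if omnibus == "auto":
            omnibus = "permutation" if min(sizes) <= 5 else "asymptotic"
        if omnibus == "asymptotic":
            p = float(sps.chi2.sf(h, len(names) - 1))
        elif omnibus == "permutation":
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_resamples):
                perm = rng.permutation(ranks)
                if _kruskal_h(perm, sizes, tie_factor) >= h - 1e-12:
                    count += 1
            p = (count + 1) / (n_resamples + 1)
        else:
            raise ContractError(f"unknown omnibus method {omnibus!r}")
        method = omnibus

    m = len(names) * (len(names) - 1) // 2
    raw = pd.DataFrame(np.nan, index=names, columns=names)
    adj = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        xa, xb = used[a], used[b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p_ab = 1.0
        else:
            p_ab = float(sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        raw.loc[a, b] = raw.loc[b, a] = p_ab
        adj.loc[a, b] = adj.loc[b, a] = min(1.0, p_ab * m)
    return SegmentComparison(h=float(h), p=float(p), omnibus_method=method,
                             pairwise_raw=raw, pairwise_adjusted=adj,
                             n_pairs=m, groups_used=tuple(names))


@dataclasses.dataclass(frozen=True)
class GroupDifferenceResult:
    test: str          # "welch_t" | "mann_whitney"
    statistic: float
    p: float
    n1: int
    n2: int


def group_difference(values, group) -> GroupDifferenceResult:
    """Two-sided two-group difference, test chosen by per-group normality.

    ``group`` is a binary label vector aligned with ``values``.  When both
    groups pass Shapiro–Wilk the (Welch) t-test is used, otherwise the
    Mann–Whitney U test.
    """
    values = np.asarray(values, float)
    group = np.asarray(group)
    levels = pd.unique(group[np.isfinite(values)])
    if len(levels) != 2:
        raise ContractError(f"group must have exactly 2 levels, got {len(levels)}")
    a = values[(group == levels[0]) & np.isfinite(values)]
    b = values[(group == levels[1]) & np.isfinite(values)]
    if len(a) < 2 or len(b) < 2:
        raise ContractError("both groups need n >= 2")
    if _shapiro_normal(a) and _shapiro_normal(b):
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupDifferenceResult("welch_t", float(res.statistic),
                                     float(res.pvalue), len(a), len(b))
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupDifferenceResult("mann_whitney", len(a) * len(b) / 2.0, 1.0,
                                     len(a), len(b))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupDifferenceResult("mann_whitney", float(res.statistic),
                                 float(res.pvalue), len(a), len(b))
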