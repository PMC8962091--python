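"""Synthetic 4D flow phantoms and a synthetic patient cohort.

Phantoms provide analytic ground truth for every geometric and energetic
operation: pulsatile laminar (parabolic) flow in straight/tilted tubes and in
a four-branch cavopulmonary junction, with optional additive Gaussian noise
and VENC wrapping applied after the analytic field is frozen.  For a straight
branch of radius R, length L carrying flow Q the closed forms are

    KE = (2/3) ρ Q² L / (π R²)        EL = 8 μ L Q² / (π R⁴)

(the Hagen–Poiseuille volume integrals of ½ρ|v|² and μ(∂v/∂r)²).  The
junction interior is blended by distance-weighted interpolation and is
explicitly non-analytic: closed-form comparisons are restricted to straight
branch regions.

The cohort generator draws patients from a multivariate normal whose default
moments and pairwise correlations mirror a published adolescent Fontan
cohort: normalized TCPC kinetic energy and viscous energy loss, liver cT1,
peak oxygen uptake (absolute and % predicted), cardiac index and ejection
fraction.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .energetics import BLOOD_DENSITY, BLOOD_VISCOSITY
from .errors import SpecError
from .flow_io import AcquisitionMeta, VelocityField4D, VesselMask

log = logging.getLogger(__name__)

SEGMENT_LABEL_NAMES = {1: "fontan_tunnel", 2: "svc", 3: "lpa", 4: "rpa", 5: "confluence"}


def raised_cosine_waveform(n_phases: int) -> np.ndarray:
    """Nonnegative periodic waveform with mean 1 and peak/mean ratio 2.

    Emulates venous (caval/conduit) pulsatility over the cardiac cycle.
    """
    t = np.arange(n_phases)
    return 1.0 + np.cos(2.0 * np.pi * t / n_phases)


def poiseuille_ke_mj(q_l_min: float, length_mm: float, radius_mm: float,
                     rho: float = BLOOD_DENSITY) -> float:
    """Closed-form KE (mJ) of steady Poiseuille flow in a straight tube."""
    q = q_l_min / 60.0e3
    L, R = length_mm * 1e-3, radius_mm * 1e-3
    return (2.0 / 3.0) * rho * q**2 * L / (np.pi * R**2) * 1e3


def poiseuille_el_mw(q_l_min: float, length_mm: float, radius_mm: float,
                     mu: float = BLOOD_VISCOSITY) -> float:
    """Closed-form EL (mW) of steady Poiseuille flow in a straight tube."""
    q = q_l_min / 60.0e3
    L, R = length_mm * 1e-3, radius_mm * 1e-3
    return 8.0 * mu * L * q**2 / (np.pi * R**4) * 1e3


def _default_radii():
    return {"fontan_tunnel": 9.0, "svc": 7.0, "lpa": 6.0, "rpa": 7.0}


def _default_lengths():
    return {"fontan_tunnel": 60.0, "svc": 50.0, "lpa": 60.0, "rpa": 60.0}


@dataclasses.dataclass
class PhantomSpec:
    """Specification of a synthetic 4D flow phantom.

    ``q_l_min`` is the tube flow for tube geometries (per tube for the
    disjoint pair) and the total systemic venous inflow for the junction
    geometry, split ``tunnel_fraction`` : 1−``tunnel_fraction`` between the
    Fontan tunnel and the SVC and ``lpa_fraction`` : 1−``lpa_fraction``
    between the pulmonary arteries.  Defaults follow the acquisition regime
    of adolescent Fontan imaging: VENC 80 cm/s, 24 cardiac phases, venous
    raised-cosine pulsatility; noise and aliasing are opt-in corruptions.
    """

    geometry: str = "straight_tube"  # straight_tube|tilted_tube|two_tube_disjoint|tcpc_junction
    radius_mm: float = 8.0
    length_mm: float = 100.0
    tilt_deg: float = 30.0
    branch_radii_mm: dict = dataclasses.field(default_factory=_default_radii)
    branch_lengths_mm: dict = dataclasses.field(default_factory=_default_lengths)
    q_l_min: float = 3.0
    tunnel_fraction: float = 0.7
    lpa_fraction: float = 0.45
    n_phases: int = 24
    waveform: np.ndarray | None = None   # default: raised cosine (ones if n_phases == 1)
    noise_sd_m_s: float = 0.0
    venc_cm_s: float = 80.0
    spacing_mm: float = 1.0
    rr_interval_ms: float = 1000.0
    rho: float = BLOOD_DENSITY
    mu: float = BLOOD_VISCOSITY
    seed: int = 0

    def resolved_waveform(self) -> np.ndarray:
        if self.waveform is not None:
            w = np.asarray(self.waveform, dtype=float)
            if w.shape != (self.n_phases,):
                raise SpecError(f"waveform length {w.shape} != n_phases {self.n_phases}")
            if np.any(w < 0):
                raise SpecError("waveform must be nonnegative")
            if abs(w.mean() - 1.0) > 1e-9:
                raise SpecError(f"waveform mean must be 1, got {w.mean():.6f}")
            return w
        if self.n_phases == 1:
            return np.ones(1)
        return raised_cosine_waveform(self.n_phases)

    def validate(self):
        if self.geometry not in ("straight_tube", "tilted_tube", "two_tube_disjoint",
                                 "tcpc_junction"):
            raise SpecError(f"unknown geometry {self.geometry!r}")
        if self.q_l_min < 0 or self.spacing_mm <= 0 or self.venc_cm_s <= 0:
            raise SpecError("flow must be >= 0; spacing and VENC positive")
        if self.geometry in ("straight_tube", "tilted_tube"):
            if self.radius_mm <= 0 or self.length_mm <= 0:
                raise SpecError("radius and length must be positive")
        if self.geometry == "tcpc_junction":
            radii = self.branch_radii_mm
            lengths = self.branch_lengths_mm
            if set(radii) != set(_default_radii()) or set(lengths) != set(radii):
                raise SpecError("tcpc branches must be fontan_tunnel, svc, lpa, rpa")
            if any(r <= 0 for r in radii.values()) or any(l <= 0 for l in lengths.values()):
                raise SpecError("branch radii and lengths must be positive")
            if 2.0 * max(radii.values()) >= min(lengths.values()):
                raise SpecError("branches overlap geometrically outside the junction")
            if not (0 < self.tunnel_fraction < 1 and 0 < self.lpa_fraction < 1):
                raise SpecError("flow fractions must lie in (0, 1)")
        self.resolved_waveform()


@dataclasses.dataclass
class PhantomResult:
    """A generated phantom with its pre-corruption ground truth."""

    field: VelocityField4D            # after noise/aliasing corruption
    clean_field: VelocityField4D      # analytic field (the ground truth)
    prewrap_field: VelocityField4D    # analytic + noise, before VENC wrapping
    mask: VesselMask                  # analytic geometric lumen mask
    labels: np.ndarray | None         # uint8 segment label map (junction geometry)
    label_names: dict
    centerline: dict[str, np.ndarray]  # analytic axis polylines, world mm
    seeds: dict[str, np.ndarray]       # labeled endpoint seeds, world mm
    q_branch: dict[str, float]         # mean flow per branch, L/min
    waveform: np.ndarray
    ground_truth: dict                 # closed-form KE/EL per branch
    n_wrapped: int = 0


def _grid_for_bbox(lo: np.ndarray, hi: np.ndarray, spacing: float, margin_vox: int = 2):
    lo = lo - margin_vox * spacing
    hi = hi + margin_vox * spacing
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    coords = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    X = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
    return lo, shape, X


def _cylinder_axis_polyline(p0: np.ndarray, d: np.ndarray, length: float,
                            step: float = 1.0) -> np.ndarray:
    s = np.arange(0.0, length + 1e-9, step)
    return p0[None, :] + s[:, None] * d[None, :]


def _closed_forms(q_l_min, length_mm, radius_mm, rho, mu, waveform):
    w2 = float(np.mean(waveform**2))
    ke = poiseuille_ke_mj(q_l_min, length_mm, radius_mm, rho)
    el = poiseuille_el_mw(q_l_min, length_mm, radius_mm, mu)
    return {"q_l_min": q_l_min, "radius_mm": radius_mm, "length_mm": length_mm,
            "ke_steady_mJ": ke, "el_steady_mW": el,
            "ke_cycle_avg_mJ": ke * w2, "el_cycle_avg_mW": el * w2,
            "waveform_mean_sq": w2}


def _corrupt(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply noise then VENC wrapping (corruption order is fixed).

    Returns (wrapped, pre-wrap noisy field, number of wrapped entries).
    """
    v = clean.copy()
    if spec.noise_sd_m_s > 0:
        v += rng.normal(0.0, spec.noise_sd_m_s, size=v.shape)
    venc = spec.venc_cm_s / 100.0
    wrapped = np.mod(v + venc, 2.0 * venc) - venc
    n_wrapped = int(np.sum(~np.isclose(wrapped, v)))
    return wrapped, v, n_wrapped


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom velocity field with analytic ground truth.

    The analytic field is built first (parabolic profiles scaled by the
    waveform; distance-weighted blending inside the junction), then noise and
    VENC wrapping corrupt a copy; all ground truth refers to the analytic
    field.  The same seed reproduces the output bit-identically.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w = spec.resolved_waveform()
    sp = spec.spacing_mm

    if spec.geometry in ("straight_tube", "tilted_tube"):
        tilt = np.deg2rad(spec.tilt_deg if spec.geometry == "tilted_tube" else 0.0)
        d = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        p0 = np.zeros(3)
        ends = np.array([p0, p0 + spec.length_mm * d])
        lo, shape, X = _grid_for_bbox(ends.min(0) - spec.radius_mm,
                                      ends.max(0) + spec.radius_mm, sp)
        rel = X - p0
        s = rel @ d
        rho2 = np.maximum(np.sum(rel**2, axis=-1) - s**2, 0.0)
        R2 = spec.radius_mm**2
        mask3 = (s >= 0) & (s <= spec.length_mm) & (rho2 <= R2)
        vmax = 2.0 * (spec.q_l_min / 60.0e3) / (np.pi * (spec.radius_mm * 1e-3) ** 2)
        prof = np.where(mask3, vmax * (1.0 - rho2 / R2), 0.0)
        clean = np.zeros(shape + (spec.n_phases, 3))
        for t in range(spec.n_phases):
            for c in range(3):
                clean[..., t, c] = d[c] * prof * w[t]
        label = "tube"
        centerline = {label: _cylinder_axis_polyline(p0, d, spec.length_mm)}
        seeds = {"inlet": p0.copy(), "outlet": p0 + spec.length_mm * d}
        q_branch = {label: spec.q_l_min}
        gt = {label: _closed_forms(spec.q_l_min, spec.length_mm, spec.radius_mm,
                                   spec.rho, spec.mu, w)}
        labels_map = None

    elif spec.geometry == "two_tube_disjoint":
        d = np.array([0.0, 0.0, 1.0])
        sep = 2.0 * spec.radius_mm + 6.0 * sp
        p0a, p0b = np.zeros(3), np.array([sep, 0.0, 0.0])
        lo, shape, X = _grid_for_bbox(np.array([-spec.radius_mm, -spec.radius_mm, 0.0]),
                                      np.array([sep + spec.radius_mm, spec.radius_mm,
                                                spec.length_mm]), sp)
        clean = np.zeros(shape + (spec.n_phases, 3))
        mask3 = np.zeros(shape, dtype=bool)
        labels_map = np.zeros(shape, dtype=np.uint8)
        R2 = spec.radius_mm**2
        vmax = 2.0 * (spec.q_l_min / 60.0e3) / (np.pi * (spec.radius_mm * 1e-3) ** 2)
        for li, p0 in ((1, p0a), (2, p0b)):
            rel = X - p0
            s = rel @ d
            rho2 = np.maximum(np.sum(rel**2, axis=-1) - s**2, 0.0)
            m = (s >= 0) & (s <= spec.length_mm) & (rho2 <= R2)
            mask3 |= m
            labels_map[m] = li
            prof = np.where(m, vmax * (1.0 - rho2 / R2), 0.0)
            for t in range(spec.n_phases):
                clean[..., t, 2] += prof * w[t]
        centerline = {"tube_a": _cylinder_axis_polyline(p0a, d, spec.length_mm),
                      "tube_b": _cylinder_axis_polyline(p0b, d, spec.length_mm)}
        seeds = {"a_inlet": p0a.copy(), "a_outlet": p0a + spec.length_mm * d,
                 "b_inlet": p0b.copy(), "b_outlet": p0b + spec.length_mm * d}
        q_branch = {"tube_a": spec.q_l_min, "tube_b": spec.q_l_min}
        gt = {lab: _closed_forms(spec.q_l_min, spec.length_mm, spec.radius_mm,
                                 spec.rho, spec.mu, w) for lab in centerline}

    else:  # tcpc_junction
        radii = spec.branch_radii_mm
        lengths = spec.branch_lengths_mm
        q_in = spec.q_l_min
        q_branch = {
            "fontan_tunnel": q_in * spec.tunnel_fraction,
            "svc": q_in * (1.0 - spec.tunnel_fraction),
            "lpa": q_in * spec.lpa_fraction,
            "rpa": q_in * (1.0 - spec.lpa_fraction),
        }
        # outward unit directions from the junction and through-flow directions
        out_dirs = {"fontan_tunnel": np.array([0.0, 0.0, -1.0]),
                    "svc": np.array([0.0, 0.0, 1.0]),
                    "lpa": np.array([1.0, 0.0, 0.0]),
                    "rpa": np.array([-1.0, 0.0, 0.0])}
        flow_dirs = {"fontan_tunnel": -out_dirs["fontan_tunnel"],  # toward junction
                     "svc": -out_dirs["svc"],
                     "lpa": out_dirs["lpa"],                        # away from junction
                     "rpa": out_dirs["rpa"]}
        c = np.zeros(3)
        maxR = max(radii.values())
        lo_b = np.array([-lengths["rpa"], -maxR, -lengths["fontan_tunnel"]])
        hi_b = np.array([lengths["lpa"], maxR, lengths["svc"]])
        lo, shape, X = _grid_for_bbox(lo_b - maxR, hi_b + maxR, sp)
        rel = X - c
        order = ["fontan_tunnel", "svc", "lpa", "rpa"]
        prof = np.zeros((4,) + shape)
        in_cyl = np.zeros((4,) + shape, dtype=bool)
        axial = np.zeros((4,) + shape)
        for bi, lab in enumerate(order):
            d = out_dirs[lab]
            s = rel @ d
            rho2 = np.maximum(np.sum(rel**2, axis=-1) - s**2, 0.0)
            R2 = radii[lab] ** 2
            in_cyl[bi] = (s >= 0) & (s <= lengths[lab]) & (rho2 <= R2)
            prof[bi] = np.where(in_cyl[bi], np.maximum(1.0 - rho2 / R2, 0.0), 0.0)
            axial[bi] = s
        mask3 = in_cyl.any(axis=0)
        wsum = prof.sum(axis=0)
        clean = np.zeros(shape + (spec.n_phases, 3))
        base = np.zeros(shape + (3,))
        for bi, lab in enumerate(order):
            vmax = 2.0 * (q_branch[lab] / 60.0e3) / (np.pi * (radii[lab] * 1e-3) ** 2)
            u = flow_dirs[lab]
            for cc in range(3):
                if u[cc]:
                    base[..., cc] += u[cc] * vmax * prof[bi] ** 2  # weight w_i * u_i
        with np.errstate(invalid="ignore", divide="ignore"):
            for cc in range(3):
                base[..., cc] = np.where(wsum > 0, base[..., cc] / wsum, 0.0)
        for t in range(spec.n_phases):
            clean[..., t, :] = base * w[t]
        # ground-truth labels: dominant branch, overridden to confluence near the junction
        dominant = np.argmax(prof, axis=0)
        labels_map = np.zeros(shape, dtype=np.uint8)
        r_conf = maxR
        for bi, lab in enumerate(order):
            sel = mask3 & (dominant == bi)
            labels_map[sel] = bi + 1
            conf = sel & (axial[bi] <= r_conf)
            labels_map[conf] = 5
        centerline = {lab: _cylinder_axis_polyline(c, out_dirs[lab], lengths[lab])
                      for lab in order}
        seeds = {lab: c + lengths[lab] * out_dirs[lab] for lab in order}
        gt = {lab: _closed_forms(q_branch[lab], lengths[lab] - r_conf, radii[lab],
                                 spec.rho, spec.mu, w) for lab in order}
        gt["confluence_radius_mm"] = r_conf

    meta = AcquisitionMeta(voxel_spacing=(sp, sp, sp), n_phases=spec.n_phases,
                           venc_cm_s=spec.venc_cm_s, rr_interval_ms=spec.rr_interval_ms,
                           origin=tuple(lo))
    clean_field = VelocityField4D(values=clean, meta=meta)
    corrupted, prewrap, n_wrapped = _corrupt(clean, spec, rng)
    field = VelocityField4D(values=corrupted, meta=meta)
    return PhantomResult(
        field=field, clean_field=clean_field,
        prewrap_field=VelocityField4D(values=prewrap, meta=meta),
        mask=VesselMask(values=mask3, meta=meta),
        labels=labels_map, label_names=dict(SEGMENT_LABEL_NAMES),
        centerline=centerline, seeds={k: np.asarray(v, float) for k, v in seeds.items()},
        q_branch=q_branch, waveform=w, ground_truth=gt, n_wrapped=n_wrapped)


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

COHORT_VARIABLES = ("ke_norm_flow", "el_norm_flow", "ct1", "peak_vo2",
                    "pct_pred_vo2", "cardiac_index", "ef")
#: mJ/(L/min), mW/(L/min), ms, ml/kg/min, %, L/min/m^2, %
COHORT_MEANS = (0.260, 0.075, 964.0, 27.1, 57.0, 3.4, 48.0)
COHORT_SDS = (0.068, 0.022, 63.0, 6.2, 12.0, 0.1, 7.0)
#: Cells printed in the source cohort are used verbatim (energetics vs cT1,
#: peak VO2, % predicted VO2, cardiac index, ejection fraction; near-zero
#: cardiac-index/EF rows); the remaining cells (KE–EL, cT1–VO2, VO2–%pred,
#: CI–EF) are declared plausible constructions that keep the matrix PSD.
COHORT_CORRELATION = np.array([
    [1.000, 0.850, 0.500, -0.610, -0.440, -0.189, -0.030],
    [0.850, 1.000, 0.390, -0.540, -0.460, -0.147, 0.048],
    [0.500, 0.390, 1.000, -0.300, -0.300, 0.000, 0.000],
    [-0.610, -0.540, -0.300, 1.000, 0.700, 0.000, 0.000],
    [-0.440, -0.460, -0.300, 0.700, 1.000, 0.000, 0.000],
    [-0.189, -0.147, 0.000, 0.000, 0.000, 1.000, 0.300],
    [-0.030, 0.048, 0.000, 0.000, 0.000, 0.300, 1.000],
])


@dataclasses.dataclass
class CohortSpec:
    """Multivariate-normal specification of a synthetic patient cohort."""

    n: int
    variables: tuple = COHORT_VARIABLES
    means: tuple = COHORT_MEANS
    sds: tuple = COHORT_SDS
    correlation: np.ndarray = dataclasses.field(
        default_factory=lambda: COHORT_CORRELATION.copy())
    seed: int = 0

    def validate(self):
        k = len(self.variables)
        if self.n < 1:
            raise SpecError("cohort size must be >= 1")
        if len(self.means) != k or len(self.sds) != k:
            raise SpecError("means/sds length must match variables")
        if any(s < 0 for s in self.sds):
            raise SpecError("SDs must be nonnegative")
        C = np.asarray(self.correlation, float)
        if C.shape != (k, k) or not np.allclose(C, C.T, atol=1e-10) \
                or not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise SpecError("correlation must be symmetric with unit diagonal")
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-8:
            w, V = np.linalg.eigh(C)
            Cn = (V * np.clip(w, 0, None)) @ V.T
            d = np.sqrt(np.diag(Cn))
            Cn = Cn / np.outer(d, d)
            log.error("correlation matrix is not PSD (min eig %.3g); nearest-PSD "
                      "candidate:\n%s", eig.min(), np.array_str(Cn, precision=3))
            raise SpecError(f"correlation matrix is not positive semi-definite "
                            f"(min eigenvalue {eig.min():.3g})")


def default_cohort_spec(n: int = 62, seed: int = 0) -> CohortSpec:
    """Cohort spec with the default published-cohort moments/correlations."""
    return CohortSpec(n=n, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the specified multivariate normal (seeded)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sds = np.asarray(spec.sds, float)
    cov = np.asarray(spec.correlation, float) * np.outer(sds, sds)
    draws = rng.multivariate_normal(np.asarray(spec.means, float), cov,
                                    size=spec.n, method="svd")
    return pd.DataFrame(draws, columns=list(spec.variables))


def write_cohort_csv(df: pd.DataFrame, spec: CohortSpec, path) -> None:
    """Write the cohort with a commented YAML provenance header."""
    import io
    import yaml
    prov = {"n": spec.n, "seed": spec.seed, "variables": list(spec.variables),
            "means": [float(m) for m in spec.means],
            "sds": [float(s) for s in spec.sds]}
    buf = io.StringIO()
    for line in yaml.safe_dump(prov, sort_keys=False).splitlines():
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
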