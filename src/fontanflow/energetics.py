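"""Voxel-wise kinetic energy and viscous energy loss rate in a vessel mask.

Kinetic energy (KE) of the blood pool is the volume integral of ½ρ|v|²,
reported in mJ.  The viscous energy loss rate (EL) is the volume integral of
the laminar Navier–Stokes dissipation function

    Φ_v = ½ Σ_ij (∂v_i/∂x_j + ∂v_j/∂x_i)² − (2/3)(∇·v)²

times the dynamic viscosity μ, reported in mW.  Both are summed voxel-wise
within the vessel mask per cardiac phase; the cycle average is the unweighted
mean over phases (retrospective gating gives uniform phase duration).

Velocity gradients use central differences where both axis-neighbors lie in
the mask and one-sided differences at mask boundaries (discarding boundary
voxels would systematically miss wall-shear-dominated dissipation).  The
divergence correction term exists because measured fields are not exactly
divergence-free; any negative per-voxel Φ_v it produces is clipped to zero.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import ContractError, NormalizationError
from .flow_io import VelocityField4D, VesselMask

log = logging.getLogger(__name__)

#: Mass density of blood, kg/m^3.
BLOOD_DENSITY = 1060.0
#: Dynamic viscosity of blood, Pa.s.
BLOOD_VISCOSITY = 3.2e-3


@dataclasses.dataclass(frozen=True)
class EnergeticsConfig:
    """Physical constants and numerical choices for the energetics integrals."""

    blood_density: float = BLOOD_DENSITY
    dynamic_viscosity: float = BLOOD_VISCOSITY
    include_divergence_term: bool = True
    boundary_scheme: str = "one_sided"  # or "interior_only"

    def __post_init__(self):
        if self.blood_density <= 0 or self.dynamic_viscosity <= 0:
            raise ContractError("density and viscosity must be positive")
        if self.boundary_scheme not in ("one_sided", "interior_only"):
            raise ContractError(f"unknown boundary scheme {self.boundary_scheme!r}")


@dataclasses.dataclass
class EnergeticsSeries:
    """Per-phase and cycle-averaged KE (mJ) and EL (mW) over a mask."""

    ke_per_phase: np.ndarray
    el_per_phase: np.ndarray
    ke_cycle_avg: float
    el_cycle_avg: float
    ke_density: np.ndarray | None = None  # J/m^3 per phase
    el_density: np.ndarray | None = None  # W/m^3 per phase
    n_clipped: int = 0


@dataclasses.dataclass(frozen=True)
class NormalizedEnergetics:
    """Flow- and flow+length-normalized cycle-averaged energetics."""

    ke_norm_flow: float          # mJ per L/min
    el_norm_flow: float          # mW per L/min
    ke_norm_flow_length: float | None = None  # mJ per L/min per cm
    el_norm_flow_length: float | None = None  # mW per L/min per cm


def _neighbor(a: np.ndarray, axis: int, step: int, fill=0.0) -> np.ndarray:
    """Value of the neighbor `step` voxels along `axis`, edge-filled."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    else:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_derivative(v: np.ndarray, mask: np.ndarray, axis: int, h_m: float,
                       scheme: str) -> np.ndarray:
    """∂v/∂x_axis on mask voxels using in-mask neighbors only (units 1/s·...).

    Central difference where both axis-neighbors are in the mask; one-sided
    where only one is (scheme "one_sided"); zero where neither is.
    """
    vp = _neighbor(v, axis, +1)
    vm = _neighbor(v, axis, -1)
    mp = _neighbor(mask, axis, +1, fill=False)
    mm = _neighbor(mask, axis, -1, fill=False)
    d = np.zeros_like(v)
    both = mask & mp & mm
    d[both] = (vp[both] - vm[both]) / (2.0 * h_m)
    if scheme == "one_sided":
        op = mask & mp & ~mm
        om = mask & ~mp & mm
        d[op] = (vp[op] - v[op]) / h_m
        d[om] = (v[om] - vm[om]) / h_m
    return d


def velocity_gradient_tensor(field: VelocityField4D, mask: VesselMask, phase: int,
                             cfg: EnergeticsConfig | None = None) -> np.ndarray:
    """Velocity gradient tensor G[i, j] = ∂v_i/∂x_j (1/s) on the grid.

    Entries are valid on mask voxels only; voxels with no in-mask neighbor on
    some axis get a zero derivative along that axis (their count is logged).
    """
    cfg = cfg or EnergeticsConfig()
    mask.require_nonempty()
    m = mask.values
    h = field.meta.spacing * 1e-3  # mm -> m
    G = np.zeros((3, 3) + field.spatial_shape)
    for i in range(3):
        v = field.values[..., phase, i]
        for j in range(3):
            G[i, j] = _masked_derivative(v, m, j, h[j], cfg.boundary_scheme)
    isolated = m & ~np.any(
        [_neighbor(m, ax, s, fill=False) for ax in range(3) for s in (+1, -1)], axis=0)
    n_iso = int(isolated.sum())
    if n_iso:
        log.warning("%d mask voxels have no in-mask neighbor on any axis", n_iso)
    return G


def kinetic_energy(field: VelocityField4D, mask: VesselMask,
                   cfg: EnergeticsConfig | None = None) -> np.ndarray:
    """Total KE per cardiac phase, mJ: Σ_voxels ½ ρ |v|² V_voxel."""
    cfg = cfg or EnergeticsConfig()
    mask.require_nonempty()
    vvox_m3 = field.meta.voxel_volume_mm3 * 1e-9
    sq = np.sum(field.values**2, axis=-1)[mask.values]  # (nvox, phase)
    ke_j = 0.5 * cfg.blood_density * sq.sum(axis=0) * vvox_m3
    return ke_j * 1e3  # J -> mJ


def dissipation_function(field: VelocityField4D, mask: VesselMask, phase: int,
                         cfg: EnergeticsConfig | None = None
                         ) -> tuple[np.ndarray, int]:
    """Per-voxel viscous dissipation Φ_v (1/s²) on the grid, and clip count."""
    cfg = cfg or EnergeticsConfig()
    G = velocity_gradient_tensor(field, mask, phase, cfg)
    phi = np.zeros(field.spatial_shape)
    for i in range(3):
        for j in range(3):
            phi += 0.5 * (G[i, j] + G[j, i]) ** 2
    n_clipped = 0
    if cfg.include_divergence_term:
        div = G[0, 0] + G[1, 1] + G[2, 2]
        phi -= (2.0 / 3.0) * div**2
        neg = phi < 0
        n_clipped = int((neg & mask.values).sum())
        phi[neg] = 0.0
    phi[~mask.values] = 0.0
    return phi, n_clipped


def viscous_energy_loss_rate(field: VelocityField4D, mask: VesselMask,
                             cfg: EnergeticsConfig | None = None) -> np.ndarray:
    """Total EL per cardiac phase, mW: Σ_voxels μ Φ_v V_voxel."""
    cfg = cfg or EnergeticsConfig()
    vvox_m3 = field.meta.voxel_volume_mm3 * 1e-9
    el = np.empty(field.meta.n_phases)
    for t in range(field.meta.n_phases):
        phi, n_clip = dissipation_function(field, mask, t, cfg)
        if n_clip:
            log.info("phase %d: clipped %d negative dissipation voxels", t, n_clip)
        el[t] = cfg.dynamic_viscosity * phi[mask.values].sum() * vvox_m3 * 1e3  # W->mW
    return el


def cycle_average(series) -> float:
    """Arithmetic mean over cardiac phases (uniform retrospective gating)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ContractError("cannot cycle-average an empty series")
    return float(series.mean())


def compute_energetics(field: VelocityField4D, mask: VesselMask,
                       cfg: EnergeticsConfig | None = None,
                       return_maps: bool = False) -> EnergeticsSeries:
    """KE and EL per phase plus cycle averages (and optional density maps)."""
    cfg = cfg or EnergeticsConfig()
    ke = kinetic_energy(field, mask, cfg)
    vvox_m3 = field.meta.voxel_volume_mm3 * 1e-9
    el = np.empty(field.meta.n_phases)
    ke_maps = el_maps = None
    n_clipped = 0
    if return_maps:
        ke_maps = np.zeros(field.spatial_shape + (field.meta.n_phases,))
        el_maps = np.zeros_like(ke_maps)
    for t in range(field.meta.n_phases):
        phi, n_clip = dissipation_function(field, mask, t, cfg)
        n_clipped += n_clip
        el[t] = cfg.dynamic_viscosity * phi[mask.values].sum() * vvox_m3 * 1e3
        if return_maps:
            sq = np.sum(field.values[..., t, :] ** 2, axis=-1)
            ke_maps[..., t] = np.where(mask.values, 0.5 * cfg.blood_density * sq, 0.0)
            el_maps[..., t] = cfg.dynamic_viscosity * phi
    return EnergeticsSeries(
        ke_per_phase=ke, el_per_phase=el,
        ke_cycle_avg=cycle_average(ke), el_cycle_avg=cycle_average(el),
        ke_density=ke_maps, el_density=el_maps, n_clipped=n_clipped)


def normalize_energetics(ke_avg_mj: float, el_avg_mw: float, inflow_l_min: float,
                         length_cm: float | None = None) -> NormalizedEnergetics:
    """Normalize cycle-averaged energetics by inflow and optionally length.

    ``inflow_l_min`` is the total inflow to the region (for the complete
    connection: caval + conduit flow); per-branch segments additionally
    normalize by the included centerline length in cm so that partially
    imaged segments remain comparable.  Central-confluence energetics are
    normalized for flow only (omit ``length_cm``).
    """
    if not inflow_l_min > 0:
        raise NormalizationError(f"inflow must be positive, got {inflow_l_min}")
    kf, ef = ke_avg_mj / inflow_l_min, el_avg_mw / inflow_l_min
    if length_cm is None:
        return NormalizedEnergetics(ke_norm_flow=kf, el_norm_flow=ef)
    if not length_cm > 0:
        raise NormalizationError(f"length must be positive, got {length_cm}")
    return NormalizedEnergetics(
        ke_norm_flow=kf, el_norm_flow=ef,
        ke_norm_flow_length=kf / length_cm, el_norm_flow_length=ef / length_cm)
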