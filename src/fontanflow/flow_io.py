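"""Read, write, validate and precondition 4D phase-contrast velocity data.

A 4D flow acquisition measures the three-directional blood velocity on a 3D
voxel grid at a number of reconstructed cardiac phases.  Internally the
velocity is held in SI units (m/s) on a 5-axis array ``(nx, ny, nz, n_phases,
3)``; the velocity-encoding limit (VENC) is kept in cm/s, the unit in which it
is prescribed at the scanner, and converted at the boundary.

On disk each velocity component is one 4D NIfTI volume (phase stacked as the
4th axis) alongside a plain-text sidecar carrying VENC, RR interval and phase
count.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ContractError, FormatError, MetadataError

log = logging.getLogger(__name__)

_COMPONENT_SUFFIXES = ("vx", "vy", "vz")


@dataclasses.dataclass(frozen=True)
class AcquisitionMeta:
    """Physical metadata of a 4D flow acquisition.

    Parameters
    ----------
    voxel_spacing : triple of float
        Voxel edge length per axis, mm.
    n_phases : int
        Reconstructed cardiac phases per cycle.
    venc_cm_s : float
        Velocity encoding limit, cm/s. Velocities beyond ±VENC alias.
    rr_interval_ms : float
        Mean cardiac cycle duration, ms.
    origin : triple of float
        World (mm) position of voxel (0, 0, 0), RAS convention.
    orientation : 3x3 array
        Orthonormal voxel-axes → world rotation.
    """

    voxel_spacing: tuple[float, float, float]
    n_phases: int
    venc_cm_s: float
    rr_interval_ms: float = 1000.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        sp = np.asarray(self.voxel_spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise MetadataError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        if self.n_phases < 1:
            raise MetadataError(f"n_phases must be >= 1, got {self.n_phases}")
        if not self.venc_cm_s > 0:
            raise MetadataError(f"venc_cm_s must be positive, got {self.venc_cm_s}")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise MetadataError("orientation must be a 3x3 orthonormal matrix")

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_spacing, dtype=float)

    @property
    def venc_m_s(self) -> float:
        return self.venc_cm_s / 100.0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """Voxel index → world mm homogeneous transform (voxel-centered, RAS)."""
        A = np.eye(4)
        A[:3, :3] = np.asarray(self.orientation, float) * self.spacing[np.newaxis, :]
        A[:3, 3] = np.asarray(self.origin, float)
        return A

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, float))
        return (ijk @ (np.asarray(self.orientation, float) * self.spacing).T) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, float))
        M = np.asarray(self.orientation, float) * self.spacing[np.newaxis, :]
        return (xyz - np.asarray(self.origin)) @ np.linalg.inv(M).T


@dataclasses.dataclass
class VelocityField4D:
    """Three-directional velocity (m/s) on a voxel grid across cardiac phases.

    ``values`` has shape ``(nx, ny, nz, n_phases, 3)``; the optional
    ``magnitude`` image (``(nx, ny, nz, n_phases)``, arbitrary units) weights
    the time-averaged speed reconstruction used for segmentation.
    """

    values: np.ndarray
    meta: AcquisitionMeta
    magnitude: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 5 or v.shape[4] != 3:
            raise FormatError(f"velocity array must be (nx,ny,nz,phase,3), got {v.shape}")
        if v.shape[3] != self.meta.n_phases:
            raise FormatError(
                f"phase axis length {v.shape[3]} != meta.n_phases {self.meta.n_phases}")
        if not np.all(np.isfinite(v)):
            raise FormatError("velocity values must all be finite")
        self.values = v
        if self.magnitude is not None:
            m = np.asarray(self.magnitude, dtype=np.float64)
            if m.shape != v.shape[:4]:
                raise FormatError(
                    f"magnitude shape {m.shape} does not match velocity grid {v.shape[:4]}")
            self.magnitude = m

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def speed(self) -> np.ndarray:
        """Voxel-wise speed |v| per phase, m/s."""
        return np.linalg.norm(self.values, axis=-1)


@dataclasses.dataclass
class VesselMask:
    """Binary vessel region of interest on the acquisition grid."""

    values: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self):
        m = np.asarray(self.values)
        if m.ndim != 3:
            raise FormatError(f"mask must be a 3-axis array, got shape {m.shape}")
        self.values = m.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self):
        if self.n_voxels == 0:
            raise ContractError("mask has no foreground voxels")


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def write_velocity_field(field: VelocityField4D, out_dir, prefix: str = "flow",
                         compress: bool = False) -> dict[str, Path]:
    """Write one 4D NIfTI per velocity component plus a key=value sidecar.

    Values are stored in float32 m/s; round-trip is lossless within float32
    quantization.  Returns the written paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    affine = field.meta.affine
    paths: dict[str, Path] = {}
    for c, suffix in enumerate(_COMPONENT_SUFFIXES):
        p = out_dir / f"{prefix}_{suffix}{ext}"
        img = nib.Nifti1Image(field.values[..., c].astype(np.float32), affine)
        img.header.set_xyzt_units("mm", "msec")
        nib.save(img, p)
        paths[suffix] = p
    if field.magnitude is not None:
        p = out_dir / f"{prefix}_mag{ext}"
        nib.save(nib.Nifti1Image(field.magnitude.astype(np.float32), affine), p)
        paths["mag"] = p
    sidecar = out_dir / f"{prefix}_meta.txt"
    with open(sidecar, "w") as fh:
        fh.write(f"venc_cm_s={field.meta.venc_cm_s!r}\n")
        fh.write(f"rr_interval_ms={field.meta.rr_interval_ms!r}\n")
        fh.write(f"n_phases={field.meta.n_phases}\n")
    paths["sidecar"] = sidecar
    return paths


def _read_sidecar(path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = float(v.strip())
    return out


def read_velocity_field(component_paths: Sequence, sidecar_path,
                        magnitude_path=None) -> VelocityField4D:
    """Read a velocity field from three per-component NIfTI files + sidecar.

    Components are ordered (vx, vy, vz).  Grids must be congruent across
    components; VENC must be present in the sidecar.
    """
    if len(component_paths) != 3:
        raise FormatError(f"expected 3 component paths, got {len(component_paths)}")
    imgs = [nib.load(str(p)) for p in component_paths]
    shapes = [img.shape for img in imgs]
    if len(set(shapes)) != 1:
        raise FormatError(f"component spatial shapes differ: {shapes}")
    affines = [img.affine for img in imgs]
    if not all(np.allclose(a, affines[0], atol=1e-4) for a in affines):
        raise FormatError("component affines (spacing/orientation) differ")
    meta_kv = _read_sidecar(sidecar_path)
    if "venc_cm_s" not in meta_kv:
        raise MetadataError(f"sidecar {sidecar_path} lacks required key venc_cm_s")
    data = [np.asanyarray(img.dataobj, dtype=np.float64) for img in imgs]
    data = [d[..., np.newaxis] if d.ndim == 3 else d for d in data]
    if len({d.shape for d in data}) != 1:
        raise FormatError("component phase counts differ")
    values = np.stack(data, axis=-1)

    A = affines[0]
    spacing = np.linalg.norm(A[:3, :3], axis=0)
    R = A[:3, :3] / spacing[np.newaxis, :]
    meta = AcquisitionMeta(
        voxel_spacing=tuple(spacing),
        n_phases=int(meta_kv.get("n_phases", values.shape[3])),
        venc_cm_s=meta_kv["venc_cm_s"],
        rr_interval_ms=meta_kv.get("rr_interval_ms", 1000.0),
        origin=tuple(A[:3, 3]),
        orientation=tuple(map(tuple, R.T)),
    )
    if meta.n_phases != values.shape[3]:
        raise FormatError(
            f"sidecar n_phases {meta.n_phases} != image phase axis {values.shape[3]}")
    magnitude = None
    if magnitude_path is not None:
        mimg = nib.load(str(magnitude_path))
        magnitude = np.asanyarray(mimg.dataobj, dtype=np.float64)
        if magnitude.ndim == 3:
            magnitude = magnitude[..., np.newaxis]
    return VelocityField4D(values=values, meta=meta, magnitude=magnitude)


def read_velocity_dir(directory, prefix: str = "flow") -> VelocityField4D:
    """Convenience reader matching :func:`write_velocity_field` file layout."""
    directory = Path(directory)
    comps = []
    for suffix in _COMPONENT_SUFFIXES:
        cands = [directory / f"{prefix}_{suffix}.nii", directory / f"{prefix}_{suffix}.nii.gz"]
        hit = next((c for c in cands if c.exists()), None)
        if hit is None:
            raise FormatError(f"missing component file {prefix}_{suffix}.nii[.gz] in {directory}")
        comps.append(hit)
    mag = next((c for c in (directory / f"{prefix}_mag.nii", directory / f"{prefix}_mag.nii.gz")
                if c.exists()), None)
    return read_velocity_field(comps, directory / f"{prefix}_meta.txt", mag)


def write_mask(mask: VesselMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), mask.meta.affine), path)
    return path


def read_mask(path, meta: AcquisitionMeta | None = None) -> VesselMask:
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj) > 0
    if meta is None:
        A = img.affine
        spacing = np.linalg.norm(A[:3, :3], axis=0)
        meta = AcquisitionMeta(voxel_spacing=tuple(spacing), n_phases=1, venc_cm_s=80.0,
                               origin=tuple(A[:3, 3]),
                               orientation=tuple(map(tuple, (A[:3, :3] / spacing).T)))
    return VesselMask(values=values, meta=meta)


# ---------------------------------------------------------------------------
# Preconditioning
# ---------------------------------------------------------------------------

_CROSS6 = np.zeros((3, 3, 3), dtype=bool)
_CROSS6[0, 1, 1] = _CROSS6[2, 1, 1] = True
_CROSS6[1, 0, 1] = _CROSS6[1, 2, 1] = True
_CROSS6[1, 1, 0] = _CROSS6[1, 1, 2] = True


def antialias_correct(field: VelocityField4D, max_passes: int = 30
                      ) -> tuple[VelocityField4D, int]:
    """Correct VENC-aliased (wrapped) velocities.

    Each component/phase volume is treated as a wrapped phase map
    (±VENC ↔ ±π) and unwrapped with the 3D Herraez algorithm, anchored so the
    majority of voxels (static background) keeps its value; every shift is an
    exact multiple of 2·VENC, so noise is preserved.  A verification pass then
    re-applies the 6-neighborhood-median test (a voxel discordant with its
    neighborhood median by more than VENC is shifted by the nearest multiple
    of 2·VENC toward it) until nothing is flagged, which makes the operation
    idempotent on its own output.  Returns the corrected field and the number
    of voxel corrections applied (0 for clean fields).

    A pure neighborhood-median detector cannot flag contiguous wrapped cores
    (their neighbors wrap too), hence the global unwrap as the primary step.
    """
    venc = field.meta.venc_m_s
    v = field.values.copy()
    total = 0
    from skimage.restoration import unwrap_phase

    for t in range(v.shape[3]):
        for c in range(3):
            comp = v[..., t, c]
            ph = comp * (np.pi / venc)
            un = np.asarray(unwrap_phase(ph))
            k = np.rint((un - ph) / (2.0 * np.pi))
            k -= np.rint(np.median(k))  # anchor to the unaliased majority
            nz = k != 0
            if nz.any():
                comp[nz] += 2.0 * venc * k[nz]
                total += int(nz.sum())
    converged = False
    for _ in range(max_passes):
        changed = 0
        for t in range(v.shape[3]):
            for c in range(3):
                comp = v[..., t, c]
                med = ndimage.median_filter(comp, footprint=_CROSS6, mode="nearest")
                k = np.rint((med - comp) / (2.0 * venc))
                flag = (np.abs(comp - med) > venc) & (k != 0)
                n = int(flag.sum())
                if n:
                    comp[flag] += 2.0 * venc * k[flag]
                    changed += n
        total += changed
        if changed == 0:
            converged = True
            break
    if not converged:
        log.warning("antialias_correct verification still flagging after %d passes",
                    max_passes)
    if total:
        log.info("antialias_correct: corrected %d voxel entries", total)
    out = VelocityField4D(values=v, meta=field.meta, magnitude=field.magnitude)
    return out, total


def magnitude_weighted_speed(field: VelocityField4D) -> np.ndarray:
    """Magnitude-weighted, phase-averaged speed image (m/s) for segmentation.

    Per voxel this is the phase-average of |v| weighted by the magnitude
    image; without a magnitude image, weights are uniform (a warning is
    logged).  The result is nonnegative everywhere.
    """
    speed = field.speed()
    if field.magnitude is None:
        log.warning("no magnitude image; using uniform weights for speed averaging")
        return speed.mean(axis=3)
    w = field.magnitude
    wsum = w.sum(axis=3)
    out = np.zeros(field.spatial_shape)
    ok = wsum > 0
    out[ok] = (speed * w).sum(axis=3)[ok] / wsum[ok]
    return out
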