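"""Semi-automatic vessel lumen segmentation from time-averaged speed images.

The workflow mirrors seed-based commercial tools: threshold the
magnitude-weighted speed image, keep the 26-connected component(s) containing
user seeds, then regularize with a 1-voxel morphological closing and hole
filling.  Anatomical extent (e.g. cutting the caval veins at defined levels,
excluding device artefacts) is expressed with oriented cut planes in world mm.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import ContractError, EmptySegmentationError
from .flow_io import AcquisitionMeta, VesselMask

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.10  # of the 99th-percentile speed


def threshold_region_grow(speed_image: np.ndarray, meta: AcquisitionMeta,
                          seeds, threshold: float | None = None,
                          relative: bool = False) -> VesselMask:
    """Segment the lumen as seeded connected components of a speed threshold.

    Parameters
    ----------
    speed_image : (nx, ny, nz) array
        Time-averaged speed, m/s (see ``magnitude_weighted_speed``).
    seeds : sequence of voxel index triples
        At least one seed inside the vessel.
    threshold : float, optional
        Speed threshold in m/s, or a fraction of the 99th-percentile speed
        when ``relative`` is true.  Default: 0.10 of the 99th percentile.
    """
    speed = np.asarray(speed_image, dtype=float)
    if speed.ndim != 3:
        raise ContractError(f"speed image must be 3D, got shape {speed.shape}")
    seeds = [tuple(int(round(c)) for c in s) for s in np.atleast_2d(seeds)]
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, speed.shape)):
            raise ContractError(f"seed {s} lies outside the image {speed.shape}")
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * np.percentile(speed, 99)
        log.info("segmentation threshold defaulted to %.4g m/s", threshold)
    elif relative:
        threshold = float(threshold) * np.percentile(speed, 99)
    if not threshold > 0:
        raise ContractError(f"threshold must be positive, got {threshold}")

    fg = speed >= threshold
    labels = measure.label(fg, connectivity=3)
    keep = {labels[s] for s in seeds if labels[s] != 0}
    if not keep:
        raise EmptySegmentationError(
            "no voxel at/above the threshold is connected to any seed")
    mask = np.isin(labels, sorted(keep))
    mask = ndimage.binary_closing(mask, structure=morphology.ball(1))
    mask = ndimage.binary_fill_holes(mask)
    for s in seeds:  # closing/filling never removes seeds inside the component
        mask[s] = True
    return VesselMask(values=mask, meta=meta)


def restrict_roi(mask: VesselMask, cut_planes) -> VesselMask:
    """Clip a mask with oriented planes given in world mm.

    Each plane is a pair ``(origin, inward_normal)``; voxels on the outward
    side of any plane (``(p - origin) . n < 0``) are removed.
    """
    planes = list(cut_planes)
    if not planes:
        return VesselMask(values=mask.values.copy(), meta=mask.meta)
    ijk = np.argwhere(mask.values)
    if len(ijk) == 0:
        raise EmptySegmentationError("mask is already empty")
    world = mask.meta.voxel_to_world(ijk)
    keep = np.ones(len(ijk), dtype=bool)
    for origin, normal in planes:
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        keep &= (world - np.asarray(origin, float)) @ n >= 0.0
    if not keep.any():
        raise EmptySegmentationError("all voxels removed by the cut planes")
    out = np.zeros_like(mask.values)
    kept = ijk[keep]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return VesselMask(values=out, meta=mask.meta)
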