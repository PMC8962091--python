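"""End-to-end orchestration: phantom/input → segmentation → segments → energetics.

A run is driven by a YAML config (echoed, with its SHA-256, into the output
directory) and a seed; all CSV outputs use fixed number formatting so that a
re-run with the same config and seed is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, flow_io, geometry, segmentation, synthetic
from .energetics import EnergeticsConfig, compute_energetics, normalize_energetics
from .errors import ContractError, FontanFlowError

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"
_CSV_KW = dict(index=False, lineterminator="\n", float_format=_FLOAT_FMT)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ContractError(f"config {path} did not parse to a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()


def _validate_config(cfg: dict):
    if "phantom" not in cfg and "inputs" not in cfg:
        raise ContractError("config must define either 'phantom' or 'inputs'")
    if "inputs" in cfg:
        inp = cfg["inputs"]
        if "velocity_dir" not in inp:
            raise ContractError("inputs config requires 'velocity_dir'")
        if "mask" not in inp and not cfg.get("segmentation", {}).get("seeds_voxel"):
            raise ContractError("inputs config requires a 'mask' or segmentation seeds")


def _phantom_spec_from_config(cfg: dict, seed: int | None) -> synthetic.PhantomSpec:
    kw = dict(cfg.get("phantom", {}))
    if seed is not None:
        kw["seed"] = seed
    if "waveform" in kw and kw["waveform"] is not None:
        kw["waveform"] = np.asarray(kw["waveform"], float)
    return synthetic.PhantomSpec(**kw)


@dataclasses.dataclass
class PipelineResult:
    out_dir: Path
    config_hash: str
    total: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None
    csa: dict = dataclasses.field(default_factory=dict)
    flows: dict = dataclasses.field(default_factory=dict)
    cohort: dict = dataclasses.field(default_factory=dict)


def run_pipeline(cfg: dict, out_dir, seed: int | None = None,
                 stages: str = "all") -> PipelineResult:
    """Execute the analysis pipeline and write a versioned results directory.

    Stages (cumulative): ``phantom`` (generate/write the field), ``segment``
    (speed image + lumen mask), ``energetics`` (total KE/EL), ``segmental``
    (centerline, 5 segments, flows, normalized energetics, CSA), ``all``.
    Any stage error propagates, prefixed with the stage name.
    """
    t0 = time.time()
    _validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    with open(out_dir / "run_config.yaml", "w") as fh:
        fh.write(f"# config_sha256: {chash}\n")
        yaml.safe_dump(cfg, fh, sort_keys=True)
    result = PipelineResult(out_dir=out_dir, config_hash=chash)
    order = ["phantom", "segment", "energetics", "segmental", "all"]
    upto = order.index(stages)
    ecfg = EnergeticsConfig(**cfg.get("energetics", {}))
    seg_cfg = cfg.get("segmentation", {})
    segm_cfg = cfg.get("segments", {})

    phantom = None
    try:
        if "phantom" in cfg:
            spec = _phantom_spec_from_config(cfg, seed)
            phantom = synthetic.generate_phantom(spec)
            field = phantom.field
            flow_io.write_velocity_field(field, out_dir, prefix="phantom")
            seeds_world = {k: list(map(float, v)) for k, v in phantom.seeds.items()}
        else:
            inp = cfg["inputs"]
            field = flow_io.read_velocity_dir(inp["velocity_dir"],
                                              inp.get("prefix", "flow"))
            seeds_world = cfg.get("segments", {}).get("endpoint_seeds_world", {})
    except FontanFlowError as exc:
        raise type(exc)(f"[stage phantom/load] {exc}") from exc
    log.info("stage load/phantom done (%.1fs)", time.time() - t0)
    if upto == 0:
        return result

    try:
        field, n_corrected = flow_io.antialias_correct(field)
        speed = flow_io.magnitude_weighted_speed(field)
        if "inputs" in cfg and "mask" in cfg["inputs"]:
            mask = flow_io.read_mask(cfg["inputs"]["mask"], field.meta)
        elif phantom is not None and seg_cfg.get("use_ground_truth_mask", False):
            mask = phantom.mask
        else:
            if phantom is not None:
                # seeds: pull each endpoint a few mm inward along its branch axis
                seeds_vox = []
                for k, pt in phantom.seeds.items():
                    lab = k if k in phantom.centerline else next(iter(phantom.centerline))
                    axis = phantom.centerline[lab]
                    inner = axis[max(len(axis) - 4, 0)] if np.allclose(axis[-1], pt) \
                        else axis[min(3, len(axis) - 1)]
                    seeds_vox.append(np.rint(field.meta.world_to_voxel(inner)[0]).astype(int))
            else:
                seeds_vox = [tuple(s) for s in seg_cfg["seeds_voxel"]]
            mask = segmentation.threshold_region_grow(
                speed, field.meta, seeds_vox, threshold=seg_cfg.get("threshold"),
                relative=seg_cfg.get("relative_threshold", False))
        planes = seg_cfg.get("cut_planes")
        if planes:
            mask = segmentation.restrict_roi(
                mask, [(p["origin"], p["normal"]) for p in planes])
        flow_io.write_mask(mask, out_dir / "mask.nii")
    except FontanFlowError as exc:
        raise type(exc)(f"[stage segment] {exc}") from exc
    log.info("stage segment done (%.1fs, %d corrected voxels)", time.time() - t0,
             n_corrected)
    if upto == 1:
        return result

    try:
        series = compute_energetics(field, mask, ecfg)
        total = pd.DataFrame({
            "phase": np.arange(field.meta.n_phases),
            "ke_mJ": series.ke_per_phase,
            "el_mW": series.el_per_phase,
        })
        summary = pd.DataFrame([{
            "ke_cycle_avg_mJ": series.ke_cycle_avg,
            "el_cycle_avg_mW": series.el_cycle_avg,
            "n_voxels": mask.n_voxels,
            "antialias_corrected_voxels": n_corrected,
        }])
        total.to_csv(out_dir / "total_energetics_per_phase.csv", **_CSV_KW)
        result.total = summary
    except FontanFlowError as exc:
        raise type(exc)(f"[stage energetics] {exc}") from exc
    log.info("stage energetics done (%.1fs)", time.time() - t0)

    if upto >= 3 or stages == "all":
        try:
            if len(seeds_world) >= 3:
                tree = geometry.extract_centerline(
                    mask, {k: np.asarray(v, float) for k, v in seeds_world.items()})
                segs = geometry.label_segments(
                    mask, tree, confluence_margin_mm=segm_cfg.get("confluence_margin_mm"))
                offset = segm_cfg.get("plane_offset_mm", 5.0)
                rows = []
                inflow_total = 0.0
                branch_flow = {}
                for lab in tree.branches:
                    br = tree.branches[lab]
                    s_plane = min(segs.confluence_margin_mm + offset,
                                  0.9 * br.length_mm)
                    pts, tangents = br.resample(1.0)
                    i = min(int(round(s_plane)), len(pts) - 1)
                    # orient the normal along the branch through-flow:
                    # inflow branches flow toward the junction (-tangent).
                    normal = -tangents[i] if lab in ("fontan_tunnel", "svc") \
                        else tangents[i]
                    q_per_phase, q_mean = geometry.plane_flow(
                        field, mask, pts[i], normal)
                    branch_flow[lab] = q_mean
                    if lab in ("fontan_tunnel", "svc"):
                        inflow_total += q_mean
                if inflow_total <= 0:
                    inflow_total = sum(abs(q) for q in branch_flow.values()) / 2.0
                norm_total = normalize_energetics(series.ke_cycle_avg,
                                                  series.el_cycle_avg, inflow_total)
                result.total = summary.assign(
                    inflow_l_min=inflow_total,
                    ke_norm_flow_mJ_per_L_min=norm_total.ke_norm_flow,
                    el_norm_flow_mW_per_L_min=norm_total.el_norm_flow)

                bsa = segm_cfg.get("bsa_m2", 1.6)
                for lab, seg_mask in segs.masks.items():
                    seg_vm = flow_io.VesselMask(values=seg_mask, meta=mask.meta)
                    row = dict(segment=lab, n_voxels=int(seg_mask.sum()),
                               length_cm=segs.lengths_cm[lab],
                               included=segs.included[lab])
                    if seg_mask.sum() == 0 or not segs.included[lab]:
                        rows.append(row)
                        continue
                    seg_series = compute_energetics(field, seg_vm, ecfg)
                    row.update(ke_cycle_avg_mJ=seg_series.ke_cycle_avg,
                               el_cycle_avg_mW=seg_series.el_cycle_avg)
                    if lab == "confluence":
                        norm = normalize_energetics(seg_series.ke_cycle_avg,
                                                    seg_series.el_cycle_avg,
                                                    inflow_total)
                        row.update(flow_l_min=inflow_total,
                                   ke_norm_flow=norm.ke_norm_flow,
                                   el_norm_flow=norm.el_norm_flow)
                    else:
                        q = abs(branch_flow[lab])
                        norm = normalize_energetics(seg_series.ke_cycle_avg,
                                                    seg_series.el_cycle_avg,
                                                    q, segs.lengths_cm[lab])
                        row.update(flow_l_min=q,
                                   ke_norm_flow=norm.ke_norm_flow,
                                   el_norm_flow=norm.el_norm_flow,
                                   ke_norm_flow_length=norm.ke_norm_flow_length,
                                   el_norm_flow_length=norm.el_norm_flow_length)
                        prof = geometry.csa_profile(seg_vm, tree.branches[lab], bsa,
                                                    arc_start_mm=segs.confluence_margin_mm)
                        row.update(mean_csa_cm2=prof.mean_csa_cm2,
                                   mean_csa_bsa=prof.mean_csa_bsa)
                        pd.DataFrame({
                            "arclength_mm": prof.positions_mm,
                            "csa_cm2": prof.csa_cm2,
                            "csa_bsa_cm2_per_m2": prof.csa_bsa,
                        }).to_csv(out_dir / f"csa_{lab}.csv", **_CSV_KW)
                        result.csa[lab] = prof
                    rows.append(row)
                seg_df = pd.DataFrame(rows)
                seg_df.to_csv(out_dir / "segments.csv", **_CSV_KW)
                result.segments = seg_df
                result.flows = branch_flow
                cl_rows = []
                for lab, br in tree.branches.items():
                    for p, s in zip(br.points, br.arclength):
                        cl_rows.append(dict(x_mm=p[0], y_mm=p[1], z_mm=p[2],
                                            arclength_mm=s, branch=lab))
                pd.DataFrame(cl_rows).to_csv(out_dir / "centerline.csv", **_CSV_KW)
                import nibabel as nib
                nib.save(nib.Nifti1Image(segs.label_map(), mask.meta.affine),
                         out_dir / "segment_labels.nii")
            else:
                log.info("fewer than 3 labeled seeds: skipping segmental analysis")
        except FontanFlowError as exc:
            raise type(exc)(f"[stage segmental] {exc}") from exc
        log.info("stage segmental done (%.1fs)", time.time() - t0)

    result.total.to_csv(out_dir / "total_energetics.csv", **_CSV_KW)

    if "cohort" in cfg and (stages == "all"):
        try:
            ccfg = cfg["cohort"]
            if "csv" in ccfg:
                table = synthetic.read_cohort_csv(ccfg["csv"])
            else:
                spec = synthetic.default_cohort_spec(
                    n=ccfg.get("n", 62), seed=seed if seed is not None
                    else ccfg.get("seed", 0))
                table = synthetic.generate_cohort(spec)
                synthetic.write_cohort_csv(table, spec, out_dir / "cohort.csv")
            desc = cohort_stats.describe(table)
            desc.to_csv(out_dir / "cohort_describe.csv", **_CSV_KW)
            pairs = [tuple(p) for p in ccfg.get("pairs", [])] or [
                ("ke_norm_flow", "ct1"), ("el_norm_flow", "ct1"),
                ("ke_norm_flow", "peak_vo2"), ("el_norm_flow", "peak_vo2")]
            pairs = [p for p in pairs if p[0] in table and p[1] in table]
            corr = cohort_stats.correlation_table(table, pairs)
            corr.to_csv(out_dir / "cohort_correlations.csv", **_CSV_KW)
            result.cohort = {"describe": desc, "correlations": corr}
        except FontanFlowError as exc:
            raise type(exc)(f"[stage cohort-stats] {exc}") from exc
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return result
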