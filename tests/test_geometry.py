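import numpy as np
import pytest

import fontanflow as ff
from fontanflow.errors import (ContractError, GeometryError, LabelingError,
                               TopologyError)
from fontanflow.geometry import Branch

TUBE_CSA_CM2 = np.pi * 0.8**2  # R = 8 mm


class TestHaycockBsa:
    def test_reference_adult(self):
        # direct evaluation of the power law for 70 kg / 170 cm
        assert ff.haycock_bsa(70, 170) == pytest.approx(1.8257, abs=2e-3)

    def test_weight_power_law(self):
        assert ff.haycock_bsa(80, 165) / ff.haycock_bsa(40, 165) == \
            pytest.approx(2**0.5378, rel=1e-12)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ContractError):
            ff.haycock_bsa(70, 0)
        with pytest.raises(ContractError):
            ff.haycock_bsa(-1, 170)


class TestCenterline:
    def test_straight_tube_single_branch_full_length(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        assert tree.junction is None
        assert len(tree.branches) == 1
        br = next(iter(tree.branches.values()))
        assert abs(br.length_mm - 100.0) <= 2.0  # within 2 voxels
        # every node within 1 voxel of the analytic axis (z-axis)
        off_axis = np.linalg.norm(br.points[:, :2], axis=1)
        assert off_axis.max() <= 1.0
        assert np.all(np.diff(br.arclength) > 0)

    def test_tcpc_four_branches_one_junction(self, tcpc_1mm, tcpc_tree):
        assert set(tcpc_tree.branches) == {"fontan_tunnel", "svc", "lpa", "rpa"}
        assert tcpc_tree.junction is not None
        # junction near the geometric center
        assert np.linalg.norm(tcpc_tree.junction) <= 5.0
        for lab, br in tcpc_tree.branches.items():
            expected = tcpc_1mm.centerline[lab][-1]
            assert np.linalg.norm(br.points[-1] - expected) <= 2.0

    def test_degenerate_mask_raises(self, simple_meta):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = m[2, 2, 3] = True
        with pytest.raises(TopologyError):
            ff.extract_centerline(ff.VesselMask(values=m, meta=simple_meta),
                                  {"a": (2, 2, 2), "b": (2, 2, 3)})

    def test_disconnected_seeds_raise(self, simple_meta):
        m = np.zeros((12, 5, 5), dtype=bool)
        m[0:4, 1:4, 1:4] = True
        m[8:12, 1:4, 1:4] = True
        with pytest.raises(TopologyError):
            ff.extract_centerline(ff.VesselMask(values=m, meta=simple_meta),
                                  {"a": (1, 2, 2), "b": (10, 2, 2)})


class TestSegments:
    def test_tcpc_label_agreement_against_generator(self, tcpc_1mm, tcpc_tree):
        segs = ff.label_segments(
            tcpc_1mm.mask, tcpc_tree,
            confluence_margin_mm=tcpc_1mm.ground_truth["confluence_radius_mm"])
        lm = segs.label_map()
        order = {lab: i + 1 for i, lab in enumerate(segs.label_order)}
        agree = total = 0
        for gval, name in tcpc_1mm.label_names.items():
            sel = tcpc_1mm.labels == gval
            total += sel.sum()
            agree += (lm[sel] == order[name]).sum()
        assert agree / total >= 0.90

    def test_segment_masks_disjoint_and_cover_mask(self, tcpc_1mm, tcpc_tree):
        segs = ff.label_segments(tcpc_1mm.mask, tcpc_tree)
        stack = np.stack(list(segs.masks.values()))
        assert stack.sum(axis=0).max() == 1  # pairwise disjoint
        assert np.array_equal(stack.any(axis=0), tcpc_1mm.mask.values)

    def test_short_branch_flagged_excluded(self):
        lengths = {"fontan_tunnel": 60.0, "svc": 50.0, "lpa": 22.0, "rpa": 60.0}
        spec = ff.PhantomSpec(geometry="tcpc_junction", branch_lengths_mm=lengths,
                              n_phases=1, spacing_mm=1.0, seed=4)
        ph = ff.generate_phantom(spec)
        tree = ff.extract_centerline(ph.mask, ph.seeds)
        segs = ff.label_segments(ph.mask, tree, confluence_margin_mm=9.0)
        # lpa included length ~ (22 - 9) mm = 1.3 cm < 1.5 cm
        assert segs.lengths_cm["lpa"] < 1.5
        assert not segs.included["lpa"]
        assert segs.included["fontan_tunnel"]

    def test_unbranched_centerline_raises(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        with pytest.raises(LabelingError):
            ff.label_segments(tube_1mm.mask, tree)


class TestCsaProfile:
    def test_straight_tube_within_5pct(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        br = next(iter(tree.branches.values()))
        prof = ff.csa_profile(tube_1mm.mask, br, bsa_m2=1.6)
        assert prof.mean_csa_cm2 == pytest.approx(TUBE_CSA_CM2, rel=0.05)

    def test_tilted_tube_within_5pct(self, tilted_tube_1mm):
        # perpendicularity is w.r.t. the centerline, not the grid
        tree = ff.extract_centerline(tilted_tube_1mm.mask, tilted_tube_1mm.seeds)
        br = next(iter(tree.branches.values()))
        prof = ff.csa_profile(tilted_tube_1mm.mask, br, bsa_m2=1.6)
        assert prof.mean_csa_cm2 == pytest.approx(TUBE_CSA_CM2, rel=0.05)

    def test_bsa_normalization_is_division(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        br = next(iter(tree.branches.values()))
        prof = ff.csa_profile(tube_1mm.mask, br, bsa_m2=1.6)
        assert prof.mean_csa_bsa == pytest.approx(prof.mean_csa_cm2 / 1.6, rel=1e-12)

    def test_position_count_at_1mm_interval(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        br = next(iter(tree.branches.values()))
        sub = Branch(label="sub", points=br.points, arclength=br.arclength)
        prof = ff.csa_profile(tube_1mm.mask, sub, bsa_m2=1.6, arc_end_mm=50.0)
        # 0..50 mm inclusive at 1 mm -> 51 positions (none skipped mid-tube)
        assert len(prof.positions_mm) + prof.n_skipped >= 51
        assert prof.positions_mm.max() <= 50.0

    def test_nonpositive_bsa_raises(self, tube_1mm):
        tree = ff.extract_centerline(tube_1mm.mask, tube_1mm.seeds)
        br = next(iter(tree.branches.values()))
        with pytest.raises(ContractError):
            ff.csa_profile(tube_1mm.mask, br, bsa_m2=0.0)


class TestPlaneFlow:
    def test_uniform_axial_flow_closed_arithmetic(self):
        # 0.1 m/s through a 2 cm^2 rectangular lumen -> 1.2 L/min
        meta = ff.AcquisitionMeta(voxel_spacing=(1, 1, 1), n_phases=1, venc_cm_s=80)
        shape = (24, 14, 20)
        vals = np.zeros(shape + (1, 3))
        mask = np.zeros(shape, dtype=bool)
        mask[2:22, 2:12, :] = True  # 20 x 10 mm cross-section
        vals[mask, :, 2] = 0.1
        field = ff.VelocityField4D(values=vals, meta=meta)
        # quarter-voxel plane offset avoids nearest-neighbor ties at the walls
        q, qm = ff.plane_flow(field, ff.VesselMask(values=mask, meta=meta),
                              origin=(11.75, 6.75, 10.0), normal=(0, 0, 1),
                              half_extent_mm=20.0)
        assert qm == pytest.approx(1.2, rel=0.02)

    def test_poiseuille_midplane_recovers_generator_flow(self, tube_1mm):
        q, qm = ff.plane_flow(tube_1mm.clean_field, tube_1mm.mask,
                              origin=(0, 0, 50.0), normal=(0, 0, 1))
        assert qm == pytest.approx(3.0, rel=0.02)

    def test_zero_field_zero_flow(self, tube_1mm):
        zero = ff.VelocityField4D(values=np.zeros_like(tube_1mm.clean_field.values),
                                  meta=tube_1mm.clean_field.meta)
        q, qm = ff.plane_flow(zero, tube_1mm.mask, (0, 0, 50.0), (0, 0, 1))
        assert qm == 0

    def test_plane_missing_mask_raises(self, tube_1mm):
        with pytest.raises(GeometryError):
            ff.plane_flow(tube_1mm.clean_field, tube_1mm.mask,
                          origin=(300.0, 300.0, 300.0), normal=(0, 0, 1),
                          half_extent_mm=5.0)


class TestMassConservation:
    def test_steady_tcpc_inflow_equals_outflow(self, tcpc_1mm, tcpc_tree):
        r_conf = tcpc_1mm.ground_truth["confluence_radius_mm"]
        flows = {}
        for lab, br in tcpc_tree.branches.items():
            pts, tangents = br.resample(1.0)
            i = int(round(r_conf + 5))
            normal = -tangents[i] if lab in ("fontan_tunnel", "svc") else tangents[i]
            _, qm = ff.plane_flow(tcpc_1mm.clean_field, tcpc_1mm.mask, pts[i], normal)
            flows[lab] = qm
        inflow = flows["fontan_tunnel"] + flows["svc"]
        outflow = flows["lpa"] + flows["rpa"]
        assert inflow == pytest.approx(outflow, rel=0.05)
        assert inflow == pytest.approx(3.0, rel=0.05)
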