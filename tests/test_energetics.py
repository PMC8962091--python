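import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fontanflow as ff
from fontanflow.energetics import dissipation_function, velocity_gradient_tensor
from fontanflow.errors import ContractError, NormalizationError

from conftest import box_field


def _box_mask(field, margin=0):
    m = np.ones(field.spatial_shape, dtype=bool)
    if margin:
        inner = np.zeros_like(m)
        inner[margin:-margin, margin:-margin, margin:-margin] = True
        m &= inner
    return ff.VesselMask(values=m, meta=field.meta)


class TestGradientTensor:
    def test_uniform_field_zero_tensor(self):
        field = box_field((6, 6, 6), 1, lambda X, Y, Z: (0.2 + 0 * X, 0 * X, 0 * X))
        G = velocity_gradient_tensor(field, _box_mask(field), 0)
        assert np.abs(G).max() == 0

    def test_linear_shear_exact_everywhere(self):
        # v_x = k*y with k = 10/s; central AND one-sided differences are exact
        k = 10.0
        field = box_field((6, 6, 6), 1,
                          lambda X, Y, Z: (k * Y * 1e-3, 0 * X, 0 * X))
        G = velocity_gradient_tensor(field, _box_mask(field), 0)
        np.testing.assert_allclose(G[0, 1], k, atol=1e-9)
        G[0, 1] = 0
        assert np.abs(G).max() < 1e-9

    def test_poiseuille_radial_gradient_exact_at_interior(self, tube_1mm):
        # the parabolic profile is quadratic, so central differences are exact
        field, mask = tube_1mm.clean_field, tube_1mm.mask
        G = velocity_gradient_tensor(field, mask, 0)
        R, Q = 0.008, 3.0 / 60e3
        vmax = 2 * Q / (np.pi * R**2)
        ijk = np.argwhere(mask.values)
        world = mask.meta.voxel_to_world(ijk) * 1e-3  # m
        interior = np.zeros(mask.values.shape, dtype=bool)
        from scipy import ndimage
        interior[tuple(ijk.T)] = True
        interior = ndimage.binary_erosion(interior, iterations=2)
        sel = interior[tuple(ijk.T)] & (np.abs(world[:, 2] - 0.05) < 0.04)
        analytic = -2 * vmax * world[sel, 0] / R**2
        numeric = G[2, 0][tuple(ijk[sel].T)]
        np.testing.assert_allclose(numeric, analytic, atol=1e-8)


class TestKineticEnergy:
    def test_zero_field_zero_ke(self, simple_meta):
        field = ff.VelocityField4D(values=np.zeros((5, 5, 5, 1, 3)), meta=simple_meta)
        assert ff.kinetic_energy(field, _box_mask(field))[0] == 0

    def test_uniform_speed_closed_arithmetic(self):
        # |v| = 0.5 m/s over 1000 voxels of 1 mm^3 at rho = 1060 -> 0.1325 mJ
        field = box_field((10, 10, 10), 1, lambda X, Y, Z: (0 * X, 0 * X, 0.5 + 0 * X))
        ke = ff.kinetic_energy(field, _box_mask(field))
        assert ke[0] == pytest.approx(0.1325, rel=1e-12)

    def test_poiseuille_matches_closed_form(self, tube_1mm):
        ke = ff.kinetic_energy(tube_1mm.clean_field, tube_1mm.mask)[0]
        assert ke == pytest.approx(tube_1mm.ground_truth["tube"]["ke_steady_mJ"],
                                   rel=0.02)


class TestViscousEnergyLoss:
    def test_uniform_translation_zero(self):
        field = box_field((6, 6, 6), 1, lambda X, Y, Z: (0.1 + 0 * X, -0.2 + 0 * X,
                                                         0.3 + 0 * X))
        assert ff.viscous_energy_loss_rate(field, _box_mask(field))[0] == 0

    def test_rigid_rotation_zero(self):
        # v = omega x r: antisymmetric gradients cancel in the strain sum
        om = 5.0
        field = box_field((8, 8, 8), 1,
                          lambda X, Y, Z: (-om * (Y - 3.5) * 1e-3,
                                           om * (X - 3.5) * 1e-3, 0 * X))
        el = ff.viscous_energy_loss_rate(field, _box_mask(field))[0]
        assert abs(el) < 1e-15

    def test_linear_shear_closed_arithmetic(self):
        # mu * k^2 * V with k = 10/s over V = 1 cm^3 -> 3.2e-4 mW
        k = 10.0
        field = box_field((10, 10, 10), 1,
                          lambda X, Y, Z: (k * Y * 1e-3, 0 * X, 0 * X))
        el = ff.viscous_energy_loss_rate(field, _box_mask(field))[0]
        assert el == pytest.approx(3.2e-4, rel=1e-12)

    def test_poiseuille_matches_closed_form(self, tube_1mm):
        el = ff.viscous_energy_loss_rate(tube_1mm.clean_field, tube_1mm.mask)[0]
        # 1 mm grid: boundary one-sided differences leave a ~10% deficit
        assert el == pytest.approx(tube_1mm.ground_truth["tube"]["el_steady_mW"],
                                   rel=0.12)

    def test_pure_expansion_killed_by_divergence_term(self):
        # v = c*r is pure dilation: full strain power equals (2/3) div^2
        c = 2.0
        field = box_field((8, 8, 8), 1,
                          lambda X, Y, Z: (c * X * 1e-3, c * Y * 1e-3, c * Z * 1e-3))
        mask = _box_mask(field)
        cfg_with = ff.EnergeticsConfig(include_divergence_term=True)
        cfg_without = ff.EnergeticsConfig(include_divergence_term=False)
        assert ff.viscous_energy_loss_rate(field, mask, cfg_with)[0] < 1e-15
        assert ff.viscous_energy_loss_rate(field, mask, cfg_without)[0] > 0

    def test_quadratic_flow_scaling(self, tube_1mm):
        field, mask = tube_1mm.clean_field, tube_1mm.mask
        el1 = ff.viscous_energy_loss_rate(field, mask)[0]
        ke1 = ff.kinetic_energy(field, mask)[0]
        alpha = 1.7
        scaled = ff.VelocityField4D(values=alpha * field.values, meta=field.meta)
        assert ff.viscous_energy_loss_rate(scaled, mask)[0] == \
            pytest.approx(alpha**2 * el1, rel=1e-12)
        assert ff.kinetic_energy(scaled, mask)[0] == \
            pytest.approx(alpha**2 * ke1, rel=1e-12)

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1), st.floats(-0.3, 0.3), st.floats(-0.3, 0.3))
    def test_el_invariant_under_uniform_velocity_addition(self, seed, ux, uz):
        rng = np.random.default_rng(seed)
        meta = ff.AcquisitionMeta(voxel_spacing=(1, 1, 1), n_phases=1, venc_cm_s=80)
        vals = rng.normal(0, 0.1, size=(6, 6, 6, 1, 3))
        field = ff.VelocityField4D(values=vals, meta=meta)
        mask = _box_mask(field)
        el0 = ff.viscous_energy_loss_rate(field, mask)[0]
        shifted = vals.copy()
        shifted[..., 0] += ux
        shifted[..., 2] += uz
        el1 = ff.viscous_energy_loss_rate(
            ff.VelocityField4D(values=shifted, meta=meta), mask)[0]
        assert el1 == pytest.approx(el0, rel=1e-9, abs=1e-15)

    def test_per_phase_sums_equal_density_map_integrals(self, simple_meta):
        rng = np.random.default_rng(7)
        meta = ff.AcquisitionMeta(voxel_spacing=(1, 1, 1), n_phases=3, venc_cm_s=80)
        field = ff.VelocityField4D(values=rng.normal(0, 0.1, (6, 6, 6, 3, 3)),
                                   meta=meta)
        mask = ff.VesselMask(values=rng.random((6, 6, 6)) > 0.3, meta=meta)
        series = ff.compute_energetics(field, mask, return_maps=True)
        vvox = 1e-9
        np.testing.assert_allclose(
            series.ke_density.sum(axis=(0, 1, 2)) * vvox * 1e3,
            series.ke_per_phase, rtol=1e-10)
        np.testing.assert_allclose(
            series.el_density.sum(axis=(0, 1, 2)) * vvox * 1e3,
            series.el_per_phase, rtol=1e-10)

    def test_boundary_schemes_bracket_and_converge(self):
        # one-sided vs interior-only brackets shrink as the grid refines
        gaps = []
        for sp in (2.0, 1.0):
            spec = ff.PhantomSpec(geometry="straight_tube", radius_mm=8.0,
                                  length_mm=40.0, q_l_min=3.0, n_phases=1,
                                  spacing_mm=sp, seed=0)
            ph = ff.generate_phantom(spec)
            one = ff.viscous_energy_loss_rate(
                ph.clean_field, ph.mask,
                ff.EnergeticsConfig(boundary_scheme="one_sided"))[0]
            interior = ff.viscous_energy_loss_rate(
                ph.clean_field, ph.mask,
                ff.EnergeticsConfig(boundary_scheme="interior_only"))[0]
            assert interior <= one
            gaps.append(one - interior)
        assert gaps[1] < gaps[0]


class TestCycleAverageAndNormalization:
    def test_cycle_average_examples(self):
        assert ff.cycle_average([1.0, 3.0]) == 2.0
        assert ff.cycle_average([4.2]) == 4.2
        with pytest.raises(ContractError):
            ff.cycle_average([])

    def test_flow_normalization_matches_cohort_magnitudes(self):
        # 0.91 mJ at 3.5 L/min -> 0.26 mJ per L/min (total-connection scale)
        norm = ff.normalize_energetics(0.91, 0.26, 3.5)
        assert norm.ke_norm_flow == pytest.approx(0.26, abs=0.0001)
        # 0.34 mJ, 2.0 L/min, 5 cm -> 0.034 mJ per L/min per cm (conduit scale)
        norm = ff.normalize_energetics(0.34, 0.1, 2.0, length_cm=5.0)
        assert norm.ke_norm_flow_length == pytest.approx(0.034)

    def test_zero_energetics_normalize_to_zero(self):
        norm = ff.normalize_energetics(0.0, 0.0, 2.5, length_cm=4.0)
        assert norm.ke_norm_flow == 0 and norm.el_norm_flow_length == 0

    def test_nonpositive_inflow_or_length_raises(self):
        with pytest.raises(NormalizationError):
            ff.normalize_energetics(1.0, 1.0, 0.0)
        with pytest.raises(NormalizationError):
            ff.normalize_energetics(1.0, 1.0, 2.0, length_cm=-1.0)
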