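import numpy as np
import pytest

import fontanflow as ff


@pytest.fixture(scope="session")
def tube_1mm():
    """Steady Poiseuille tube, R = 8 mm, L = 100 mm, Q = 3 L/min, 1 mm grid."""
    spec = ff.PhantomSpec(geometry="straight_tube", radius_mm=8.0, length_mm=100.0,
                          q_l_min=3.0, n_phases=1, spacing_mm=1.0, seed=1)
    return ff.generate_phantom(spec)


@pytest.fixture(scope="session")
def tilted_tube_1mm():
    """Same tube tilted 30 degrees to the grid axes."""
    spec = ff.PhantomSpec(geometry="tilted_tube", radius_mm=8.0, length_mm=100.0,
                          q_l_min=3.0, tilt_deg=30.0, n_phases=1, spacing_mm=1.0, seed=1)
    return ff.generate_phantom(spec)


@pytest.fixture(scope="session")
def tcpc_1mm():
    """Steady four-branch cavopulmonary junction phantom on a 1 mm grid."""
    spec = ff.PhantomSpec(geometry="tcpc_junction", n_phases=1, spacing_mm=1.0, seed=2)
    return ff.generate_phantom(spec)


@pytest.fixture(scope="session")
def tcpc_tree(tcpc_1mm):
    return ff.extract_centerline(tcpc_1mm.mask, tcpc_1mm.seeds)


@pytest.fixture
def simple_meta():
    return ff.AcquisitionMeta(voxel_spacing=(1.0, 1.0, 1.0), n_phases=1,
                              venc_cm_s=80.0)


def box_field(shape, n_phases, fn, meta=None, venc=80.0, spacing=1.0):
    """Velocity field from fn(X, Y, Z) -> (vx, vy, vz) on voxel-index coords (mm)."""
    meta = meta or ff.AcquisitionMeta(voxel_spacing=(spacing,) * 3,
                                      n_phases=n_phases, venc_cm_s=venc)
    X, Y, Z = np.meshgrid(*(spacing * np.arange(s) for s in shape), indexing="ij")
    vx, vy, vz = fn(X, Y, Z)
    values = np.zeros(shape + (n_phases, 3))
    for t in range(n_phases):
        values[..., t, 0] = vx
        values[..., t, 1] = vy
        values[..., t, 2] = vz
    return ff.VelocityField4D(values=values, meta=meta)
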