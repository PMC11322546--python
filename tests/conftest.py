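import numpy as np
import pytest

from samquant import synthetic
from samquant.stack_io import IsotropicStack, VoxelStack


@pytest.fixture
def small_dome():
    """A modest untilted dome stack with a noiseless uniform reporter."""
    dome = synthetic.DomeSpec(apex_um=(12.8, 12.8, 4.0), a1=0.05, a2=0.05)
    rep = synthetic.ReporterSpec(mode="uniform-interior", value=100.0,
                                 name="reporter")
    stack, manifest = synthetic.make_dome_stack(
        dome, [rep], shape_zyx=(48, 64, 64), voxel_size_xy=0.4,
        voxel_size_z=0.8, seed=7)
    return dome, stack, manifest


@pytest.fixture
def uniform_iso_stack():
    """Isotropic two-channel stack with constant intensities."""
    data = np.stack([np.full((30, 32, 32), 50.0), np.full((30, 32, 32), 100.0)])
    return IsotropicStack(data, 0.4, 0.4, ["wall", "reporter"])


def brute_force_interior(p, shape_zyx, voxel_size):
    """Scalar-math oracle for paraboloid membership, independent of the
    vectorised implementation: per-slice evaluation with explicit rotation."""
    import math

    nz, ny, nx = shape_zyx
    x0, y0, z0 = p.apex_um
    t = math.radians(p.theta_deg)
    c, s = math.cos(t), math.sin(t)
    out = np.zeros(shape_zyx, dtype=bool)
    ys = np.arange(ny) * voxel_size - y0
    xs = np.arange(nx) * voxel_size - x0
    for k in range(nz):
        dz = k * voxel_size - z0
        xi = c * xs + s * dz                      # (nx,)
        zeta = -s * xs + c * dz                   # (nx,)
        rhs = xi**2 / p.c1_sq                     # (nx,)
        out[k] = zeta[None, :] - rhs[None, :] >= (ys**2 / p.c2_sq)[:, None]
    return out
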