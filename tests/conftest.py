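import numpy as np
import pytest

from hemomap.fields import SegMask
from hemomap.geometry import (
    compute_inward_normals_and_radius,
    extract_surface,
    smooth_laplacian,
)
from hemomap.phantom import FlowProfileSpec, TubeGeometry, make_tube_subject


@pytest.fixture(scope="session")
def tube_geom():
    return TubeGeometry(arch_radius=30.0, lumen_radius=10.0, limb_length=100.0)


@pytest.fixture(scope="session")
def tube_single():
    """Default noise-free phantom with a single cardiac frame (fast)."""
    profile = FlowProfileSpec(v_peak=100.0, waveform=[1.0])
    return make_tube_subject(profile=profile, seed=0)


@pytest.fixture(scope="session")
def tube_mesh(tube_single):
    _, mask, _ = tube_single
    mesh = smooth_laplacian(extract_surface(mask), iterations=10, lam=0.5)
    return compute_inward_normals_and_radius(mesh, mask)


@pytest.fixture(scope="session")
def sphere_mask():
    """Digitized sphere, radius 20 mm at 1 mm spacing, centered on the grid."""
    n = 46
    g = np.indices((n, n, n)).astype(float) - (n - 1) / 2
    data = (g**2).sum(axis=0) <= 20.0**2
    return SegMask(data, spacing=1.0, origin=-np.full(3, (n - 1) / 2))


@pytest.fixture(scope="session")
def sphere_mesh(sphere_mask):
    return extract_surface(sphere_mask)
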