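import numpy as np
import pytest
from scipy.spatial import cKDTree

from wm3dseg.phantoms import PhantomSpec, make_axon_phantom


def straight_tube(shape, p0, direction, radius, length=None):
    """Voxelized straight tube used by skeleton/cross-section tests."""
    p0 = np.asarray(p0, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    if length is None:
        length = 2 * max(shape)
    t = np.linspace(-length / 2, length / 2, int(2 * length))
    seg = p0[None, :] + t[:, None] * d[None, :]
    inb = np.all((seg >= 0) & (seg <= np.array(shape) - 1), axis=1)
    seg = seg[inb]
    pts = np.indices(shape).reshape(3, -1).T.astype(float)
    dist, _ = cKDTree(seg).query(pts, workers=1)
    return (dist <= radius).reshape(shape)


@pytest.fixture(scope="session")
def merged_two_tube_phantom():
    """One 60-degree two-tube fusion phantom shared across tests."""
    spec = PhantomSpec(shape=(64, 64, 64), n_axons=2, merge_fraction=1.0,
                       crossing_angle_deg=60, n_mitochondria_per_axon=(1, 2),
                       noise_sd=0.03, seed=1)
    return make_axon_phantom(spec)
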