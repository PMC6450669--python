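import numpy as np
import pytest

from mesotrack.model import Region, TrackDataset, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_traj(positions, times=None, cell_id="c1", embryo_id="e1",
              region=Region.EMBRYONIC):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions), dtype=float) * 20.0
    return Trajectory(embryo_id, cell_id, region, np.asarray(times, float), positions)


@pytest.fixture
def zigzag():
    """(0,0,0)->(1,1,0)->(2,0,0)->(3,1,0): net √10, travel 3√2."""
    return make_traj([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]])


@pytest.fixture
def straight_line():
    """10 points spaced 2 µm along x at 20-min intervals."""
    pos = np.zeros((10, 3))
    pos[:, 0] = 2.0 * np.arange(10)
    return make_traj(pos)


def random_dataset(rng, n_cells=5, n_points=6, region=Region.EMBRYONIC):
    trajs = []
    for i in range(n_cells):
        pos = np.cumsum(rng.normal(scale=3.0, size=(n_points, 3)), axis=0)
        trajs.append(make_traj(pos, cell_id=f"c{i}", region=region))
    return TrackDataset(trajectories=trajs)


def random_rotation(rng):
    """Haar-ish random proper rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
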