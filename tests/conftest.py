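import numpy as np
import pytest

from p450kit.structio import AtomRecord, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20210901)


def make_trajectory(coords, names=None, elements=None, resnames=None,
                    resnums=None, chains=None, frame_times=None):
    """Build a Trajectory from a (n_frames, n_atoms, 3) array with
    defaulted roster metadata."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    names = names or [f"X{i}" for i in range(n)]
    elements = elements or ["C"] * n
    resnames = resnames or ["UNK"] * n
    resnums = resnums or [1] * n
    chains = chains or ["A"] * n
    roster = [
        AtomRecord(i + 1, names[i], elements[i], resnames[i], resnums[i],
                   chains[i], tuple(coords[0, i]))
        for i in range(n)
    ]
    return Trajectory(roster=roster, coords=coords, frame_times=frame_times)


@pytest.fixture
def tiny_water_trajectory():
    """2 frames, 1 carbon + 4 water oxygens, fixed geometry."""
    coords = np.zeros((2, 5, 3))
    coords[:, 1] = [3, 0, 0]
    coords[:, 2] = [0, 4, 0]
    coords[:, 3] = [0, 0, 5]
    coords[:, 4] = [6, 0, 0]
    return make_trajectory(
        coords,
        names=["C1", "O", "O", "O", "O"],
        elements=["C", "O", "O", "O", "O"],
        resnames=["LIG", "HOH", "HOH", "HOH", "HOH"],
        resnums=[1, 101, 102, 103, 104],
        chains=["A", "W", "W", "W", "W"],
    )
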