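import numpy as np
import pytest

from lesionmap.imaging_io import VolumeGrid
from lesionmap.synthetic import FixtureSpec, build_fixture, write_fixture


@pytest.fixture
def grid8():
    return VolumeGrid((8, 8, 8), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture(scope="session")
def fixture_bundle():
    """Default in-memory fixture: 20^3 grid, 50 subjects, 60 timepoints,
    loading 1, noise_sd 0.5 — the planted-recovery simulation."""
    cohort, masks, truth, atlas, networks, config = build_fixture(FixtureSpec())
    return {
        "cohort": cohort,
        "masks": masks,
        "truth": truth,
        "atlas": atlas,
        "networks": networks,
        "config": config,
    }


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A smaller on-disk fixture for I/O and pipeline tests."""
    directory = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(n_subjects=12, n_timepoints=40, seed=7)
    return write_fixture(directory, spec), spec


def make_mask_array(shape, idx):
    arr = np.zeros(shape, dtype=np.uint8)
    for i in idx:
        arr[i] = 1
    return arr
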