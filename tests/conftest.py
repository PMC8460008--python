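import numpy as np
import pytest

from fragmodes import GroupState, CommunityState, ModelParams


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


def make_group(wt, mut=None):
    wt = np.atleast_1d(np.asarray(wt, dtype=np.int64))
    mut = (np.zeros_like(wt) if mut is None
           else np.atleast_1d(np.asarray(mut, dtype=np.int64)))
    return GroupState(wt, mut)


def random_community(rng, m=2, n_groups=5, max_cells=30, mut_frac=0.3):
    """A random small community with at least one cell per group."""
    groups = []
    for _ in range(n_groups):
        while True:
            wt = rng.integers(0, max_cells, size=m)
            mut = (rng.random(m) < mut_frac) * rng.integers(0, max_cells // 2, size=m)
            if wt.sum() + mut.sum() > 0:
                break
        groups.append(GroupState(wt.astype(np.int64), mut.astype(np.int64)))
    return CommunityState(groups, 0.0)


@pytest.fixture
def default_params():
    return ModelParams()
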