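import numpy as np
import pytest

from fairnmf import FitConfig, GroupedMatrix, estimate_all_baselines, gen_dataset1


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grouped(rng):
    """A 2-group 40x8 random non-negative matrix, feature-normalized."""
    X = rng.uniform(size=(40, 8))
    labels = np.array(["a"] * 25 + ["b"] * 15)
    return GroupedMatrix(X, labels).normalized()


@pytest.fixture(scope="session")
def dataset1():
    """The two-group orthogonal benchmark (ranks 6 and 3), normalized."""
    return gen_dataset1(101).normalized()


@pytest.fixture(scope="session")
def dataset1_baseline_r6(dataset1):
    cfg = FitConfig(rank=6, max_iter=500, error_floor_pct=0.1)
    return estimate_all_baselines(dataset1, cfg, T=5, seed=77)
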