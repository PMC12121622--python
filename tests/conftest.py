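import numpy as np
import pandas as pd
import pytest

from zicount import AnalysisDataset, Scenario, generate_dataset


def make_dataset(y, group, extra=None):
    """AnalysisDataset from raw arrays, identical count/inflate designs."""
    cols = {"const": np.ones(len(y)), "group": np.asarray(group, dtype=float)}
    if extra:
        cols.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    X = pd.DataFrame(cols)
    return AnalysisDataset(outcome=np.asarray(y), count_design=X,
                           inflate_design=X.copy(), group_column="group")


@pytest.fixture(scope="session")
def zi_dataset():
    """One medium zero-heavy dataset: 52.5% structural zeros, Poisson counts."""
    scn = Scenario(n_subjects=800, structural_zero_prob=0.525,
                   sampling_zero_target=0.18)
    data, labels = generate_dataset(scn, seed=20240511)
    return data, labels, scn


@pytest.fixture(scope="session")
def small_counts():
    """Tiny deterministic count vector with zeros for cheap unit tests."""
    rng = np.random.default_rng(7)
    n = 200
    group = rng.binomial(1, 0.5, n)
    mu = np.exp(0.2 + 0.4 * group)
    y = rng.poisson(mu) * rng.binomial(1, 0.6, n)
    return make_dataset(y, group)
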