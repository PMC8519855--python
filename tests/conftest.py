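"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized similarity path:
per-pair correlations go through scipy.stats and permutations are
enumerated with itertools, so they can serve as an independent check.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

import spicetest as st


def brute_force_a0(x, y, measure="pearson"):
    """Mean within-subject correlation via per-row scipy calls."""
    corr = stats.pearsonr if measure == "pearson" else stats.spearmanr
    return float(np.mean([corr(xi, yi)[0] for xi, yi in zip(x, y)]))


def exhaustive_p_value(x, y, measure="pearson"):
    """Exact permutation p-value over all n! relabelings of the y rows.

    The identity permutation is one of the n! terms, so no +1 correction
    is applied; the two-sided tie rule (<=) matches the estimator.
    """
    n = len(x)
    a0 = brute_force_a0(x, y, measure)
    stats_all = [
        brute_force_a0(x, y[list(perm)], measure)
        for perm in itertools.permutations(range(n))
    ]
    hits = sum(1 for a in stats_all if abs(a0) <= abs(a) + 1e-12)
    return hits / len(stats_all), a0, np.array(stats_all)


@pytest.fixture(scope="session")
def mean_maps_500():
    return st.make_mean_maps(500, -0.15, seed=101)


@pytest.fixture(scope="session")
def strong_signal_data(mean_maps_500):
    cfg = st.SimulationConfig(
        n=50, sigma_a_sq=3.0, sigma_e_sq=0.5, mean_maps=mean_maps_500, seed=7
    )
    return st.simulate_dataset(cfg)


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(42)
    x = rng.standard_normal((4, 12))
    y = 0.5 * x + rng.standard_normal((4, 12))
    return st.ModalityDataset(x, y, subject_ids=list("abcd"))
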