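import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aflpmask as am

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_example():
    """The printed single replicate-pair worked example over ten bins."""
    calls = np.array(
        [
            [0, 0, 1, 1, 0, 0, 1, 1, 0, 0],
            [0, 0, 1, 1, 1, 1, 1, 1, 0, -1],
        ],
        dtype=np.int8,
    )
    matrix = am.AFLPMatrix(
        sample_ids=["IndA_rep1", "IndA_rep2"],
        bin_ids=[str(i) for i in range(1, 11)],
        calls=calls,
    )
    reps = am.ReplicateSet(pairs=[("IndA_rep1", "IndA_rep2")])
    return matrix, reps


def random_matrix(rng, n_samples, n_bins, p_missing=0.05, with_sizes=False):
    calls = rng.integers(0, 2, size=(n_samples, n_bins)).astype(np.int8)
    calls[rng.random((n_samples, n_bins)) < p_missing] = -1
    return am.AFLPMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        bin_ids=[f"b{j}" for j in range(n_bins)],
        calls=calls,
        bin_size=60.0 + np.arange(n_bins) if with_sizes else None,
        source_tag="rand",
    )


def random_table(rng, n_pairs, n_bins, p_missing=0.1):
    """Random pair-state table (uniform calls, independent missingness)."""
    a = rng.integers(0, 2, size=(n_pairs, n_bins)).astype(np.int8)
    b = rng.integers(0, 2, size=(n_pairs, n_bins)).astype(np.int8)
    a[rng.random((n_pairs, n_bins)) < p_missing] = -1
    b[rng.random((n_pairs, n_bins)) < p_missing] = -1
    return am.PairStateTable(
        pair_ids=[(f"p{y}a", f"p{y}b") for y in range(n_pairs)],
        bin_ids=[f"b{x}" for x in range(n_bins)],
        a=a,
        b=b,
    )


@pytest.fixture
def small_simulation():
    cfg = am.SimulationConfig(
        n_individuals=30, n_bins=60, n_replicated=8, n_groups=3, seed=11
    )
    return cfg, am.simulate_matrix(cfg)
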