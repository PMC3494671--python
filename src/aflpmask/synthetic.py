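"""Synthetic AFLP studies with replicate pairs and controlled technical error.

The generator emulates the situation the masking method is built for: a set
of individuals structured into groups (populations/species), scored over
size-ordered fragment bins, with a subset of individuals profiled twice.
Bins fall into two reliability classes — a "good" class with a small
per-observation flip probability and a "bad" class with a large one — and
every observed call can drop out to ``?``.  Replicate profiles are
independent re-observations of the same true genotype, so the per-bin
probability that a pair disagrees at a bin with flip rate eps is
2*eps*(1-eps), which gives closed-form expectations for both mismatch error
rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, AFLPError, AFLPMatrix, ReplicateSet

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_matrix", "expected_error_rates"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated AFLP data set.

    Defaults describe a mid-sized phylogenetic AFLP study: 100 individuals in
    5 groups scored over 300 bins, with 20 replicated individuals (20%, above
    the recommended >10%), a few-percent flip rate for reliable bins, a
    strongly unreliable bin class, and rare scoring dropouts.
    """

    n_individuals: int = 100
    n_bins: int = 300
    n_replicated: int = 20
    n_groups: int = 5
    p_presence: float = 0.3
    epsilon_good: float = 0.02
    epsilon_bad: float = 0.30
    frac_bad_bins: float = 0.20
    dropout: float = 0.01
    bin_size_start: float = 60.0
    bin_size_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_bins < 1:
            raise AFLPError("degenerate simulation: need at least one individual and one bin")
        if not (0 < self.n_groups <= self.n_individuals):
            raise AFLPError("n_groups must be in [1, n_individuals]")
        if not (0 <= self.n_replicated <= self.n_individuals):
            raise AFLPError("n_replicated must be in [0, n_individuals]")
        for name in ("p_presence", "epsilon_good", "epsilon_bad", "frac_bad_bins", "dropout"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise AFLPError(f"{name} must be a probability in [0, 1]")
        if self.bin_size_spacing <= 0:
            raise AFLPError("bin size spacing must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set."""

    group_of_individual: np.ndarray  # (n_individuals,)
    genotypes: np.ndarray            # (n_individuals, n_bins) true 0/1
    bin_epsilon: np.ndarray          # (n_bins,) per-bin flip probability
    bin_is_bad: np.ndarray           # (n_bins,) bool


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    width = max(3, len(str(config.n_individuals)))
    base = [f"S{i + 1:0{width}d}" for i in range(config.n_individuals)]
    reps = [f"{base[i]}r" for i in range(config.n_replicated)]
    return base, reps


def simulate_matrix(
    config: SimulationConfig,
) -> tuple[AFLPMatrix, ReplicateSet, SimulationTruth]:
    """Draw one study: character matrix, replicate declaration, and truth.

    True genotypes are shared within groups: each bin carries a per-group
    presence pattern drawn with ``p_presence`` per group, conditioned on the
    fragment being present in at least one group (a bin only exists because
    some fragment was observed).  Individuals 1..n_replicated (spread over
    groups round-robin) receive a second, independently re-observed profile.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m, g = config.n_individuals, config.n_bins, config.n_groups

    group = np.arange(n) % g
    patterns = rng.random((g, m)) < config.p_presence
    # condition every bin on >=1 carrying group: redraw the all-absent columns
    empty = ~patterns.any(axis=0)
    while empty.any():
        patterns[:, empty] = rng.random((g, int(empty.sum()))) < config.p_presence
        empty = ~patterns.any(axis=0)
    genotypes = patterns[group, :]

    bad = rng.random(m) < config.frac_bad_bins
    eps = np.where(bad, config.epsilon_bad, config.epsilon_good)

    def observe(truth_rows: np.ndarray) -> np.ndarray:
        flips = rng.random(truth_rows.shape) < eps[None, :]
        obs = (truth_rows ^ flips).astype(np.int8)
        drop = rng.random(truth_rows.shape) < config.dropout
        obs[drop] = MISSING
        return obs

    base_ids, rep_ids = _sample_ids(config)
    calls_base = observe(genotypes)
    calls_rep = observe(genotypes[: config.n_replicated, :])

    matrix = AFLPMatrix(
        sample_ids=base_ids + rep_ids,
        bin_ids=[f"B{j + 1:04d}" for j in range(m)],
        calls=np.vstack([calls_base, calls_rep]) if rep_ids else calls_base,
        bin_size=config.bin_size_start + config.bin_size_spacing * np.arange(m),
        source_tag="simulated",
    )
    reps = ReplicateSet(pairs=[(base_ids[i], rep_ids[i]) for i in range(config.n_replicated)])
    truth = SimulationTruth(
        group_of_individual=group,
        genotypes=genotypes.astype(np.int8),
        bin_epsilon=eps,
        bin_is_bad=bad,
    )
    return matrix, reps, truth


def _pair_probs(eps: float, p_eff: float) -> tuple[float, float]:
    """(P(mismatch), P((1,1))) for a replicate pair at a bin with flip rate eps
    and marginal presence probability p_eff."""
    p_mis = 2 * eps * (1 - eps)
    p_11 = p_eff * (1 - eps) ** 2 + (1 - p_eff) * eps**2
    return p_mis, p_11


def expected_error_rates(config: SimulationConfig) -> tuple[float, float]:
    """Closed-form expectations of the two mismatch error rates.

    The mismatch probability per pair-bin is 2*eps*(1-eps) regardless of
    presence frequency, so the plain mismatch rate mixes the two bin classes
    directly.  The Jaccard rate additionally needs P((1,1)), which uses the
    effective marginal presence probability after conditioning each bin on
    having at least one carrying group.  Ambiguous states cancel from both
    numerator and denominator in expectation.
    """
    p = config.p_presence
    g = config.n_groups
    # P(a given group carries | not all groups absent), by symmetry
    p_eff = p / (1 - (1 - p) ** g) if p > 0 else 0.0
    f = config.frac_bad_bins
    mis_g, p11_g = _pair_probs(config.epsilon_good, p_eff)
    mis_b, p11_b = _pair_probs(config.epsilon_bad, p_eff)
    mis = (1 - f) * mis_g + f * mis_b
    p11 = (1 - f) * p11_g + f * p11_b
    e_bonin = mis
    e_jaccard = mis / (mis + p11) if (mis + p11) > 0 else 0.0
    return e_bonin, e_jaccard


def write_fixture_files(matrix: AFLPMatrix, directory: str, double_peak_bins: dict[str, int] | None = None) -> dict[str, str]:
    """Emit the matrix in all three reader dialects; returns path per dialect."""
    import os

    from .matrix_io import write_ceq_table, write_genemapper_table

    os.makedirs(directory, exist_ok=True)
    paths = {
        "genemapper": os.path.join(directory, "matrix.genemapper.txt"),
        "ceq": os.path.join(directory, "matrix.ceq.txt"),
        "csv": os.path.join(directory, "matrix.csv"),
    }
    write_genemapper_table(matrix, paths["genemapper"], delimiter="\t")
    write_ceq_table(matrix, paths["ceq"], delimiter="\t", double_peak_extra=double_peak_bins)
    write_genemapper_table(matrix, paths["csv"], delimiter=",")
    return paths
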