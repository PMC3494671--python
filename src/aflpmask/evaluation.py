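"""Matrix-quality criteria for choosing among masked character matrices.

For each candidate matrix the suite computes binary genetic distances
(Nei-Li restriction-fragment similarity or simple uncorrected dissimilarity),
a neighbor-joining tree, nonparametric bootstrap support over bins, the
resolution score (sum of supports above 50% over the maximum n-3 internal
branches), stemminess (internal branch length as a proportion of total tree
length; low values flag star-like trees), and the percentage of distance
variation captured by the leading axes of a principal coordinates analysis.

Missing calls (?) are handled by pairwise deletion: each sample pair is
compared only over bins where both are unambiguously scored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import AFLPError, AFLPMatrix
from .tree import PhyloTree, TreeError, neighbor_joining as _nj_core

__all__ = [
    "DistanceMatrix",
    "SupportedTree",
    "nei_li_distance",
    "uncorrected_distance",
    "neighbor_joining",
    "bootstrap_support",
    "resolution_score",
    "stemminess",
    "pcoa_variance",
    "evaluate_matrix",
    "QualityReport",
]


@dataclass(eq=False)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise AFLPError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise AFLPError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise AFLPError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise AFLPError("nonzero self-distance")
        if np.any(self.d < -1e-12):
            raise AFLPError("negative distance")

    @property
    def n(self) -> int:
        return len(self.labels)

    def write_phylip(self, path: str) -> None:
        """PHYLIP-style square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def _presence_layers(matrix: AFLPMatrix) -> tuple[np.ndarray, np.ndarray]:
    present = (matrix.calls == 1).astype(float)
    scored = (matrix.calls >= 0).astype(float)
    return present, scored


def nei_li_distance(matrix: AFLPMatrix) -> DistanceMatrix:
    """Nei-Li restriction-fragment distance, d = 1 - 2*n_uv / (n_u + n_v).

    n_u and n_v count fragment presences of each sample and n_uv the shared
    presences, all over bins where both samples are unambiguously scored.
    A pair of all-absent profiles has no defined similarity and is an error.
    """
    if matrix.n_samples < 2:
        raise AFLPError("need at least two samples for distances")
    A, V = _presence_layers(matrix)
    shared = A @ A.T
    denom = A @ V.T + V @ A.T  # n_u + n_v over jointly scored bins
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    bad = (denom == 0) & ~np.eye(matrix.n_samples, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AFLPError(
            "Nei-Li distance undefined for all-absent profile pair "
            f"({matrix.sample_ids[i]!r}, {matrix.sample_ids[j]!r})"
        )
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return DistanceMatrix(list(matrix.sample_ids), d)


def uncorrected_distance(matrix: AFLPMatrix) -> DistanceMatrix:
    """Proportion of jointly scored bins at which two samples differ."""
    if matrix.n_samples < 2:
        raise AFLPError("need at least two samples for distances")
    A, V = _presence_layers(matrix)
    absent = V - A
    joint = V @ V.T
    diff = A @ absent.T + absent @ A.T
    bad = (joint == 0) & ~np.eye(matrix.n_samples, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AFLPError(
            "no jointly scored bins for sample pair "
            f"({matrix.sample_ids[i]!r}, {matrix.sample_ids[j]!r})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / joint
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return DistanceMatrix(list(matrix.sample_ids), d)


_DISTANCES = {"neili": nei_li_distance, "uncorrected": uncorrected_distance}


def distance_matrix(matrix: AFLPMatrix, kind: str = "neili") -> DistanceMatrix:
    try:
        return _DISTANCES[kind](matrix)
    except KeyError:
        raise AFLPError(f"unknown distance kind {kind!r} (use 'neili' or 'uncorrected')") from None


def neighbor_joining(dist: DistanceMatrix, clamp: bool = True) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix (deterministic tie-breaks)."""
    return _nj_core(list(dist.labels), dist.d, clamp=clamp)


@dataclass
class SupportedTree:
    """A point-estimate tree with bootstrap support per internal bipartition."""

    tree: PhyloTree
    support: dict[frozenset[str], float]
    n_replicates: int
    n_failed: int = 0

    def support_values(self) -> list[float]:
        return list(self.support.values())


def bootstrap_support(
    matrix: AFLPMatrix,
    distance_kind: str = "neili",
    n_reps: int = 1000,
    seed: int | None = None,
) -> SupportedTree:
    """Nonparametric bootstrap over bins (columns sampled with replacement).

    Support of each internal edge of the point-estimate tree is the
    percentage of replicate NJ trees containing the same leaf bipartition.
    Replicates whose resampled matrix yields an undefined distance are
    skipped and counted in ``n_failed``.
    """
    if n_reps < 1:
        raise AFLPError("need at least one bootstrap replicate")
    point = neighbor_joining(distance_matrix(matrix, distance_kind))
    target = list(point.internal_bipartitions().keys())
    counts = {bip: 0 for bip in target}
    rng = np.random.default_rng(seed)
    n_failed = 0
    n_bins = matrix.n_bins
    for _ in range(n_reps):
        cols = rng.integers(0, n_bins, size=n_bins)
        resampled = AFLPMatrix(
            sample_ids=list(matrix.sample_ids),
            bin_ids=[f"bs{k}" for k in range(n_bins)],
            calls=matrix.calls[:, cols],
            source_tag=matrix.source_tag,
        )
        try:
            rep_tree = neighbor_joining(distance_matrix(resampled, distance_kind))
        except AFLPError:
            n_failed += 1
            continue
        rep_bips = set(rep_tree.internal_bipartitions().keys())
        for bip in target:
            if bip in rep_bips:
                counts[bip] += 1
    n_ok = n_reps - n_failed
    if n_ok == 0:
        raise AFLPError("every bootstrap replicate failed")
    support = {bip: 100.0 * c / n_ok for bip, c in counts.items()}
    return SupportedTree(tree=point, support=support, n_replicates=n_reps, n_failed=n_failed)


def resolution_score(stree: SupportedTree, inclusive: bool = False) -> float:
    """Sum of bootstrap supports above 50%, divided by the maximum number of
    internal branches (n_leaves - 3); a percentage in [0, 100] for binary
    trees.  ``inclusive`` counts supports equal to 50 as well."""
    n = stree.tree.n_leaves
    if n < 4:
        return 0.0
    threshold = 50.0
    if inclusive:
        total = sum(s for s in stree.support_values() if s >= threshold)
    else:
        total = sum(s for s in stree.support_values() if s > threshold)
    return total / (n - 3)


def stemminess(tree: PhyloTree) -> float:
    """Internal branch length over total branch length, in [0, 1]."""
    total = tree.total_length()
    if total <= 0:
        raise TreeError("stemminess undefined: total branch length is zero")
    return tree.internal_length() / total


def pcoa_variance(dist: DistanceMatrix, n_axes: int = 3) -> float:
    """Percentage of variation captured by the first ``n_axes`` PCoA axes.

    Classical metric scaling: double-center the squared distances and take
    the eigendecomposition; the share is 100 x (sum of the largest
    ``n_axes`` positive eigenvalues) / (sum of all positive eigenvalues).
    Negative eigenvalues (non-Euclidean input) are excluded from the
    denominator.
    """
    if dist.n < 2:
        raise AFLPError("need at least two samples for ordination")
    n = dist.n
    D2 = dist.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals = np.linalg.eigvalsh((B + B.T) / 2)
    tol = 1e-10 * max(1.0, float(np.abs(vals).max()))
    pos = vals[vals > tol]
    if pos.size == 0:
        raise AFLPError("no positive eigenvalue: degenerate distance matrix")
    top = np.sort(pos)[::-1][:n_axes].sum()
    return float(100.0 * top / pos.sum())


@dataclass
class QualityReport:
    """Quality-estimate row for one character matrix."""

    n_samples: int
    n_bins: int
    distance_kind: str
    resolution: float
    stemminess: float
    pcoa_pct: float
    supported_tree: SupportedTree
    r_bonin: float | None = None
    r_jaccard: float | None = None


def evaluate_matrix(
    matrix: AFLPMatrix,
    distance_kind: str = "neili",
    n_bootstrap: int = 1000,
    seed: int | None = None,
    n_axes: int = 3,
) -> QualityReport:
    """Distance -> NJ -> bootstrap -> resolution/stemminess/PCoA in one call."""
    dist = distance_matrix(matrix, distance_kind)
    stree = bootstrap_support(matrix, distance_kind, n_reps=n_bootstrap, seed=seed)
    return QualityReport(
        n_samples=matrix.n_samples,
        n_bins=matrix.n_bins,
        distance_kind=distance_kind,
        resolution=resolution_score(stree),
        stemminess=stemminess(stree.tree),
        pcoa_pct=pcoa_variance(dist, n_axes=n_axes),
        supported_tree=stree,
    )
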