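"""Replicate-based reliability scoring and iterative masking of AFLP matrices.

The method rests on replicate pairs: two independently generated AFLP profiles
of the same individual.  At every bin a pair shows one of nine ordered states
(i, j) with i, j in {0, 1, ?}.  (0,0) and (1,1) are reproducible, (0,1) and
(1,0) unreproducible, and any state containing ? is ambiguous and excluded
from all ratios.

Three criteria drive the masking loop:

* bin reliability ``BR_x`` — reproducible / unambiguous states at bin *x*
  across pairs;
* replicate reliability ``RR_y`` — the same ratio for pair *y* across bins;
* bin distance ``BD`` — minimum spacing (in bases) between size-adjacent bins,
  guarding against one allele oversplit into two bins by imperfect sizing.

Masking iterates: pairs with RR_y <= RR are masked, then bins with BR_x <= BR,
bins without any (1,1) pair, and (by default) bins showing only (0,0) pairs,
then bins violating the distance criterion; reliabilities are recomputed over
the survivors until a full pass masks nothing.  A sweep over the (BR, RR)
threshold grid emits every masked matrix whose mismatch error rate falls below
a cutoff while retaining more than a minimum number of bins.

Threshold comparisons use integer arithmetic over hundredths so that grid
values like 0.7 + 7*0.01 are compared exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import MISSING, AFLPError, AFLPMatrix, ReplicateSet

__all__ = [
    "MaskingError",
    "PairStateTable",
    "Thresholds",
    "MaskResult",
    "SweepCell",
    "MaskGroup",
    "SweepResult",
    "classify_pairs",
    "bin_reliability",
    "replicate_reliability",
    "bonin_error",
    "jaccard_error",
    "bin_distance_mask",
    "mask_fixpoint",
    "threshold_sweep",
    "apply_mask",
]


class MaskingError(AFLPError):
    """Raised when masking or an error-rate ratio has no defined value."""


def _as_char(code: int) -> str:
    return {0: "0", 1: "1", MISSING: "?"}[int(code)]


@dataclass(eq=False)
class PairStateTable:
    """Replicate-pair x bin grid of ordered call states.

    ``a`` and ``b`` hold the first and second profile's calls (int8, -1 = ?),
    shape (n_pairs, n_bins).
    """

    pair_ids: list[tuple[str, str]]
    bin_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    bin_size: np.ndarray | None = None
    bin_source: list[str] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int8)
        self.b = np.asarray(self.b, dtype=np.int8)
        shape = (len(self.pair_ids), len(self.bin_ids))
        if self.a.shape != shape or self.b.shape != shape:
            raise AFLPError("pair state arrays do not match pair/bin counts")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    # boolean layers reused throughout the loop
    @property
    def unambiguous(self) -> np.ndarray:
        return (self.a >= 0) & (self.b >= 0)

    @property
    def reproducible(self) -> np.ndarray:
        return self.unambiguous & (self.a == self.b)

    @property
    def mismatch(self) -> np.ndarray:
        return self.unambiguous & (self.a != self.b)

    @property
    def both_present(self) -> np.ndarray:
        return (self.a == 1) & (self.b == 1)

    @property
    def both_absent(self) -> np.ndarray:
        return (self.a == 0) & (self.b == 0)

    def state(self, pair_index: int, bin_index: int) -> tuple[str, str]:
        """The ordered state at one cell, e.g. ('0', '1') or ('0', '?')."""
        return (_as_char(self.a[pair_index, bin_index]), _as_char(self.b[pair_index, bin_index]))

    def states(self, pair_index: int) -> list[tuple[str, str]]:
        return [self.state(pair_index, x) for x in range(self.n_bins)]

    def bin_state_counts(self, bin_id: str) -> dict[tuple[str, str], int]:
        """N_x(i, j): observed count of each of the nine states at one bin."""
        x = self._bin_index(bin_id)
        return self._counts(self.a[:, x], self.b[:, x])

    def pair_state_counts(self, pair_id: tuple[str, str]) -> dict[tuple[str, str], int]:
        """M_y(i, j): observed count of each of the nine states for one pair."""
        y = self._pair_index(pair_id)
        return self._counts(self.a[y, :], self.b[y, :])

    @staticmethod
    def _counts(a: np.ndarray, b: np.ndarray) -> dict[tuple[str, str], int]:
        out = {(i, j): 0 for i in "01?" for j in "01?"}
        for i, j in zip(a.tolist(), b.tolist()):
            out[(_as_char(i), _as_char(j))] += 1
        return out

    def _bin_index(self, bin_id: str) -> int:
        try:
            return self.bin_ids.index(str(bin_id))
        except ValueError:
            raise AFLPError(f"unknown bin id {bin_id!r}") from None

    def _pair_index(self, pair_id: tuple[str, str]) -> int:
        pid = (str(pair_id[0]), str(pair_id[1]))
        try:
            return self.pair_ids.index(pid)
        except ValueError:
            raise AFLPError(f"unknown replicate pair {pid!r}") from None


def classify_pairs(matrix: AFLPMatrix, reps: ReplicateSet) -> PairStateTable:
    """Transform declared replicate pairs into the pair x bin state table."""
    if reps.n_pairs == 0:
        raise AFLPError("no replicate pairs declared; the method is replicate-based")
    reps.validate_against(matrix)
    ia = [matrix.sample_index(a) for a, _ in reps.pairs]
    ib = [matrix.sample_index(b) for _, b in reps.pairs]
    return PairStateTable(
        pair_ids=list(reps.pairs),
        bin_ids=list(matrix.bin_ids),
        a=matrix.calls[ia, :],
        b=matrix.calls[ib, :],
        bin_size=None if matrix.bin_size is None else matrix.bin_size.copy(),
        bin_source=None if matrix.bin_source is None else list(matrix.bin_source),
    )


# ---------------------------------------------------------------------------
# reliability criteria and error rates
# ---------------------------------------------------------------------------

def bin_reliability(
    table: PairStateTable,
    bin_id: str,
    pair_keep: np.ndarray | None = None,
) -> float:
    """BR_x = (N_x(0,0)+N_x(1,1)) / (all unambiguous states at bin x).

    Returns NaN when no unambiguous pair state exists at the bin (undefined).
    """
    x = table._bin_index(bin_id)
    keep = slice(None) if pair_keep is None else np.asarray(pair_keep, dtype=bool)
    rep = int(table.reproducible[keep, x].sum())
    tot = int(table.unambiguous[keep, x].sum())
    return rep / tot if tot else float("nan")


def replicate_reliability(
    table: PairStateTable,
    pair_id: tuple[str, str],
    bin_keep: np.ndarray | None = None,
) -> float:
    """RR_y = (M_y(0,0)+M_y(1,1)) / (all unambiguous states of pair y).

    Returns NaN when the pair has no unambiguous state over the kept bins.
    """
    y = table._pair_index(pair_id)
    keep = slice(None) if bin_keep is None else np.asarray(bin_keep, dtype=bool)
    rep = int(table.reproducible[y, keep].sum())
    tot = int(table.unambiguous[y, keep].sum())
    return rep / tot if tot else float("nan")


def _submask(table: PairStateTable, pair_keep, bin_keep) -> np.ndarray:
    sel = np.ones((table.n_pairs, table.n_bins), dtype=bool)
    if pair_keep is not None:
        sel &= np.asarray(pair_keep, dtype=bool)[:, None]
    if bin_keep is not None:
        sel &= np.asarray(bin_keep, dtype=bool)[None, :]
    return sel


def bonin_error(
    table: PairStateTable,
    pair_keep: np.ndarray | None = None,
    bin_keep: np.ndarray | None = None,
    denominator: str = "unambiguous",
) -> float:
    """Replicate mismatch error rate: mismatches over all scored pair states.

    ``denominator="unambiguous"`` (default) counts only unambiguous states;
    ``"all"`` counts every pair state including ambiguous ones.
    """
    sel = _submask(table, pair_keep, bin_keep)
    num = int((table.mismatch & sel).sum())
    if denominator == "unambiguous":
        den = int((table.unambiguous & sel).sum())
    elif denominator == "all":
        den = int(sel.sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if den == 0:
        raise MaskingError("mismatch error rate undefined: no scored pair states")
    return num / den


def jaccard_error(
    table: PairStateTable,
    pair_keep: np.ndarray | None = None,
    bin_keep: np.ndarray | None = None,
) -> float:
    """Jaccard mismatch error rate: mismatches / (mismatches + (1,1) states).

    Shared absences (0,0) are excluded from the denominator, so this rate is
    never smaller than the plain mismatch rate.
    """
    sel = _submask(table, pair_keep, bin_keep)
    num = int((table.mismatch & sel).sum())
    den = num + int((table.both_present & sel).sum())
    if den == 0:
        raise MaskingError(
            "Jaccard error rate undefined: no (1,1), (0,1) or (1,0) pair states"
        )
    return num / den


# ---------------------------------------------------------------------------
# bin distance criterion
# ---------------------------------------------------------------------------

_BD_EPS = 1e-9  # absorb float noise in size differences at the threshold


def bin_distance_mask(
    matrix: AFLPMatrix | PairStateTable,
    unmasked_bins: Sequence[str] | np.ndarray,
    bd: float,
) -> set[str]:
    """Bins violating the minimum size spacing ``bd`` (bases).

    Size-adjacent pairs of currently unmasked bins (within one source block)
    whose centers differ by <= ``bd`` are both returned.  Empty when no sizes
    are recorded.
    """
    if not (0 <= bd < 1):
        raise AFLPError("BD must be between 0 and 1 (bases); larger exceeds a bin width")
    if matrix.bin_size is None:
        return set()
    bin_ids = list(matrix.bin_ids)
    if isinstance(unmasked_bins, np.ndarray) and unmasked_bins.dtype == bool:
        keep = [bin_ids[i] for i in np.flatnonzero(unmasked_bins)]
    else:
        keep = [str(b) for b in unmasked_bins]
    keep_set = set(keep)
    sources = matrix.bin_source if matrix.bin_source is not None else [""] * len(bin_ids)
    by_source: dict[str, list[tuple[float, str]]] = {}
    for bid, size, src in zip(bin_ids, matrix.bin_size, sources):
        if bid in keep_set:
            by_source.setdefault(src, []).append((float(size), bid))
    out: set[str] = set()
    for entries in by_source.values():
        entries.sort()
        for (s1, b1), (s2, b2) in zip(entries, entries[1:]):
            if s2 - s1 <= bd + _BD_EPS:
                out.update((b1, b2))
    return out


# ---------------------------------------------------------------------------
# thresholds, fixpoint loop, sweep
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Grid and emission settings for the threshold sweep.

    BR runs from ``br_min`` to ``br_max`` in steps of ``br_step``; RR takes the
    values in ``rr_values``.  A masked matrix is emitted when the selected
    error metric is below ``error_cutoff`` and more than ``min_bins`` bins
    survive.
    """

    br_min: float = 0.70
    br_max: float = 0.95
    br_step: float = 0.01
    rr_values: tuple[float, ...] = tuple(v / 10 for v in range(10))
    bd: float = 0.0
    error_metric: str = "bonin"
    error_cutoff: float = 0.1
    min_bins: int = 5
    mask_all_absent_bins: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.br_min <= self.br_max <= 0.95 + 1e-12):
            raise AFLPError("need 0 <= br_min <= br_max <= 0.95")
        if not (0 <= self.bd < 1):
            raise AFLPError("BD must be between 0 and 1")
        if not (0 < self.error_cutoff <= 1):
            raise AFLPError("error_cutoff must be in (0, 1]")
        if self.error_metric not in ("bonin", "jaccard"):
            raise AFLPError("error_metric must be 'bonin' or 'jaccard'")

    def br_grid(self) -> list[float]:
        """Exact-decimal BR values (ascending)."""
        lo, hi = round(self.br_min * 100), round(self.br_max * 100)
        step = round(self.br_step * 100)
        return [h / 100 for h in range(lo, hi + 1, step)]

    def rr_grid(self) -> list[float]:
        return sorted(round(r * 100) / 100 for r in self.rr_values)

    @property
    def grid_size(self) -> int:
        return len(self.br_grid()) * len(self.rr_grid())


@dataclass(frozen=True)
class MaskResult:
    """Outcome of one (BR, RR, BD) masking fixpoint."""

    br_threshold: float
    rr_threshold: float
    masked_bins: frozenset[str]
    masked_pairs: frozenset[tuple[str, str]]
    r_bonin: float
    r_jaccard: float
    n_bins_remaining: int
    n_pairs_remaining: int
    iterations: int


def mask_fixpoint(
    matrix: AFLPMatrix | None,
    reps: ReplicateSet | None,
    br: float,
    rr: float,
    bd: float = 0.0,
    *,
    table: PairStateTable | None = None,
    mask_all_absent_bins: bool = True,
    bonin_denominator: str = "unambiguous",
    prelim_masked_bins: Iterable[str] = (),
) -> MaskResult:
    """Iterate the three masking steps to a fixpoint and score the survivors.

    Each pass masks (1) pairs with RR_y <= ``rr`` (undefined RR fails),
    (2) bins with BR_x <= ``br``, bins without any (1,1) pair, bins showing
    only (0,0) pairs (when ``mask_all_absent_bins``), and bins with undefined
    BR, (3) bins violating the ``bd`` spacing; reliabilities are recomputed
    over survivors until nothing changes.  Termination is guaranteed because
    masks only grow over a finite set.
    """
    if table is None:
        if matrix is None or reps is None:
            raise AFLPError("either a pair-state table or (matrix, reps) is required")
        table = classify_pairs(matrix, reps)
    br_h, rr_h = round(br * 100), round(rr * 100)
    if not (0 <= bd < 1):
        raise AFLPError("BD must be between 0 and 1")

    unamb, rep = table.unambiguous, table.reproducible
    ones, zeros = table.both_present, table.both_absent

    bin_keep = np.ones(table.n_bins, dtype=bool)
    for bid in prelim_masked_bins:
        bin_keep[table._bin_index(bid)] = False
    analyzable = bin_keep.copy()
    pair_keep = np.ones(table.n_pairs, dtype=bool)

    iterations = 0
    while True:
        iterations += 1
        changed = False

        # step 1 — replicate reliability over currently kept bins
        tot_p = unamb[:, bin_keep].sum(axis=1)
        rep_p = rep[:, bin_keep].sum(axis=1)
        fail_p = pair_keep & ((tot_p == 0) | (100 * rep_p <= rr_h * tot_p))
        if fail_p.any():
            pair_keep &= ~fail_p
            changed = True
        if not pair_keep.any():
            raise MaskingError(
                f"all replicate pairs masked at RR <= {rr}: no basis for reliability"
            )

        # step 2 — bin reliability over the surviving pairs
        tot_b = unamb[pair_keep, :].sum(axis=0)
        rep_b = rep[pair_keep, :].sum(axis=0)
        n11 = ones[pair_keep, :].sum(axis=0)
        n00 = zeros[pair_keep, :].sum(axis=0)
        undefined = tot_b == 0
        low_br = 100 * rep_b <= br_h * tot_b
        all_absent = (tot_b > 0) & (n00 == tot_b)
        no_presence = n11 == 0
        if mask_all_absent_bins:
            presence_rule = no_presence
        else:
            # keep pure invariant-absent bins; still mask any other bin
            # that lacks a confirming (1,1) pair
            presence_rule = no_presence & ~all_absent
        fail_b = bin_keep & (undefined | low_br | presence_rule)
        if fail_b.any():
            bin_keep &= ~fail_b
            changed = True

        # step 3 — minimum bin distance among the survivors (permanent)
        if bd > 0 or table.bin_size is not None:
            too_close = bin_distance_mask(table, bin_keep, bd)
            if too_close:
                idx = [table._bin_index(b) for b in too_close]
                if bin_keep[idx].any():
                    bin_keep[idx] = False
                    changed = True

        if not changed:
            break

    masked_bins = frozenset(
        b for b, a, k in zip(table.bin_ids, analyzable, bin_keep) if a and not k
    )
    masked_pairs = frozenset(p for p, k in zip(table.pair_ids, pair_keep) if not k)
    try:
        r_b = bonin_error(table, pair_keep, bin_keep, denominator=bonin_denominator)
    except MaskingError:
        r_b = float("nan")
    try:
        r_j = jaccard_error(table, pair_keep, bin_keep)
    except MaskingError:
        r_j = float("nan")
    return MaskResult(
        br_threshold=br_h / 100,
        rr_threshold=rr_h / 100,
        masked_bins=masked_bins,
        masked_pairs=masked_pairs,
        r_bonin=r_b,
        r_jaccard=r_j,
        n_bins_remaining=int(bin_keep.sum()),
        n_pairs_remaining=int(pair_keep.sum()),
        iterations=iterations,
    )


@dataclass(frozen=True)
class SweepCell:
    br: float
    rr: float
    result: MaskResult | None
    error: str | None = None


@dataclass
class MaskGroup:
    """Grid cells sharing one identical masked set, reported as BR/RR ranges."""

    br_range: tuple[float, float]
    rr_range: tuple[float, float]
    cells: list[tuple[float, float]]
    result: MaskResult
    emitted: bool

    @property
    def label(self) -> str:
        def fmt(lo: float, hi: float, prec: int) -> str:
            return f"{lo:.{prec}f}" if lo == hi else f"{lo:.{prec}f}-{hi:.{prec}f}"

        return f"BR{fmt(*self.br_range, 2)}_RR{fmt(*self.rr_range, 1)}"


@dataclass
class SweepResult:
    cells: list[SweepCell]
    groups: list[MaskGroup]
    thresholds: Thresholds

    @property
    def emitted_groups(self) -> list[MaskGroup]:
        return [g for g in self.groups if g.emitted]

    def largest_emitted(self) -> MaskGroup:
        """The emitted group retaining the most bins (the usual user choice)."""
        emitted = self.emitted_groups
        if not emitted:
            raise MaskingError("no masked matrix met the emission criteria")
        return max(emitted, key=lambda g: g.result.n_bins_remaining)


def threshold_sweep(
    matrix: AFLPMatrix | None,
    reps: ReplicateSet | None,
    thresholds: Thresholds | None = None,
    *,
    table: PairStateTable | None = None,
    bonin_denominator: str = "unambiguous",
    prelim_masked_bins: Iterable[str] = (),
) -> SweepResult:
    """Run the masking fixpoint over the whole BR x RR grid.

    Cells whose fixpoint fails (e.g. every pair masked at a strict RR) are
    recorded as failed, not fatal.  Cells with identical masked bin and pair
    sets are grouped into one representative labelled by its BR and RR ranges;
    a group is flagged emitted when the selected error metric is strictly
    below the cutoff and more than ``min_bins`` bins survive.
    """
    th = thresholds or Thresholds()
    if table is None:
        if matrix is None or reps is None:
            raise AFLPError("either a pair-state table or (matrix, reps) is required")
        table = classify_pairs(matrix, reps)
    prelim = tuple(prelim_masked_bins)

    cells: list[SweepCell] = []
    group_index: dict[tuple[frozenset, frozenset], MaskGroup] = {}
    for br in th.br_grid():
        for rr in th.rr_grid():
            try:
                res = mask_fixpoint(
                    None,
                    None,
                    br,
                    rr,
                    th.bd,
                    table=table,
                    mask_all_absent_bins=th.mask_all_absent_bins,
                    bonin_denominator=bonin_denominator,
                    prelim_masked_bins=prelim,
                )
            except MaskingError as exc:
                cells.append(SweepCell(br, rr, None, str(exc)))
                continue
            cells.append(SweepCell(br, rr, res))
            key = (res.masked_bins, res.masked_pairs)
            grp = group_index.get(key)
            if grp is None:
                metric = res.r_bonin if th.error_metric == "bonin" else res.r_jaccard
                emitted = (
                    np.isfinite(metric)
                    and metric < th.error_cutoff
                    and res.n_bins_remaining > th.min_bins
                )
                group_index[key] = MaskGroup(
                    br_range=(br, br),
                    rr_range=(rr, rr),
                    cells=[(br, rr)],
                    result=res,
                    emitted=bool(emitted),
                )
            else:
                grp.cells.append((br, rr))
                grp.br_range = (min(grp.br_range[0], br), max(grp.br_range[1], br))
                grp.rr_range = (min(grp.rr_range[0], rr), max(grp.rr_range[1], rr))
    return SweepResult(cells=cells, groups=list(group_index.values()), thresholds=th)


def apply_mask(
    matrix: AFLPMatrix,
    result: MaskResult,
    drop_masked_replicates: bool = True,
    drop_paired_individuals: bool = False,
) -> AFLPMatrix:
    """Project a masking outcome onto the complete character matrix.

    Masked bins are removed for all sampled individuals.  For each masked
    replicate pair the second (replicate) profile is dropped when
    ``drop_masked_replicates`` is set; ``drop_paired_individuals`` drops both
    profiles of the pair.
    """
    unknown = result.masked_bins - set(matrix.bin_ids)
    if unknown:
        raise AFLPError(
            f"mask refers to bins outside this matrix, e.g. {sorted(unknown)[0]!r}"
        )
    out = matrix.drop_bins(result.masked_bins)
    drop: set[str] = set()
    if drop_masked_replicates or drop_paired_individuals:
        for a, b in result.masked_pairs:
            drop.add(b)
            if drop_paired_individuals:
                drop.add(a)
    if drop:
        out = out.drop_samples(drop & set(out.sample_ids))
    return out
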