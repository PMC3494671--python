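"""Core containers for AFLP presence/absence character matrices.

An AFLP profile is scored into size-ordered fragment bins; each (sample, bin)
cell records fragment presence (1), absence (0) or a failed/unscorable call
(``?``).  Calls are stored as an int8 array with ``-1`` encoding ``?``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

#: accepted spellings of the three call states on input (case-insensitive for NA)
CALL_TOKENS = {
    "0": 0,
    "1": 1,
    "?": MISSING,
    "": MISSING,
    "na": MISSING,
}

CALL_CHARS = {0: "0", 1: "1", MISSING: "?"}


class AFLPError(ValueError):
    """Base error for malformed AFLP data or invalid analysis requests."""


def parse_call(token: str) -> int:
    """Map one cell token to the internal call code; unparseable tokens -> ``?``."""
    return CALL_TOKENS.get(str(token).strip().lower(), MISSING)


def calls_from_tokens(rows: Sequence[Sequence[object]]) -> np.ndarray:
    return np.array([[parse_call(c) for c in row] for row in rows], dtype=np.int8)


@dataclass(eq=False)
class AFLPMatrix:
    """Samples x size-ordered bins matrix of {0, 1, ?} calls.

    Parameters
    ----------
    sample_ids : ordered unique sample labels (rows).
    bin_ids : ordered unique bin labels (columns).
    calls : int8 array of shape (n_samples, n_bins) over {0, 1, -1}.
    bin_size : optional fragment-length center per bin, in bases; strictly
        increasing within each source block.
    source_tag : provenance label (primer combination / input file).
    bin_source : per-bin source tag; only concatenated supermatrices carry
        more than one distinct value.
    """

    sample_ids: list[str]
    bin_ids: list[str]
    calls: np.ndarray
    bin_size: np.ndarray | None = None
    source_tag: str = ""
    bin_source: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.bin_ids = [str(b) for b in self.bin_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (len(self.sample_ids), len(self.bin_ids)):
            raise AFLPError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.bin_ids)} bins"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise AFLPError(f"duplicate sample id {dup!r}")
        if len(set(self.bin_ids)) != len(self.bin_ids):
            dup = _first_duplicate(self.bin_ids)
            raise AFLPError(f"duplicate bin id {dup!r}")
        bad = set(np.unique(self.calls)) - {0, 1, MISSING}
        if bad:
            raise AFLPError(f"invalid call codes {sorted(bad)}; allowed are 0, 1, -1 (?)")
        if self.bin_source is not None and len(self.bin_source) != len(self.bin_ids):
            raise AFLPError("bin_source length does not match bin count")
        if self.bin_size is not None:
            self.bin_size = np.asarray(self.bin_size, dtype=float)
            if self.bin_size.shape != (len(self.bin_ids),):
                raise AFLPError("bin_size length does not match bin count")
            for tag, idx in self._source_blocks().items():
                sizes = self.bin_size[idx]
                if np.any(np.diff(sizes) <= 0):
                    raise AFLPError(
                        f"bin sizes must be strictly increasing within source {tag!r}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise AFLPError(f"unknown sample id {sample_id!r}") from None

    def bin_index(self, bin_id: str) -> int:
        try:
            return self.bin_ids.index(bin_id)
        except ValueError:
            raise AFLPError(f"unknown bin id {bin_id!r}") from None

    def _source_blocks(self) -> dict[str, np.ndarray]:
        tags = self.bin_source if self.bin_source is not None else [self.source_tag] * self.n_bins
        blocks: dict[str, list[int]] = {}
        for i, t in enumerate(tags):
            blocks.setdefault(t, []).append(i)
        return {t: np.array(ix, dtype=int) for t, ix in blocks.items()}

    # -- derived views --------------------------------------------------
    def subset(
        self,
        samples: Iterable[str] | None = None,
        bins: Iterable[str] | None = None,
    ) -> "AFLPMatrix":
        """Sub-matrix restricted to the given samples/bins, original order kept."""
        keep_s = set(self.sample_ids if samples is None else samples)
        keep_b = set(self.bin_ids if bins is None else bins)
        for s in keep_s - set(self.sample_ids):
            raise AFLPError(f"unknown sample id {s!r}")
        for b in keep_b - set(self.bin_ids):
            raise AFLPError(f"unknown bin id {b!r}")
        si = [i for i, s in enumerate(self.sample_ids) if s in keep_s]
        bi = [j for j, b in enumerate(self.bin_ids) if b in keep_b]
        return AFLPMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            bin_ids=[self.bin_ids[j] for j in bi],
            calls=self.calls[np.ix_(si, bi)],
            bin_size=None if self.bin_size is None else self.bin_size[bi],
            source_tag=self.source_tag,
            bin_source=None if self.bin_source is None else [self.bin_source[j] for j in bi],
        )

    def drop_bins(self, bin_ids: Iterable[str]) -> "AFLPMatrix":
        drop = set(bin_ids)
        return self.subset(bins=[b for b in self.bin_ids if b not in drop])

    def drop_samples(self, sample_ids: Iterable[str]) -> "AFLPMatrix":
        drop = set(sample_ids)
        return self.subset(samples=[s for s in self.sample_ids if s not in drop])

    def call_strings(self) -> list[str]:
        """One '01?' string per sample, bins in order."""
        return ["".join(CALL_CHARS[int(c)] for c in row) for row in self.calls]

    def equals(self, other: "AFLPMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.bin_ids == other.bin_ids
            and np.array_equal(self.calls, other.calls)
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class ReplicateSet:
    """Declared pairing of sample IDs into replicate pairs of single individuals.

    ``extras`` lists third-or-later replicate profiles that stay in the data
    set as control samples but never enter reliability analysis.
    """

    pairs: list[tuple[str, str]]
    extras: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise AFLPError(f"replicate pair ({a!r}, {b!r}) pairs a sample with itself")
            for s in (a, b):
                if s in seen:
                    raise AFLPError(f"sample {s!r} occurs in more than one replicate pair")
                seen.add(s)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def paired_samples(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]

    def validate_against(self, matrix: AFLPMatrix) -> None:
        known = set(matrix.sample_ids)
        for s in self.paired_samples() + list(self.extras):
            if s not in known:
                raise AFLPError(f"replicate declaration references unknown sample {s!r}")
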