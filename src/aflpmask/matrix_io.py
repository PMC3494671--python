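"""Readers and writers for AFLP character-matrix table dialects.

Two genotyping-software export styles are supported, plus a generic delimited
matrix.  The exact byte layouts of commercial exports vary between versions,
so each dialect is defined here (versioned with the package) and the
``dialect_options`` of each reader absorb real-world variants:

**GeneMapper-style dialect** (also the generic CSV layout)
    One header row: first cell is a sample-column title (ignored), remaining
    cells are bin labels; numeric bin labels double as fragment-size centers.
    One row per sample: sample ID followed by one call per bin.  ``0``/``1``
    are calls; blank, ``?`` and ``NA`` read as missing.  Tab-delimited by
    default (comma for the generic CSV form).

**CEQ-style dialect**
    Bins as rows.  Columns ``Bin``, ``Size``, ``Fragments``, ``Samples``
    followed by one column per sample.  ``Fragments`` counts peaks in the bin
    and ``Samples`` the samples showing at least one peak; ``Fragments`` >
    ``Samples`` reveals a double peak (two markers inside one bin) and the bin
    is pre-masked before any reliability analysis.

Mixing dialect families in one concatenation run is rejected.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masking import MaskResult, PairStateTable, SweepResult
from .matrix import CALL_CHARS, MISSING, AFLPError, AFLPMatrix, ReplicateSet, parse_call

__all__ = [
    "MatrixFormatError",
    "read_genemapper_table",
    "read_ceq_table",
    "read_generic_matrix",
    "read_replicate_pairs",
    "concatenate",
    "write_matrix",
    "write_genemapper_table",
    "write_ceq_table",
    "write_replicate_pairs",
    "write_run_log",
    "render_replicate_overview",
]


class MatrixFormatError(AFLPError):
    """Raised for unparseable or internally inconsistent table files."""


def _read_table(path: str, delimiter: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise MatrixFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0,
            dtype=str,
            keep_default_na=False,
            comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise MatrixFormatError(f"empty table: {path}") from None
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise MatrixFormatError(f"empty or column-less table: {path}")
    return df


def _maybe_sizes(bin_ids: Sequence[str]) -> np.ndarray | None:
    """Numeric, strictly increasing bin labels double as size centers."""
    try:
        sizes = np.array([float(b) for b in bin_ids])
    except ValueError:
        return None
    if np.any(np.diff(sizes) <= 0):
        return None
    return sizes


def read_genemapper_table(
    path: str,
    delimiter: str = "\t",
    source_tag: str | None = None,
) -> AFLPMatrix:
    """Read a GeneMapper-style samples-as-rows table into an AFLPMatrix.

    Calls preserve file order; unparseable cells become ``?``; bin sizes are
    taken from the bin labels when those are numeric and increasing.
    """
    # ragged rows: pandas pads short rows with NaN -> caught as ragged below
    raw = [line.rstrip("\n").split(delimiter) for line in open(path) if line.strip()]
    if not raw or len(raw) < 2:
        raise MatrixFormatError(f"empty table: {path}")
    header = raw[0]
    n_cols = len(header)
    bin_ids = [h.strip() for h in header[1:]]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for r, row in enumerate(raw[1:], start=2):
        if len(row) != n_cols:
            raise MatrixFormatError(
                f"{path}: ragged row {r} has {len(row)} fields, expected {n_cols}"
            )
        sid = row[0].strip()
        if sid in sample_ids:
            raise MatrixFormatError(f"{path}: duplicate sample row {sid!r}")
        sample_ids.append(sid)
        rows.append([parse_call(c) for c in row[1:]])
    tag = source_tag if source_tag is not None else os.path.basename(path)
    return AFLPMatrix(
        sample_ids=sample_ids,
        bin_ids=bin_ids,
        calls=np.array(rows, dtype=np.int8),
        bin_size=_maybe_sizes(bin_ids),
        source_tag=tag,
    )


def read_generic_matrix(path: str, delimiter: str = ",", source_tag: str | None = None) -> AFLPMatrix:
    """Generic delimited matrix: the GeneMapper-style layout with commas."""
    return read_genemapper_table(path, delimiter=delimiter, source_tag=source_tag)


@dataclass
class CeqColumns:
    """Header names of the CEQ-style dialect's count columns."""

    bin: str = "Bin"
    size: str = "Size"
    fragments: str = "Fragments"
    samples: str = "Samples"


def read_ceq_table(
    path: str,
    delimiter: str = "\t",
    columns: CeqColumns | None = None,
    source_tag: str | None = None,
) -> tuple[AFLPMatrix, set[str]]:
    """Read a CEQ-style bins-as-rows table.

    Returns the matrix over analyzable bins plus the IDs of double-peak bins
    (``Fragments != Samples``) that are pre-masked before any analysis.
    """
    cols = columns or CeqColumns()
    df = _read_table(path, delimiter)
    for name in (cols.bin, cols.fragments, cols.samples):
        if name not in df.columns:
            raise MatrixFormatError(f"{path}: missing required column {name!r}")
    has_size = cols.size in df.columns
    meta = {cols.bin, cols.fragments, cols.samples} | ({cols.size} if has_size else set())
    sample_ids = [c for c in df.columns if c not in meta]
    if not sample_ids:
        raise MatrixFormatError(f"{path}: no sample columns found")

    bin_ids = [b.strip() for b in df[cols.bin].tolist()]
    prelim: set[str] = set()
    keep_rows: list[int] = []
    for i, bid in enumerate(bin_ids):
        try:
            frags = int(df[cols.fragments].iloc[i])
            samps = int(df[cols.samples].iloc[i])
        except ValueError:
            raise MatrixFormatError(
                f"{path}: non-numeric Fragments/Samples count at bin {bid!r}"
            ) from None
        if frags < samps:
            raise MatrixFormatError(
                f"{path}: bin {bid!r} has Fragments={frags} < Samples={samps} (impossible)"
            )
        if frags != samps:
            prelim.add(bid)
        else:
            keep_rows.append(i)

    calls = np.array(
        [[parse_call(df[s].iloc[i]) for i in keep_rows] for s in sample_ids],
        dtype=np.int8,
    ).reshape(len(sample_ids), len(keep_rows))
    sizes = None
    if has_size:
        try:
            sizes = np.array([float(df[cols.size].iloc[i]) for i in keep_rows])
        except ValueError:
            sizes = None
    tag = source_tag if source_tag is not None else os.path.basename(path)
    matrix = AFLPMatrix(
        sample_ids=sample_ids,
        bin_ids=[bin_ids[i] for i in keep_rows],
        calls=calls,
        bin_size=sizes,
        source_tag=tag,
    )
    return matrix, prelim


def read_replicate_pairs(path: str, delimiter: str = "\t") -> ReplicateSet:
    """Two-column pairing file: first and second replicate sample ID per line."""
    pairs: list[tuple[str, str]] = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) < 2:
            raise MatrixFormatError(f"{path}: replicate line needs two sample IDs: {line!r}")
        pairs.append((fields[0], fields[1]))
    return ReplicateSet(pairs=pairs)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate(matrices: Sequence[AFLPMatrix]) -> AFLPMatrix:
    """Concatenate per-primer matrices into one supermatrix.

    Samples are the union (first-appearance order); bins are the disjoint
    union namespaced ``sourceTag:binID`` when more than one matrix is given.
    A sample absent from a source matrix gets ``?`` at all of that source's
    bins.
    """
    matrices = list(matrices)
    if not matrices:
        raise AFLPError("nothing to concatenate: empty matrix list")
    if len(matrices) == 1:
        return matrices[0]
    tags = [m.source_tag for m in matrices]
    if len(set(tags)) != len(tags):
        # colliding bin IDs across sources can no longer be disambiguated
        flat = [b for m in matrices for b in m.bin_ids]
        if len(set(flat)) != len(flat):
            raise AFLPError(
                "bin IDs collide across sources and source tags are not distinct"
            )
    samples: list[str] = []
    for m in matrices:
        for s in m.sample_ids:
            if s not in samples:
                samples.append(s)
    bin_ids: list[str] = []
    bin_source: list[str] = []
    sizes: list[float] = []
    have_sizes = all(m.bin_size is not None for m in matrices)
    blocks: list[np.ndarray] = []
    for m in matrices:
        tag = m.source_tag
        for b in m.bin_ids:
            bin_ids.append(f"{tag}:{b}")
            bin_source.append(tag)
        if have_sizes:
            sizes.extend(m.bin_size.tolist())
        block = np.full((len(samples), m.n_bins), MISSING, dtype=np.int8)
        for i, s in enumerate(m.sample_ids):
            block[samples.index(s), :] = m.calls[i, :]
        blocks.append(block)
    if len(set(bin_ids)) != len(bin_ids):
        raise AFLPError("bin IDs collide across sources even after namespacing")
    return AFLPMatrix(
        sample_ids=samples,
        bin_ids=bin_ids,
        calls=np.hstack(blocks),
        bin_size=np.array(sizes) if have_sizes else None,
        source_tag="+".join(tags),
        bin_source=bin_source,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _apply_write_mask(
    matrix: AFLPMatrix,
    mask: Iterable[str],
    masked_samples: Iterable[str],
) -> AFLPMatrix:
    mask = set(mask)
    masked_samples = set(masked_samples)
    unknown = mask - set(matrix.bin_ids)
    if unknown:
        raise AFLPError(f"mask references unknown bin {sorted(unknown)[0]!r}")
    unknown_s = masked_samples - set(matrix.sample_ids)
    if unknown_s:
        raise AFLPError(f"mask references unknown sample {sorted(unknown_s)[0]!r}")
    out = matrix.drop_bins(mask).drop_samples(masked_samples)
    if out.n_bins == 0:
        raise AFLPError("all bins masked: nothing to write")
    return out


def write_genemapper_table(matrix: AFLPMatrix, path: str, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["Sample", *matrix.bin_ids]) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.calls):
            fh.write(delimiter.join([sid, *(CALL_CHARS[int(c)] for c in row)]) + "\n")


def write_ceq_table(
    matrix: AFLPMatrix,
    path: str,
    delimiter: str = "\t",
    double_peak_extra: dict[str, int] | None = None,
) -> None:
    """Write the CEQ-style dialect.

    ``Fragments``/``Samples`` counts are derived from the presence calls;
    ``double_peak_extra`` adds surplus fragments to selected bins, marking
    them as double-peak bins (used for fixtures and round-trip tests).
    """
    extra = double_peak_extra or {}
    sizes = matrix.bin_size
    with open(path, "w") as fh:
        fh.write(delimiter.join(["Bin", "Size", "Fragments", "Samples", *matrix.sample_ids]) + "\n")
        for j, bid in enumerate(matrix.bin_ids):
            n_present = int((matrix.calls[:, j] == 1).sum())
            frags = n_present + int(extra.get(bid, 0))
            size = f"{sizes[j]:.2f}" if sizes is not None else f"{60 + j:.2f}"
            calls = (CALL_CHARS[int(c)] for c in matrix.calls[:, j])
            fh.write(delimiter.join([bid, size, str(frags), str(n_present), *calls]) + "\n")


def _nexus_quote(label: str) -> str:
    if any(ch in label for ch in " '(){}[]/\\,;:=*\"`+<>~"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(matrix: AFLPMatrix, path: str) -> None:
    """Standard-datatype NEXUS characters block, symbols "01", missing "?"."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_samples} NCHAR={matrix.n_bins};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
        fh.write("    MATRIX\n")
        width = max(len(_nexus_quote(s)) for s in matrix.sample_ids) + 2
        for sid, row in zip(matrix.sample_ids, matrix.call_strings()):
            fh.write(f"    {_nexus_quote(sid):<{width}}{row}\n")
        fh.write("    ;\nEND;\n")


def write_matrix(
    matrix: AFLPMatrix,
    mask: Iterable[str] = (),
    format: str = "txt",
    path: str = "matrix.txt",
    masked_samples: Iterable[str] = (),
) -> None:
    """Write the matrix with masked bins (and samples) omitted.

    ``format="txt"`` mirrors the GeneMapper-style input layout; ``"nexus"``
    writes a characters block loadable by downstream phylogeny programs.
    """
    out = _apply_write_mask(matrix, mask, masked_samples)
    if format == "txt":
        write_genemapper_table(out, path)
    elif format == "nexus":
        write_nexus(out, path)
    else:
        raise AFLPError(f"unknown output format {format!r} (use 'txt' or 'nexus')")


def write_replicate_pairs(reps: ReplicateSet, path: str, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in reps.pairs:
            fh.write(f"{a}{delimiter}{b}\n")


def write_run_log(sweep: SweepResult, path: str) -> None:
    """Main log: every threshold set with its error rates and bin counts,
    followed by the grouped (emitted) matrices."""
    th = sweep.thresholds
    with open(path, "w") as fh:
        fh.write("# Masking threshold sweep\n")
        fh.write(
            f"# BR {th.br_min:.2f}..{th.br_max:.2f} step {th.br_step:.2f}; "
            f"RR {', '.join(f'{r:.1f}' for r in th.rr_grid())}; BD {th.bd}\n"
        )
        fh.write(
            f"# emission: {th.error_metric} error < {th.error_cutoff} "
            f"and > {th.min_bins} bins remaining\n"
        )
        fh.write("BR\tRR\tstatus\tr_bonin\tr_jaccard\tbins\tpairs\titerations\n")
        for cell in sweep.cells:
            if cell.result is None:
                fh.write(f"{cell.br:.2f}\t{cell.rr:.1f}\tfailed\t-\t-\t-\t-\t-\t# {cell.error}\n")
            else:
                r = cell.result
                fh.write(
                    f"{cell.br:.2f}\t{cell.rr:.1f}\tok\t{r.r_bonin:.5f}\t{r.r_jaccard:.5f}\t"
                    f"{r.n_bins_remaining}\t{r.n_pairs_remaining}\t{r.iterations}\n"
                )
        fh.write("\n# Distinct masked matrices (grouped by identical masked sets)\n")
        fh.write("group\tBR_range\tRR_range\temitted\tr_bonin\tr_jaccard\tbins\tpairs\n")
        for g in sweep.groups:
            r = g.result
            fh.write(
                f"{g.label}\t{g.br_range[0]:.2f}-{g.br_range[1]:.2f}\t"
                f"{g.rr_range[0]:.1f}-{g.rr_range[1]:.1f}\t{'yes' if g.emitted else 'no'}\t"
                f"{r.r_bonin:.5f}\t{r.r_jaccard:.5f}\t{r.n_bins_remaining}\t{r.n_pairs_remaining}\n"
            )


# three-way state colors plus ambiguous, per the replicate-overview convention
_STATE_COLORS = {
    0: "#9ecae1",  # (0,0) reproducible absence — light blue
    1: "#08519c",  # (1,1) reproducible presence — dark blue
    2: "#de2d26",  # (0,1)/(1,0) unreproducible — red
    3: "#bdbdbd",  # any ? — ambiguous, grey
}


def replicate_overview_codes(
    table: PairStateTable,
    bin_keep: np.ndarray | None = None,
    pair_keep: np.ndarray | None = None,
) -> np.ndarray:
    """Integer-coded overview grid: 0=(0,0), 1=(1,1), 2=mismatch, 3=ambiguous."""
    codes = np.full((table.n_pairs, table.n_bins), 3, dtype=np.int8)
    codes[table.both_absent] = 0
    codes[table.both_present] = 1
    codes[table.mismatch] = 2
    if pair_keep is not None:
        codes = codes[np.asarray(pair_keep, dtype=bool), :]
    if bin_keep is not None:
        codes = codes[:, np.asarray(bin_keep, dtype=bool)]
    return codes


def render_replicate_overview(
    table: PairStateTable,
    path: str,
    bin_keep: np.ndarray | None = None,
    pair_keep: np.ndarray | None = None,
    title: str | None = None,
) -> None:
    """Render the replicate-pair x bin overview image (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    codes = replicate_overview_codes(table, bin_keep, pair_keep)
    cmap = ListedColormap([_STATE_COLORS[i] for i in range(4)])
    h = max(1.5, 0.25 * codes.shape[0] + 1.2)
    w = max(4.0, 0.05 * codes.shape[1] + 2.0)
    fig, ax = plt.subplots(figsize=(min(w, 16), min(h, 10)))
    ax.imshow(codes, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="nearest")
    ax.set_xlabel("bin")
    ax.set_ylabel("replicate pair")
    if title:
        ax.set_title(title)
    legend = [
        Patch(color=_STATE_COLORS[0], label="(0,0) reproducible"),
        Patch(color=_STATE_COLORS[1], label="(1,1) reproducible"),
        Patch(color=_STATE_COLORS[2], label="(0,1)/(1,0) unreproducible"),
        Patch(color=_STATE_COLORS[3], label="ambiguous (?)"),
    ]
    ax.legend(handles=legend, loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
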