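"""Readers and writers for every external representation the pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout.  Genomic
windows are fixed-width, non-overlapping tiles of the genome; motifs are
TRANSFAC-dialect count matrices; sample sheets and motif->TF-group maps are
headered TSV tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomeWindow:
    """A fixed-width genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class SampleSheet:
    """Mapping of samples to cell types (one cell type per sample)."""

    table: pd.DataFrame  # columns: sample_id, cell_type [, file_path]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "cell_type"):
            if col not in t.columns:
                raise ParseError(f"sample sheet missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ParseError(f"duplicate sample_id {dup!r}")
        empty = t["cell_type"].isna() | (t["cell_type"].astype(str).str.len() == 0)
        if empty.any():
            sid = t.loc[empty, "sample_id"].iloc[0]
            raise ParseError(f"sample {sid!r} has empty cell_type")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_types(self) -> list[str]:
        """Distinct cell types in first-appearance order."""
        return list(dict.fromkeys(self.table["cell_type"]))

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def samples_of(self, cell_type: str) -> list[str]:
        t = self.table
        return list(t.loc[t["cell_type"] == cell_type, "sample_id"])


@dataclass
class MotifMatrix:
    """Per-position base-count matrix for one TF motif (columns A,C,G,T)."""

    motif_id: str
    name: str
    counts: np.ndarray  # shape (width, 4), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be (width, 4)")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative count")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError(f"motif {self.motif_id}: all-zero position")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass
class MotifGroupMap:
    """Total mapping motif_id -> TF group/family label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ParseError("motif-group map is empty")

    @property
    def n_motifs(self) -> int:
        return len(self.mapping)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def n_groups(self) -> int:
        return len(set(self.mapping.values()))

    def group_of(self, motif_id: str) -> str:
        return self.mapping[motif_id]


# ---------------------------------------------------------------------------
# genome tiling


def tile_genome(
    genome_lengths: Mapping[str, int],
    width: int = 200,
    blacklist: Iterable[tuple[str, int, int]] | None = None,
    min_overlap: int = 1,
) -> list[GenomeWindow]:
    """Tile each chromosome into non-overlapping fixed-width windows.

    Trailing sub-width remainders are dropped.  A window overlapping any
    blacklist interval by at least ``min_overlap`` bp is removed.  Windows are
    returned sorted by (chrom, start).
    """
    if not genome_lengths:
        raise ValueError("empty genome_lengths")
    if width < 1:
        raise ValueError("width must be >= 1")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    removed: dict[str, set[int]] = {}
    for chrom, bstart, bend in blacklist or ():
        if bstart < 0 or bend < bstart:
            raise ValueError(f"negative/inverted blacklist interval {chrom}:{bstart}-{bend}")
        idx = removed.setdefault(chrom, set())
        first = bstart // width
        last = (bend - 1) // width if bend > bstart else first - 1
        for i in range(first, last + 1):
            w_start, w_end = i * width, (i + 1) * width
            if min(w_end, bend) - max(w_start, bstart) >= min_overlap:
                idx.add(i)

    windows: list[GenomeWindow] = []
    for chrom in sorted(genome_lengths):
        length = genome_lengths[chrom]
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
        bad = removed.get(chrom, set())
        for i in range(length // width):
            if i not in bad:
                windows.append(GenomeWindow(chrom, i * width, (i + 1) * width))
    return windows


# ---------------------------------------------------------------------------
# TRANSFAC motif flat file

_TRANSFAC_SKIP = {"XX", "BF", "BA", "BS", "CC", "DT", "DE", "OS", "OC", "RN", "RA", "RT", "RL", "RX", "VV"}


def parse_transfac(text: str) -> list[MotifMatrix]:
    """Parse the TRANSFAC matrix flat-file dialect (AC/ID/P0 + numbered rows).

    Each record contributes one :class:`MotifMatrix`; row order defines the
    motif width.  Malformed count rows raise :class:`ParseError` naming the
    offending line number.
    """
    motifs: list[MotifMatrix] = []
    ac: str | None = None
    name: str = ""
    rows: list[list[float]] = []
    in_matrix = False
    saw_record = False

    def flush(lineno: int) -> None:
        nonlocal ac, name, rows, in_matrix
        if ac is None and not rows:
            return
        if ac is None:
            raise ParseError(f"line {lineno}: matrix record without AC accession")
        if not rows:
            raise ParseError(f"line {lineno}: record {ac} has no matrix rows")
        try:
            motifs.append(MotifMatrix(ac, name or ac, np.array(rows)))
        except ValueError as exc:
            raise ParseError(f"record ending at line {lineno}: {exc}") from exc
        ac, name, rows, in_matrix = None, "", [], False

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        tag = line.split(maxsplit=1)[0]
        if tag == "//":
            flush(lineno)
            saw_record = True
            continue
        if tag == "AC":
            if ac is not None or rows:
                flush(lineno)
            parts = line.split(maxsplit=1)
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: AC row without accession")
            ac = parts[1].strip()
            saw_record = True
            continue
        if tag == "ID" or tag == "NA":
            parts = line.split(maxsplit=1)
            name = parts[1].strip() if len(parts) == 2 else name
            continue
        if tag == "P0" or tag == "PO":
            in_matrix = True
            continue
        if tag in _TRANSFAC_SKIP:
            continue
        if in_matrix and tag[:1].isdigit():
            fields = line.split()
            # position label, four base counts, optional consensus letter
            vals = fields[1:5]
            if len(vals) != 4:
                raise ParseError(f"line {lineno}: expected 4 count fields, got {len(fields) - 1}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric count field") from None
            continue
        # unknown tag outside matrix: tolerate (TRANSFAC carries many annotations)
    flush(lineno)
    if not saw_record and not motifs:
        raise ParseError("no TRANSFAC records found")
    return motifs


def write_transfac(motifs: Sequence[MotifMatrix]) -> str:
    """Serialize motifs to the TRANSFAC dialect accepted by :func:`parse_transfac`."""
    out: list[str] = []
    for m in motifs:
        out.append(f"AC  {m.motif_id}")
        out.append("XX")
        out.append(f"ID  {m.name}")
        out.append("XX")
        out.append("P0      A      C      G      T")
        for i, row in enumerate(m.counts, start=1):
            cells = "  ".join(f"{v:g}" for v in row)
            out.append(f"{i:02d}  {cells}  {BASES[int(np.argmax(row))]}")
        out.append("XX")
        out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# tables


def load_sample_map(path_or_buf) -> SampleSheet:
    """Load the sample->cell-type sheet (TSV with header)."""
    table = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    return SampleSheet(table)


def load_motif_group_map(path_or_buf) -> MotifGroupMap:
    """Load the motif->TF-group map (TSV with columns motif_id, tf_group)."""
    t = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    for col in ("motif_id", "tf_group"):
        if col not in t.columns:
            raise ParseError(f"motif-group map missing column {col!r}")
    conflicts = t.groupby("motif_id")["tf_group"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ParseError(f"motif {bad.index[0]!r} listed with {bad.iloc[0]} different groups")
    return MotifGroupMap(dict(zip(t["motif_id"], t["tf_group"])))


def write_motif_group_map(mg: MotifGroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {"motif_id": list(mg.mapping), "tf_group": list(mg.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / FASTA helpers


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3+ intervals (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED fields")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_bed_reads(path: str | Path):
    """Yield (chrom, start, end, strand) for each BED6 read interval.

    Missing strand defaults to '+'.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "+"
            yield f[0], int(f[1]), int(f[2]), strand


def write_bed(windows: Iterable[GenomeWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.id}\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


class SequenceSource:
    """Uniform per-window sequence access over a FASTA file or a dict.

    FASTA files are read through ``pyfaidx`` (indexed access); in-memory
    dictionaries map chromosome name -> sequence string.
    """

    def __init__(self, source) -> None:
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}

    def fetch(self, window: GenomeWindow) -> str:
        if self._dict is not None:
            chrom = self._dict.get(window.chrom)
            if chrom is None or window.end > len(chrom):
                raise KeyError(f"window {window.id} not resolvable in sequence source")
            return chrom[window.start : window.end]
        if window.chrom not in self._fasta:
            raise KeyError(f"window {window.id}: unknown chromosome")
        if window.end > len(self._fasta[window.chrom]):
            raise KeyError(f"window {window.id} extends beyond chromosome end")
        return str(self._fasta[window.chrom][window.start : window.end])

    def lengths(self) -> dict[str, int]:
        if self._dict is not None:
            return {k: len(v) for k, v in self._dict.items()}
        return {name: len(rec) for name, rec in self._fasta.items()}
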