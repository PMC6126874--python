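"""Chromatin-accessibility specificity scoring.

Builds the window x sample count matrix from per-sample read intervals,
log-normalizes it for sequencing depth, computes a regularized t-statistic
per window per cell type, and selects the top-l cell-type-specific (CTS)
and top-l ubiquitously open DHS windows.

The t-statistic for window w and cell type ct is

    t_ct = (X̄_ct − X̄) / (sqrt(1/m + 1/n_ct) · (s + s0))

where X̄_ct is the mean log count over the cell type's samples, X̄ the mean
of the m cell-type means, s the pooled within-cell-type standard deviation
of the window, and s0 the mean of s over all windows (a variance
regularizer preventing division by small per-window estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeWindow, SampleSheet, SequenceSource


@dataclass
class CountMatrix:
    """Window x sample accessibility matrix with a processing-stage marker."""

    windows: list[GenomeWindow]
    samples: SampleSheet
    values: np.ndarray  # (n_windows, n_samples)
    stage: str = "raw"  # "raw" (counts) or "log" (log-normalized)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.windows), self.samples.n_samples):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.windows)} windows x {self.samples.n_samples} samples"
            )
        if self.stage == "raw":
            if (self.values < 0).any():
                raise ValueError("raw counts must be non-negative")
        elif self.stage == "log":
            if (self.values < 0).any():
                raise ValueError("log-stage values must be >= 0")
        else:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def window_ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.window_ids, columns=self.samples.sample_ids)


@dataclass
class SpecificityResult:
    """Per-window, per-cell-type regularized t-statistics and components."""

    windows: list[GenomeWindow]
    cell_types: list[str]
    t: np.ndarray            # (n_windows, m)
    s: np.ndarray            # (n_windows,) pooled within-cell-type SD
    s0: float                # regularizer: mean of s over windows
    cell_means: np.ndarray   # (n_windows, m)
    global_mean: np.ndarray  # (n_windows,)


@dataclass
class DHSSelection:
    """Top-l CTS windows per cell type plus the shared top-l ubiquitous windows."""

    cts: dict[str, list[GenomeWindow]]
    ubiq: list[GenomeWindow]
    l: int

    def __post_init__(self) -> None:
        ubiq_ids = {w.id for w in self.ubiq}
        if len(self.ubiq) != self.l:
            raise ValueError(f"ubiquitous selection has {len(self.ubiq)} windows, expected l={self.l}")
        for ct, ws in self.cts.items():
            if len(ws) != self.l:
                raise ValueError(f"{ct}: {len(ws)} CTS windows, expected l={self.l}")
            if ubiq_ids & {w.id for w in ws}:
                raise ValueError(f"{ct}: CTS and ubiquitous selections overlap")

    def stratum(self, cell_type: str) -> tuple[list[GenomeWindow], np.ndarray]:
        """The 2l joint DHS list (CTS first, then ubiq) and the CTS indicator z."""
        dhss = list(self.cts[cell_type]) + list(self.ubiq)
        z = np.zeros(2 * self.l, dtype=bool)
        z[: self.l] = True
        return dhss, z


# ---------------------------------------------------------------------------


def count_reads(
    windows: list[GenomeWindow],
    reads_per_sample: dict[str, "object"],
    samples: SampleSheet,
) -> CountMatrix:
    """Count reads by strand-aware 5' end into non-overlapping windows.

    A plus-strand read's 5' end is its start; a minus-strand read's 5' end is
    ``end − 1``.  Each read therefore increments at most one window.  Reads on
    chromosomes absent from the tiling are skipped with a warning.
    """
    if not windows:
        raise ValueError("no windows")
    width = windows[0].width
    index = {(w.chrom, w.start): i for i, w in enumerate(windows)}
    values = np.zeros((len(windows), samples.n_samples), dtype=float)
    unknown: set[str] = set()
    chroms = {w.chrom for w in windows}

    for j, sid in enumerate(samples.sample_ids):
        for chrom, start, end, strand in reads_per_sample[sid]:
            if chrom not in chroms:
                unknown.add(chrom)
                continue
            pos = start if strand != "-" else end - 1
            key = (chrom, (pos // width) * width)
            i = index.get(key)
            if i is not None:
                values[i, j] += 1
    if unknown:
        warnings.warn(f"skipped reads on unknown chromosomes: {sorted(unknown)}", stacklevel=2)
    return CountMatrix(windows, samples, values, stage="raw")


def normalize_log(raw: CountMatrix, grand_mean: str = "entries") -> CountMatrix:
    """Depth-normalize raw counts and apply the natural-log transform.

    Each sample's counts are scaled by (mean read count over all samples) /
    (sample's mean read count), then transformed as ln(scaled + 1).  The
    pseudocount is applied after scaling so it is depth-independent.
    ``grand_mean`` selects whether the numerator averages over all matrix
    entries (default) or over the per-sample means.
    """
    if raw.stage != "raw":
        raise ValueError("normalize_log expects a raw-stage matrix")
    sample_means = raw.values.mean(axis=0)
    zero = np.flatnonzero(sample_means == 0)
    if zero.size:
        raise ValueError(f"sample {raw.samples.sample_ids[zero[0]]!r} has all-zero counts")
    if grand_mean == "entries":
        gm = raw.values.mean()
    elif grand_mean == "sample_means":
        gm = sample_means.mean()
    else:
        raise ValueError(f"unknown grand_mean mode {grand_mean!r}")
    factors = gm / sample_means
    values = np.log(raw.values * factors + 1.0)
    return CountMatrix(raw.windows, raw.samples, values, stage="log")


def t_statistic(logmat: CountMatrix, radical: str = "factor") -> SpecificityResult:
    """Regularized t-statistic of cell-type specificity for every window.

    Cell types with a single sample contribute nothing to the pooled SD but
    still receive a t value.  ``radical`` selects the denominator form:
    ``"factor"`` (default) uses sqrt(1/m + 1/n_ct)·(s + s0); ``"full"``
    places s + s0 under the radical.
    """
    if logmat.stage != "log":
        raise ValueError("t_statistic expects a log-stage matrix")
    sheet = logmat.samples
    cell_types = sheet.cell_types
    m = len(cell_types)
    if m < 2:
        raise ValueError("need at least 2 cell types")

    X = logmat.values
    n_w = X.shape[0]
    col_of = {sid: j for j, sid in enumerate(sheet.sample_ids)}
    groups = [[col_of[s] for s in sheet.samples_of(ct)] for ct in cell_types]
    n_ct = np.array([len(g) for g in groups], dtype=float)

    cell_means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    global_mean = cell_means.mean(axis=1)

    ss = np.zeros(n_w)
    dof = 0.0
    for g, means_col in zip(groups, cell_means.T):
        if len(g) > 1:
            ss += ((X[:, g] - means_col[:, None]) ** 2).sum(axis=1)
            dof += len(g) - 1
    if dof == 0:
        raise ValueError("pooled SD undefined: every cell type has a single sample")
    s = np.sqrt(ss / dof)
    s0 = float(s.mean())

    scale = np.sqrt(1.0 / m + 1.0 / n_ct)  # (m,)
    if radical == "factor":
        denom = scale[None, :] * (s + s0)[:, None]
    elif radical == "full":
        denom = np.sqrt((1.0 / m + 1.0 / n_ct)[None, :] * (s + s0)[:, None])
    else:
        raise ValueError(f"unknown radical mode {radical!r}")
    num = cell_means - global_mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    # degenerate windows (zero pooled SD and zero regularizer): zero deviation -> t = 0
    t[np.broadcast_to(denom == 0, t.shape) & (num == 0)] = 0.0
    return SpecificityResult(logmat.windows, cell_types, t, s, s0, cell_means, global_mean)


def _coord_order(windows: list[GenomeWindow]) -> np.ndarray:
    """Stable rank of windows by (chrom, start), used to break score ties."""
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    rank = np.empty(len(windows), dtype=int)
    rank[order] = np.arange(len(windows))
    return rank


def select_cts(spec: SpecificityResult, l: int) -> dict[str, list[GenomeWindow]]:
    """Per cell type, the l windows with largest t, descending; ties by coordinate."""
    n = len(spec.windows)
    if l > n:
        raise ValueError(f"l={l} exceeds {n} windows")
    rank = _coord_order(spec.windows)
    out: dict[str, list[GenomeWindow]] = {}
    for j, ct in enumerate(spec.cell_types):
        order = np.lexsort((rank, -spec.t[:, j]))
        out[ct] = [spec.windows[i] for i in order[:l]]
    return out


def select_ubiq(
    spec: SpecificityResult,
    l: int,
    open_quantile: float = 0.75,
    exclude: set[str] | None = None,
) -> list[GenomeWindow]:
    """The l open windows with global t-score closest to zero.

    Eligible windows have global mean accessibility above the
    ``open_quantile`` quantile of all windows; among those (minus any
    explicitly excluded ids), the l windows with smallest max_ct |t| are
    returned ascending, ties broken by coordinate.
    """
    thr = float(np.quantile(spec.global_mean, open_quantile))
    eligible = spec.global_mean > thr
    if exclude:
        for i, w in enumerate(spec.windows):
            if w.id in exclude:
                eligible[i] = False
    idx = np.flatnonzero(eligible)
    if idx.size < l:
        raise ValueError(f"only {idx.size} eligible windows for l={l}")
    score = np.abs(spec.t[idx]).max(axis=1)
    rank = _coord_order(spec.windows)[idx]
    order = np.lexsort((rank, score))
    return [spec.windows[idx[i]] for i in order[:l]]


def select_dhs(spec: SpecificityResult, l: int, open_quantile: float = 0.75) -> DHSSelection:
    """Select CTS windows per cell type, then ubiquitous windows from the rest.

    Windows chosen as CTS for any cell type are excluded from the ubiquitous
    pool so the two strata are disjoint.
    """
    cts = select_cts(spec, l)
    taken = {w.id for ws in cts.values() for w in ws}
    ubiq = select_ubiq(spec, l, open_quantile, exclude=taken)
    return DHSSelection(cts, ubiq, l)


def characterize_dhs(
    windows: list[GenomeWindow],
    genome: SequenceSource,
    annotations: dict[str, list[tuple[str, int, int]]] | None = None,
) -> dict:
    """GC content and annotation-overlap summary for a DHS window set.

    Returns mean GC fraction over the windows and, per annotation set, the
    fraction of windows overlapping it by at least 1 bp.
    """
    if not windows:
        raise ValueError("empty window set")
    gc = []
    for w in windows:
        seq = genome.fetch(w)
        acgt = sum(seq.count(b) for b in "ACGT")
        gc.append((seq.count("G") + seq.count("C")) / acgt if acgt else np.nan)
    result = {"n": len(windows), "mean_gc": float(np.nanmean(gc))}
    overlaps = {}
    for name, intervals in (annotations or {}).items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        hit = 0
        for w in windows:
            for s, e in by_chrom.get(w.chrom, ()):
                if min(w.end, e) - max(w.start, s) >= 1:
                    hit += 1
                    break
        overlaps[name] = hit / len(windows)
    result["overlap_fraction"] = overlaps
    return result


# ---------------------------------------------------------------------------
# table I/O for resumable pipelines


def load_count_matrix(path, samples: SampleSheet, stage: str = "raw") -> CountMatrix:
    """Read a window x sample TSV (rows indexed by window id "chrom:start-end")."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df[samples.sample_ids]
    windows = []
    for wid in df.index:
        chrom, rest = wid.rsplit(":", 1)
        start, end = rest.split("-")
        windows.append(GenomeWindow(chrom, int(start), int(end)))
    return CountMatrix(windows, samples, df.to_numpy(), stage=stage)


def specificity_frame(spec: SpecificityResult) -> pd.DataFrame:
    df = pd.DataFrame(spec.t, index=[w.id for w in spec.windows], columns=spec.cell_types)
    df.insert(0, "global_mean", spec.global_mean)
    df.insert(1, "pooled_sd", spec.s)
    return df
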