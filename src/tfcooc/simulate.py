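"""Synthetic study generator with planted ground truth.

Emulates the data model the pipeline assumes: a multi-cell-type DNase-seq
count matrix over fixed-width genome windows with planted cell-type-specific
and ubiquitously open windows, and window sequences with planted
co-occurring motif pairs.  Counts are negative-binomial (DNase-seq
replicates are overdispersed relative to Poisson, and the t-statistic's s0
regularization only matters under within-class variance).  Planted motif
occurrences are consensus words so the truth table is unambiguous.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so each sub-generator is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    GenomeWindow,
    MotifGroupMap,
    MotifMatrix,
    SampleSheet,
    write_bed,
    write_fasta,
    write_motif_group_map,
    write_transfac,
)
from .chromatin import CountMatrix

CHROM = "chrS"


def default_motif_set(
    n_motifs: int = 12,
    n_groups: int = 8,
    width: int = 8,
    seed: int = 7,
    consensus_count: float = 20.0,
    off_count: float = 1.0,
) -> tuple[list[MotifMatrix], MotifGroupMap]:
    """A deterministic motif collection with distinct random consensus words.

    The first ``n_groups`` motifs get their own TF group; the remainder are
    assigned round-robin to the first groups (so some groups hold several
    motifs, as TF families do).
    """
    if n_motifs < n_groups:
        raise ValueError("need n_motifs >= n_groups")
    rng = np.random.default_rng(seed)
    words: list[str] = []
    while len(words) < n_motifs:
        w = "".join(rng.choice(list(BASES), size=width))
        if w not in words:
            words.append(w)
    motifs = []
    mapping = {}
    for i, word in enumerate(words):
        counts = np.full((width, 4), off_count)
        for pos, base in enumerate(word):
            counts[pos, BASES.index(base)] = consensus_count
        mid = f"M{i:03d}"
        motifs.append(MotifMatrix(mid, f"TFM{i:03d}", counts))
        mapping[mid] = f"G{i % n_groups:02d}"
    return motifs, MotifGroupMap(mapping)


@dataclass
class PlantedSpec:
    """Parameters of one synthetic study (the generator's study conditions)."""

    n_windows: int = 2000
    n_cell_types: int = 4
    samples_per_cell_type: int = 3
    window_width: int = 200
    baseline_mean: float = 50.0        # expected count in ubiquitously open windows
    closed_mean: float = 2.0           # expected count in closed/background windows
    specificity_effect: float = 8.0    # multiplicative elevation in planted CTS windows
    nb_dispersion: float = 10.0        # negative-binomial size parameter
    n_cts_per_type: int = 100
    n_ubiq: int = 100
    n_motifs: int = 12
    n_motif_groups: int = 8
    motif_width: int = 8
    planting_rate: float = 0.6         # per-window probability of planting a pair
    background_motif_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planting_rate <= 1 or not 0 <= self.background_motif_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.specificity_effect < 1:
            raise ValueError("specificity_effect must be >= 1")
        needed = self.n_ubiq + self.n_cell_types * self.n_cts_per_type
        if needed > self.n_windows:
            raise ValueError(f"window budget infeasible: {needed} planted > {self.n_windows} total")
        if self.motif_width >= self.window_width:
            raise ValueError("motifs must be narrower than windows")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i}" for i in range(self.n_cell_types)]

    def motif_set(self) -> tuple[list[MotifMatrix], MotifGroupMap]:
        return default_motif_set(self.n_motifs, self.n_motif_groups, self.motif_width)

    def cooccur_pairs(self) -> list[tuple[str, str, str, float]]:
        """Default planting design: one cross-group motif pair per cell type.

        Cell type i gets the pair (M{2i}, M{2i+1}); with the default grouping
        those motifs sit in distinct groups.
        """
        pairs = []
        for i, ct in enumerate(self.cell_types):
            a, b = 2 * i, 2 * i + 1
            if b >= self.n_motifs:
                break
            pairs.append((f"M{a:03d}", f"M{b:03d}", ct, self.planting_rate))
        return pairs


def _streams(spec: PlantedSpec) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(4)
    names = ("layout", "counts", "background_seq", "planting")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _nb(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_count_matrix(spec: PlantedSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the raw window x sample count matrix and its ground-truth labels.

    Labels mark each window as ``background``, ``ubiq``, or ``cts`` with the
    owning cell type.  Planted CTS windows are elevated
    (closed_mean x specificity_effect) only in their own cell type; planted
    ubiquitous windows sit at baseline_mean in every sample.
    """
    rng = _streams(spec)
    width = spec.window_width
    windows = [GenomeWindow(CHROM, i * width, (i + 1) * width) for i in range(spec.n_windows)]

    sample_rows = []
    for ct in spec.cell_types:
        for r in range(spec.samples_per_cell_type):
            sample_rows.append({"sample_id": f"{ct}_rep{r}", "cell_type": ct})
    sheet = SampleSheet(pd.DataFrame(sample_rows))

    perm = rng["layout"].permutation(spec.n_windows)
    labels = pd.DataFrame(
        {"window_id": [w.id for w in windows], "label": "background", "cell_type": ""}
    )
    ubiq_idx = perm[: spec.n_ubiq]
    labels.loc[ubiq_idx, "label"] = "ubiq"
    offset = spec.n_ubiq
    for ct in spec.cell_types:
        idx = perm[offset : offset + spec.n_cts_per_type]
        labels.loc[idx, "label"] = "cts"
        labels.loc[idx, "cell_type"] = ct
        offset += spec.n_cts_per_type

    mean = np.full((spec.n_windows, sheet.n_samples), spec.closed_mean)
    mean[ubiq_idx, :] = spec.baseline_mean
    col_of_ct = {ct: [j for j, c in enumerate(sheet.table["cell_type"]) if c == ct] for ct in spec.cell_types}
    for ct in spec.cell_types:
        idx = labels.index[(labels["label"] == "cts") & (labels["cell_type"] == ct)]
        for j in col_of_ct[ct]:
            mean[idx, j] = spec.closed_mean * spec.specificity_effect
    values = _nb(rng["counts"], mean, spec.nb_dispersion).astype(float)
    return CountMatrix(windows, sheet, values, stage="raw"), labels


def simulate_dhs_sequences(
    spec: PlantedSpec,
    labels: pd.DataFrame,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate per-window sequences with planted motif sites.

    Background is i.i.d. uniform over A/C/G/T.  Every motif is planted as a
    singleton at ``background_motif_rate`` in every window; in the CTS
    windows of each planted pair's target cell type both consensus words are
    planted together at the pair's planting rate, at non-overlapping random
    offsets.  Returns the chromosome-indexed sequence dict (one synthetic
    chromosome, windows tiling it) and the truth table of planted sites.
    """
    motifs, _ = spec.motif_set()
    by_id = {m.motif_id: m for m in motifs}
    for m in motifs:
        if m.width >= spec.window_width:
            raise ValueError(f"motif {m.motif_id} too wide for windows")
    rng_bg = _streams(spec)["background_seq"]
    rng_pl = _streams(spec)["planting"]
    width = spec.window_width

    seq_arr = rng_bg.integers(0, 4, size=spec.n_windows * width, dtype=np.int8)
    truth_rows: list[dict] = []

    def plant(window_idx: int, motif: MotifMatrix, offset: int, kind: str, ct: str, partner: str = "") -> None:
        start = window_idx * width + offset
        codes = [BASES.index(b) for b in motif.consensus]
        seq_arr[start : start + motif.width] = codes
        truth_rows.append(
            {
                "window_id": f"{CHROM}:{window_idx * width}-{(window_idx + 1) * width}",
                "motif_id": motif.motif_id,
                "offset": offset,
                "kind": kind,
                "cell_type": ct,
                "partner": partner,
            }
        )

    # singleton background occurrences everywhere
    for m in motifs:
        hits = np.flatnonzero(rng_pl.random(spec.n_windows) < spec.background_motif_rate)
        for i in hits:
            plant(int(i), m, int(rng_pl.integers(0, width - m.width + 1)), "background", "")

    # co-occurring pair plantings in the target cell type's CTS windows
    for a_id, b_id, ct, rate in spec.cooccur_pairs():
        a, b = by_id[a_id], by_id[b_id]
        cts_idx = labels.index[(labels["label"] == "cts") & (labels["cell_type"] == ct)]
        for i in cts_idx:
            if rng_pl.random() >= rate:
                continue
            # rejection-sample two non-overlapping offsets
            while True:
                oa = int(rng_pl.integers(0, width - a.width + 1))
                ob = int(rng_pl.integers(0, width - b.width + 1))
                if oa + a.width <= ob or ob + b.width <= oa:
                    break
            plant(int(i), a, oa, "pair", ct, partner=b_id)
            plant(int(i), b, ob, "pair", ct, partner=a_id)

    seq = "".join(BASES[c] for c in seq_arr)
    truth = pd.DataFrame(
        truth_rows, columns=["window_id", "motif_id", "offset", "kind", "cell_type", "partner"]
    )
    return {CHROM: seq}, truth


@dataclass
class FixtureBundle:
    """In-memory synthetic study: everything the pipeline consumes plus truth."""

    spec: PlantedSpec
    counts: CountMatrix
    labels: pd.DataFrame
    genome: dict[str, str]
    motifs: list[MotifMatrix]
    groups: MotifGroupMap
    truth_sites: pd.DataFrame

    @property
    def planted_pairs(self) -> list[tuple[str, str, str, float]]:
        return self.spec.cooccur_pairs()


def end_to_end_fixture(spec: PlantedSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the full synthetic study; optionally write it as a run directory.

    The directory layout (genome.fa, windows.bed, samples.tsv, counts.tsv,
    motifs.transfac, groups.tsv, truth.json) is consumable by the CLI
    unmodified.
    """
    counts, labels = simulate_count_matrix(spec)
    genome, truth = simulate_dhs_sequences(spec, labels)
    motifs, groups = spec.motif_set()
    bundle = FixtureBundle(spec, counts, labels, genome, motifs, groups, truth)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_bed(counts.windows, out / "windows.bed")
        counts.samples.table.to_csv(out / "samples.tsv", sep="\t", index=False)
        counts.to_frame().to_csv(out / "counts.tsv", sep="\t")
        (out / "motifs.transfac").write_text(write_transfac(motifs))
        write_motif_group_map(groups, out / "groups.tsv")
        truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "planted_pairs": [
                        {"motif_a": a, "motif_b": b, "cell_type": ct, "rate": r}
                        for a, b, ct, r in bundle.planted_pairs
                    ],
                    "labels": labels.to_dict(orient="list"),
                    "seed": spec.seed,
                },
                fh,
                indent=1,
            )
    return bundle
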