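"""End-to-end orchestration: specificity -> affinity -> co-occurrence -> networks.

`run_pipeline` drives the on-disk, resumable pipeline the CLI exposes;
`analyze_bundle` is the in-memory equivalent over a synthetic
:class:`~tfcooc.simulate.FixtureBundle` (used heavily in testing and
calibration experiments).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    SequenceSource,
    load_motif_group_map,
    load_sample_map,
    parse_transfac,
    read_bed_reads,
    write_bed,
)
from .chromatin import (
    CountMatrix,
    count_reads,
    load_count_matrix,
    normalize_log,
    select_dhs,
    specificity_frame,
    t_statistic,
)
from .affinity import call_bound, energy_from_counts, score_dhs_set
from .stats import (
    aggregate_to_tf_pairs,
    overrepresentation,
    results_frame,
    score_all_pairs,
    select_significant,
)
from .networks import build_networks, export_network, filter_common


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run."""

    window_width: int = 200
    l: int = 5000            # CTS and ubiquitous DHSs selected per stratum
    k: int = 1000            # DHSs called bound per motif (within the 2l stratum)
    open_quantile: float = 0.75
    upper_q: float = 0.995
    lower_q: float = 0.005
    max_freq: int = 30       # drop TF pairs significant in >= this many cell types
    lambda_: float = 0.7
    pseudocount: float = 1.0
    r0: float | None = None  # None -> width-dependent default
    grand_mean: str = "entries"
    radical: str = "factor"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.k <= 2 * self.l:
            raise ValueError(f"need 0 < k <= 2l, got k={self.k}, l={self.l}")
        if not 0 < self.lower_q < self.upper_q < 1:
            raise ValueError("need 0 < lower_q < upper_q < 1")
        if self.window_width < 1 or self.pseudocount <= 0 or self.lambda_ <= 0:
            raise ValueError("window_width, pseudocount and lambda_ must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisResult:
    """Everything one run computes, in memory."""

    selection: object
    pair_results: dict[str, list]        # cell type -> PairResult list (flagged)
    pair_frame: pd.DataFrame
    tf_pairs: pd.DataFrame
    overrep: dict[str, list]
    networks: dict[str, object]
    pair_frequency: pd.DataFrame
    specificity: object


def analyze_counts(
    counts: CountMatrix,
    genome: SequenceSource,
    motifs,
    groups,
    config: RunConfig,
) -> AnalysisResult:
    """Run the full analysis from a raw count matrix onward."""
    logmat = normalize_log(counts, grand_mean=config.grand_mean)
    spec = t_statistic(logmat, radical=config.radical)
    selection = select_dhs(spec, config.l, config.open_quantile)
    ems = [
        energy_from_counts(m, pseudocount=config.pseudocount, lambda_=config.lambda_, r0=config.r0)
        for m in motifs
    ]
    tables = score_dhs_set(selection, genome, ems)

    pair_results = {}
    overrep = {}
    frames = []
    for ct, table in tables.items():
        calls = call_bound(table, config.k)
        res = score_all_pairs(calls, groups)
        if res:
            select_significant(res, config.upper_q, config.lower_q)
        pair_results[ct] = res
        overrep[ct] = overrepresentation(calls)
        frames.append(results_frame(res, groups))

    pair_frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    all_results = [r for res in pair_results.values() for r in res]
    tf_pairs = aggregate_to_tf_pairs(all_results, groups)
    networks, freq = build_networks(tf_pairs)
    return AnalysisResult(selection, pair_results, pair_frame, tf_pairs, overrep, networks, freq, spec)


def analyze_bundle(bundle, config: RunConfig | None = None, **overrides) -> AnalysisResult:
    """Analyze a synthetic :class:`FixtureBundle` with study-scaled defaults.

    Unless overridden, l is set to the planted CTS count per cell type and k
    to the expected number of planted sites per motif (planting_rate x l):
    the bound-call cutoff must be commensurate with the number of genuinely
    bound sites in the stratum, else top-k membership degenerates into
    tie-breaking among equal-affinity consensus sites.
    """
    if config is None:
        spec = bundle.spec
        params = dict(
            window_width=spec.window_width,
            l=spec.n_cts_per_type,
            k=max(1, round(spec.planting_rate * spec.n_cts_per_type)),
            seed=spec.seed,
        )
        params.update(overrides)
        config = RunConfig(**params)
    return analyze_counts(
        bundle.counts, SequenceSource(bundle.genome), bundle.motifs, bundle.groups, config
    )


# ---------------------------------------------------------------------------
# on-disk pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, indir: str | Path, outdir: str | Path) -> AnalysisResult:
    """Run the pipeline over a run directory and write per-stage outputs.

    Expects in ``indir``: genome.fa (or a sequence FASTA), samples.tsv,
    motifs.transfac, groups.tsv and either counts.tsv (window x sample) or
    per-sample BED read files referenced by a file_path column in
    samples.tsv.  Writes t-statistics, selections, co-occurrence tables,
    overrepresentation tables, networks and a manifest into ``outdir``.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    required = ["samples.tsv", "motifs.transfac", "groups.tsv", "genome.fa"]
    for name in required:
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input {indir / name}")

    samples = load_sample_map(indir / "samples.tsv")
    motifs = parse_transfac((indir / "motifs.transfac").read_text())
    groups = load_motif_group_map(indir / "groups.tsv")
    genome = SequenceSource(indir / "genome.fa")

    if (indir / "counts.tsv").exists():
        counts = load_count_matrix(indir / "counts.tsv", samples, stage="raw")
    else:
        from .io_formats import tile_genome

        windows = tile_genome(genome.lengths(), config.window_width)
        reads = {
            row.sample_id: read_bed_reads(indir / row.file_path)
            for row in samples.table.itertuples()
        }
        counts = count_reads(windows, reads, samples)
        counts.to_frame().to_csv(outdir / "counts.tsv", sep="\t")

    result = analyze_counts(counts, genome, motifs, groups, config)

    specificity_frame(result.specificity).to_csv(outdir / "t_statistic.tsv", sep="\t")
    for ct, ws in result.selection.cts.items():
        write_bed(ws, outdir / f"cts_{ct}.bed")
    write_bed(result.selection.ubiq, outdir / "ubiq.bed")
    result.pair_frame.to_csv(outdir / "pair_results.tsv", sep="\t", index=False)
    result.tf_pairs.to_csv(outdir / "tf_pairs.tsv", sep="\t", index=False)
    result.pair_frequency.to_csv(outdir / "pair_frequency.tsv", sep="\t", index=False)
    over_rows = [
        {
            "cell_type": r.cell_type,
            "motif_id": r.motif_id,
            "rank": r.rank,
            "log_p": r.log_p,
        }
        for rs in result.overrep.values()
        for r in rs
    ]
    pd.DataFrame(over_rows).to_csv(outdir / "overrepresentation.tsv", sep="\t", index=False)
    for ct, net in result.networks.items():
        filtered = filter_common(net, result.pair_frequency, config.max_freq)
        (outdir / f"network_{ct}.graphml").write_text(export_network(filtered, "graphml"))
        (outdir / f"network_{ct}.sif").write_text(export_network(filtered, "sif"))

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {
            p.name: _sha256(p)
            for p in sorted(indir.iterdir())
            if p.is_file() and p.suffix not in {".fai"}
        },
        "cell_types": list(result.pair_results),
        "counts": {
            "windows": len(counts.windows),
            "samples": counts.samples.n_samples,
            "pairs_tested_per_cell_type": {
                ct: len(res) for ct, res in result.pair_results.items()
            },
            "pairs_significant_per_cell_type": {
                ct: int(sum(r.cts_significant for r in res))
                for ct, res in result.pair_results.items()
            },
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
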