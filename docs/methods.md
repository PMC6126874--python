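# Methods

This document describes what `tfcooc` computes, the parameter defaults and
the reasoning behind them, what the synthetic study generator does and does
not emulate, and the numerical choices that matter for reproducibility.

## 1. Input model

The unit of analysis is a fixed-width genomic window (default 200 bp,
0-based half-open coordinates, id `chrom:start-end`). Inputs to a full run
are: a genome FASTA, a window BED (or a genome to tile), per-sample read
5′-end counts per window (TSV), a sample→cell-type sheet, a TRANSFAC-format
motif collection, and a motif→TF-group map. Windows overlapping a blacklist
can be removed at tiling time. Read counting is strand-aware: a read
contributes at its 5′ end (plus strand: `start`; minus strand: `end − 1`).

## 2. Normalization and the regularized t-statistic

Sample *i* is scaled by `factor_i = grand_mean / mean_i` and transformed as
`x = ln(raw · factor_i + 1)` — the pseudocount is added *after* scaling so
that empty windows map to exactly 0 in every sample. By default the grand
mean is the mean over all matrix entries (`grand_mean="entries"`); the mean
of sample means is available as `grand_mean="sample_means"`.

For window *w* and cell type *c* (with `n_c` samples, `m` cell types):

- `x̄_{cw}`: mean over the samples of *c*;
- `x̄_w`: the mean of the `m` cell-type means (not the mean over samples, so
  unbalanced designs do not bias the reference);
- `s_w`: pooled within-cell-type standard deviation, denominator
  `Σ_c (n_c − 1)`;
- `s₀`: the mean of `s_w` over all windows (a variance regularizer in the
  moderated-t tradition: it prevents near-constant windows from achieving
  huge t by chance).

```
t_{cw} = (x̄_{cw} − x̄_w) / ( sqrt(1/m + 1/n_c) · (s_w + s₀) )
```

By default the `sqrt(1/m + 1/n_c)` factor multiplies the regularized
standard deviation (`radical="factor"`); `radical="full"` instead places the
regularizer outside, `sqrt(1/m + 1/n_c)·s_w + s₀`. The two orderings differ
only in how strongly s₀ damps small-sample noise; both are exposed because
the formula is stated ambiguously in common usage. Degenerate windows with
zero deviation and zero denominator get t = 0.

## 3. Stratum selection

Per cell type, the *l* windows with largest t (default l = 5000) form the
CTS stratum, ties broken by coordinate. The ubiquitous stratum is selected
from windows whose global mean accessibility strictly exceeds the
`open_quantile` (default 0.75) quantile: among those, after excluding every
window already chosen as CTS for any cell type, the *l* windows with
smallest `max_c |t_{cw}|` are taken. CTS selection runs first, so the two
strata are disjoint by construction; this matters because the co-occurrence
contrast assumes the ubiquitous stratum is a background, not a copy of the
signal.

## 4. Biophysical affinity and bound calls

Position count matrices are converted to frequencies with a pseudocount
(default 1.0 per cell), and the mismatch energy of a site relative to the
consensus is `E = Σ_j (1/λ) ln(p_max(j)/p_{b_j}(j))` with λ = 0.7. A window's
affinity for a motif is the sum over all sites on both strands of the
expected occupancy `r₀ e^{−E} / (1 + r₀ e^{−E})`, with
`ln r₀ = 0.584·W − 5.66` for motif width W (overridable). Sites containing N
contribute 0. Scoring uses a vectorized sliding-window implementation; the
reverse strand is scored by complement-encoding the window once, so
affinities are exactly strand-symmetric.

For each cell type and motif, the *k* windows (default k = 1000) with
highest affinity *within that cell type's joint stratum of 2l windows* (CTS
followed by ubiquitous) are called bound, ties broken by coordinate —
exactly k calls per motif.

The cutoff k must be commensurate with the number of genuinely high-affinity
windows in the stratum. In the synthetic study the expected number of
planted sites per motif is `planting_rate × l`, so `analyze_bundle` defaults
to `k = round(planting_rate × l)`; choosing k far above that makes top-k
membership degenerate into tie-breaking among background windows and washes
out the contrast. This default was fixed from the generative model (expected
planted-site count), not tuned against test outcomes.

## 5. Contrastive co-occurrence

For an unordered motif pair (a, b) from *different* TF groups (same-group
pairs are excluded: their matrices are typically near-duplicates), each
stratum yields a 2×2 table of bound/unbound indicator vectors. Both tables
are tested with a one-sided upper-tail Fisher exact test and

```
L = ln p_ubiq − ln p_cts .
```

Large positive L: the pair co-binds in the cell-type-specific stratum but
not ubiquitously. Large negative L: ubiquitous-only co-binding.

**Numerics.** The log tail probability is computed exactly in log space from
`gammaln` via `logsumexp` over the upper tail of the hypergeometric support.
This is deliberate: p-values reach 10^-300 and below, where survival
functions evaluated in linear space underflow to 0 and destroy L. The
implementation is cross-checked in the tests against an exact
`fractions.Fraction` enumeration oracle.

**Flagging.** Per cell type, pairs with L strictly above the empirical
0.995 quantile (`numpy.quantile`, linear interpolation) are flagged
cell-type-specifically co-occurring; pairs strictly below the 0.005 quantile
are flagged ubiquitously co-occurring. Benjamini–Hochberg-adjusted p-values
(statsmodels `fdr_bh`) for both strata are reported alongside but do not
enter the L ranking. With small pair universes the quantile rule is
discrete: at 62 pairs the strict 0.995 rule flags exactly 1 pair (1.6%, the
top order statistic), not 0.5%.

Motif-pair results are aggregated to TF-group pairs (max L, min log p, any
significant) and assembled into per-cell-type networks; edges present in at
least `max_freq` (default 30) cell types can be filtered out as
housekeeping-like. Overrepresentation of the top pairs, co-factor profiles
per TF, and pair-set enrichment between runs are provided as query helpers.

## 6. Synthetic study generator

`PlantedSpec` defines a study: 2000 windows × 4 cell types × 3 samples by
default. Counts are negative-binomial (dispersion 10), mean 50 for open
windows, 2 for closed; planted CTS windows have an 8-fold effect in their
cell type. A single chromosome is the concatenation of uniform-random window
sequences; each cell type gets one planted cross-group motif pair whose
consensus words are inserted (non-overlapping, both members) into a fraction
`planting_rate = 0.6` of that cell type's CTS windows; singleton motif
occurrences are planted at a background rate of 0.05 per window elsewhere.
All randomness flows from one seed through `numpy.random.SeedSequence`
spawning with named streams ("layout", "counts", "background_seq",
"planting"), so every artifact is reproducible bit-for-bit.

What the generator emulates: depth variation across samples,
overdispersed counts, a distinct open-everywhere class, planted specificity
with realistic misranking at the selection boundary, motif sites embedded in
random sequence, and cross-group pair structure.

What it does not emulate: mappability and GC bias, correlated biological
replicates, motif families with correlated matrices, nucleosome structure,
real genomic sequence composition, and TF groups larger than two motifs.
Conclusions about absolute false-discovery rates therefore transfer to real
data only qualitatively.

## 7. Calibration checks

Under the null (no planted pairs) the distribution of L for a given pair
across independently seeded runs is symmetric about zero (verified with a
two-sample KS test of L against −L, one L value per seed). Within a single
run the 62 pair L values are *not* independent — they share 12 bound
vectors and one ubiquitous stratum — so pooled symmetry tests across pairs
within runs are miscalibrated and are not used.

## 8. Determinism and outputs

`run_pipeline` writes `t_statistic.tsv`, per-cell-type CTS/ubiquitous BED
files, `pair_results.tsv`, `tf_pairs.tsv`, `pair_frequency.tsv`,
`overrepresentation.tsv`, per-cell-type `.graphml`/`.sif` networks, and
`manifest.json` containing the config and SHA-256 checksums of the inputs.
All tie-breaks are by genomic coordinate and all reductions are ordered, so
reruns are byte-identical.

## 9. Default parameters

| Parameter | Default | Role |
|---|---|---|
| `window_width` | 200 | window size (bp) |
| `l` | 5000 | windows per stratum |
| `k` | 1000 | bound calls per motif and cell type |
| `open_quantile` | 0.75 | ubiquitous eligibility threshold |
| `upper_q` / `lower_q` | 0.995 / 0.005 | L flagging quantiles |
| `max_freq` | 30 | common-edge filter (cell types) |
| `lambda` | 0.7 | energy scale |
| `ln r₀` | `0.584·W − 5.66` | width-dependent occupancy scale |
| `pseudocount` | 1.0 | motif frequency regularizer |
| `grand_mean` | `"entries"` | normalization reference |
| `radical` | `"factor"` | t-statistic regularizer placement |
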