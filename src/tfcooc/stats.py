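"""Statistical core: contrastive co-occurrence testing of motif pairs.

For each motif pair and cell type, two 2x2 tables cross-classify the 2l
selected DHSs by bound/unbound status for the two motifs, stratified into
the l cell-type-specific (CTS) and l ubiquitous DHSs.  Each table gets a
one-sided (upper-tail) Fisher exact p-value, computed exactly in log space.
The L score contrasts the strata:

    L = −ln p_cts + ln p_ubiq

so large positive L means the pair co-binds on cell-type-specific chromatin
far beyond what the same pair does on constitutively open chromatin.
Significance is empirical-quantile based per cell type (default: L above
the 99.5% quantile is cell-type-specifically co-occurring, below the 0.5%
quantile ubiquitously co-occurring); BH-adjusted q-values are reported
alongside but do not enter L.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .affinity import BindingCalls
from .io_formats import MotifGroupMap


@dataclass
class PairTables:
    """The two stratified 2x2 co-binding tables for one motif pair."""

    cts: np.ndarray   # [[n11, n10], [n01, n00]] on CTS DHSs
    ubiq: np.ndarray  # same layout on ubiquitous DHSs

    def __post_init__(self) -> None:
        self.cts = np.asarray(self.cts, dtype=np.int64)
        self.ubiq = np.asarray(self.ubiq, dtype=np.int64)
        for t in (self.cts, self.ubiq):
            if t.shape != (2, 2) or (t < 0).any():
                raise ValueError("each table must be 2x2 with non-negative counts")


def build_pair_tables(calls_a: np.ndarray, calls_b: np.ndarray, z: np.ndarray) -> PairTables:
    """Cross-classify DHSs by the two motifs' bound calls within each stratum."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    z = np.asarray(z, dtype=bool)
    if not (a.shape == b.shape == z.shape):
        raise ValueError("calls_a, calls_b and z must have the same length")

    def table(mask: np.ndarray) -> np.ndarray:
        aa, bb = a[mask], b[mask]
        return np.array(
            [
                [np.sum(aa & bb), np.sum(aa & ~bb)],
                [np.sum(~aa & bb), np.sum(~aa & ~bb)],
            ]
        )

    return PairTables(table(z), table(~z))


def log_fisher_upper(table: np.ndarray) -> float:
    """Natural-log upper-tail Fisher p-value, ln P(X >= n11), computed exactly.

    The tail of the hypergeometric distribution with the table's margins is
    summed in log space (log-gamma terms combined with log-sum-exp), so
    extreme tables do not underflow.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    n11 = int(t[0, 0])
    K = int(t[0].sum())      # bound by first motif
    n = int(t[:, 0].sum())   # bound by second motif
    N = int(t.sum())
    if N == 0:
        return 0.0
    lo = max(0, K + n - N)
    hi = min(K, n)
    if n11 <= lo:
        return 0.0  # the whole support is in the tail: p = 1

    def logpmf(x: np.ndarray) -> np.ndarray:
        return (
            gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
            + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )

    xs = np.arange(n11, hi + 1)
    return float(min(0.0, logsumexp(logpmf(xs))))


def l_score(log_p_cts: float, log_p_ubiq: float) -> float:
    """Contrastive co-occurrence score L = ln p_ubiq − ln p_cts."""
    return log_p_ubiq - log_p_cts


@dataclass
class PairResult:
    motif_a: str
    motif_b: str
    cell_type: str
    tables: PairTables
    log_p_cts: float
    log_p_ubiq: float
    L: float
    q_cts: float = np.nan
    q_ubiq: float = np.nan
    cts_significant: bool = False
    ubiq_cooccurring: bool = False


def score_all_pairs(
    calls: BindingCalls,
    groups: MotifGroupMap,
    cell_type: str | None = None,
) -> list[PairResult]:
    """Score every unordered cross-group motif pair in one cell type.

    Pairs whose two motifs belong to the same TF group are skipped: distinct
    motifs in one group typically represent one factor or near-identical
    binding preferences, so their co-occurrence is homotypic by construction.
    """
    ct = cell_type or calls.cell_type
    motif_ids = calls.motif_ids
    if len({groups.group_of(m) for m in motif_ids}) < 2:
        return []
    B = calls.bound
    z = calls.z
    # pairwise joint-bound counts per stratum via matrix products
    Bc = B[z].astype(np.int64)
    Bu = B[~z].astype(np.int64)
    n11c = Bc.T @ Bc
    n11u = Bu.T @ Bu
    kc = Bc.sum(axis=0)  # bound counts within the CTS stratum, per motif
    ku = Bu.sum(axis=0)
    l_cts = int(z.sum())
    l_ub = int((~z).sum())

    results = []
    for i, j in combinations(range(len(motif_ids)), 2):
        a, b = motif_ids[i], motif_ids[j]
        if groups.group_of(a) == groups.group_of(b):
            continue
        tc = np.array(
            [
                [n11c[i, j], kc[i] - n11c[i, j]],
                [kc[j] - n11c[i, j], l_cts - kc[i] - kc[j] + n11c[i, j]],
            ]
        )
        tu = np.array(
            [
                [n11u[i, j], ku[i] - n11u[i, j]],
                [ku[j] - n11u[i, j], l_ub - ku[i] - ku[j] + n11u[i, j]],
            ]
        )
        lp_c = log_fisher_upper(tc)
        lp_u = log_fisher_upper(tu)
        results.append(
            PairResult(a, b, ct, PairTables(tc, tu), lp_c, lp_u, l_score(lp_c, lp_u))
        )
    return results


def n_cross_group_pairs(groups: MotifGroupMap) -> int:
    """Size of the test universe: unordered motif pairs spanning two TF groups."""
    from collections import Counter

    sizes = Counter(groups.mapping.values())
    n = groups.n_motifs
    within = sum(g * (g - 1) // 2 for g in sizes.values())
    return n * (n - 1) // 2 - within


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(
    results: list[PairResult],
    upper_q: float = 0.995,
    lower_q: float = 0.005,
) -> list[PairResult]:
    """Flag pairs by the empirical quantiles of L within one cell type.

    cts_significant: L strictly above the upper_q quantile; ubiq_cooccurring:
    L strictly below the lower_q quantile.  Quantiles use linear
    interpolation between order statistics.  BH q-values are attached for
    both strata (each cell type is corrected separately).
    """
    if not results:
        raise ValueError("no pair results to flag")
    if not 0 < lower_q < upper_q < 1:
        raise ValueError("need 0 < lower_q < upper_q < 1")
    L = np.array([r.L for r in results])
    hi = float(np.quantile(L, upper_q))
    lo = float(np.quantile(L, lower_q))
    q_cts = bh_adjust(np.exp(np.array([r.log_p_cts for r in results])))
    q_ubiq = bh_adjust(np.exp(np.array([r.log_p_ubiq for r in results])))
    for r, qc, qu in zip(results, q_cts, q_ubiq):
        r.q_cts = float(qc)
        r.q_ubiq = float(qu)
        r.cts_significant = bool(r.L > hi)
        r.ubiq_cooccurring = bool(r.L < lo)
    return results


def results_frame(results: list[PairResult], groups: MotifGroupMap) -> pd.DataFrame:
    """Flat results table (one row per motif pair per cell type)."""
    ln10 = np.log(10)
    rows = [
        {
            "cell_type": r.cell_type,
            "tf_a": groups.group_of(r.motif_a),
            "tf_b": groups.group_of(r.motif_b),
            "motif_a": r.motif_a,
            "motif_b": r.motif_b,
            "n11_cts": int(r.tables.cts[0, 0]),
            "n11_ubiq": int(r.tables.ubiq[0, 0]),
            "neg_log10_p_cts": -r.log_p_cts / ln10,
            "neg_log10_p_ubiq": -r.log_p_ubiq / ln10,
            "L": r.L,
            "q_cts": r.q_cts,
            "q_ubiq": r.q_ubiq,
            "cts_significant": r.cts_significant,
            "ubiq_cooccurring": r.ubiq_cooccurring,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def aggregate_to_tf_pairs(results: list[PairResult], groups: MotifGroupMap) -> pd.DataFrame:
    """Collapse motif-pair results onto unordered TF-group pairs.

    A TF pair is significant if any constituent motif pair is; it carries
    the best (max) L and the smallest CTS log-p among its motif pairs.
    """
    rows = []
    for r in results:
        ga, gb = sorted((groups.group_of(r.motif_a), groups.group_of(r.motif_b)))
        rows.append(
            {
                "cell_type": r.cell_type,
                "tf_a": ga,
                "tf_b": gb,
                "L": r.L,
                "log_p_cts": r.log_p_cts,
                "cts_significant": r.cts_significant,
                "ubiq_cooccurring": r.ubiq_cooccurring,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["cell_type", "tf_a", "tf_b"], as_index=False)
        .agg(
            L=("L", "max"),
            log_p_cts=("log_p_cts", "min"),
            n_motif_pairs=("L", "size"),
            cts_significant=("cts_significant", "any"),
            ubiq_cooccurring=("ubiq_cooccurring", "any"),
        )
    )


@dataclass
class OverrepResult:
    motif_id: str
    cell_type: str
    table: np.ndarray  # [[bound&CTS, bound&ubiq], [unbound&CTS, unbound&ubiq]]
    log_p: float
    rank: int = 0


def overrepresentation(calls: BindingCalls, top: int = 50) -> list[OverrepResult]:
    """Per-motif enrichment of bound DHSs among the CTS stratum.

    One 2x2 table per motif (bound/unbound x CTS/ubiquitous), one-sided
    Fisher upper tail on the bound-and-CTS cell; motifs are ranked ascending
    by p and the ``top`` most significant are returned.
    """
    z = calls.z
    out = []
    for j, motif in enumerate(calls.motif_ids):
        b = calls.bound[:, j]
        t = np.array(
            [
                [np.sum(b & z), np.sum(b & ~z)],
                [np.sum(~b & z), np.sum(~b & ~z)],
            ]
        )
        out.append(OverrepResult(motif, calls.cell_type, t, log_fisher_upper(t)))
    out.sort(key=lambda r: (r.log_p, r.motif_id))
    for i, r in enumerate(out, start=1):
        r.rank = i
    return out[:top]
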