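"""Cell-type-specific TF co-occurrence networks.

Nodes are TF groups; an edge connects two TFs whose co-occurrence on
cell-type-specific open chromatin is significant in that cell type.  Pairs
significant across very many cell types ("common" pairs) can be filtered
out to expose the cell-type-specific wiring, and a focal TF can be queried
for its co-factors across all cell types.
"""

from __future__ import annotations

import io

import networkx as nx
import numpy as np
import pandas as pd

from .stats import log_fisher_upper


def build_networks(tf_pair_results: pd.DataFrame) -> tuple[dict[str, nx.Graph], pd.DataFrame]:
    """One undirected network per cell type plus a cross-cell-type frequency table.

    ``tf_pair_results`` is the aggregated TF-pair table (columns cell_type,
    tf_a, tf_b, L, log_p_cts, cts_significant, ...).  Edge attributes carry
    the cell type, L and the number of cell types in which the pair is
    significant.
    """
    if tf_pair_results.empty:
        return {}, pd.DataFrame(columns=["tf_a", "tf_b", "n_cell_types"])
    sig = tf_pair_results[tf_pair_results["cts_significant"]].copy()
    freq = (
        sig.groupby(["tf_a", "tf_b"], as_index=False)
        .agg(n_cell_types=("cell_type", "nunique"))
    )
    freq_of = {(r.tf_a, r.tf_b): int(r.n_cell_types) for r in freq.itertuples()}

    nets: dict[str, nx.Graph] = {}
    for ct in tf_pair_results["cell_type"].unique():
        g = nx.Graph(cell_type=ct)
        for r in sig[sig["cell_type"] == ct].itertuples():
            g.add_edge(
                r.tf_a,
                r.tf_b,
                cell_type=ct,
                L=float(r.L),
                n_cell_types_observed=freq_of[(r.tf_a, r.tf_b)],
            )
        nets[ct] = g
    return nets, freq


def filter_common(network: nx.Graph, freq: pd.DataFrame, max_freq: int = 30) -> nx.Graph:
    """Drop edges whose TF pair is significant in >= max_freq cell types.

    Pan-cell-type pairs carry little cell-type-specific information; removing
    them (and any node left isolated) sharpens the specific subnetworks.
    """
    freq_of = {tuple(sorted((r.tf_a, r.tf_b))): int(r.n_cell_types) for r in freq.itertuples()}
    g = network.copy()
    drop = [
        (u, v)
        for u, v in g.edges
        if freq_of.get(tuple(sorted((u, v))), 0) >= max_freq
    ]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def cofactor_profile(tf: str, tf_pair_results: pd.DataFrame) -> pd.DataFrame:
    """All significant partners of one TF with their supporting cell types.

    Returns one row per partner: the list of cell types where the pair is
    significant and the support count (the edge-weight semantics of a
    TF-centric network view).
    """
    known = set(tf_pair_results["tf_a"]) | set(tf_pair_results["tf_b"])
    if tf not in known:
        raise KeyError(f"unknown TF {tf!r}")
    sig = tf_pair_results[tf_pair_results["cts_significant"]]
    mine = sig[(sig["tf_a"] == tf) | (sig["tf_b"] == tf)].copy()
    if mine.empty:
        return pd.DataFrame(columns=["partner", "cell_types", "support"])
    mine["partner"] = np.where(mine["tf_a"] == tf, mine["tf_b"], mine["tf_a"])
    prof = (
        mine.groupby("partner")["cell_type"]
        .agg(lambda s: sorted(set(s)))
        .reset_index()
        .rename(columns={"cell_type": "cell_types"})
    )
    prof["support"] = prof["cell_types"].str.len()
    return prof.sort_values(["support", "partner"], ascending=[False, True]).reset_index(drop=True)


def pairset_enrichment(
    predicted: set[tuple[str, str]],
    reference: set[tuple[str, str]],
    universe: set[tuple[str, str]],
) -> dict:
    """Odds ratio and one-sided Fisher p for overlap of two TF-pair sets.

    Both sets are normalized to unordered pairs and must be subsets of the
    universe of testable pairs.
    """
    norm = lambda s: {tuple(sorted(p)) for p in s}
    uni = norm(universe)
    if not uni:
        raise ValueError("empty universe")
    pred, ref = norm(predicted) & uni, norm(reference) & uni
    a = len(pred & ref)
    b = len(pred - ref)
    c = len(ref - pred)
    d = len(uni) - a - b - c
    table = np.array([[a, b], [c, d]])
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return {"table": table, "odds_ratio": float(odds), "log_p": log_fisher_upper(table)}


def export_network(network: nx.Graph, fmt: str) -> str:
    """Serialize a network as 'graphml' (lossless attributes), 'sif' or 'tsv'."""
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(network, named_key_ids=True))
    if fmt == "sif":
        return "".join(f"{u}\tcooccur\t{v}\n" for u, v in sorted(network.edges))
    if fmt == "tsv":
        rows = [
            {"tf_a": u, "tf_b": v, **network.edges[u, v]} for u, v in sorted(network.edges)
        ]
        buf = io.StringIO()
        pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    raise ValueError(f"unknown network format {fmt!r}")
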