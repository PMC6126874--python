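"""Biophysical motif-binding affinity (TRAP-style) and bound/unbound calls.

A count matrix is converted to a mismatch-energy matrix: at each position the
consensus base has energy 0 and base b costs E_b = (1/λ)·ln(p_max/p_b) with
p_b the pseudocounted base frequency.  The affinity of a sequence is the
expected number of occupied sites,

    A(seq) = Σ_sites  R0·exp(−E_site) / (1 + R0·exp(−E_site)),

summed over all start positions on both strands (reverse strand scored on
the reverse complement).  Defaults λ = 0.7 and ln R0 = 0.584·width − 5.66
follow the published parameterization of the model.  Unlike hit-based motif
scanning there is no score cutoff: weak sites contribute partial occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BASES, GenomeWindow, MotifMatrix, SequenceSource
from .chromatin import DHSSelection, _coord_order

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# complement codes: A<->T, C<->G; N (4) stays 4
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass
class EnergyMatrix:
    """Per-position, per-base mismatch energies for one motif."""

    motif_id: str
    energies: np.ndarray  # (width, 4), min per position == 0
    lambda_: float
    r0: float

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.lambda_ <= 0 or self.r0 <= 0:
            raise ValueError("lambda_ and r0 must be positive")
        if not np.allclose(self.energies.min(axis=1), 0.0):
            raise ValueError("each position must have a zero-energy (consensus) base")

    @property
    def width(self) -> int:
        return self.energies.shape[0]


def default_r0(width: int) -> float:
    """Site-occupancy prefactor ln R0 = 0.584·width − 5.66."""
    return float(np.exp(0.584 * width - 5.66))


def energy_from_counts(
    motif: MotifMatrix,
    pseudocount: float = 1.0,
    lambda_: float = 0.7,
    r0: float | None = None,
) -> EnergyMatrix:
    """Convert a base-count matrix to a mismatch-energy matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = motif.counts
    p = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    energies = np.log(p.max(axis=1, keepdims=True) / p) / lambda_
    return EnergyMatrix(
        motif.motif_id, energies, lambda_, default_r0(motif.width) if r0 is None else r0
    )


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def trap_affinity(seq: str, em: EnergyMatrix) -> float:
    """Expected site occupancy of the motif over both strands of ``seq``.

    Sites containing an ambiguous base (N) contribute zero; a sequence
    shorter than the motif has affinity 0.
    """
    w = em.width
    if len(seq) < w:
        return 0.0
    codes = _encode(seq)
    total = 0.0
    for strand_codes in (codes, _COMP[codes[::-1]]):
        sites = np.lib.stride_tricks.sliding_window_view(strand_codes, w)
        valid = ~(sites == 4).any(axis=1)
        if not valid.any():
            continue
        safe = np.where(sites == 4, 0, sites)
        E = em.energies[np.arange(w), safe].sum(axis=1)
        x = em.r0 * np.exp(-E[valid])
        total += float((x / (1.0 + x)).sum())
    return total


@dataclass
class AffinityTable:
    """Per cell type: affinity of every selected DHS (l CTS + l ubiq) for every motif."""

    cell_type: str
    dhss: list[GenomeWindow]       # CTS windows first, then the shared ubiq windows
    z: np.ndarray                  # CTS indicator over rows
    motif_ids: list[str]
    values: np.ndarray             # (2l, n_motifs), >= 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=[w.id for w in self.dhss], columns=self.motif_ids)
        df.insert(0, "is_cts", self.z.astype(int))
        return df


@dataclass
class BindingCalls:
    """Boolean bound/unbound calls over the joint 2l DHS stratum of one cell type."""

    cell_type: str
    dhss: list[GenomeWindow]
    z: np.ndarray
    motif_ids: list[str]
    bound: np.ndarray  # (2l, n_motifs) bool, exactly k True per column
    k: int

    def __post_init__(self) -> None:
        if not (self.bound.sum(axis=0) == self.k).all():
            raise ValueError("each motif must have exactly k bound DHSs")

    def calls_for(self, motif_id: str) -> np.ndarray:
        return self.bound[:, self.motif_ids.index(motif_id)]


def score_dhs_set(
    selection: DHSSelection,
    genome: SequenceSource,
    energy_matrices: list[EnergyMatrix],
) -> dict[str, AffinityTable]:
    """TRAP affinity of every selected DHS for every motif, per cell type.

    Ubiquitous windows are shared across cell types, so their sequences are
    scored once and reused.
    """
    motif_ids = [em.motif_id for em in energy_matrices]
    cache: dict[str, np.ndarray] = {}

    def row(w: GenomeWindow) -> np.ndarray:
        if w.id not in cache:
            try:
                seq = genome.fetch(w)
            except KeyError as exc:
                raise KeyError(f"cannot resolve sequence for DHS {w.id}") from exc
            cache[w.id] = np.array([trap_affinity(seq, em) for em in energy_matrices])
        return cache[w.id]

    tables: dict[str, AffinityTable] = {}
    for ct in selection.cts:
        dhss, z = selection.stratum(ct)
        values = np.vstack([row(w) for w in dhss])
        tables[ct] = AffinityTable(ct, dhss, z, motif_ids, values)
    return tables


def call_bound(affinity: AffinityTable, k: int) -> BindingCalls:
    """Mark the top-k DHSs by affinity as bound, per motif.

    The k-th-place tie is broken by genomic coordinate (lower first) so the
    call is deterministic and exactly k DHSs are bound.
    """
    n = len(affinity.dhss)
    if not 0 < k <= n:
        raise ValueError(f"k={k} must be in 1..{n}")
    rank = _coord_order(affinity.dhss)
    bound = np.zeros_like(affinity.values, dtype=bool)
    for j in range(affinity.values.shape[1]):
        order = np.lexsort((rank, -affinity.values[:, j]))
        bound[order[:k], j] = True
    return BindingCalls(affinity.cell_type, affinity.dhss, affinity.z, affinity.motif_ids, bound, k)
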