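"""Synthetic promoter universes and gene sets with known structure.

The generator emulates the statistical shape of the human promoter universe
used throughout the package: i.i.d.-base promoters with a tunable GC
fraction, Poisson-distributed motif copies planted at random non-overlapping
starts inside a target window, and gene-set draws with a tunable enrichment
odds for motif-containing genes.  Defaults reproduce the study conditions of
the real EPD hg38 analysis: 16,455 genes over [-500, +100], a proximal
window of (-140, -41), and a planting rate calibrated so that roughly 46.5%
of genes carry at least one in-window GC-box (the human baseline).

Also provides deterministic count-level fixtures whose marginals equal the
published GC-box and GA-box contingency tables, for validating the
enrichment statistics without external promoter data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from promotif.motif_scan import GC_BOX, MotifSpec, reverse_complement
from promotif.promoter_io import GeneSet, PromoterRecord, PromoterUniverse

# ln(0.9524 / 0.5349): with gc_fraction 0.5 the chance of >= 1 background
# GC-box start in a 100-start window is ~4.76%, so a Poisson planting rate of
# ~0.577 yields an overall motif-containing fraction of ~46.5%.
DEFAULT_PLANT_RATE = 0.577


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic universe draw."""

    n_genes: int = 16455
    region: tuple[int, int] = (-500, 100)
    gc_fraction: float = 0.5
    motif: MotifSpec = GC_BOX
    plant_rate: float = DEFAULT_PLANT_RATE
    plant_window: tuple[int, int] = (-140, -41)
    enrichment_odds: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if self.plant_rate < 0:
            raise ValueError("plant_rate must be >= 0")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment_odds must be > 0")
        lo, hi = self.plant_window
        rlo, rhi = self.region
        if lo < rlo or hi > rhi:
            raise ValueError(f"plant_window {self.plant_window} outside region {self.region}")
        if self.plant_rate > 0 and (hi - lo + 1) < self.motif.length:
            raise ValueError(
                f"plant_window {self.plant_window} too small to host motif "
                f"{self.motif.name!r} (length {self.motif.length})"
            )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_universe(cfg: SyntheticConfig) -> PromoterUniverse:
    """Draw a synthetic promoter universe.

    Each base is i.i.d. with P(G) = P(C) = gc_fraction/2 and
    P(A) = P(T) = (1 - gc_fraction)/2.  Then, per gene, a Poisson(plant_rate)
    number of motif copies is written at random non-overlapping starts inside
    ``plant_window`` on a uniformly chosen strand, overwriting the background
    in place (sequence length never changes).  A copy count exceeding what
    fits without overlap is truncated to capacity.  Deterministic under seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rlo, rhi = cfg.region
    length = rhi - rlo + 1
    g = cfg.gc_fraction
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
    base_idx = rng.choice(4, size=(cfg.n_genes, length), p=probs)
    seqs = _BASES[base_idx]  # (n_genes, length) byte matrix

    if cfg.plant_rate > 0:
        m = cfg.motif.length
        fwd = np.frombuffer(cfg.motif.pattern.encode(), dtype="S1")
        rev = np.frombuffer(reverse_complement(cfg.motif.pattern).encode(), dtype="S1")
        wlo, whi = cfg.plant_window
        # candidate start offsets; a copy must fit inside the record
        last_ok = min(whi, rhi - m + 1)
        candidates = np.arange(wlo, last_ok + 1)
        counts = rng.poisson(cfg.plant_rate, size=cfg.n_genes)
        for gene in np.nonzero(counts)[0]:
            order = rng.permutation(candidates)
            placed: list[int] = []
            for s in order:
                if len(placed) >= counts[gene]:
                    break
                if all(abs(s - q) >= m for q in placed):
                    placed.append(int(s))
            for s in placed:
                i = s - rlo
                seqs[gene, i : i + m] = fwd if rng.random() < 0.5 else rev

    ids = [f"G{i + 1:06d}" for i in range(cfg.n_genes)]
    records = tuple(
        PromoterRecord(gene_id=gid, sequence=row.tobytes().decode("ascii"), start_offset=rlo)
        for gid, row in zip(ids, seqs)
    )
    return PromoterUniverse(records=records)


def gen_gene_set(
    universe_summaries: pd.DataFrame,
    set_size: int,
    enrichment_odds: float = 1.0,
    seed: int = 0,
    name: str = "synthetic_set",
) -> GeneSet:
    """Draw a gene set, optionally enriched for motif-containing genes.

    Weighted sampling without replacement with weight ``enrichment_odds`` for
    motif-containing genes and 1 for the rest (exponential-race scheme);
    odds = 1 gives a uniform null set.  The returned set is already matched
    (its symbols are universe gene ids).
    """
    n_univ = len(universe_summaries)
    if not 1 <= set_size <= n_univ:
        raise ValueError(f"set_size must be in [1, {n_univ}], got {set_size}")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be > 0")
    rng = np.random.default_rng(seed)
    weights = np.where(universe_summaries["has_motif"].to_numpy(), enrichment_odds, 1.0)
    keys = rng.exponential(size=n_univ) / weights
    chosen = np.argsort(keys, kind="stable")[:set_size]
    symbols = tuple(universe_summaries["gene_id"].to_numpy()[np.sort(chosen)])
    return GeneSet(name=name, symbols=symbols, matched=symbols, unmatched=())


# Published contingency counts for the GC-box (K = 7653 of N = 16455 genes)
# and GA-box (K = 5485) proximal-promoter analyses.  Per set:
# (total symbols, matched in universe, motif-containing among matched).
_GCBOX_ROWS: list[tuple[str, int, int, int]] = [
    ("SCZ_S1", 32, 28, 19),   # rare high-risk genes, exome meta-analysis, p<1e-4
    ("SCZ_S2", 61, 47, 31),   # expanded rare-variant list, p<1e-3
    ("SCZ_G1", 69, 63, 36),   # GWAS FINEMAP-prioritized genes
    ("SCZ_G2", 643, 357, 184),  # all GWAS-prioritized genes
    ("ASD", 102, 88, 42),
    ("DD_ID", 299, 258, 141),
]
_GABOX_ROWS: list[tuple[str, int, int, int]] = [
    ("SCZ_S1", 32, 28, 10),
    ("SCZ_S2", 61, 47, 18),
    ("SCZ_G1", 69, 63, 25),
    ("SCZ_G2", 643, 357, 126),
    ("ASD", 102, 88, 37),
    ("DD_ID", 299, 258, 118),
]


def _count_fixture(
    N: int, K: int, rows: Sequence[tuple[str, int, int, int]]
) -> tuple[pd.DataFrame, list[GeneSet]]:
    """Deterministic summaries + gene sets with exact marginal counts.

    Genes M000001..M{K} carry the motif; the rest do not.  Each set takes its
    k motif-containing and n-k other genes from disjoint slices, plus
    placeholder unmatched symbols to restore the pre-matching total.
    """
    ids = [f"M{i + 1:06d}" for i in range(K)] + [f"U{i + 1:06d}" for i in range(N - K)]
    summaries = pd.DataFrame(
        {
            "gene_id": ids,
            "n_occurrences": [1] * K + [0] * (N - K),
            "has_motif": [True] * K + [False] * (N - K),
            "gc_content": [0.6] * K + [0.5] * (N - K),
        }
    )
    sets: list[GeneSet] = []
    m_cursor = 0
    u_cursor = 0
    for name, total, n, k in rows:
        with_motif = ids[m_cursor : m_cursor + k]
        without = ids[K + u_cursor : K + u_cursor + (n - k)]
        m_cursor += k
        u_cursor += n - k
        matched = tuple(with_motif + without)
        missing = tuple(f"{name}_unmatched_{j + 1}" for j in range(total - n))
        sets.append(
            GeneSet(name=name, symbols=matched + missing, matched=matched, unmatched=missing)
        )
    return summaries, sets


def gen_table1_fixture() -> tuple[pd.DataFrame, list[GeneSet]]:
    """GC-box fixture: 16,455 genes, 7,653 motif-containing, six risk-gene sets."""
    return _count_fixture(16455, 7653, _GCBOX_ROWS)


def gen_table2_fixture() -> tuple[pd.DataFrame, list[GeneSet]]:
    """GA-box fixture: 16,455 genes, 5,485 motif-containing, six risk-gene sets."""
    return _count_fixture(16455, 5485, _GABOX_ROWS)
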