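"""Over-representation tests for motif-containing genes in gene sets.

The test statistic is the upper-tail cumulative hypergeometric probability
P(X >= k) of observing k or more motif-containing genes in a matched set of
size n drawn without replacement from a universe of N genes of which K
contain the motif.  Families of tests are corrected with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from promotif.promoter_io import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation test against the universe baseline."""

    set_name: str
    N: int  # universe size
    K: int  # motif-containing genes in universe
    n: int  # matched set size
    k: int  # motif-containing genes in set
    p_hyper: float
    p_adj: float | None = None  # filled after family-wise BH correction

    @property
    def percent(self) -> float:
        """Percentage of motif-containing genes in the set, 100*k/n."""
        return 100.0 * self.k / self.n


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail cumulative hypergeometric probability P(X >= k).

    X ~ Hypergeometric(N, K, n): the number of "success" genes in a sample of
    n drawn without replacement from N genes of which K are successes.
    Computed with scipy's exact survival function; P(X >= 0) is exactly 1.
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {val!r}")
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    if n > N:
        raise ValueError(f"n={n} exceeds N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)=min({n}, {K})")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (p_(j) * m / j), capped at 1 and order-preserving on
    the sorted p-values.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("pvals must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    return [float(x) for x in multipletests(p, method="fdr_bh")[1]]


def enrich_gene_set(summaries: pd.DataFrame, gs: GeneSet) -> EnrichmentResult:
    """Test over-representation of motif-containing genes in one matched set.

    ``summaries`` is the per-gene universe table from
    :func:`promotif.motif_scan.summarize_universe` (columns ``gene_id`` and
    ``has_motif`` required).  ``gs`` must have been matched against the same
    universe.
    """
    if not gs.matched:
        raise ValueError(
            f"gene set {gs.name!r} has no matched genes; match it against the "
            "universe first (an unmatched or empty set cannot be tested)"
        )
    has_motif = summaries.set_index("gene_id")["has_motif"]
    missing = [g for g in gs.matched if g not in has_motif.index]
    if missing:
        raise ValueError(
            f"gene set {gs.name!r}: matched genes absent from summaries: {missing[:5]}"
        )
    N = int(len(has_motif))
    K = int(has_motif.sum())
    n = len(gs.matched)
    k = int(has_motif.loc[list(gs.matched)].sum())
    return EnrichmentResult(
        set_name=gs.name, N=N, K=K, n=n, k=k, p_hyper=hypergeom_upper(N, K, n, k)
    )


def enrich_gene_sets(
    summaries: pd.DataFrame, gene_sets: Sequence[GeneSet]
) -> list[EnrichmentResult]:
    """Test a family of gene sets and BH-correct across exactly that family."""
    results = [enrich_gene_set(summaries, gs) for gs in gene_sets]
    adj = bh_adjust([r.p_hyper for r in results])
    return [replace(r, p_adj=a) for r, a in zip(results, adj)]


def enrichment_table(results: Sequence[EnrichmentResult], total_genes: Sequence[int] | None = None) -> pd.DataFrame:
    """Tidy table of enrichment results (one row per set).

    ``total_genes`` optionally supplies each set's pre-matching size (the
    "total genes" column); defaults to the matched size.
    """
    totals = list(total_genes) if total_genes is not None else [r.n for r in results]
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "total_genes": totals,
            "matched_genes": [r.n for r in results],
            "containing_genes": [r.k for r in results],
            "percent": [r.percent for r in results],
            "p_hyper": [r.p_hyper for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
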