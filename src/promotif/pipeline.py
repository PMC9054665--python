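"""End-to-end orchestration: enrichment tables, group comparisons, profiles.

Each operation mirrors one artifact of the promoter analysis: a per-motif
enrichment table (one row per gene set, BH-corrected within that motif's
family), a per-group comparison table (randomization test on in-window motif
counts among motif-containing genes; Welch's t on GC content), and sliding
window frequency tracks per motif and gene group.  All outputs are pure
functions of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from promotif.enrichment_stats import bh_adjust, enrich_gene_sets, enrichment_table
from promotif.group_comparison import permutation_test, welch_t
from promotif.motif_scan import (
    BUILTIN_MOTIFS,
    MotifSpec,
    ProfileTrack,
    profile,
    summarize_universe,
)
from promotif.promoter_io import GeneSet, PromoterUniverse, match_gene_set


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings shared by the pipeline stages."""

    motifs: tuple[MotifSpec, ...] = (BUILTIN_MOTIFS["GC-box"],)
    window: tuple[int, int] = (-140, -41)
    profile_window_size: int = 100
    profile_region: tuple[int, int] | None = (-500, 50)
    n_perm: int = 9999
    seed: int = 0
    fdr_level: float = 0.05
    permutation_background: Literal["full", "exclusive"] = "full"


def _matched(gene_sets: Sequence[GeneSet], universe: PromoterUniverse) -> list[GeneSet]:
    return [
        gs if gs.matched else match_gene_set(gs, universe) for gs in gene_sets
    ]


def run_enrichment(
    universe: PromoterUniverse,
    gene_sets: Sequence[GeneSet],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Per-motif, per-set over-representation table.

    For each motif the universe is summarized over ``config.window`` and
    every gene set is tested with the upper-tail hypergeometric; BH
    correction is applied within that motif's family of sets.  Columns:
    motif, set, total_genes, matched_genes, containing_genes, percent,
    p_hyper, p_adj.
    """
    gene_sets = _matched(gene_sets, universe)
    frames = []
    for motif in config.motifs:
        summaries = summarize_universe(universe, motif, config.window)
        results = enrich_gene_sets(summaries, gene_sets)
        tbl = enrichment_table(results, total_genes=[len(gs.symbols) for gs in gene_sets])
        tbl.insert(0, "motif", motif.name)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def run_group_comparisons(
    universe: PromoterUniverse,
    gene_sets: Sequence[GeneSet],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Per-group motif-count and GC-content comparisons against the universe.

    The count comparison is restricted to motif-containing genes: each
    group's counts (genes in the group with >= 1 in-window occurrence) are
    tested against the universe's motif-containing genes with a
    randomization test on the mean difference.  GC content over the window
    is compared for all matched genes against the whole universe with
    Welch's t.  Both p-value families are BH-corrected across groups,
    separately per motif and test.  With ``permutation_background`` set to
    "exclusive" the group's own genes are removed from the count background.
    """
    gene_sets = _matched(gene_sets, universe)
    rows = []
    for mi, motif in enumerate(config.motifs):
        summaries = summarize_universe(universe, motif, config.window).set_index("gene_id")
        containing = summaries[summaries["has_motif"]]
        for gi, gs in enumerate(gene_sets):
            if not gs.matched:
                raise ValueError(f"gene set {gs.name!r} matched no universe genes")
            member = containing.index.isin(gs.matched)
            group_counts = containing.loc[member, "n_occurrences"].to_numpy()
            if config.permutation_background == "exclusive":
                bg_counts = containing.loc[~member, "n_occurrences"].to_numpy()
            else:
                bg_counts = containing["n_occurrences"].to_numpy()
            perm = permutation_test(
                group_counts,
                bg_counts,
                n_perm=config.n_perm,
                # one independent, reproducible stream per (motif, group)
                seed=config.seed + 1000 * mi + gi,
            ) if group_counts.size else None
            gc_group = summaries.loc[list(gs.matched), "gc_content"].to_numpy()
            gc_test = welch_t(gc_group, summaries["gc_content"].to_numpy())
            rows.append(
                {
                    "motif": motif.name,
                    "group": gs.name,
                    "n_containing": int(group_counts.size),
                    "background_containing": int(bg_counts.size),
                    "count_mean_diff": perm.observed if perm else float("nan"),
                    "count_p": perm.p_value if perm else float("nan"),
                    "n_matched": len(gs.matched),
                    "gc_mean": float(gc_group.mean()),
                    "gc_universe_mean": float(summaries["gc_content"].mean()),
                    "gc_t": gc_test.t,
                    "gc_p": gc_test.p_value,
                    "n_perm": config.n_perm,
                    "seed": config.seed + 1000 * mi + gi,
                }
            )
    table = pd.DataFrame(rows)
    for col, adj_col in (("count_p", "count_p_adj"), ("gc_p", "gc_p_adj")):
        table[adj_col] = float("nan")
        for motif in table["motif"].unique():
            mask = (table["motif"] == motif) & table[col].notna()
            if mask.any():
                table.loc[mask, adj_col] = bh_adjust(table.loc[mask, col].tolist())
    return table


def run_profiles(
    universe: PromoterUniverse,
    gene_sets: Sequence[GeneSet],
    config: RunConfig = RunConfig(),
) -> dict[tuple[str, str], ProfileTrack]:
    """Sliding-window frequency tracks per (motif, group), plus the universe.

    Returns a dict keyed by (motif name, group name); the full universe is
    included under group name "ALL" as the control track.
    """
    gene_sets = _matched(gene_sets, universe)
    region = config.profile_region or universe.region
    tracks: dict[tuple[str, str], ProfileTrack] = {}
    for motif in config.motifs:
        tracks[(motif.name, "ALL")] = profile(
            universe, motif, config.profile_window_size, region
        )
        for gs in gene_sets:
            if not gs.matched:
                raise ValueError(f"gene set {gs.name!r} matched no universe genes")
            records = [universe[g] for g in gs.matched]
            tracks[(motif.name, gs.name)] = profile(
                records, motif, config.profile_window_size, region
            )
    return tracks


def write_run_metadata(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a machine-readable sidecar recording seed and settings."""
    from promotif import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "promotif_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "window": list(config.window),
        "profile_window_size": config.profile_window_size,
        "profile_region": list(config.profile_region) if config.profile_region else None,
        "fdr_level": config.fdr_level,
        "motifs": [{"name": m.name, "pattern": m.pattern} for m in config.motifs],
    }
    if extra:
        payload.update(extra)
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
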