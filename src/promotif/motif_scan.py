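"""Exact bidirectional motif search in TSS-relative coordinates.

All searching is exact-string: a motif occurs on the plus strand where the
promoter sequence equals the pattern, and on the minus strand where it equals
the pattern's reverse complement.  Occurrence positions are reported as the
TSS-relative offset of the leftmost plus-strand base, so a window [lo, hi]
contains an occurrence iff its start offset lies in [lo, hi] (start-based
membership; the motif may extend past hi).  Overlapping occurrences all
count, and N bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from promotif.promoter_io import PromoterRecord, PromoterUniverse

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """An exact DNA motif to search, by default on both strands."""

    name: str
    pattern: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (4 <= len(self.pattern) <= 12):
            raise ValueError(f"motif {self.name!r}: pattern length must be 4-12")
        if not set(self.pattern) <= set("ACGT"):
            raise ValueError(f"motif {self.name!r}: pattern must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def revcomp(self) -> str:
        return reverse_complement(self.pattern)


# The motifs used in the promoter analysis: the GC-box and GA-box bound by
# Sp1-family factors, plus the MAZ and KLF13 binding motifs as controls.
GC_BOX = MotifSpec("GC-box", "GGGCGG")
GA_BOX = MotifSpec("GA-box", "GGGAGG")
MAZ_MOTIF = MotifSpec("MAZ", "CCCCTCC")
KLF13_MOTIF = MotifSpec("KLF13", "ACGCCC")

BUILTIN_MOTIFS: dict[str, MotifSpec] = {
    m.name: m for m in (GC_BOX, GA_BOX, MAZ_MOTIF, KLF13_MOTIF)
}


@dataclass(frozen=True)
class MotifOccurrence:
    """One exact match: start is the TSS-relative offset of the leftmost base."""

    gene_id: str
    motif: str
    strand: Literal["+", "-"]
    start: int


@dataclass(frozen=True)
class GeneMotifSummary:
    """Per-gene window summary: occurrence count, presence flag, GC content."""

    gene_id: str
    window: tuple[int, int]
    n_occurrences: int
    has_motif: bool
    gc_content: float

    def __post_init__(self) -> None:
        assert self.has_motif == (self.n_occurrences >= 1)
        assert 0.0 <= self.gc_content <= 1.0


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) match indices of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_motif(record: PromoterRecord, motif: MotifSpec) -> list[MotifOccurrence]:
    """All exact occurrences of ``motif`` in ``record``, sorted by (start, strand).

    Plus-strand hits are positions where the sequence equals the pattern;
    minus-strand hits are plus-strand positions of the pattern's reverse
    complement.  A motif longer than the sequence yields an empty list.
    """
    occ = [
        MotifOccurrence(record.gene_id, motif.name, "+", record.start_offset + i)
        for i in _find_all(record.sequence, motif.pattern)
    ]
    if motif.both_strands:
        occ.extend(
            MotifOccurrence(record.gene_id, motif.name, "-", record.start_offset + i)
            for i in _find_all(record.sequence, motif.revcomp)
        )
    occ.sort(key=lambda o: (o.start, o.strand))
    return occ


def occurrence_starts(record: PromoterRecord, motif: MotifSpec) -> list[int]:
    """Start offsets of all occurrences (both strands merged, sorted).

    For a palindromic motif scanned on both strands the same start appears
    twice (once per strand), matching :func:`scan_motif`.
    """
    starts = _find_all(record.sequence, motif.pattern)
    if motif.both_strands:
        starts = starts + _find_all(record.sequence, motif.revcomp)
    return sorted(record.start_offset + i for i in starts)


def gc_content(record: PromoterRecord, window: tuple[int, int]) -> float:
    """Fraction of G or C bases in the window's plus-strand sequence.

    Counting G-or-C on both strands and dividing by twice the window length
    gives the identical number, because every plus-strand G or C pairs with a
    minus-strand C or G.  N counts as non-GC.
    """
    lo, hi = window
    _check_window(record.region, window)
    sub = record.sequence[lo - record.start_offset : hi - record.start_offset + 1]
    return (sub.count("G") + sub.count("C")) / len(sub)


def _check_window(region: tuple[int, int], window: tuple[int, int]) -> None:
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window {window}: lo must be <= hi")
    if lo < region[0] or hi > region[1]:
        raise ValueError(f"window {window} outside region {region}")


def summarize_gene(
    record: PromoterRecord, motif: MotifSpec, window: tuple[int, int] = (-140, -41)
) -> GeneMotifSummary:
    """Count in-window occurrences and GC content for one gene.

    An occurrence is in the window iff its start offset lies in [lo, hi].
    The default window (-140, -41) is the proximal promoter region where
    GC-boxes are concentrated and bound by Sp1/Sp4.
    """
    lo, hi = window
    _check_window(record.region, window)
    n = sum(lo <= s <= hi for s in occurrence_starts(record, motif))
    return GeneMotifSummary(
        gene_id=record.gene_id,
        window=(lo, hi),
        n_occurrences=n,
        has_motif=n >= 1,
        gc_content=gc_content(record, window),
    )


def summarize_universe(
    universe: PromoterUniverse, motif: MotifSpec, window: tuple[int, int] = (-140, -41)
) -> pd.DataFrame:
    """Per-gene summary table: gene_id, n_occurrences, has_motif, gc_content."""
    rows = [summarize_gene(r, motif, window) for r in universe]
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in rows],
            "n_occurrences": [s.n_occurrences for s in rows],
            "has_motif": [s.has_motif for s in rows],
            "gc_content": [s.gc_content for s in rows],
        }
    )


@dataclass(frozen=True)
class ProfileTrack:
    """Positional motif-frequency profile across a universe.

    ``values[i]`` is the fraction of genes hit in the sliding window starting
    at ``starts[i]``; window starts advance by 1 nucleotide.
    """

    motif: str
    window_size: int
    region: tuple[int, int]
    mode: Literal["genes_with_hit", "per_position_occurrence"]
    starts: tuple[int, ...]
    values: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start": self.starts, "fraction": self.values})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _start_indicator(
    records: Sequence[PromoterRecord] | PromoterUniverse,
    motif: MotifSpec,
    region: tuple[int, int],
) -> np.ndarray:
    """Boolean matrix (gene x offset in region): occurrence starting there?"""
    lo, hi = region
    span = hi - lo + 1
    ind = np.zeros((len(records), span), dtype=bool)
    for g, rec in enumerate(records):
        for s in occurrence_starts(rec, motif):
            if lo <= s <= hi:
                ind[g, s - lo] = True
    return ind


def profile(
    universe: PromoterUniverse | Sequence[PromoterRecord],
    motif: MotifSpec,
    window_size: int,
    region: tuple[int, int] | None = None,
    mode: Literal["genes_with_hit", "per_position_occurrence"] = "genes_with_hit",
) -> ProfileTrack:
    """Sliding-window motif-frequency track with 1-nt window shift.

    For each window start s in [lo, hi - window_size + 1]:

    * ``genes_with_hit`` — fraction of genes with >= 1 occurrence starting in
      [s, s + window_size - 1] (the large-window percentage track);
    * ``per_position_occurrence`` — requires window_size == motif length;
      fraction of genes with an occurrence starting exactly at s (the
      fine-grained relative-abundance track).
    """
    records = list(universe)
    if not records:
        raise ValueError("profile requires at least one record")
    univ_region = records[0].region
    if region is None:
        region = univ_region
    _check_window(univ_region, region)
    lo, hi = region
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size > hi - lo + 1:
        raise ValueError(f"window_size {window_size} exceeds region span {hi - lo + 1}")
    if mode == "per_position_occurrence" and window_size != motif.length:
        raise ValueError("per_position_occurrence mode requires window_size == motif length")

    ind = _start_indicator(records, motif, region)
    n_windows = hi - lo + 1 - window_size + 1
    if mode == "per_position_occurrence":
        values = ind[:, :n_windows].mean(axis=0)
    else:
        # windowed any-occurrence via cumulative sums along the offset axis
        csum = np.zeros((ind.shape[0], ind.shape[1] + 1), dtype=np.int32)
        np.cumsum(ind, axis=1, out=csum[:, 1:])
        counts = csum[:, window_size:] - csum[:, :-window_size]
        values = (counts > 0).mean(axis=0)
    starts = tuple(range(lo, lo + n_windows))
    return ProfileTrack(
        motif=motif.name,
        window_size=window_size,
        region=region,
        mode=mode,
        starts=starts,
        values=tuple(float(v) for v in values),
    )


def occurrences_table(
    universe: PromoterUniverse | Iterable[PromoterRecord], motif: MotifSpec
) -> pd.DataFrame:
    """All occurrences across a universe as a tidy table (TSV-exportable)."""
    rows = [o for rec in universe for o in scan_motif(rec, motif)]
    return pd.DataFrame(
        {
            "gene_id": [o.gene_id for o in rows],
            "motif": [o.motif for o in rows],
            "strand": [o.strand for o in rows],
            "start": [o.start for o in rows],
        }
    )
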