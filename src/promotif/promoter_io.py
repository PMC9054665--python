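"""Reading and validation of promoter universes and gene sets.

Promoters live in a TSS-relative coordinate frame: offset 0 is the
transcription start site, negative offsets are upstream.  A universe (for
example the EPD hg38 export, one representative promoter per gene over
[-500, +100]) is a collection of equal-length records sharing that frame.
The frame is declared by the caller, not parsed from FASTA headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class PromoterRecord:
    """One gene's TSS-anchored promoter sequence.

    ``start_offset`` is the TSS-relative offset of the first base; the record
    spans the closed interval [start_offset, start_offset + len - 1].
    """

    gene_id: str
    sequence: str
    start_offset: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.gene_id}: sequence must have length >= 1")
        if not set(self.sequence) <= _VALID_BASES:
            pos = next(i for i, b in enumerate(self.sequence) if b not in _VALID_BASES)
            raise ValueError(
                f"{self.gene_id}: invalid base {self.sequence[pos]!r} at sequence "
                f"index {pos} (offset {self.start_offset + pos}); only A/C/G/T/N allowed"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end_offset(self) -> int:
        """TSS-relative offset of the last base (inclusive)."""
        return self.start_offset + len(self.sequence) - 1

    @property
    def region(self) -> tuple[int, int]:
        return (self.start_offset, self.end_offset)


@dataclass(frozen=True)
class PromoterUniverse:
    """A gene universe: equal-region promoter records with unique gene ids."""

    records: tuple[PromoterRecord, ...]
    region: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("universe must contain at least one record")
        regions = {r.region for r in self.records}
        if len(regions) != 1:
            raise ValueError(
                f"all records must share one region; found {sorted(regions)[:3]}..."
                if len(regions) > 3
                else f"all records must share one region; found {sorted(regions)}"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene_id {r.gene_id!r} in universe")
            seen.add(r.gene_id)
        object.__setattr__(self, "region", self.records[0].region)
        object.__setattr__(self, "_by_id", {r.gene_id: r for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id  # type: ignore[attr-defined]

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._by_id[gene_id]  # type: ignore[attr-defined]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(r.gene_id for r in self.records)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols, optionally matched against a universe.

    ``matched`` holds the universe's spelling of every symbol found in the
    universe (case-insensitive comparison); ``unmatched`` holds the supplied
    spelling of the rest.  Both are empty until :func:`match_gene_set` runs.
    """

    name: str
    symbols: tuple[str, ...]
    matched: tuple[str, ...] = ()
    unmatched: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.symbols)


def read_promoters(fasta_path: str | Path, start_offset: int) -> PromoterUniverse:
    """Read a promoter universe from FASTA with a declared coordinate frame.

    The gene id is the first whitespace-delimited header token.  Sequences are
    upper-cased and validated (A/C/G/T/N only, all the same length, unique
    ids).  ``start_offset`` is the TSS-relative offset of every record's first
    base, e.g. -500 for the region [-500, +100].
    """
    fasta_path = Path(fasta_path)
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"{fasta_path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        records.append(
            PromoterRecord(gene_id=gene_id, sequence=str(rec.seq).upper(), start_offset=start_offset)
        )
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    lengths = {r.length for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{fasta_path}: ragged sequence lengths {sorted(lengths)}")
    return PromoterUniverse(records=tuple(records))


def write_promoters(universe: PromoterUniverse, fasta_path: str | Path) -> None:
    """Write a universe back to FASTA (ids and sequences round-trip exactly)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in universe
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, '#' comments and blanks ignored.

    Symbols are de-duplicated case-insensitively, preserving the first
    occurrence's spelling and order.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            key = token.casefold()
            if key not in seen:
                seen.add(key)
                symbols.append(token)
    if not symbols:
        raise ValueError(f"{path}: gene-set file is empty after filtering")
    return GeneSet(name=name if name is not None else path.stem, symbols=tuple(symbols))


def match_gene_set(gs: GeneSet, universe: PromoterUniverse) -> GeneSet:
    """Match gene-set symbols against universe ids, case-insensitively.

    Returns a new GeneSet whose ``matched`` entries carry the universe's
    spelling.  Zero matches is a valid outcome.  Idempotent: re-matching a
    matched set changes nothing.
    """
    if len(universe) == 0:  # pragma: no cover - universe construction forbids this
        raise ValueError("cannot match against an empty universe")
    by_fold = {gid.casefold(): gid for gid in universe.gene_ids}
    matched: list[str] = []
    unmatched: list[str] = []
    for sym in gs.symbols:
        hit = by_fold.get(sym.casefold())
        if hit is None:
            unmatched.append(sym)
        else:
            matched.append(hit)
    return replace(gs, matched=tuple(matched), unmatched=tuple(unmatched))


def match_all(gene_sets: Iterable[GeneSet], universe: PromoterUniverse) -> list[GeneSet]:
    return [match_gene_set(gs, universe) for gs in gene_sets]
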