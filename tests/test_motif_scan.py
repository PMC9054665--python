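"""Bidirectional exact motif search, window summaries, positional profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif import (
    GC_BOX,
    MotifSpec,
    profile,
    reverse_complement,
    scan_motif,
    summarize_gene,
    summarize_universe,
)
from promotif.motif_scan import gc_content
from tests.conftest import make_record, make_universe, random_dna

ALL_MOTIFS = ["GGGCGG", "GGGAGG", "CCCCTCC", "ACGCCC"]


def oracle_scan(seq: str, pattern: str, both_strands: bool = True):
    """Naive sliding-window comparison: the independent scanner oracle."""
    m = len(pattern)
    rc = reverse_complement(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        sub = seq[i : i + m]
        if sub == pattern:
            hits.append((i, "+"))
        if both_strands and sub == rc:
            hits.append((i, "-"))
    return sorted(hits)


class TestScanMotif:
    def test_plus_strand_hit_at_offset(self):
        rec = make_record("GGGCGG", start_offset=-140)
        (occ,) = scan_motif(rec, GC_BOX)
        assert (occ.strand, occ.start) == ("+", -140)

    def test_minus_strand_hit(self):
        rec = make_record("CCGCCC", start_offset=-10)
        (occ,) = scan_motif(rec, GC_BOX)
        assert (occ.strand, occ.start) == ("-", -10)

    def test_overlapping_hits_all_reported(self):
        rec = make_record("GGGCGGGCGG", start_offset=0)
        occ = scan_motif(rec, GC_BOX)
        assert [(o.start, o.strand) for o in occ] == [(0, "+"), (4, "+")]

    def test_no_hit(self):
        assert scan_motif(make_record("AAAAAA"), GC_BOX) == []

    def test_motif_longer_than_sequence_empty(self):
        assert scan_motif(make_record("GGGC"), GC_BOX) == []

    def test_n_never_matches(self):
        assert scan_motif(make_record("GGGCGN"), GC_BOX) == []

    def test_plus_only_when_both_strands_off(self):
        motif = MotifSpec("gc", "GGGCGG", both_strands=False)
        assert scan_motif(make_record("CCGCCC"), motif) == []

    def test_palindromic_motif_counts_both_strands(self):
        motif = MotifSpec("pal", "GGCC")
        occ = scan_motif(make_record("AGGCCA", start_offset=0), motif)
        assert [(o.start, o.strand) for o in occ] == [(1, "+"), (1, "-")]

    @settings(max_examples=200, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=6, max_size=200),
        pattern=st.sampled_from(ALL_MOTIFS),
    )
    def test_matches_naive_oracle(self, seq, pattern):
        rec = make_record(seq, start_offset=-50)
        motif = MotifSpec("m", pattern)
        got = [(o.start + 50, o.strand) for o in scan_motif(rec, motif)]
        assert sorted(got) == oracle_scan(seq, pattern)

    def test_strand_symmetry(self, rng):
        """Reverse-complementing the universe mirrors occurrence positions."""
        seq = random_dna(rng, 400, gc=0.6)
        rec = make_record(seq, start_offset=0)
        mirrored = make_record(reverse_complement(seq), start_offset=0)
        L, m = len(seq), GC_BOX.length
        fwd = {(o.start, o.strand) for o in scan_motif(rec, GC_BOX)}
        rev = {
            (L - m - o.start, "+-"[o.strand == "+"])
            for o in scan_motif(mirrored, GC_BOX)
        }
        assert fwd == rev


class TestSummarizeGene:
    def test_window_membership_is_start_based(self):
        # hit starting exactly at the window edge counts; one base later does not
        def rec_with_hit_at(start):
            i = start + 500
            return make_record("A" * i + "GGGCGG" + "A" * (601 - i - 6), start_offset=-500)

        assert summarize_gene(rec_with_hit_at(-41), GC_BOX, (-140, -41)).n_occurrences == 1
        assert summarize_gene(rec_with_hit_at(-40), GC_BOX, (-140, -41)).n_occurrences == 0

    def test_has_motif_iff_count_positive(self):
        rec = make_record("GGGCGGAAAA", start_offset=-10)
        s = summarize_gene(rec, GC_BOX, (-10, -5))
        assert s.has_motif and s.n_occurrences == 1
        s2 = summarize_gene(rec, GC_BOX, (-4, -1))
        assert not s2.has_motif and s2.n_occurrences == 0

    def test_gc_content_extremes(self):
        assert summarize_gene(make_record("GGGCGGCC", 0), GC_BOX, (0, 7)).gc_content == 1.0
        assert summarize_gene(make_record("ACGTACGT", 0), GC_BOX, (0, 7)).gc_content == 0.5

    def test_n_counts_as_non_gc(self):
        assert gc_content(make_record("GCNN", 0), (0, 3)) == 0.5

    def test_window_outside_region_is_error(self):
        with pytest.raises(ValueError, match="outside region"):
            summarize_gene(make_record("ACGTACGT", 0), GC_BOX, (-1, 3))

    def test_reversed_window_is_error(self):
        with pytest.raises(ValueError, match="lo"):
            summarize_gene(make_record("ACGTACGT", 0), GC_BOX, (5, 3))

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=10, max_size=100))
    def test_plus_strand_gc_equals_both_strand_count(self, seq):
        """#GC on the plus strand / L == both-strand G-or-C count / 2L.

        Every plus-strand G or C pairs with a minus-strand C or G, so the two
        definitions coincide exactly.
        """
        rec = make_record(seq, start_offset=0)
        window = (0, len(seq) - 1)
        both = sum(
            s.count("G") + s.count("C") for s in (seq, reverse_complement(seq))
        )
        assert gc_content(rec, window) == pytest.approx(both / (2 * len(seq)))


class TestProfile:
    def test_planted_plateau(self):
        def gene(start):
            i = start + 500
            return "A" * i + "GGGCGG" + "A" * (601 - i - 6)

        universe = make_universe([gene(-100)] * 5, start_offset=-500)
        track = profile(universe, GC_BOX, window_size=100, region=(-500, 50))
        vals = dict(zip(track.starts, track.values))
        # window [s, s+99] covers start -100 iff -199 <= s <= -100
        assert vals[-199] == 1.0 and vals[-100] == 1.0
        assert vals[-200] == 0.0 and vals[-99] == 0.0

    def test_absent_motif_all_zero(self):
        universe = make_universe(["A" * 50] * 3, start_offset=0)
        track = profile(universe, GC_BOX, window_size=10, region=(0, 49))
        assert set(track.values) == {0.0}

    def test_equals_brute_force_recount(self, rng):
        universe = make_universe(
            [random_dna(rng, 120, gc=0.7) for _ in range(20)], start_offset=-60
        )
        ws = 15
        track = profile(universe, GC_BOX, window_size=ws, region=(-60, 59))
        from promotif.motif_scan import occurrence_starts

        per_gene = [occurrence_starts(r, GC_BOX) for r in universe]
        for s, v in zip(track.starts, track.values):
            expect = np.mean(
                [any(s <= x <= s + ws - 1 for x in starts) for starts in per_gene]
            )
            assert v == pytest.approx(expect)

    def test_per_position_sum_equals_total_occurrences(self, rng):
        universe = make_universe(
            [random_dna(rng, 200, gc=0.7) for _ in range(30)], start_offset=0
        )
        track = profile(
            universe, GC_BOX, window_size=GC_BOX.length, region=(0, 199),
            mode="per_position_occurrence",
        )
        from promotif.motif_scan import occurrence_starts

        total = sum(
            1
            for r in universe
            for s in occurrence_starts(r, GC_BOX)
            if s <= 199 - GC_BOX.length + 1
        )
        assert sum(track.values) * len(universe) == pytest.approx(total)

    def test_window_size_exceeding_span_is_error(self):
        universe = make_universe(["ACGTACGTAC"], start_offset=0)
        with pytest.raises(ValueError, match="window_size"):
            profile(universe, GC_BOX, window_size=20, region=(0, 9))

    def test_window_starts_advance_by_one(self):
        universe = make_universe(["A" * 50], start_offset=-25)
        track = profile(universe, GC_BOX, window_size=10, region=(-25, 24))
        assert list(np.diff(track.starts)) == [1] * (len(track.starts) - 1)
        assert track.starts[0] == -25 and track.starts[-1] == 24 - 10 + 1


def test_summarize_universe_columns(rng):
    universe = make_universe([random_dna(rng, 60) for _ in range(5)], start_offset=-30)
    df = summarize_universe(universe, GC_BOX, (-30, 10))
    assert list(df.columns) == ["gene_id", "n_occurrences", "has_motif", "gc_content"]
    assert (df["has_motif"] == (df["n_occurrences"] >= 1)).all()


def test_motif_spec_validation():
    with pytest.raises(ValueError):
        MotifSpec("bad", "GGX CGG")
    with pytest.raises(ValueError):
        MotifSpec("short", "GGG")
    assert MotifSpec("gc", "GGGCGG").revcomp == "CCGCCC"
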