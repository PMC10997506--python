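"""Window generation, exact matching, interval plumbing and masking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbrobust import (
    AlignmentHit,
    ContractError,
    ExhaustiveParams,
    FormatError,
    GenomeSet,
    Interval,
    PlantedDatabaseSpec,
    find_exact_matches,
    generate_windows,
    hits_to_intervals,
    make_planted_database,
    mask_database,
    merge_intervals,
    read_sam_hits,
    run_exhaustive,
)
from mbrobust.exhaustive import IntervalPrecursor
from mbrobust.genomes import revcomp

from oracles import brute_force_masked_positions


class TestGenerateWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (300, [(0, 150), (75, 225), (150, 300), (225, 300)]),
            (74, []),  # below the minimum window length
            (150, [(0, 150), (75, 150)]),
        ],
    )
    def test_positional_enumeration(self, length, expected):
        gs = GenomeSet([("c", "A" * length)])
        assert [(w.start, w.end) for w in generate_windows(gs)] == expected

    def test_n_filter_boundary(self):
        # the [0,150) window holds exactly max_n Ns and is dropped; the
        # trailing [75,150) window holds only 75 Ns and survives
        gs = GenomeSet([("c", "A" * 50 + "N" * 100)])
        assert [(w.start, w.end) for w in generate_windows(gs)] == [(75, 150)]
        # one fewer N and the full window passes too
        gs = GenomeSet([("c", "A" * 51 + "N" * 99)])
        assert [(w.start, w.end) for w in generate_windows(gs)] == [(0, 150), (75, 150)]

    def test_window_sequences_are_contig_slices(self):
        gs = GenomeSet([("c", "ACGT" * 100)])
        seq = gs.get("c").sequence
        for w in generate_windows(gs):
            assert w.sequence == seq[w.start : w.end]
            assert w.start % 75 == 0
            assert 75 <= len(w) <= 150

    def test_empty_reference_is_empty_stream(self):
        assert list(generate_windows(GenomeSet([]))) == []

    def test_invalid_character_rejected_with_location(self):
        with pytest.raises(FormatError, match=r"offset 2"):
            GenomeSet([("bad", "ACXGT")])

    def test_deterministic_window_ids_encode_contig_and_start(self):
        gs = GenomeSet([("chr1", "A" * 300)])
        assert [w.id for w in generate_windows(gs)] == [
            "chr1:0", "chr1:75", "chr1:150", "chr1:225",
        ]


class TestFindExactMatches:
    def test_forward_hit(self):
        hits = find_exact_matches("ACGT", GenomeSet([("c", "TTACGTTT")]))
        assert [(h.pos, h.strand) for h in hits] == [(3, "+")]

    def test_reverse_complement_hit(self):
        hits = find_exact_matches("AAAC", GenomeSet([("c", "TTGTTTAA")]))
        assert [(h.pos, h.strand) for h in hits] == [(3, "-")]

    def test_no_match(self):
        assert find_exact_matches("GGGG", GenomeSet([("c", "AAAA")])) == []

    def test_overlapping_occurrences_all_reported(self):
        hits = find_exact_matches("AAA", GenomeSet([("c", "AAAAA")]))
        assert [h.pos for h in hits if h.strand == "+"] == [1, 2, 3]

    def test_palindromic_query_reported_once_per_position(self):
        hits = find_exact_matches("ACGT", GenomeSet([("c", "AACGTA")]))
        assert [(h.pos, h.strand) for h in hits] == [(2, "+")]

    def test_ordered_by_contig_then_pos(self):
        db = GenomeSet([("b", "AAAT"), ("a", "TAAA")])
        hits = find_exact_matches("AAA", db)
        assert [(h.ref_contig, h.pos) for h in hits] == [("a", 2), ("b", 1)]


class TestHitsToIntervals:
    def test_standard_conversion(self, _db400=None):
        db = GenomeSet([("c", "A" * 400)])
        hit = AlignmentHit("q", "c", 100, 150)
        (p,) = hits_to_intervals([hit], db)
        assert (p.start, p.end) == (99, 249)

    def test_clipping_to_contig_length(self):
        db = GenomeSet([("c", "A" * 200)])
        (p,) = hits_to_intervals([AlignmentHit("q", "c", 100, 150)], db)
        assert (p.start, p.end) == (99, 200)

    def test_awk_compat_is_plus_one_shift(self):
        db = GenomeSet([("c", "A" * 400)])
        hit = AlignmentHit("q", "c", 100, 150)
        (p,) = hits_to_intervals([hit], db, awk_compat=True)
        assert (p.start, p.end) == (100, 250)

    def test_unknown_contig_error_names_id(self):
        db = GenomeSet([("c", "AAAA")])
        with pytest.raises(ContractError, match="nope"):
            hits_to_intervals([AlignmentHit("q", "nope", 1, 4)], db)

    def test_pos_beyond_contig_error(self):
        db = GenomeSet([("c", "AAAA")])
        with pytest.raises(ContractError, match="beyond"):
            hits_to_intervals([AlignmentHit("q", "c", 5, 4)], db)

    def test_sorted_and_deduplicated(self):
        db = GenomeSet([("c", "A" * 100), ("b", "A" * 100)])
        hits = [
            AlignmentHit("q2", "c", 10, 5),
            AlignmentHit("q1", "b", 20, 5),
            AlignmentHit("q2", "c", 10, 5),  # exact duplicate
        ]
        ps = hits_to_intervals(hits, db)
        assert ps == [
            IntervalPrecursor("b", 19, 24, "q1"),
            IntervalPrecursor("c", 9, 14, "q2"),
        ]


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([(0, 10), (5, 15)], [(0, 15, 2)]),  # overlap
            ([(0, 10), (10, 20)], [(0, 20, 2)]),  # book-ended, distance 0
            ([(0, 10), (12, 20)], [(0, 10, 1), (12, 20, 1)]),  # disjoint
        ],
    )
    def test_merge_semantics(self, spans, expected):
        ps = [IntervalPrecursor("c", s, e, f"q{i}") for i, (s, e) in enumerate(spans)]
        merged = merge_intervals(ps)
        assert [(iv.start, iv.end, iv.support) for iv in merged] == expected

    def test_unsorted_input_is_an_error(self):
        ps = [IntervalPrecursor("c", 10, 20, "a"), IntervalPrecursor("c", 0, 5, "b")]
        with pytest.raises(ContractError, match="unsorted"):
            merge_intervals(ps)

    def test_contigs_never_merge_across(self):
        ps = [IntervalPrecursor("a", 0, 10, "q"), IntervalPrecursor("b", 0, 10, "q")]
        assert len(merge_intervals(ps)) == 2

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_merged_output_disjoint_with_gaps(self, raw):
        ps = sorted(
            IntervalPrecursor("c", s, s + l, f"q{i}") for i, (s, l) in enumerate(raw)
        )
        merged = merge_intervals(ps)
        for left, right in zip(merged, merged[1:]):
            assert right.start > left.end  # gap of >= 1 base
        assert sum(iv.support for iv in merged) == len(ps)


class TestMaskDatabase:
    def test_basic_masking(self):
        db = GenomeSet([("c", "ACGTACGT")])
        report = mask_database(db, [Interval("c", 2, 5)])
        assert report.masked_db.get("c").sequence == "ACNNNCGT"
        assert report.total_masked_bases == 3

    def test_empty_intervals_identity(self):
        db = GenomeSet([("c", "ACGTACGT")])
        report = mask_database(db, [])
        assert report.masked_db.get("c").sequence == "ACGTACGT"
        assert report.genomes_affected == 0

    def test_whole_contig(self):
        db = GenomeSet([("c", "ACGT")])
        report = mask_database(db, [Interval("c", 0, 4)])
        assert report.masked_db.get("c").sequence == "NNNN"
        assert report.masked_bases_per_genome == {"c": 4}

    def test_out_of_bounds_error(self):
        db = GenomeSet([("c", "ACGT")])
        with pytest.raises(ContractError, match="exceeds"):
            mask_database(db, [Interval("c", 2, 10)])

    def test_idempotent(self):
        db = GenomeSet([("c", "ACGTACGTAC")])
        ivs = [Interval("c", 1, 4), Interval("c", 6, 8)]
        once = mask_database(db, ivs).masked_db
        twice = mask_database(once, ivs).masked_db
        assert once.get("c").sequence == twice.get("c").sequence

    def test_length_conserved_and_non_n_decreases_exactly(self, planted):
        report = run_exhaustive(planted.host, planted.db)
        for contig in planted.db:
            masked = report.masked_db.get(contig.id)
            assert len(masked) == len(contig)
        before = sum(c.sequence.count("N") for c in planted.db)
        after = sum(c.sequence.count("N") for c in report.masked_db)
        assert after - before == report.total_masked_bases


class TestSamIngest:
    SAM = [
        "@HD\tVN:1.6",
        "q1\t0\tc\t3\t60\t4M\t*\t0\t0\tACGT\tIIII",
        "q2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII",  # unmapped
        "q3\t256\tc\t1\t0\t4M\t*\t0\t0\tAAAA\tIIII",  # secondary
        "q4\t16\tc\t2\t60\t4M\t*\t0\t0\tTTTT\tIIII",  # reverse
    ]

    def test_parse_skips_header_and_unmapped(self):
        hits = list(read_sam_hits(self.SAM))
        assert [h.query_id for h in hits] == ["q1", "q3", "q4"]
        assert hits[0].pos == 3 and hits[0].seq_len == 4
        assert hits[2].strand == "-"

    def test_secondary_kept_by_default_excludable_by_flag(self):
        assert len(list(read_sam_hits(self.SAM))) == 3
        kept = list(read_sam_hits(self.SAM, exclude_secondary=True))
        assert [h.query_id for h in kept] == ["q1", "q4"]

    def test_star_seq_is_format_error(self):
        lines = ["q\t0\tc\t1\t60\t*\t*\t0\t0\t*\t*"]
        with pytest.raises(FormatError, match="SEQ"):
            list(read_sam_hits(lines))

    def test_short_line_is_format_error(self):
        with pytest.raises(FormatError, match="fields"):
            list(read_sam_hits(["q\t0\tc\t1"]))


class TestRunExhaustive:
    def test_grid_aligned_plant_recovered_exactly(self, planted):
        report = run_exhaustive(planted.host, planted.db)
        got = [(iv.contig, iv.start, iv.end) for iv in report.intervals]
        want = [(iv.contig, iv.start, iv.end) for iv in planted.truth]
        assert got == want

    def test_disjoint_db_masks_nothing(self):
        pdb = make_planted_database(PlantedDatabaseSpec(seed=5, n_segments=0))
        report = run_exhaustive(pdb.host, pdb.db)
        assert report.intervals == [] and report.total_masked_bases == 0

    def test_off_grid_plant_under_covers_edges_only(self):
        pdb = make_planted_database(
            PlantedDatabaseSpec(seed=8, n_segments=1, segment_length=200,
                                grid_aligned=False)
        )
        report = run_exhaustive(pdb.host, pdb.db)
        truth = pdb.truth[0]
        masked = {
            (iv.contig, pos)
            for iv in report.intervals
            for pos in range(iv.start, iv.end)
        }
        truth_pos = {(truth.contig, p) for p in range(truth.start, truth.end)}
        assert masked <= truth_pos
        # any missed positions are within step-1 of a segment edge
        for contig, pos in truth_pos - masked:
            assert min(pos - truth.start, truth.end - 1 - pos) < 75

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        pdb = make_planted_database(
            PlantedDatabaseSpec(
                seed=seed, n_genomes=2, genome_length=2000, host_length=1500,
                n_segments=seed % 3, segment_length=225, grid_aligned=(seed % 2 == 0),
            )
        )
        report = run_exhaustive(pdb.host, pdb.db)
        expected = brute_force_masked_positions(pdb.host, pdb.db)
        for contig in pdb.db:
            got = {
                i for i, base in enumerate(report.masked_db.get(contig.id).sequence)
                if base == "N"
            }
            assert got == expected[contig.id]

    def test_monotone_in_reference_content(self, planted):
        base = run_exhaustive(planted.host, planted.db).total_masked_bases
        # adding reference sequence (a copy of a db chunk) can only add masking
        extra_seq = planted.db.get(planted.db.contig_ids[0]).sequence[:300]
        bigger = GenomeSet(
            [(c.id, c.sequence) for c in planted.host] + [("extra", extra_seq)]
        )
        more = run_exhaustive(bigger, planted.db).total_masked_bases
        assert more >= base

    def test_awk_compat_intervals_shift_plus_one(self, planted):
        std = run_exhaustive(planted.host, planted.db)
        awk = run_exhaustive(
            planted.host, planted.db, ExhaustiveParams(awk_compat=True)
        )
        contig_len = {c.id: len(c) for c in planted.db}
        got = [(iv.contig, iv.start, iv.end) for iv in awk.intervals]
        want = [
            (iv.contig, iv.start + 1, min(iv.end + 1, contig_len[iv.contig]))
            for iv in std.intervals
        ]
        assert got == want

    def test_stage_errors_carry_stage_name(self):
        db = GenomeSet([("c", "A" * 100)])
        refs = GenomeSet([("h", "A" * 100)])
        bad_hits = [AlignmentHit("q", "missing", 1, 10)]
        with pytest.raises(ContractError, match=r"\[intervals\]"):
            run_exhaustive(refs, db, sam=bad_hits)
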