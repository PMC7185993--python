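"""Alignment I/O, trimming, filters and the similarity network."""

import numpy as np
import pytest

from gtacore.alignment import (
    AMINO_ACIDS,
    AlignedSequenceSet,
    AlignmentFormatError,
    AlignmentParseError,
    SequenceRecord,
    ancient_filter,
    column_gap_fractions,
    consensus_sequence,
    detect_hypervariable,
    filter_gapped_columns,
    pairwise_identity,
    prototype_select,
    read_core_alignment,
    redundancy_filter,
    similarity_network,
    trim_to_core,
    write_core_alignment,
)

from conftest import make_alignment, make_annotation


# ---------------------------------------------------------------------------
# A2M parsing


class TestA2MParsing:
    def test_match_states_and_no_inserts(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAC-DE\n>s2\nAAAAA\n>s3\nC-C-C\n")
        aln = read_core_alignment(p)
        assert aln.n_core_columns == 5
        assert len(aln) == 3
        assert all(not r.inserts for r in aln)

    def test_lowercase_run_becomes_anchored_insert(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACdefG\n")
        aln = read_core_alignment(p)
        rec = aln.records[0]
        assert aln.n_core_columns == 3
        assert rec.core_states == "ACG"
        assert rec.inserts == {2: "DEF"}

    def test_leading_and_trailing_lowercase_are_flanks(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nmkACGwy\n")
        rec = read_core_alignment(p).records[0]
        assert rec.n_term == "MK" and rec.c_term == "WY"
        assert rec.inserts == {}

    def test_inconsistent_match_counts_name_the_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDEF\n>bad\nACDE\n")
        with pytest.raises(AlignmentFormatError, match="bad"):
            read_core_alignment(p)

    def test_illegal_character_reports_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAC*DE\n")
        with pytest.raises(AlignmentParseError, match="position 3"):
            read_core_alignment(p)

    def test_parse_write_parse_is_identity(self, tmp_path):
        text = ">s1\nmkAC-defGH\n>s2\nACDxxGH\n".replace("x", "w")
        p = tmp_path / "a.fasta"
        p.write_text(text)
        aln = read_core_alignment(p)
        q = tmp_path / "b.fasta"
        write_core_alignment(aln, q)
        aln2 = read_core_alignment(q)
        for a, b in zip(aln, aln2):
            assert (a.core_states, a.inserts, a.n_term, a.c_term) == (
                b.core_states, b.inserts, b.n_term, b.c_term
            )


# ---------------------------------------------------------------------------
# Trimming and gap statistics


class TestTrimAndGaps:
    def test_trim_discards_inserts_keeps_core(self):
        aln = make_alignment(["ACG", "A-G"], inserts=[{2: "WW"}, {}])
        trimmed = trim_to_core(aln)
        assert [r.core_states for r in trimmed] == ["ACG", "A-G"]
        assert all(not r.inserts for r in trimmed)

    def test_trim_is_idempotent(self):
        aln = make_alignment(["ACG", "A-G"], inserts=[{2: "WW"}, {}])
        once = trim_to_core(aln)
        twice = trim_to_core(once)
        assert [r.core_states for r in once] == [r.core_states for r in twice]

    def test_gap_fraction_counts(self):
        rows = ["ACDEA"] * 8 + ["ACDE-"] * 2
        gf = column_gap_fractions(make_alignment(rows))
        assert gf[4] == pytest.approx(0.2)
        assert np.all(gf[:4] == 0.0)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            column_gap_fractions(AlignedSequenceSet([], 0))

    def test_filter_is_strict_at_threshold(self):
        # 100 records: column 1 at exactly 15% gaps, column 2 at 16%
        rows = []
        for i in range(100):
            c1 = "-" if i < 15 else "A"
            c2 = "-" if i < 16 else "A"
            rows.append(c1 + c2 + "C")
        filtered, kept = filter_gapped_columns(make_alignment(rows), 0.15)
        assert kept == [1, 3]
        assert filtered.n_core_columns == 2

    def test_threshold_one_keeps_everything(self):
        aln = make_alignment(["---", "A--"])
        _, kept = filter_gapped_columns(aln, 1.0)
        assert kept == [1, 2, 3]

    def test_constructed_fixture_removes_exactly_flagged_columns(self, rng):
        # 20 records x 10 columns; plant >15% gaps in columns 2, 5, 9
        rows = []
        for i in range(20):
            row = list("ACDEFGHIKL")
            for c in (2, 5, 9):
                if i < 4:  # 20% gaps
                    row[c - 1] = "-"
            rows.append("".join(row))
        _, kept = filter_gapped_columns(make_alignment(rows), 0.15)
        assert kept == [c for c in range(1, 11) if c not in (2, 5, 9)]

    def test_filter_matches_brute_force_recount(self, rng):
        rows = [
            "".join(rng.choice(list("AC-"), size=12)) for _ in range(30)
        ]
        aln = make_alignment(rows)
        for t in (0.0, 0.1, 0.3, 0.5):
            _, kept = filter_gapped_columns(aln, t)
            brute = [
                c for c in range(1, 13)
                if sum(r[c - 1] == "-" for r in rows) / 30 <= t
            ]
            assert kept == brute


# ---------------------------------------------------------------------------
# Consensus and prototype


class TestConsensus:
    def test_majority_vote_ignores_gaps(self):
        aln = make_alignment(["R", "R", "K", "-"])
        res = consensus_sequence(aln)
        assert res.sequence == "R"
        assert res.tie_columns == []

    def test_tie_breaks_alphabetically_and_is_flagged(self):
        aln = make_alignment(["D", "E"])
        res = consensus_sequence(aln)
        assert res.sequence == "D"
        assert res.tie_columns == [1]

    def test_identical_sequences_give_that_sequence(self):
        aln = make_alignment(["ACDEF"] * 4)
        assert consensus_sequence(aln).sequence == "ACDEF"

    def test_all_gap_column_flagged(self):
        aln = make_alignment(["A-", "C-"])
        res = consensus_sequence(aln)
        assert res.sequence[1] == "-"
        assert res.all_gap_columns == [2]


class TestPrototype:
    def test_consensus_member_wins_with_self_score(self):
        aln = make_alignment(["ACDEF", "AWDEF", "ACDEW"])
        rec, score = prototype_select(aln, "ACDEF")
        assert rec.id == "seq1"

    def test_conservative_substitution_beats_radical(self):
        # K for R is conservative (BLOSUM62 +2); W for R is radical (-3)
        aln = make_alignment(["AKNDC", "AWNDC"])
        rec, _ = prototype_select(aln, "ARNDC")
        assert rec.core_states == "AKNDC"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            prototype_select(AlignedSequenceSet([], 3), "ACD")


# ---------------------------------------------------------------------------
# Hypervariable regions


class TestHypervariable:
    def test_insert_longer_than_28_flags_hv2(self):
        ann = make_annotation(10, hv1=2, hv2=5, hv3=8)
        aln = make_alignment(
            ["ACDEFGHIKL"], inserts=[{5: "W" * 29}], families=["GT2"]
        )
        report = detect_hypervariable(aln, ann)
        assert report.loc[0, "hv"] == "HV2"
        assert bool(report.loc[0, "hv2_flag"]) is True

    def test_28_residue_insert_not_flagged(self):
        ann = make_annotation(10, hv1=2, hv2=5, hv3=8)
        aln = make_alignment(["ACDEFGHIKL"], inserts=[{5: "W" * 28}])
        report = detect_hypervariable(aln, ann)
        assert bool(report.loc[0, "hv2_flag"]) is False

    def test_trimmed_alignment_gives_empty_report(self):
        ann = make_annotation(10, hv1=2, hv2=5, hv3=8)
        aln = make_alignment(["ACDEFGHIKL", "ACDEFGHIKL"])
        assert detect_hypervariable(aln, ann).empty


# ---------------------------------------------------------------------------
# Redundancy and ancient filters


def _rec(n_aligned=150, n_insert=10, n_term=80, c_term=150, rid="r", n_core=231):
    states = "A" * n_aligned + "-" * (n_core - n_aligned)
    return SequenceRecord(
        id=rid,
        core_states=states,
        inserts={1: "W" * n_insert} if n_insert else {},
        n_term="A" * n_term,
        c_term="A" * c_term,
    )


class TestRedundancyFilter:
    def test_identical_records_keep_one(self):
        aln = make_alignment(["ACDEF", "ACDEF"], families=["GT2", "GT2"])
        assert len(redundancy_filter(aln, 0.70)) == 1

    def test_triplet_at_60_percent_identity(self):
        # 10 columns, pairwise identity 0.6 by construction
        rows = ["AAAAAACDEF", "AAAAAAWHKL", "AAAAAAMNPQ"]
        fams = ["GT2"] * 3
        aln = make_alignment(rows, families=fams)
        assert len(redundancy_filter(aln, 0.70)) == 3
        assert len(redundancy_filter(aln, 0.50)) == 1

    def test_per_family_overrides_apply(self):
        rows = ["AAAAAACDEF", "AAAAAAWHKL", "CCCCCCCDEF", "CCCCCCWHKL"]
        fams = ["GT2", "GT2", "GT7", "GT7"]
        aln = make_alignment(rows, families=fams)
        kept = redundancy_filter(aln, 0.70, {"GT2": 0.50})
        fams_kept = [r.family_label for r in kept]
        assert fams_kept.count("GT2") == 1  # filtered at the stricter bound
        assert fams_kept.count("GT7") == 2

    def test_output_pairwise_identities_below_threshold(self, rng):
        rows = ["".join(rng.choice(list("ACD"), size=20)) for _ in range(30)]
        aln = make_alignment(rows, families=["X"] * 30)
        kept = redundancy_filter(aln, 0.6)
        for i, a in enumerate(kept.records):
            for b in kept.records[i + 1 :]:
                assert pairwise_identity(a, b) < 0.6


class TestAncientFilter:
    def test_all_four_thresholds_satisfied_is_kept(self):
        kept, reasons = ancient_filter([_rec(150, 10, 80, 150)])
        assert len(kept) == 1 and reasons["r"] is None

    def test_exactly_140_aligned_is_rejected(self):
        kept, reasons = ancient_filter([_rec(n_aligned=140)])
        assert not kept and reasons["r"] == "aligned positions"

    def test_exactly_20_inserts_is_rejected(self):
        kept, reasons = ancient_filter([_rec(n_aligned=200, n_insert=20)])
        assert not kept and reasons["r"] == "insert positions"

    def test_flank_bounds_are_inclusive(self):
        kept, _ = ancient_filter([_rec(n_term=100, c_term=200)])
        assert len(kept) == 1
        _, reasons = ancient_filter([_rec(n_term=101)])
        assert reasons["r"] == "N-terminal region"
        _, reasons = ancient_filter([_rec(c_term=201)])
        assert reasons["r"] == "C-terminal region"

    def test_relaxing_thresholds_is_monotone(self, rng):
        recs = [
            _rec(
                n_aligned=int(rng.integers(100, 231)),
                n_insert=int(rng.integers(0, 40)),
                n_term=int(rng.integers(0, 150)),
                c_term=int(rng.integers(0, 250)),
                rid=f"r{i}",
            )
            for i in range(40)
        ]
        kept_strict, _ = ancient_filter(recs)
        kept_loose, _ = ancient_filter(
            recs, min_aligned=120, max_insert=30, max_n_term=120, max_c_term=220
        )
        assert {r.id for r in kept_strict} <= {r.id for r in kept_loose}


# ---------------------------------------------------------------------------
# Similarity network


class TestSimilarityNetwork:
    def test_identical_long_pair_connected(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=231))
        aln = make_alignment([seq, seq])
        edges, singletons = similarity_network(aln, 0.05)
        assert len(edges) == 1 and not singletons

    def test_shuffled_unrelated_pairs_unconnected(self, rng):
        n_edges = 0
        for _ in range(100):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=231))
            b = "".join(rng.permutation(list(a)))
            edges, _ = similarity_network(make_alignment([a, b]), 0.05)
            n_edges += len(edges)
        assert n_edges <= 2  # no edge expected for shuffled sequences

    def test_zero_cutoff_gives_empty_network(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        edges, singletons = similarity_network(make_alignment([seq, seq]), 0.0)
        assert edges == [] and len(singletons) == 2
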