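import numpy as np
import pytest

from starwfa import (
    Chain,
    MSA,
    PairMatch,
    PairwiseAlignment,
    Sequence,
    SequenceSet,
    align_all,
    align_pair,
    gap_profile,
    merge_alignments,
    select_center,
)
from starwfa.sequence_io import GAP
from starwfa.star_msa import AlignParams


def project(msa: MSA, i: int, j: int) -> PairwiseAlignment:
    """Restrict an MSA to two rows and drop columns gapped in both."""
    a, b = msa.rows[i], msa.rows[j]
    keep = [(ca, cb) for ca, cb in zip(a, b) if not (ca == GAP and cb == GAP)]
    return PairwiseAlignment("".join(c for c, _ in keep), "".join(c for _, c in keep))


class TestAlignPair:
    def test_identity_with_full_anchor(self):
        c = Sequence("c", "ACGTACGT")
        pa = align_pair(c, Sequence("q", "ACGTACGT"), Chain([PairMatch(0, 0, 8)]))
        assert pa.center_row == pa.query_row == "ACGTACGT"

    def test_empty_chain_single_wfa_call(self):
        pa = align_pair(Sequence("c", "ACGT"), Sequence("q", "AACGT"), Chain([]))
        assert len(pa.center_row) == 5
        assert pa.center_row.replace(GAP, "") == "ACGT"
        assert pa.query_row == "AACGT"
        assert pa.center_row.count(GAP) == 1

    def test_inter_anchor_insertion(self):
        c = Sequence("c", "AAAATTTT")
        q = Sequence("q", "AAAAGGTTTT")
        pa = align_pair(c, q, Chain([PairMatch(0, 0, 4), PairMatch(4, 6, 4)]))
        assert pa.center_row == "AAAA--TTTT"
        assert pa.query_row == "AAAAGGTTTT"

    def test_inconsistent_chain_errors(self):
        c = Sequence("c", "ACGTACGT")
        with pytest.raises(ValueError):
            align_pair(c, Sequence("q", "TTTTTTTT"), Chain([PairMatch(0, 0, 4)]))

    def test_no_column_gapped_in_both(self, small_sim, small_set):
        center = small_set.center
        for q in small_set.sequences:
            pa = align_pair(center, q, Chain([]))
            assert not any(
                a == GAP and b == GAP for a, b in zip(pa.center_row, pa.query_row)
            )


class TestGapProfile:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ("-ACGT", [1, 0, 0, 0, 0]),
            ("ACGT-", [0, 0, 0, 0, 1]),
            ("AC--GT", [0, 0, 2, 0, 0]),
            ("ACGT", [0, 0, 0, 0, 0]),
        ],
    )
    def test_slot_counting(self, row, expected):
        pa = PairwiseAlignment(row, "A" * len(row))
        assert list(gap_profile(pa, 4)) == expected

    def test_center_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            gap_profile(PairwiseAlignment("ACG", "ACG"), 4)


class TestMergeAlignments:
    def test_slotwise_max_padding(self):
        c = Sequence("c", "ACGT")
        pa1 = PairwiseAlignment("-ACGT", "AACGT")
        pa2 = PairwiseAlignment("ACGT-", "ACGTA")
        msa = merge_alignments(c, [pa1, pa2], ["q1", "q2"])
        assert msa.width == 6
        assert msa.rows[0] == "-ACGT-"
        assert project(msa, 0, 1) == pa1
        assert project(msa, 0, 2) == pa2

    def test_single_query_reproduces_pairwise(self):
        c = Sequence("c", "ACGT")
        pa = PairwiseAlignment("AC-GT", "ACAGT")
        msa = merge_alignments(c, [pa], ["q"])
        assert msa.rows == ["AC-GT", "ACAGT"]

    def test_identical_queries_gap_free(self):
        c = Sequence("c", "ACGT")
        pas = [PairwiseAlignment("ACGT", "ACGT")] * 3
        msa = merge_alignments(c, pas, ["a", "b", "d"])
        assert msa.width == 4 and all(GAP not in r for r in msa.rows)

    def test_wrong_center_errors(self):
        with pytest.raises(ValueError):
            merge_alignments(
                Sequence("c", "AAAA"), [PairwiseAlignment("ACGT", "ACGT")], ["q"]
            )


class TestAlignAll:
    def test_identical_sequences_gap_free(self):
        seqs = [Sequence(f"s{i}", "ACGTACGTAC") for i in range(10)]
        msa = align_all(SequenceSet(seqs, 0))
        assert msa.width == 10
        assert all(r == "ACGTACGTAC" for r in msa.rows)

    def test_single_sequence(self):
        msa = align_all(SequenceSet([Sequence("only", "ACGT")], 0))
        assert msa.ids == ["only"] and msa.rows == ["ACGT"]

    def test_round_trip_and_rectangular(self, small_sim, small_set):
        msa = align_all(small_set)
        assert len({len(r) for r in msa.rows}) == 1
        for row, seq in zip(msa.rows, small_set.sequences):
            assert row.replace(GAP, "") == seq.residues

    def test_center_row_at_input_position(self, small_set):
        msa = align_all(small_set)
        assert msa.ids == [s.id for s in small_set.sequences]
        ci = small_set.center_index
        assert msa.rows[ci].replace(GAP, "") == small_set.center.residues

    def test_projection_property(self, small_set):
        """Restricting the MSA to (center, query) recovers stage 2 exactly."""
        from starwfa.anchor_finder import build_reverse_index, find_candidates
        from starwfa.chainer import select_chain

        msa = align_all(small_set)
        ci = small_set.center_index
        center = small_set.center
        rindex = build_reverse_index(center.residues)
        row_of = {rid: k for k, rid in enumerate(msa.ids)}
        for q in small_set.sequences:
            if q.id == center.id:
                continue
            chain = select_chain(find_candidates(rindex, q.residues))
            expected = align_pair(center, q, chain)
            got = project(msa, ci, row_of[q.id])
            assert got == expected

    def test_width_is_center_plus_profile_sum(self, small_set):
        msa = align_all(small_set)
        ci = small_set.center_index
        assert msa.width == len(small_set.center) + msa.rows[ci].count(GAP)

    @pytest.mark.parametrize("workers", [2, 4])
    def test_worker_count_independence(self, small_set, workers):
        base = align_all(small_set, AlignParams(workers=1))
        par = align_all(small_set, AlignParams(workers=workers))
        assert par.rows == base.rows and par.ids == base.ids
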