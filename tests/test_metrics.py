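import numpy as np
import pytest

from starwfa import MSA, q_score, scaled_sp_score, sp_score, tc_score


def random_msa(rng, n=4, length=12) -> MSA:
    rows = []
    for _ in range(n):
        chars = [
            "-" if rng.random() < 0.2 else "ACGT"[int(rng.integers(4))]
            for _ in range(length)
        ]
        if all(c == "-" for c in chars):
            chars[0] = "A"
        rows.append("".join(chars))
    return MSA([f"s{i}" for i in range(n)], rows)


class TestSP:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            (["ACGT", "ACGT"], 4),
            (["ACGT", "TGCA"], -4),
            (["AC-T", "ACGT", "AC-T"], 5),
            (["--", "AA"], -4),
            (["-A", "-A"], 1),  # shared gap column scores 0
        ],
    )
    def test_column_pair_scoring(self, rows, expected):
        msa = MSA([f"s{i}" for i in range(len(rows))], rows)
        assert sp_score(msa) == expected

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            sp_score(MSA(["a"], ["ACGT"]))

    def test_invariant_under_row_permutation(self, rng):
        for _ in range(20):
            msa = random_msa(rng)
            perm = rng.permutation(len(msa.rows))
            shuffled = MSA([msa.ids[i] for i in perm], [msa.rows[i] for i in perm])
            assert sp_score(shuffled) == sp_score(msa)

    def test_invariant_under_column_permutation(self, rng):
        msa = random_msa(rng, n=3, length=10)
        perm = rng.permutation(msa.width)
        permuted = MSA(msa.ids, ["".join(r[i] for i in perm) for r in msa.rows])
        assert sp_score(permuted) == sp_score(msa)


class TestScaledSP:
    def test_perfect_alignment_saturates_at_one(self):
        assert scaled_sp_score(MSA(["a", "b"], ["ACGT", "ACGT"])) == 1.0

    def test_worked_example(self):
        msa = MSA(["a", "b", "c"], ["AC-T", "ACGT", "AC-T"])
        assert scaled_sp_score(msa) == pytest.approx(10 / 24)

    def test_single_mismatch_column(self):
        assert scaled_sp_score(MSA(["a", "b"], ["A", "T"])) == -1.0


class TestQ:
    def test_self_comparison(self, rng):
        msa = random_msa(rng)
        assert q_score(msa, msa) == 1.0

    def test_half_reproduced_pairs(self):
        # ref aligns AB|AB as two columns of pairs; test shifts the second row
        ref = MSA(["a", "b"], ["AC", "AC"])
        test = MSA(["a", "b"], ["AC-", "-AC"])
        # ref has 2 pairs, test aligns C with A: reproduces 1 of 2? enumerate:
        # ref pairs: (a0,b0), (a1,b1); test pairs: (a1,b0) -> none shared
        assert q_score(test, ref) == 0.0
        assert q_score(ref, ref) == 1.0

    def test_fraction_of_pairs(self):
        ref = MSA(["a", "b"], ["ACGT", "ACGT"])  # 4 pairs
        test = MSA(["a", "b"], ["ACGT--", "AC--GT"])  # shares (0,0) and (1,1)
        assert q_score(test, ref) == 0.5

    def test_disjoint_blocks_zero(self):
        ref = MSA(["a", "b"], ["AC", "AC"])
        test = MSA(["a", "b"], ["AC--", "--AC"])
        assert q_score(test, ref) == 0.0

    def test_no_ref_pairs_defined_as_one(self):
        ref = MSA(["a", "b"], ["AC--", "--AC"])
        test = MSA(["a", "b"], ["AC", "AC"])
        assert q_score(test, ref) == 1.0

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError):
            q_score(MSA(["a"], ["AC"]), MSA(["b"], ["AC"]))

    def test_mismatched_sequences_error(self):
        with pytest.raises(ValueError):
            q_score(MSA(["a", "b"], ["AC", "AC"]), MSA(["a", "b"], ["AC", "AG"]))


class TestTC:
    def test_self_comparison(self, rng):
        msa = random_msa(rng)
        assert tc_score(msa, msa) == 1.0

    def test_three_of_four_columns(self):
        ref = MSA(["a", "b"], ["ACG-T", "ACGTT"])
        test = MSA(["a", "b"], ["ACGT-", "ACGTT"])
        # columns 0,1,2 identical; the two gap placements differ
        assert tc_score(test, ref) == 3 / 5

    def test_incompatible_alignments_zero(self):
        ref = MSA(["a", "b"], ["AC", "CA"])
        test = MSA(["a", "b"], ["AC--", "--CA"])
        assert tc_score(test, ref) == 0.0


def gap_free_ref_and_perturbed_test(rng, n, length, extra_gaps):
    """A gap-free reference plus a test MSA made by inserting gap columns.

    With a gap-free reference every column carries the same number of residue
    pairs, which is exactly the regime where TC <= Q is provable.
    """
    rows = [
        "".join("ACGT"[int(rng.integers(4))] for _ in range(length))
        for _ in range(n)
    ]
    ref = MSA([f"s{i}" for i in range(n)], rows)
    width = length + extra_gaps
    test_rows = []
    for r in rows:
        gap_pos = set(rng.choice(width, size=extra_gaps, replace=False).tolist())
        it = iter(r)
        test_rows.append(
            "".join("-" if i in gap_pos else next(it) for i in range(width))
        )
    return ref, MSA(ref.ids, test_rows)


class TestCrossMetricConsistency:
    def test_tc_never_exceeds_q_for_gap_free_reference(self, rng):
        """Every reproduced reference column reproduces all n(n-1)/2 of its
        pairs, so against a gap-free reference TC <= Q."""
        for _ in range(100):
            ref, test = gap_free_ref_and_perturbed_test(
                rng, n=int(rng.integers(2, 5)), length=14,
                extra_gaps=int(rng.integers(1, 5)),
            )
            assert tc_score(test, ref) <= q_score(test, ref) + 1e-12
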