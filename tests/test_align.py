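"""Alignment stage: pairwise optimum, MSA invariants, masking, AAI, logos."""

import numpy as np
import pytest

from cycscreen import synthetic
from cycscreen.align import (
    MSA,
    AlignParams,
    MaskConfig,
    aai_matrix,
    build_msa,
    consensus_logo,
    global_align,
    mask_msa,
    percent_identity,
    read_msa_fasta,
    write_msa_fasta,
)
from cycscreen.screen import ProteinRecord
from helpers import brute_force_mask, enumerate_alignment_score, random_msa


class TestGlobalAlign:
    def test_identical_sequences_score_is_diagonal_sum(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.score == 24.0  # BLOSUM62: A4 + C9 + D6 + E5
        assert aln.identity == 1.0
        assert aln.aligned_a == aln.aligned_b == "ACDE"

    def test_single_residue(self):
        aln = global_align("A", "A")
        assert aln.identity == 1.0 and "-" not in aln.aligned_a

    def test_matches_exhaustive_enumeration_on_random_pairs(self, rng):
        alphabet = np.array(list("ACDE"))
        for _ in range(30):
            a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
            b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
            assert global_align(a, b).score == pytest.approx(
                enumerate_alignment_score(a, b)
            ), (a, b)

    def test_score_and_identity_symmetric(self, rng):
        alphabet = np.array(list("ACDEFGHIK"))
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=12))
            b = "".join(rng.choice(alphabet, size=10))
            f, r = global_align(a, b), global_align(b, a)
            assert f.score == r.score
            assert f.identity == r.identity

    def test_selenocysteine_scored_via_wildcard(self):
        aln = global_align("ACUE", "ACUE")  # U maps to the matrix wildcard
        assert aln.aligned_a == "ACUE"  # original letters preserved

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACDE", "ACDE", 1.0), ("ACDE", "ACDF", 0.75), ("ACDE", "WYHR", 0.0)],
    )
    def test_gapless_examples(self, a, b, expected):
        from cycscreen.align import PairwiseAlignment

        aln = PairwiseAlignment(aligned_a=a, aligned_b=b, score=0.0, identity=0.0)
        assert percent_identity(aln) == expected

    def test_gap_columns_count_in_denominator(self):
        from cycscreen.align import PairwiseAlignment

        aln = PairwiseAlignment(aligned_a="ACDE", aligned_b="AC-E", score=0.0, identity=0.0)
        assert percent_identity(aln) == 0.75


class TestBuildMsa:
    def test_identical_pair_is_gap_free(self):
        recs = [ProteinRecord("a", "ACDEFGHIKL"), ProteinRecord("b", "ACDEFGHIKL")]
        msa = build_msa(recs)
        assert msa.rows == ["ACDEFGHIKL", "ACDEFGHIKL"]

    def test_two_sequences_reduce_to_optimal_pairwise(self):
        msa = build_msa([ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACE")])
        assert msa.ncol == 4
        assert msa.rows[0] == "ACDE"
        assert msa.rows[1].count("-") == 1

    def test_single_record_trivial_msa(self):
        msa = build_msa([ProteinRecord("a", "ACDE")])
        assert msa.rows == ["ACDE"]

    def test_degapped_rows_equal_inputs_and_order_preserved(self, small_family):
        records, _ = small_family
        msa = build_msa(records)
        assert msa.ids == [r.id for r in records]
        for i, rec in enumerate(records):
            assert msa.degapped(i) == rec.seq

    def test_msa_fasta_roundtrip(self, tmp_path, small_family):
        records, _ = small_family
        msa = build_msa(records[:4])
        p = tmp_path / "m.afa"
        write_msa_fasta(msa, p)
        back = read_msa_fasta(p)
        assert back.ids == msa.ids and back.rows == msa.rows


class TestMaskMsa:
    def test_one_gap_in_three_rows_is_removed(self):
        msa = MSA(ids=list("abc"), rows=["AC", "A-", "AD"])  # col 1: 33.3% gaps
        masked = mask_msa(msa)
        assert masked.rows == ["A", "A", "A"]

    def test_gap_free_msa_unchanged(self):
        msa = MSA(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert mask_msa(msa).rows == msa.rows

    def test_exactly_thirty_percent_gaps_retained(self):
        # 10 rows, 3 gaps = 30% exactly: the rule is strictly-greater-than
        rows = ["A"] * 7 + ["-"] * 3
        msa = MSA(ids=[f"r{i}" for i in range(10)], rows=rows)
        assert mask_msa(msa, MaskConfig(0.30)).ncol == 1

    def test_idempotent_and_never_grows(self, rng):
        for _ in range(10):
            rows = random_msa(rng, nrow=rng.integers(2, 8), ncol=rng.integers(1, 30))
            msa = MSA(ids=[f"r{i}" for i in range(len(rows))], rows=rows)
            once = mask_msa(msa)
            assert once.ncol <= msa.ncol
            assert mask_msa(once).rows == once.rows

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            rows = random_msa(rng, nrow=rng.integers(2, 10), ncol=rng.integers(1, 40))
            msa = MSA(ids=[f"r{i}" for i in range(len(rows))], rows=rows)
            assert mask_msa(msa).rows == brute_force_mask(rows, 0.30)

    def test_all_columns_removed_yields_empty_msa(self):
        msa = MSA(ids=["a", "b", "c"], rows=["A-", "-A", "--"])
        assert mask_msa(msa, MaskConfig(0.0)).ncol == 0


class TestAaiMatrix:
    def test_duplicate_pair_and_symmetry(self):
        recs = [
            ProteinRecord("a", "ACDEFGHIKL"),
            ProteinRecord("b", "ACDEFGHIKL"),
            ProteinRecord("c", "WYHRNMSTVP"),
        ]
        M = aai_matrix(recs)
        assert M.loc["a", "b"] == 1.0
        assert np.allclose(M.values, M.values.T)
        assert np.allclose(np.diag(M.values), 1.0)

    def test_within_family_identity_exceeds_family_vs_decoy(self):
        fam, _ = synthetic.gen_cluster_family(
            synthetic.FamilyConfig(cluster_label="1", n_members=4, seed=17)
        )
        other, _ = synthetic.gen_cluster_family(
            synthetic.FamilyConfig(cluster_label="2", n_members=4, seed=17)
        )
        M = aai_matrix(fam + other).values
        within = np.concatenate([M[:4, :4][np.triu_indices(4, 1)], M[4:, 4:][np.triu_indices(4, 1)]])
        between = M[:4, 4:].ravel()
        assert within.mean() > between.mean()

    def test_msa_mode_agrees_for_gapless_case(self):
        recs = [ProteinRecord("a", "ACDEFGHIKL"), ProteinRecord("b", "ACDEFGHIKW")]
        msa = build_msa(recs)
        fresh = aai_matrix(recs)
        from_msa = aai_matrix(recs, mode="msa", msa=msa)
        assert fresh.loc["a", "b"] == from_msa.loc["a", "b"] == 0.9


class TestConsensusLogo:
    def test_invariant_column_carries_full_information(self):
        msa = MSA(ids=list("abcd"), rows=["C", "C", "C", "C"])
        logo = consensus_logo(msa)
        assert logo.information[0] == pytest.approx(np.log2(20))
        assert logo.consensus == ["C"]

    def test_uniform_column_is_wildcard_with_zero_information(self):
        rows = list("ACDEFGHIKLMNPQRSTVWY")
        msa = MSA(ids=[f"r{i}" for i in range(20)], rows=rows)
        logo = consensus_logo(msa)
        assert logo.information[0] == pytest.approx(0.0)
        assert logo.consensus == ["X"]

    def test_two_way_split_renders_bracket_notation(self):
        rows = ["Q"] * 11 + ["K"] * 9  # 0.55 / 0.45, both above the tie margin
        msa = MSA(ids=[f"r{i}" for i in range(20)], rows=rows)
        assert consensus_logo(msa).consensus == ["[Q/K]"]

    def test_all_gap_column(self):
        msa = MSA(ids=["a", "b"], rows=["-A", "-A"])
        logo = consensus_logo(msa)
        assert logo.consensus[0] == "-" and logo.information[0] == 0.0
        assert logo.consensus[1] == "A"

    def test_information_invariant_under_row_permutation(self, rng):
        rows = random_msa(rng, 12, 20, gap_p=0.1)
        msa = MSA(ids=[f"r{i}" for i in range(12)], rows=rows)
        perm = list(rng.permutation(12))
        msa_p = MSA(ids=[msa.ids[i] for i in perm], rows=[rows[i] for i in perm])
        assert np.allclose(consensus_logo(msa).information, consensus_logo(msa_p).information)

    def test_frequencies_sum_to_one_over_nongap(self, rng):
        rows = random_msa(rng, 10, 15, gap_p=0.2)
        msa = MSA(ids=[f"r{i}" for i in range(10)], rows=rows)
        logo = consensus_logo(msa)
        sums = logo.frequencies.sum(axis=1).values
        assert np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0))
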