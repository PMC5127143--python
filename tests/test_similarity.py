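"""Pairwise alignment scoring, symmetrization and matrix I/O."""

import numpy as np
import pytest

from ssnphylo.similarity import (
    MatrixFormatError,
    RawScores,
    ScoringParams,
    SequenceError,
    SequenceRecord,
    SimilarityMatrix,
    compute_similarity,
    pairwise_scores,
    read_fasta,
    read_similarity_tsv,
    symmetrize,
    write_fasta,
    write_similarity_tsv,
)
from ssnphylo.synthetic import AMINO_ACIDS


def random_protein(rng, length=250) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


class TestSequenceRecord:
    def test_rejects_empty_sequence(self):
        with pytest.raises(SequenceError, match="empty"):
            SequenceRecord(id="x", label="x", residues="")

    def test_rejects_non_amino_characters(self):
        with pytest.raises(SequenceError, match="non-amino-acid"):
            SequenceRecord(id="x", label="x", residues="ACDEFO")

    def test_accepts_ambiguity_code_x(self):
        rec = SequenceRecord(id="x", label="x", residues="ACDXW")
        assert len(rec) == 5


class TestPairwiseScores:
    def test_identical_sequences_score_100_both_directions(self, rng):
        seq = random_protein(rng)
        raw = pairwise_scores(
            [SequenceRecord("a", "a", seq), SequenceRecord("b", "b", seq)]
        )
        assert raw.score[0, 1] == raw.score[1, 0] == 100.0
        assert np.all(np.diag(raw.score) == 100.0)
        assert np.all(np.diag(raw.evalue) == 0.0)

    @pytest.mark.parametrize("metric,floor", [("positives", 99.0),
                                              ("identity", 99.0),
                                              ("bitscore", 95.0)])
    def test_single_substitution_scores_near_100(self, rng, metric, floor):
        base = random_protein(rng)
        mutated = list(base)
        mutated[100] = "W" if mutated[100] != "W" else "Y"
        raw = pairwise_scores(
            [SequenceRecord("a", "a", base),
             SequenceRecord("b", "b", "".join(mutated))],
            ScoringParams(metric=metric),
        )
        assert raw.score[0, 1] >= floor
        assert raw.evalue[0, 1] < 1e-30

    def test_unrelated_random_pairs_sit_at_the_alignment_noise_floor(self):
        # Band frozen from the empirical distribution of Smith-Waterman
        # percent positives over 300 random length-250 pairs.
        rng = np.random.default_rng(777)
        pos_scores, evalues = [], []
        for _ in range(25):
            a, b = random_protein(rng), random_protein(rng)
            raw = pairwise_scores(
                [SequenceRecord("a", "a", a), SequenceRecord("b", "b", b)],
                ScoringParams(metric="positives"),
            )
            pos_scores.append(raw.score[0, 1])
            evalues.append(raw.evalue[0, 1])
        assert 38 < np.mean(pos_scores) < 62
        # random-pair E-values are orders of magnitude above homologous
        # ones (~1e-150), but the E <= 1 validity cutoff is permissive:
        # many random pairs still pass it
        assert min(evalues) > 1e-4
        assert 0.01 < np.median(evalues) < 10

    def test_normalised_bitscore_keeps_unrelated_pairs_low(self):
        # the short-best-HSP artifact that can push percent positives of
        # unrelated pairs to 100 must not affect the normalised bit score
        rng = np.random.default_rng(777)
        scores = []
        for _ in range(25):
            a, b = random_protein(rng), random_protein(rng)
            raw = pairwise_scores(
                [SequenceRecord("a", "a", a), SequenceRecord("b", "b", b)],
                ScoringParams(metric="bitscore"),
            )
            scores.append(raw.score[0, 1])
        assert max(scores) < 20

    def test_rejects_single_sequence_and_duplicate_ids(self, rng):
        seq = random_protein(rng, 60)
        with pytest.raises(SequenceError):
            pairwise_scores([SequenceRecord("a", "a", seq)])
        with pytest.raises(SequenceError, match="duplicate"):
            pairwise_scores(
                [SequenceRecord("a", "a", seq), SequenceRecord("a", "a", seq)]
            )

    def test_similarity_matrix_invariant_under_input_permutation(self, rng):
        seqs = [
            SequenceRecord(f"s{i}", f"s{i}", random_protein(rng, 80))
            for i in range(5)
        ]
        S1 = compute_similarity(seqs)
        perm = [3, 1, 4, 0, 2]
        S2 = compute_similarity([seqs[i] for i in perm])
        order = [S2.labels.index(lab) for lab in S1.labels]
        assert np.allclose(S1.values, S2.values[np.ix_(order, order)])
        assert np.array_equal(S1.valid, S2.valid[np.ix_(order, order)])


class TestSymmetrize:
    def test_mean_of_directed_scores(self):
        raw = RawScores(
            labels=["a", "b"],
            score=np.array([[100.0, 80.0], [90.0, 100.0]]),
            evalue=np.array([[0.0, 0.1], [0.2, 0.0]]),
        )
        S = symmetrize(raw)
        assert S.values[0, 1] == S.values[1, 0] == 85.0

    def test_symmetric_input_unchanged_and_idempotent(self, rng):
        vals = rng.uniform(0, 100, (4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        raw = RawScores(labels=list("abcd"), score=vals,
                        evalue=np.zeros((4, 4)))
        S = symmetrize(raw)
        assert np.allclose(S.values, vals)
        again = symmetrize(
            RawScores(labels=S.labels, score=S.values,
                      evalue=np.zeros((4, 4)))
        )
        assert np.allclose(again.values, S.values)

    def test_evalue_filter_uses_the_better_direction(self):
        score = np.array([[100.0, 50.0, 50.0],
                          [50.0, 100.0, 50.0],
                          [50.0, 50.0, 100.0]])
        evalue = np.array([[0.0, 2.0, 2.0],
                           [3.0, 0.0, 0.5],
                           [2.0, 1.5, 0.0]])
        S = symmetrize(RawScores(labels=list("abc"), score=score,
                                 evalue=evalue))
        # a-b: both E-values above 1 -> invalid, stored as 0
        assert not S.valid[0, 1] and S.values[0, 1] == 0.0
        # b-c: one direction passes -> valid
        assert S.valid[1, 2] and S.values[1, 2] == 50.0
        assert np.all(S.effective() == np.where(S.valid, S.values, 0.0))

    def test_non_square_input_rejected(self):
        raw = RawScores(labels=["a", "b"], score=np.zeros((2, 3)),
                        evalue=np.zeros((2, 3)))
        with pytest.raises(MatrixFormatError, match="square"):
            symmetrize(raw)


class TestMatrixIO:
    def test_round_trip_preserves_values_and_mask(self, rng, tmp_path):
        from conftest import random_similarity

        S = random_similarity(rng, 7, invalid_frac=0.2)
        path = tmp_path / "sim.tsv"
        write_similarity_tsv(S, path)
        back = read_similarity_tsv(path)
        assert back.labels == S.labels
        assert np.allclose(back.values, S.values)
        assert np.array_equal(back.valid, S.valid)

    def test_literal_cell_formatting(self, tmp_path):
        S = SimilarityMatrix(
            labels=["a", "b"],
            values=np.array([[100.0, 42.5], [42.5, 100.0]]),
            valid=np.ones((2, 2), bool),
        )
        path = tmp_path / "sim.tsv"
        write_similarity_tsv(S, path)
        assert "42.5" in path.read_text()
        assert np.allclose(read_similarity_tsv(path).values, S.values)

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\ta\tb\na\t100\t40\nb\t41\t100\n")
        with pytest.raises(MatrixFormatError, match="asymmetric"):
            read_similarity_tsv(path)

    def test_missing_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\ta\t\na\t100\t40\nb\t40\t100\n")
        with pytest.raises(MatrixFormatError, match="label"):
            read_similarity_tsv(path)

    def test_submatrix_restricts_and_preserves_order(self, rng):
        from conftest import random_similarity

        S = random_similarity(rng, 6)
        sub = S.submatrix(["t4", "t1"])
        assert sub.labels == ["t1", "t4"]
        assert sub.values[0, 1] == S.values[1, 4]


class TestFasta:
    def test_round_trip(self, rng, tmp_path):
        recs = [
            SequenceRecord("id1", "Homo sapiens", random_protein(rng, 70)),
            SequenceRecord("id2", "id2", random_protein(rng, 70)),
        ]
        path = tmp_path / "seqs.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert back == recs

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACDE\n>a\nACDE\n")
        with pytest.raises(SequenceError, match="duplicate"):
            read_fasta(path)


class TestBlastpEngine:
    """Cross-check the internal aligner against the blastp binary."""

    def test_blastp_agrees_with_internal_on_a_small_family(self, rng):
        from ssnphylo.synthetic import FamilyDesign, simulate_protein_family

        seqs = simulate_protein_family(
            FamilyDesign(n_groups=2, seqs_per_group=2, seq_length=120,
                         d_between=0.8, d_within=0.05, seed=5)
        )
        internal = compute_similarity(
            seqs, ScoringParams(metric="identity", engine="internal")
        )
        external = compute_similarity(
            seqs, ScoringParams(metric="identity", engine="blastp")
        )
        assert external.labels == internal.labels
        assert np.all(np.diag(external.values) == 100.0)
        # within-group identities are full-length alignments on which the
        # two engines must closely agree
        for i, j in [(0, 1), (2, 3)]:
            assert internal.values[i, j] > 80
            assert abs(external.values[i, j] - internal.values[i, j]) < 5
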