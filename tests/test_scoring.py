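import math

import numpy as np
import pandas as pd
import pytest

from seqlda import (
    MembershipMatrix,
    SequenceRecord,
    TopicModel,
    centered_subsequence,
    classify_reading_frames,
    count_frame_kmers,
    enumerate_vocabulary,
    position_log_likelihood,
    predict_label,
    sequence_log_likelihood,
    topic_label_scores,
)
from seqlda.scoring import FramePrediction

from conftest import run_frame_pipeline


def bulk_model(k, phi_rows):
    vocab = enumerate_vocabulary(k)
    return TopicModel(
        phi=np.asarray(phi_rows),
        alpha=0.5,
        eta=0.5,
        feature_ids=list(vocab.kmers),
    )


def brute_force_ll(seq, phi_row, vocab, k):
    total = 0.0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            total += math.log(phi_row[vocab.index[w]])
    return total


class TestSequenceLogLikelihood:
    def test_uniform_topic_closed_form(self):
        model = bulk_model(4, [np.full(256, 1 / 256)])
        seq = "ACGTACGTAC"
        assert sequence_log_likelihood(seq, model, 0, 4) == pytest.approx(
            7 * math.log(1 / 256), abs=1e-9
        )

    def test_two_window_closed_form(self):
        phi = np.full(256, 0.1 / 255)
        phi[0] = 0.9  # AAAA
        model = bulk_model(4, [phi])
        assert sequence_log_likelihood("AAAAA", model, 0, 4) == pytest.approx(
            2 * math.log(0.9), abs=1e-12
        )

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(17)
        vocab = enumerate_vocabulary(3)
        phi = rng.dirichlet(np.full(64, 0.5), size=3)
        model = bulk_model(3, phi)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=30, p=[0.24] * 4 + [0.04]))
            t = int(rng.integers(3))
            assert sequence_log_likelihood(seq, model, t, 3) == pytest.approx(
                brute_force_ll(seq, phi[t], vocab, 3), abs=1e-9
            )

    def test_too_short_sequence_is_an_error(self):
        model = bulk_model(4, [np.full(256, 1 / 256)])
        with pytest.raises(ValueError, match="shorter"):
            sequence_log_likelihood("ACG", model, 0, 4)

    def test_non_bulk_vocabulary_rejected(self):
        model = TopicModel(
            phi=np.array([[0.5, 0.5]]), alpha=1, eta=1, feature_ids=["x", "y"]
        )
        with pytest.raises(ValueError, match="vocabulary"):
            sequence_log_likelihood("ACGT", model, 0, 2)


class TestPositionLogLikelihood:
    def _model(self):
        return TopicModel(
            phi=np.array([[0.5, 0.25, 0.25]]), alpha=1, eta=1,
            feature_ids=["a", "b", "c"],
        )

    def test_zero_counts_give_zero(self):
        assert position_log_likelihood(np.zeros(3), self._model(), 0) == 0.0

    def test_single_feature_closed_form(self):
        counts = np.array([3, 0, 0])
        assert position_log_likelihood(counts, self._model(), 0) == pytest.approx(
            3 * math.log(0.5), abs=1e-12
        )

    def test_schema_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="does not match"):
            position_log_likelihood(np.zeros(5), self._model(), 0)


class TestTopicLabelScores:
    def test_identical_memberships_score_zero(self):
        theta = np.tile([0.3, 0.7], (6, 1))
        mem = MembershipMatrix([f"s{i}" for i in range(6)], theta)
        scores = topic_label_scores(mem, ["a", "a", "a", "b", "b", "b"])
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_log2_enrichment_value(self):
        # label mean 0.8 vs overall mean 0.5 -> log2(1.6)
        theta = np.array([[0.8, 0.2], [0.8, 0.2], [0.2, 0.8], [0.2, 0.8]])
        mem = MembershipMatrix(["s1", "s2", "s3", "s4"], theta)
        scores = topic_label_scores(mem, ["a", "a", "b", "b"])
        assert scores.loc[0, "a"] == pytest.approx(math.log2(1.6), abs=1e-12)

    def test_single_label_scores_zero(self):
        theta = np.array([[0.6, 0.4], [0.1, 0.9]])
        mem = MembershipMatrix(["s1", "s2"], theta)
        scores = topic_label_scores(mem, ["only", "only"])
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet([1, 1, 1], size=10)
        labels = ["a"] * 4 + ["b"] * 6
        mem = MembershipMatrix([f"s{i}" for i in range(10)], theta)
        perm = rng.permutation(10)
        mem_p = MembershipMatrix([f"s{i}" for i in perm], theta[perm])
        s1 = topic_label_scores(mem, labels)
        s2 = topic_label_scores(mem_p, [labels[i] for i in perm])
        assert np.allclose(s1.to_numpy(), s2.to_numpy())


class TestPredictLabel:
    def test_single_positive_column_wins(self):
        scores = pd.DataFrame({"a": [-1.0, -1.0], "b": [2.0, 2.0]})
        assert predict_label(np.array([0.5, 0.5]), scores) == "b"

    def test_exact_tie_resolves_alphabetically(self):
        scores = pd.DataFrame({"zeta": [1.0], "alpha": [1.0]})
        assert predict_label(np.array([1.0]), scores) == "alpha"

    def test_matches_brute_force_matrix_product(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            K, L = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            theta = rng.dirichlet(np.ones(K))
            labels = [f"lab{j}" for j in range(L)]
            scores = pd.DataFrame(rng.normal(size=(K, L)), columns=labels)
            expect = max(
                sorted(labels), key=lambda l: sum(theta[t] * scores[l][t] for t in range(K))
            )
            # max() keeps the first of equals in sorted order, matching the tie rule
            assert predict_label(theta, scores) == expect


class TestFramePrediction:
    def test_triples_logic(self):
        fp = FramePrediction("x", (1, 2, 3), all_correct=True, frameshift=False)
        assert fp.all_correct and not fp.frameshift
        fp = FramePrediction("x", (2, 3, 1), all_correct=False, frameshift=True)
        assert fp.frameshift
        fp = FramePrediction("x", (1, 3, 2), all_correct=False, frameshift=False)
        assert not fp.frameshift

    def test_frameshift_and_all_correct_incompatible(self):
        with pytest.raises(ValueError):
            FramePrediction("x", (1, 2, 3), all_correct=True, frameshift=True)


class TestFrameClassification:
    def test_end_to_end_small_pipeline(self, frame_pipeline_small):
        acc, model, scores, test = frame_pipeline_small
        assert acc >= 0.9

    def test_cyclic_shift_is_flagged(self, frame_pipeline_small):
        _, model, scores, test = frame_pipeline_small
        shifted = test[0].seq[1:]
        shifted = shifted[: len(shifted) - len(shifted) % 3]
        fp = classify_reading_frames(shifted, model, scores, 6, "shifted")
        assert fp.predicted in ((2, 3, 1), (3, 1, 2))
        assert fp.frameshift and not fp.all_correct

    def test_requires_frame_labels(self, frame_pipeline_small):
        _, model, _, test = frame_pipeline_small
        bad = pd.DataFrame({"a": [0.0] * 3, "b": [0.0] * 3})
        with pytest.raises(ValueError, match="frame"):
            classify_reading_frames(test[0].seq, model, bad, 6)


class TestCenteredSubsequence:
    def test_worked_offsets(self):
        seq = "".join("ACG"[i % 3] for i in range(300))
        sub = centered_subsequence(seq, 30)
        assert sub == seq[105:195]

    def test_whole_sequence_identity(self):
        seq = "ATGGCAATT"
        assert centered_subsequence(seq, 3) == seq

    def test_frame_preserved_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGT"), size=3 * n))
            m = int(rng.integers(1, n + 1))
            sub = centered_subsequence(seq, m)
            start = seq.index(sub)
            assert start % 3 == 0 and len(sub) == 3 * m
            fc_par = count_frame_kmers(seq, 3)
            # the subsequence's codons are codons of the parent
            for i in range(0, len(sub), 3):
                assert sub[i : i + 3] == seq[start + i : start + i + 3]

    def test_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            centered_subsequence("ACGTA", 1)
        with pytest.raises(ValueError, match="cannot take"):
            centered_subsequence("ACGACG", 3)
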