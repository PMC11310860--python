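import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import sparse

from seqlda import (
    CountMatrix,
    SequenceRecord,
    count_bulk_kmers,
    count_frame_kmers,
    count_positional_kmers,
    enumerate_vocabulary,
    pool_samples,
)
from seqlda.features import (
    build_position_sample_matrix,
    positional_feature_ids,
)

seqs_st = st.text(alphabet="ACGTN", min_size=1, max_size=60)


def as_dict(vec, k):
    vocab = enumerate_vocabulary(k)
    return {vocab.kmers[i]: int(c) for i, c in enumerate(vec) if c}


class TestBulkCounts:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AGTTAT", 4, {"AGTT": 1, "GTTA": 1, "TTAT": 1}),
            ("AAAA", 4, {"AAAA": 1}),
            ("ACGTACGT", 2, {"AC": 2, "CG": 2, "GT": 2, "TA": 1}),
        ],
    )
    def test_hand_enumerated_counts(self, seq, k, expected):
        assert as_dict(count_bulk_kmers(seq, k), k) == expected

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="shorter"):
            count_bulk_kmers("ACG", 4)

    @given(seqs_st, st.integers(min_value=1, max_value=4))
    def test_total_equals_number_of_valid_windows(self, seq, k):
        if len(seq) < k:
            return
        n_valid = sum(
            1
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        )
        assert count_bulk_kmers(seq, k).sum() == n_valid


class TestPositionalCounts:
    def test_worked_example_first_base_position_one(self):
        # AGTTAT with its first base at position 1 yields AGTT_1, GTTA_2, TTAT_3
        vec = count_positional_kmers("AGTTAT", 4, (1, 4), anchor=-1)
        ids = positional_feature_ids(4, (1, 4))
        hits = [ids[i] for i in np.flatnonzero(vec)]
        assert hits == ["AGTT_at_1", "GTTA_at_2", "TTAT_at_3"]
        assert vec.sum() == 3

    def test_all_n_sequence_gives_empty_vector(self):
        assert count_positional_kmers("N" * 10, 4, (0, 5), anchor=0).sum() == 0

    def test_total_is_number_of_valid_positions(self):
        vec = count_positional_kmers("ACGTACGTAC", 3, (-4, 0), anchor=5)
        assert vec.sum() == 4

    def test_region_outside_sequence_is_bounds_error(self):
        with pytest.raises(ValueError, match="outside"):
            count_positional_kmers("ACGTAC", 4, (0, 5), anchor=0)


class TestFrameCounts:
    def test_frame_assignment_from_annotated_start(self):
        fc = count_frame_kmers("ATGGCA", 3)
        assert as_dict(fc[0], 3) == {"ATG": 1, "GCA": 1}
        assert as_dict(fc[1], 3) == {"TGG": 1}
        assert as_dict(fc[2], 3) == {"GGC": 1}

    def test_per_frame_totals_for_12nt_hexamers(self):
        fc = count_frame_kmers("ACGTACGTACGT", 6)
        assert fc.sum(axis=1).tolist() == [3, 2, 2]
        assert fc.sum() == 12 - 6 + 1

    def test_homopolymer_symmetry(self):
        fc = count_frame_kmers("A" * 18, 4)
        vocab = enumerate_vocabulary(4)
        col = vocab.index["AAAA"]
        assert (fc.sum(axis=1) == fc[:, col]).all()

    @given(seqs_st, st.integers(min_value=1, max_value=4))
    def test_frame_totals_sum_to_bulk_total(self, seq, k):
        if len(seq) < k:
            return
        assert count_frame_kmers(seq, k).sum() == count_bulk_kmers(seq, k).sum()


def random_anchored(rng, n, length, anchor):
    return [
        SequenceRecord(
            id=f"s{i}",
            seq="".join(rng.choice(list("ACGT"), size=length)),
            anchor=anchor,
        )
        for i in range(n)
    ]


class TestPositionSampleMatrix:
    def test_window_one_is_per_position_counts(self):
        rng = np.random.default_rng(0)
        seqs = random_anchored(rng, 5, 30, anchor=20)
        m = build_position_sample_matrix(seqs, 3, 1, (-10, -4))
        for row, p in zip(m.to_dense(), range(-10, -4)):
            expect = np.zeros(64, dtype=int)
            for rec in seqs:
                expect += count_bulk_kmers(rec.seq[20 + p : 20 + p + 3], 3)
            assert (row == expect).all()

    def test_window_w_equals_sum_of_w_unit_windows(self):
        rng = np.random.default_rng(1)
        seqs = random_anchored(rng, 8, 40, anchor=30)
        w = 4
        mw = build_position_sample_matrix(seqs, 2, w, (-20, -10))
        m1 = build_position_sample_matrix(seqs, 2, 1, (-20, -10 + w - 1))
        d1 = m1.to_dense()
        for i in range(mw.shape[0]):
            assert (mw.to_dense()[i] == d1[i : i + w].sum(axis=0)).all()

    def test_row_totals_conserved(self):
        rng = np.random.default_rng(2)
        seqs = random_anchored(rng, 10, 50, anchor=40)
        m = build_position_sample_matrix(seqs, 6, 5, (-30, -15))
        assert (m.row_totals() == 5 * 10).all()

    def test_short_sequence_rejected_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        seqs = random_anchored(rng, 4, 50, anchor=40)
        seqs.append(SequenceRecord(id="short", seq="ACGTACGT", anchor=8))
        with caplog.at_level(logging.WARNING):
            m = build_position_sample_matrix(seqs, 3, 2, (-20, -10))
        assert "short" in caplog.text
        assert (m.row_totals() == 2 * 4).all()


class TestPooling:
    def _matrix(self, n_rows, n_feat=6, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 5, size=(n_rows, n_feat))
        return CountMatrix(
            [f"s{i}" for i in range(n_rows)],
            [f"f{j}" for j in range(n_feat)],
            counts,
        )

    def test_pack_one_is_identity_up_to_order(self):
        m = self._matrix(9)
        labels = ["a"] * 4 + ["b"] * 5
        pooled, plabels = pool_samples(m, labels, 1, seed=0)
        assert sorted(plabels) == sorted(labels)
        orig = {tuple(r) for r in m.to_dense()}
        assert {tuple(r) for r in pooled.to_dense()} <= orig
        assert (pooled.to_dense().sum(axis=0) == m.to_dense().sum(axis=0)).all()

    def test_pooling_15000_sequences_into_60_packs(self):
        counts = sparse.csr_matrix(np.ones((15000, 2), dtype=np.int64))
        m = CountMatrix([f"s{i}" for i in range(15000)], ["f0", "f1"], counts)
        pooled, _ = pool_samples(m, ["intron"] * 15000, 250, seed=0)
        assert len(pooled.sample_ids) == 60

    def test_column_sums_conserved_when_pack_divides(self):
        m = self._matrix(12)
        labels = ["a"] * 6 + ["b"] * 6
        pooled, _ = pool_samples(m, labels, 3, seed=5)
        assert (pooled.to_dense().sum(axis=0) == m.to_dense().sum(axis=0)).all()

    def test_incomplete_packs_dropped(self):
        m = self._matrix(10)
        pooled, _ = pool_samples(m, ["a"] * 10, 3, seed=1)
        assert len(pooled.sample_ids) == 3

    def test_deterministic_given_seed(self):
        m = self._matrix(20, seed=4)
        labels = ["a"] * 11 + ["b"] * 9
        p1, l1 = pool_samples(m, labels, 4, seed=9)
        p2, l2 = pool_samples(m, labels, 4, seed=9)
        assert (p1.to_dense() == p2.to_dense()).all()
        assert l1 == l2

    def test_pack_larger_than_label_errors_with_name(self):
        m = self._matrix(5)
        with pytest.raises(ValueError, match="'b'"):
            pool_samples(m, ["a", "a", "a", "b", "b"], 3, seed=0)
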