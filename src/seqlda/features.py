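"""Sequence featurization: the three count-matrix representations and pooling.

Three ways of turning nucleotide sequences into the documents of a topic
model are supported:

* **bulk** — occurrences of every k-mer, ignoring position (used for
  unaligned sequences such as coding regions);
* **frame** — bulk counts split by reading frame, where the k-mer starting
  at 0-based offset ``i`` belongs to frame ``(i mod 3) + 1`` of the
  annotated frame-1 sequence;
* **positional** — each feature couples a k-mer with its start position
  relative to an alignment anchor (rendered ``KMER_at_POS``, e.g.
  ``CCAG_at_-4``);
* **position_window** — positions in an alignment are themselves the
  samples, each one holding the k-mer counts inside a sliding window of
  start positions pooled over all sequences.

Any k-mer window containing a non-ACGT base is skipped entirely: it is
counted in neither numerator nor denominator anywhere.
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .config import CountMatrix, SequenceRecord, enumerate_vocabulary

logger = logging.getLogger(__name__)

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3; anything else -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding k-mer integer ids and a validity mask (no non-ACGT base).

    Invalid windows carry garbage ids; callers must apply the mask.
    """
    win = sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = win.astype(np.int64) @ pows
    return ids, valid


def count_bulk_kmers(seq: str, k: int) -> np.ndarray:
    """Count every k-mer occurrence in ``seq`` (column order: lexicographic).

    Entry ``w`` is the number of start offsets ``i`` with
    ``seq[i:i+k] == w`` and no non-ACGT base in the window; the vector sum
    equals the number of valid windows.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    ids, valid = _kmer_ids(encode_sequence(seq), k)
    return np.bincount(ids[valid], minlength=4**k).astype(np.int64)


def count_frame_kmers(seq: str, k: int) -> np.ndarray:
    """Count k-mers separately for the three reading frames.

    The sequence is taken to be in annotated frame 1: the k-mer starting at
    0-based offset ``i`` is assigned to frame ``(i mod 3) + 1``.  Returns a
    (3, 4^k) array whose rows are frames 1, 2, 3; the row totals sum to the
    bulk total.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    ids, valid = _kmer_ids(encode_sequence(seq), k)
    frames = np.arange(len(ids)) % 3
    out = np.zeros((3, 4**k), dtype=np.int64)
    for f in range(3):
        m = valid & (frames == f)
        out[f] = np.bincount(ids[m], minlength=4**k)
    return out


FRAME_LABELS = ("frame1", "frame2", "frame3")


def positional_feature_ids(k: int, region: tuple[int, int]) -> list:
    """Feature ids ``KMER_at_POS`` for every (position, k-mer) pair.

    Position-major then lexicographic k-mer order, positions ascending over
    the half-open ``region``.
    """
    vocab = enumerate_vocabulary(k)
    start, end = region
    return [f"{w}_at_{p}" for p in range(start, end) for w in vocab.kmers]


def count_positional_kmers(
    seq: str, k: int, region: tuple[int, int], anchor: int
) -> np.ndarray:
    """Count position-tagged k-mers in ``region`` (relative to ``anchor``).

    Position ``p`` corresponds to sequence index ``anchor + p``; the
    returned vector is aligned with :func:`positional_feature_ids`.  Each
    valid start position contributes exactly one count; windows touching a
    non-ACGT base contribute nothing.
    """
    seq = seq.upper()
    start, end = region
    if start >= end:
        raise ValueError(f"empty region {region}")
    lo, hi = anchor + start, anchor + end - 1 + k
    if lo < 0 or hi > len(seq):
        raise ValueError(
            f"region {region} with anchor {anchor} outside sequence of length {len(seq)}"
        )
    codes = encode_sequence(seq)
    ids, valid = _kmer_ids(codes, k) if len(seq) >= k else (np.empty(0, int), np.empty(0, bool))
    n_pos = end - start
    out = np.zeros(n_pos * 4**k, dtype=np.int64)
    offsets = anchor + np.arange(start, end)
    ok = valid[offsets]
    out[(np.arange(n_pos)[ok]) * 4**k + ids[offsets[ok]]] = 1
    return out


def build_positional_matrix(
    seqs: list, k: int, region: tuple[int, int]
) -> CountMatrix:
    """Stack per-sequence positional k-mer counts into a CountMatrix.

    Each :class:`SequenceRecord` must carry an anchor.  Sequences that do
    not cover the region are rejected with a logged warning.
    """
    feature_ids = positional_feature_ids(k, region)
    rows, ids = [], []
    for rec in seqs:
        if rec.anchor is None:
            raise ValueError(f"sequence {rec.id!r} has no anchor")
        try:
            vec = count_positional_kmers(rec.seq, k, region, rec.anchor)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
            continue
        rows.append(sparse.csr_matrix(vec))
        ids.append(rec.id)
    if not rows:
        raise ValueError("no sequence covers the requested region")
    return CountMatrix(ids, feature_ids, sparse.vstack(rows).tocsr(), mode="positional")


def build_bulk_matrix(seqs: list, k: int) -> CountMatrix:
    """One bulk k-mer count row per sequence."""
    vocab = enumerate_vocabulary(k)
    counts = sparse.csr_matrix(
        np.vstack([count_bulk_kmers(rec.seq, k) for rec in seqs])
    )
    return CountMatrix([rec.id for rec in seqs], list(vocab.kmers), counts, mode="bulk")


def build_frame_matrix(seqs: list, k: int) -> tuple[CountMatrix, list]:
    """Three frame-count rows per sequence, with frame labels.

    Returns the matrix (sample ids ``<seqid>|frameN``) and the aligned list
    of frame labels, ready for pooling and label scoring.
    """
    vocab = enumerate_vocabulary(k)
    rows, ids, labels = [], [], []
    for rec in seqs:
        fc = count_frame_kmers(rec.seq, k)
        for f in range(3):
            rows.append(fc[f])
            ids.append(f"{rec.id}|{FRAME_LABELS[f]}")
            labels.append(FRAME_LABELS[f])
    m = CountMatrix(ids, list(vocab.kmers), sparse.csr_matrix(np.vstack(rows)), mode="frame")
    return m, labels


def build_position_sample_matrix(
    seqs: list, k: int, window: int, positions: tuple[int, int]
) -> CountMatrix:
    """Positions in an alignment as samples; k-mers as features.

    Sample ``p`` (one per window start position in the half-open
    ``positions`` range, relative to each sequence's anchor) holds, for
    each k-mer ``w``, the number of occurrences of ``w`` starting at any
    position in ``[p, p + window)`` across all sequences.  When every
    window is valid each row sums to ``window * n_seqs``.

    Sequences too short to cover the region (plus the k-1 downstream bases
    of the last window) are rejected with a logged warning, never silently
    truncated.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    start, end = positions
    if start >= end:
        raise ValueError(f"empty position range {positions}")
    vocab = enumerate_vocabulary(k)
    V = 4**k
    # k-mer start positions needed: [start, end + window - 1)
    n_pos = end + window - 1 - start
    per_pos = np.zeros((n_pos, V), dtype=np.int64)
    n_used = 0
    for rec in seqs:
        if rec.anchor is None:
            raise ValueError(f"sequence {rec.id!r} has no anchor")
        lo = rec.anchor + start
        hi = rec.anchor + end - 1 + window - 1 + k
        if lo < 0 or hi > len(rec.seq):
            logger.warning(
                "skipping %s: does not cover positions %s..%s (+%d nt) given anchor %d",
                rec.id, start, end + window - 2, k - 1, rec.anchor,
            )
            continue
        ids, valid = _kmer_ids(encode_sequence(rec.seq), k)
        offs = rec.anchor + np.arange(start, end + window - 1)
        ok = valid[offs]
        np.add.at(per_pos, (np.arange(n_pos)[ok], ids[offs[ok]]), 1)
        n_used += 1
    if n_used == 0:
        raise ValueError("no sequence covers the requested positions")
    rows = np.vstack(
        [per_pos[i : i + window].sum(axis=0) for i in range(end - start)]
    )
    return CountMatrix(
        [str(p) for p in range(start, end)],
        list(vocab.kmers),
        rows,
        mode="position_window",
    )


def pool_samples(
    m: CountMatrix, labels: list, pack: int, seed: int
) -> tuple[CountMatrix, list]:
    """Group same-label samples into packs of ``pack`` and sum their counts.

    Within each label, samples are shuffled with ``seed`` and grouped into
    consecutive packs of exactly ``pack`` rows; incomplete final packs are
    dropped.  Returns the pooled matrix (sample ids ``<label>|packN``) and
    the per-pack labels.  Deterministic given the seed.
    """
    if pack < 1:
        raise ValueError(f"pack must be >= 1, got {pack}")
    if len(labels) != len(m.sample_ids):
        raise ValueError("labels must align with samples")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    X = m.to_csr()
    out_rows, out_ids, out_labels = [], [], []
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(np.asarray([l == lab for l in labels]))
        if len(idx) < pack:
            raise ValueError(
                f"label {lab!r} has {len(idx)} samples, fewer than pack={pack}"
            )
        idx = idx[rng.permutation(len(idx))]
        n_packs = len(idx) // pack
        for j in range(n_packs):
            sel = idx[j * pack : (j + 1) * pack]
            out_rows.append(sparse.csr_matrix(X[sel].sum(axis=0)))
            out_ids.append(f"{lab}|pack{j}")
            out_labels.append(lab)
    pooled = sparse.vstack(out_rows).tocsr()
    if not m.is_sparse():
        pooled = np.asarray(pooled.todense())
    return CountMatrix(out_ids, m.feature_ids, pooled, mode=m.mode), out_labels
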