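"""Likelihood scoring, subtype classification, and reading-frame analysis.

Two scores connect a fitted topic model back to sequences:

* the **likelihood** of generating a sequence from a single topic — the
  product over all k-mer windows of P(window | topic), reported in log
  space (nats);
* the **label score** of a topic — log2 of the ratio between a topic's
  average membership within one class of samples and its average
  membership over all samples.  Multiplying a sample's memberships by the
  topic-label score matrix and taking the argmax yields a simple subtype
  classifier.

Reading-frame classification applies this classifier to the three
frame-tagged k-mer count vectors of a coding sequence: a sequence is
correct when frames 1, 2, 3 are predicted as (1, 2, 3), and a cyclic
prediction (2, 3, 1) or (3, 1, 2) flags a potential frame shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CountMatrix, enumerate_vocabulary
from .features import FRAME_LABELS, count_bulk_kmers, count_frame_kmers
from .lda import MembershipMatrix, TopicModel, transform

_CYCLIC_SHIFTS = ((2, 3, 1), (3, 1, 2))


@dataclass
class FramePrediction:
    """Predicted reading frames for the three true frames of one sequence."""

    sequence_id: str
    predicted: tuple
    all_correct: bool
    frameshift: bool

    def __post_init__(self) -> None:
        if self.frameshift and self.all_correct:
            raise ValueError("a frame-shifted prediction cannot be all-correct")


def sequence_log_likelihood(
    seq: str, model: TopicModel, topic: int, k: int
) -> float:
    """Log-likelihood (nats) of generating ``seq`` from one topic.

    Sum over all valid k-mer windows of ``ln phi[topic][w]``; windows
    containing a non-ACGT base are skipped.  Requires a bulk-mode model
    whose features are the full k-mer vocabulary.
    """
    vocab = enumerate_vocabulary(k)
    if list(model.feature_ids) != list(vocab.kmers):
        raise ValueError(
            "model features are not the bulk k-mer vocabulary for this k"
        )
    if not 0 <= topic < model.n_topics:
        raise ValueError(f"topic {topic} out of range [0, {model.n_topics})")
    counts = count_bulk_kmers(seq, k)
    return float(counts @ np.log(model.phi[topic]))


def position_log_likelihood(
    counts: np.ndarray, model: TopicModel, topic: int
) -> float:
    """Multinomial log-likelihood of one count row under one topic.

    Returns sum_w counts[w] * ln phi[topic][w]; the count-only multinomial
    constant is topic-independent and omitted.
    """
    counts = np.asarray(counts).ravel()
    if counts.shape[0] != model.phi.shape[1]:
        raise ValueError(
            f"count vector length {counts.shape[0]} does not match "
            f"model vocabulary size {model.phi.shape[1]}"
        )
    if not 0 <= topic < model.n_topics:
        raise ValueError(f"topic {topic} out of range [0, {model.n_topics})")
    return float(counts @ np.log(model.phi[topic]))


def likelihood_curve(m: CountMatrix, model: TopicModel) -> pd.DataFrame:
    """Per-sample, per-topic multinomial log-likelihoods (samples x topics).

    With a position-as-samples matrix this is the per-position likelihood
    curve of every topic.
    """
    if list(m.feature_ids) != list(model.feature_ids):
        raise ValueError("feature spaces do not match")
    ll = m.to_csr().astype(float) @ np.log(model.phi).T
    return pd.DataFrame(
        np.asarray(ll), index=m.sample_ids,
        columns=[f"topic{t}" for t in range(model.n_topics)],
    )


def topic_label_scores(
    memberships: MembershipMatrix, labels: list
) -> pd.DataFrame:
    """Topic x label matrix of log2 enrichment scores.

    Score(topic | label) = log2(mean membership of the topic over the
    label's N samples / mean membership over all M samples).  Columns are
    sorted label names; rows are topics.
    """
    if len(labels) != len(memberships.sample_ids):
        raise ValueError("labels must align with samples")
    if len(labels) == 0:
        raise ValueError("no samples")
    labels = np.asarray(list(labels), dtype=object)
    overall = memberships.theta.mean(axis=0)
    cols = {}
    for lab in sorted(set(labels)):
        sel = memberships.theta[labels == lab]
        cols[lab] = np.log2(sel.mean(axis=0) / overall)
    scores = pd.DataFrame(cols)
    scores.index.name = "topic"
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite label scores (degenerate memberships)")
    return scores


def predict_label(membership: np.ndarray, scores: pd.DataFrame) -> str:
    """Argmax-label of membership . score-column; ties to the first label.

    Columns of ``scores`` are consulted in sorted order, so an exact tie
    resolves to the alphabetically first label.
    """
    membership = np.asarray(membership).ravel()
    if membership.shape[0] != scores.shape[0]:
        raise ValueError(
            f"membership length {membership.shape[0]} does not match "
            f"{scores.shape[0]} topics"
        )
    ordered = scores[sorted(scores.columns)]
    vals = membership @ ordered.to_numpy()
    return ordered.columns[int(np.argmax(vals))]


def classify_reading_frames(
    seq: str,
    model: TopicModel,
    scores: pd.DataFrame,
    k: int,
    sequence_id: str = "",
) -> FramePrediction:
    """Predict the reading frame of all three frame-count vectors of a CDS.

    ``seq`` is taken in annotated frame 1.  Its three frame-tagged k-mer
    count vectors are transformed to topic memberships and classified with
    the frame label scores.  ``all_correct`` iff the predicted triple is
    (1, 2, 3); ``frameshift`` iff it is the cyclic shift (2, 3, 1) or
    (3, 1, 2).
    """
    if sorted(scores.columns) != list(FRAME_LABELS):
        raise ValueError(f"scores must have columns {FRAME_LABELS}")
    if len(seq) < k + 2:
        raise ValueError(f"sequence of length {len(seq)} too short for k={k}")
    fc = count_frame_kmers(seq, k)
    m = CountMatrix(
        [f"{sequence_id}|{lab}" for lab in FRAME_LABELS],
        list(model.feature_ids),
        fc,
        mode="frame",
    )
    theta = transform(model, m).theta
    predicted = tuple(
        int(predict_label(theta[i], scores).removeprefix("frame")) for i in range(3)
    )
    return FramePrediction(
        sequence_id=sequence_id,
        predicted=predicted,
        all_correct=predicted == (1, 2, 3),
        frameshift=predicted in _CYCLIC_SHIFTS,
    )


def centered_subsequence(seq: str, n_codons: int) -> str:
    """Extract ``3 * n_codons`` nt centered on the midpoint of a CDS.

    The start is snapped down to the nearest codon boundary so that the
    subsequence's frame 1 coincides with the parent's frame 1.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
    if n_codons < 1 or 3 * n_codons > len(seq):
        raise ValueError(
            f"cannot take {n_codons} codons from a {len(seq) // 3}-codon CDS"
        )
    start = ((len(seq) - 3 * n_codons) // 2) // 3 * 3
    return seq[start : start + 3 * n_codons]
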