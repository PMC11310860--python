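"""Topic interpretation: driving k-mers, structure-plot data, PWMs.

A topic is interpretable through the k-mers that are most *distinctively*
distributed in it.  Raw per-topic probabilities are a poor guide because
abundant k-mers can top several topics at once; instead, the observation
of a single k-mer under a topic is treated as a Bernoulli variable with
success probability phi[t][w], and distinctiveness of k-mer w in topic t
is the smallest Kullback-Leibler divergence between that Bernoulli and the
corresponding Bernoulli of any other topic.  Each k-mer is assigned to the
topic where it is most distinctive, and each topic reports its assigned
k-mers ranked by distinctiveness — its "driving" k-mers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SequenceRecord
from .lda import MembershipMatrix, TopicModel

_CLAMP = 1e-12


def bernoulli_kl(p: float, q: float) -> float:
    """KL divergence (nats) between Bernoulli(p) and Bernoulli(q).

    Probabilities are clamped to [1e-12, 1 - 1e-12] to guard serialized
    model round-off; the result is >= 0 and 0 iff p == q.
    """
    p = min(max(p, _CLAMP), 1.0 - _CLAMP)
    q = min(max(q, _CLAMP), 1.0 - _CLAMP)
    return float(p * np.log(p / q) + (1.0 - p) * np.log((1.0 - p) / (1.0 - q)))


def _bernoulli_kl_matrix(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    q = np.clip(q, _CLAMP, 1.0 - _CLAMP)
    return p * np.log(p / q) + (1.0 - p) * np.log((1.0 - p) / (1.0 - q))


def driving_features(model: TopicModel, top_n: int = 10) -> pd.DataFrame:
    """Per-topic ranked driving features by Bernoulli-KL distinctiveness.

    For feature w and topic t the distinctiveness is
    ``d(t, w) = min over t' != t of bernoulli_kl(phi[t][w], phi[t'][w])``
    (nats); w is assigned to ``argmax_t d(t, w)``.  Each topic reports its
    assigned features ranked by d descending (ties broken by lexicographic
    feature id), truncated to ``top_n``.

    Returns a DataFrame with columns topic, rank, feature, distinctiveness,
    assigned.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    K, V = model.phi.shape
    if K < 2:
        raise ValueError("distinctiveness is undefined with a single topic")
    d = np.empty((K, V))
    for t in range(K):
        others = [tp for tp in range(K) if tp != t]
        kl = _bernoulli_kl_matrix(model.phi[t][None, :], model.phi[others])
        d[t] = kl.min(axis=0)
    assigned_topic = d.argmax(axis=0)  # ties -> lowest topic index
    feats = np.asarray(model.feature_ids, dtype=object)
    records = []
    for t in range(K):
        idx = np.flatnonzero(assigned_topic == t)
        order = sorted(idx, key=lambda i: (-d[t, i], feats[i]))[:top_n]
        for rank, i in enumerate(order, start=1):
            records.append((t, rank, feats[i], float(d[t, i]), True))
    return pd.DataFrame(
        records, columns=["topic", "rank", "feature", "distinctiveness", "assigned"]
    )


def export_structure_data(
    memberships: MembershipMatrix,
    group: list,
    sort_by: int | None = None,
) -> pd.DataFrame:
    """Long-format structure-plot table: (sample, group, topic, proportion).

    One row per (sample, topic); proportions per sample sum to 1.  When
    ``sort_by`` names a topic, samples are ordered within each group by
    that topic's proportion, descending.
    """
    if len(group) != len(memberships.sample_ids):
        raise ValueError("group labels must align with samples")
    K = memberships.n_topics
    if sort_by is not None and not 0 <= sort_by < K:
        raise ValueError(f"sort topic {sort_by} out of range [0, {K})")
    df = pd.DataFrame(
        {
            "sample": np.repeat(memberships.sample_ids, K),
            "group": np.repeat(list(group), K),
            "topic": np.tile(np.arange(K), len(memberships.sample_ids)),
            "proportion": memberships.theta.ravel(),
        }
    )
    if sort_by is not None:
        key = dict(
            zip(memberships.sample_ids, memberships.theta[:, sort_by])
        )
        df = df.sort_values(
            by=["group", "sample"],
            key=lambda col: col.map(key) if col.name == "sample" else col,
            ascending=[True, False],
            kind="stable",
        ).reset_index(drop=True)
    return df


def pwm_from_sequences(seqs: list, region: tuple[int, int]) -> pd.DataFrame:
    """Position x base frequency matrix over an anchored region.

    Column sums are 1 at every position over the counted A/C/G/T bases; N
    bases are excluded from both numerator and denominator.  A position
    with zero coverage (all N) is an error.
    """
    start, end = region
    if start >= end:
        raise ValueError(f"empty region {region}")
    counts = np.zeros((end - start, 4), dtype=float)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for rec in seqs:
        if rec.anchor is None:
            raise ValueError(f"sequence {rec.id!r} has no anchor")
        lo, hi = rec.anchor + start, rec.anchor + end
        if lo < 0 or hi > len(rec.seq):
            raise ValueError(f"sequence {rec.id!r} does not cover region {region}")
        for j, base in enumerate(rec.seq[lo:hi]):
            if base in base_index:
                counts[j, base_index[base]] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [start + int(i) for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"zero coverage at positions {bad}")
    freq = counts / totals[:, None]
    return pd.DataFrame(
        freq, index=pd.Index(range(start, end), name="position"), columns=list("ACGT")
    )
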