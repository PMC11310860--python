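"""Shared analysis parameters and core matrix/sequence types.

Every featurization and model-fitting step in this package is driven by the
same small set of knobs: the k-mer length ``k``, the sliding-window size
``window`` used when positions are samples, the number of same-label
sequences pooled into one sample (``pack``), and the number of topics
``n_topics`` of the mixture model.  :class:`AnalysisConfig` holds them
together with the Dirichlet priors and the random seed so that a fitted
model can record exactly how it was produced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy import sparse

ALPHABET = "ACGT"
#: Bases accepted in input sequences; anything outside this set invalidates
#: every k-mer window it touches.
SEQUENCE_ALPHABET = frozenset("ACGTN")

COUNT_MODES = ("bulk", "positional", "frame", "position_window")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters shared across featurization and model fitting.

    Parameters
    ----------
    k : int
        k-mer length in nucleotides, 1-8.
    window : int
        Sliding-window size (number of adjacent start positions batched
        together) when positions in an alignment are used as samples.
    pack : int
        Number of same-label sequences summed into one pooled sample.
    n_topics : int
        Number of topics K of the mixture model.
    seed : int
        Random seed used for pooling and model initialization.
    alpha, eta : float, optional
        Symmetric Dirichlet priors on sample-topic and topic-feature
        distributions.  When ``None`` both default to ``1 / n_topics``,
        the common default of mainstream batch variational LDA
        implementations.
    """

    k: int = 6
    window: int = 5
    pack: int = 250
    n_topics: int = 6
    seed: int = 0
    alpha: float | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 8:
            raise ValueError(f"k must be in [1, 8], got {self.k}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.pack < 1:
            raise ValueError(f"pack must be >= 1, got {self.pack}")
        if self.n_topics < 1:
            raise ValueError(f"n_topics must be >= 1, got {self.n_topics}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.eta is not None and self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")

    @property
    def alpha_(self) -> float:
        """Resolved document-topic prior (default ``1 / n_topics``)."""
        return self.alpha if self.alpha is not None else 1.0 / self.n_topics

    @property
    def eta_(self) -> float:
        """Resolved topic-feature prior (default ``1 / n_topics``)."""
        return self.eta if self.eta is not None else 1.0 / self.n_topics

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SequenceRecord:
    """A nucleotide sequence with optional class label and alignment anchor.

    ``anchor`` is a 0-based offset into ``seq`` marking the alignment point
    (e.g. the 3' splice site).  Positions handed to featurization routines
    are interpreted relative to this anchor, with the intron-terminal AG of
    a 3' splice site occupying positions -2/-1.
    """

    id: str
    seq: str
    label: str | None = None
    anchor: int | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if self.anchor is not None and not 0 <= self.anchor <= len(self.seq):
            raise ValueError(
                f"anchor {self.anchor} outside [0, {len(self.seq)}] for {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class KmerVocabulary:
    """All 4^k k-mers over ACGT in lexicographic order, with a total index."""

    k: int
    kmers: tuple[str, ...]
    index: dict = field(repr=False)

    def __len__(self) -> int:
        return len(self.kmers)


@lru_cache(maxsize=None)
def enumerate_vocabulary(k: int) -> KmerVocabulary:
    """Enumerate the full k-mer vocabulary for a given k.

    Returns all ``4**k`` k-mers in lexicographic order (A < C < G < T);
    ``vocab.index[kmer]`` is the column of ``kmer`` in every count matrix
    built at this k.
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    kmers = tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))
    return KmerVocabulary(k=k, kmers=kmers, index={w: i for i, w in enumerate(kmers)})


@dataclass
class CountMatrix:
    """Samples x features matrix of non-negative integer counts.

    The universal input to the topic model.  ``mode`` records which
    featurization produced it: plain k-mers counted over whole sequences
    (``bulk``), k-mers tagged by reading frame (``frame``), position-tagged
    k-mers such as ``CCAG_at_-4`` (``positional``), or per-position counts
    where alignment positions are the samples (``position_window``).
    """

    sample_ids: list
    feature_ids: list
    counts: "np.ndarray | sparse.spmatrix"
    mode: str = "bulk"

    def __post_init__(self) -> None:
        if self.mode not in COUNT_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {COUNT_MODES}")
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.feature_ids)})"
            )
        if self.counts.size and self.min_count() < 0:
            raise ValueError("counts must be non-negative")
        if self.mode == "positional" and self.feature_ids:
            if "_at_" not in self.feature_ids[0]:
                raise ValueError("positional feature ids must look like 'KMER_at_POS'")

    # -- small helpers -----------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def is_sparse(self) -> bool:
        return sparse.issparse(self.counts)

    def min_count(self):
        return self.counts.min()

    def to_dense(self) -> np.ndarray:
        if self.is_sparse():
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def to_csr(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(self.counts)

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()
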