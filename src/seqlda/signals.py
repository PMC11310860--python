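"""Position-wise motif-fraction curves (branch site, polypyrimidine tract).

These curves give an independent, model-free reference against which the
topic-membership curves of a position-as-samples analysis can be compared:
at each window of alignment positions, the fraction of k-mers containing a
given IUPAC pattern (e.g. TNAC for the human branch-site core, YYYYYY for
a run of pyrimidines) is computed across all sequences.

The literature convention reported here divides that raw fraction by
(window size x k-mer size) to express a per-single-position value; both
the raw and the normalized curve are returned, because the division
changes units without changing shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import enumerate_vocabulary
from .features import build_position_sample_matrix

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def motif_match(kmer: str, pattern: str) -> bool:
    """True iff the IUPAC ``pattern`` occurs as a substring of ``kmer``.

    Containment semantics: e.g. GCTAAC matches TNAC via TAAC at offset 2.
    A YYYYYY pattern of the k-mer's full length requires every base to be
    C or T.  An invalid IUPAC code raises.
    """
    bad = set(pattern.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {pattern!r}")
    pattern = pattern.upper()
    kmer = kmer.upper()
    if len(pattern) > len(kmer):
        raise ValueError(
            f"pattern {pattern!r} longer than k-mer {kmer!r}"
        )
    span = len(pattern)
    for off in range(len(kmer) - span + 1):
        if all(kmer[off + j] in IUPAC[p] for j, p in enumerate(pattern)):
            return True
    return False


def matching_kmer_mask(k: int, pattern: str) -> np.ndarray:
    """Boolean mask over the lexicographic k-mer vocabulary for a pattern."""
    vocab = enumerate_vocabulary(k)
    return np.array([motif_match(w, pattern) for w in vocab.kmers])


@dataclass
class SignalCurve:
    """A motif-fraction curve over alignment positions.

    ``raw_fraction[i]`` is the fraction of k-mers in the window starting at
    ``positions[i]`` that contain the pattern; ``values`` is that fraction
    divided by (window * k).
    """

    positions: np.ndarray
    raw_fraction: np.ndarray
    values: np.ndarray
    pattern: str
    k: int
    window: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if (self.values < 0).any() or (self.raw_fraction < 0).any():
            raise ValueError("curve values must be non-negative")

    def peak_position(self) -> int:
        return int(self.positions[int(np.argmax(self.raw_fraction))])


def motif_fraction_curve(
    seqs: list,
    pattern: str,
    k: int,
    window: int,
    positions: tuple[int, int],
) -> SignalCurve:
    """Fraction of pattern-containing k-mers at each anchored window.

    Step 1: at each window start position, divide the number of matching
    k-mers by the total number of k-mers in the window across sequences.
    Step 2: divide that fraction by (window * k) to obtain the reported
    per-position value.  Both are returned.
    """
    m = build_position_sample_matrix(seqs, k, window, positions)
    mask = matching_kmer_mask(k, pattern)
    counts = m.to_dense().astype(float)
    totals = counts.sum(axis=1)
    matches = counts[:, mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(totals > 0, matches / np.maximum(totals, 1), 0.0)
    return SignalCurve(
        positions=np.array([int(p) for p in m.sample_ids]),
        raw_fraction=raw,
        values=raw / (window * k),
        pattern=pattern,
        k=k,
        window=window,
        meta={"n_sequences_requested": len(seqs)},
    )
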