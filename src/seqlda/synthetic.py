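"""Synthetic corpora and sequences with known structure.

Every analysis stage in this package is testable offline against data with
a known ground truth:

* :func:`simulate_topic_corpus` draws a count corpus directly from the LDA
  generative model with known topic-feature and sample-topic
  distributions, the oracle for parameter-recovery tests;
* :func:`simulate_anchored_introns` emits intron-like sequences anchored
  at a 3' splice site (positions -2/-1 are the final two bases) with a
  branch-site motif planted at a chosen upstream offset and an elevated
  C/T (polypyrimidine) region;
* :func:`simulate_cds` emits coding sequences with codon-usage bias drawn
  i.i.d. from a supplied 64-entry codon weight table, so reading-frame
  signal exists by construction.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .config import ALPHABET, CountMatrix, SequenceRecord
from .signals import IUPAC

CODONS = tuple("".join(c) for c in itertools.product(ALPHABET, repeat=3))
STOP_CODONS = ("TAA", "TAG", "TGA")
_STOP_IDX = [CODONS.index(c) for c in STOP_CODONS]


def simulate_topic_corpus(
    K: int,
    V: int,
    n_samples: int,
    tokens_per_sample: int,
    phi_concentration: float = 0.1,
    theta_concentration: float = 0.3,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Draw a count corpus from the LDA generative model.

    Topic rows phi* ~ Dirichlet(phi_concentration) over V features; sample
    rows theta* ~ Dirichlet(theta_concentration) over K topics; each
    sample's tokens are multinomial from its mixture distribution
    theta* . phi*.  Returns (CountMatrix, phi*, theta*).
    """
    if K < 1 or V < 2:
        raise ValueError(f"need K >= 1 and V >= 2, got K={K}, V={V}")
    if n_samples < 1 or tokens_per_sample < 1:
        raise ValueError("n_samples and tokens_per_sample must be >= 1")
    if phi_concentration <= 0 or theta_concentration <= 0:
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, phi_concentration), size=K)
    theta = rng.dirichlet(np.full(K, theta_concentration), size=n_samples)
    mix = theta @ phi
    counts = np.vstack(
        [rng.multinomial(tokens_per_sample, mix[d]) for d in range(n_samples)]
    )
    m = CountMatrix(
        [f"s{d:04d}" for d in range(n_samples)],
        [f"f{v:04d}" for v in range(V)],
        counts,
        mode="bulk",
    )
    return m, phi, theta


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[p])) for p in pattern.upper())


def simulate_anchored_introns(
    n: int,
    length: int,
    classes: dict,
    seed: int = 0,
    background: tuple = (0.25, 0.25, 0.25, 0.25),
) -> list:
    """Intron-like sequences with planted branch/pyrimidine signals.

    ``classes`` maps a label to a spec dict with keys:

    * ``branch_offset``: motif start relative to the anchor (negative);
    * ``branch_motif``: IUPAC pattern, instantiated uniformly per sequence;
    * ``branch_prob``: probability a sequence carries the motif;
    * ``branch_jitter``: max absolute shift of the offset (default 0);
    * ``pyrimidine_region``: half-open (start, end) relative to the anchor
      with elevated C/T probability (optional);
    * ``pyrimidine_strength``: total C+T probability in that region
      (default 0.85).

    Each record gets ``anchor = length`` so the 3' splice site convention
    holds: the final two bases sit at positions -2/-1.  ``n`` sequences
    are generated per class.  Overlapping branch/pyrimidine regions are an
    error.
    """
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    records = []
    for label in sorted(classes):
        spec = classes[label]
        motif = spec.get("branch_motif", "TNAC")
        offset = spec["branch_offset"]
        prob = spec.get("branch_prob", 1.0)
        jitter = spec.get("branch_jitter", 0)
        pyr = spec.get("pyrimidine_region")
        strength = spec.get("pyrimidine_strength", 0.85)
        lo = offset - jitter
        hi = offset + jitter + len(motif)
        if lo < -length or hi > 0:
            raise ValueError(
                f"class {label!r}: branch motif region [{lo}, {hi}) does not fit "
                f"inside a length-{length} intron"
            )
        if pyr is not None:
            if pyr[0] >= pyr[1] or pyr[0] < -length or pyr[1] > 0:
                raise ValueError(f"class {label!r}: bad pyrimidine region {pyr}")
            if lo < pyr[1] and pyr[0] < hi:
                raise ValueError(
                    f"class {label!r}: branch region [{lo}, {hi}) overlaps "
                    f"pyrimidine region {pyr}"
                )
        pyr_p = np.array(
            [(1 - strength) / 2, strength / 2, (1 - strength) / 2, strength / 2]
        )  # A C G T
        for i in range(n):
            codes = rng.choice(4, size=length, p=bg)
            if pyr is not None:
                span = pyr[1] - pyr[0]
                codes[length + pyr[0] : length + pyr[1]] = rng.choice(
                    4, size=span, p=pyr_p
                )
            if rng.random() < prob:
                off = offset + (rng.integers(-jitter, jitter + 1) if jitter else 0)
                inst = _instantiate_iupac(motif, rng)
                pos = length + off
                codes[pos : pos + len(motif)] = [ALPHABET.index(b) for b in inst]
            seq = "".join(ALPHABET[c] for c in codes)
            records.append(
                SequenceRecord(
                    id=f"{label}_{i:05d}", seq=seq, label=label, anchor=length
                )
            )
    return records


def skewed_codon_weights(seed: int = 0, s: float = 1.5) -> np.ndarray:
    """A Zipf-skewed codon usage table over the 61 sense codons.

    Weight 1/rank^s is assigned to sense codons in a seed-shuffled order;
    stop codons get zero mass.  The strong skew is the desk-scale analogue
    of species codon bias: it guarantees that the three reading frames of
    a coding sequence have distinguishable k-mer distributions.
    """
    rng = np.random.default_rng(seed)
    sense = [i for i in range(64) if i not in _STOP_IDX]
    order = rng.permutation(len(sense))
    w = np.zeros(64)
    for rank, j in enumerate(order, start=1):
        w[sense[j]] = 1.0 / rank**s
    return w


def simulate_cds(
    codon_weights: np.ndarray,
    n: int,
    n_codons_range: tuple[int, int] = (100, 300),
    seed: int = 0,
    label: str | None = None,
    id_prefix: str = "cds",
) -> list:
    """Codon-usage-biased coding sequences in annotated frame 1.

    Each sequence begins with ATG, ends with a uniformly drawn stop codon,
    and carries internal codons i.i.d. from the normalized weight table
    (which must place zero mass on stop codons, so no internal in-frame
    stop occurs).  The internal codon count is uniform over
    ``n_codons_range`` (inclusive); the minimum must be >= 30.
    """
    w = np.asarray(codon_weights, dtype=float)
    if w.shape != (64,):
        raise ValueError(f"codon_weights must have 64 entries, got {w.shape}")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("codon weights must be non-negative with positive mass")
    if any(w[i] > 0 for i in _STOP_IDX):
        raise ValueError("codon weights must place zero mass on stop codons")
    lo, hi = n_codons_range
    if lo < 30 or hi < lo:
        raise ValueError(f"n_codons_range must satisfy 30 <= min <= max, got {n_codons_range}")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(64, size=n_codons, p=p)
        stop = STOP_CODONS[rng.integers(3)]
        seq = "ATG" + "".join(CODONS[c] for c in internal) + stop
        records.append(
            SequenceRecord(id=f"{id_prefix}_{i:05d}", seq=seq, label=label)
        )
    return records
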