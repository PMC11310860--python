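"""Small ORF discovery in UTR/lncRNA sequences and coding-potential scoring.

A small ORF (smORF) is a start codon (ATG) paired with the next in-frame
stop codon (TAA/TAG/TGA) with at least ``min_codons`` potential codons
strictly between them.  Candidates are searched on the sense strand in all
three frames — UTR and lncRNA inputs are transcript sequences, so the
reverse complement is not scanned.  A smORF's coding potential is scored
by treating its sequence as frame 1 and asking a CDS-trained topic model
whether all three of its reading frames are recognized correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scoring import FramePrediction, classify_reading_frames

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class SmORF:
    """An open reading frame found inside a longer transcript sequence.

    Coordinates are 0-based, half-open on the parent (sense strand);
    ``frame_on_parent`` is ``start % 3 + 1``; ``n_internal_codons`` counts
    codons strictly between the start and stop codons.
    """

    parent_id: str
    start: int
    end: int
    frame_on_parent: int
    n_internal_codons: int
    seq: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end <= self.start:
            raise ValueError("smORF span must be a positive multiple of 3")
        if len(self.seq) != self.end - self.start:
            raise ValueError("seq length does not match coordinates")
        if not self.seq.startswith(START_CODON):
            raise ValueError("smORF must begin with ATG")
        if self.seq[-3:] not in STOP_CODONS:
            raise ValueError("smORF must end with a stop codon")
        internal = [
            self.seq[i : i + 3] for i in range(3, len(self.seq) - 3, 3)
        ]
        if any(c in STOP_CODONS for c in internal):
            raise ValueError("smORF contains an in-frame stop codon")
        if self.n_internal_codons != (self.end - self.start) // 3 - 2:
            raise ValueError("n_internal_codons inconsistent with coordinates")
        if self.frame_on_parent != self.start % 3 + 1:
            raise ValueError("frame_on_parent inconsistent with start")


def find_smorfs(
    seq: str,
    min_codons: int = 25,
    parent_id: str = "",
    longest_only: bool = True,
) -> list:
    """Find qualifying smORFs in all three sense-strand frames.

    For each stop codon, the default pairs it with the most upstream
    in-frame ATG after the previous in-frame stop (longest-ORF rule);
    ``longest_only=False`` emits every qualifying ATG for each stop.
    Returns ORFs with at least ``min_codons`` internal codons, sorted by
    start (then end).  Codons containing N match neither ATG nor a stop.
    """
    seq = seq.upper()
    out = []
    for f in range(3):
        open_starts: list = []
        for i in range(f, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                for s in open_starts:
                    n_internal = (i - s) // 3 - 1
                    if n_internal >= min_codons:
                        out.append(
                            SmORF(
                                parent_id=parent_id,
                                start=s,
                                end=i + 3,
                                frame_on_parent=s % 3 + 1,
                                n_internal_codons=n_internal,
                                seq=seq[s : i + 3],
                            )
                        )
                    if longest_only:
                        break
                open_starts = []
            elif codon == START_CODON and (not open_starts or not longest_only):
                open_starts.append(i)
    out.sort(key=lambda o: (o.start, o.end))
    return out


def score_smorf_coding(
    smorf: SmORF,
    model,
    scores: pd.DataFrame,
    k: int,
) -> FramePrediction:
    """Classify a smORF's three reading frames with a CDS-trained model.

    The smORF sequence is treated as frame 1; it is flagged coding-like
    iff all three frames are predicted correctly (``all_correct``).
    """
    return classify_reading_frames(
        smorf.seq, model, scores, k,
        sequence_id=f"{smorf.parent_id}:{smorf.start}-{smorf.end}",
    )


def smorfs_to_table(smorfs: list, verdicts: list | None = None) -> pd.DataFrame:
    """BED6-compatible table (+ optional coding-like verdict column)."""
    rows = []
    for i, o in enumerate(smorfs):
        row = {
            "chrom": o.parent_id,
            "start": o.start,
            "end": o.end,
            "name": f"smorf_{i}",
            "score": o.n_internal_codons,
            "strand": "+",
        }
        if verdicts is not None:
            row["coding_like"] = bool(verdicts[i])
        rows.append(row)
    return pd.DataFrame(rows)
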