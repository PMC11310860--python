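"""File formats: FASTA in, TSV/JSON out, plus run manifests.

All tabular artifacts are TSV with header rows and models are JSON, so
every output of the pipeline is diff-able text.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .config import CountMatrix, SequenceRecord

logger = logging.getLogger(__name__)


def read_fasta(path) -> list:
    """Read sequences into :class:`SequenceRecord` objects.

    Duplicate ids are rejected; lowercase input is uppercased with a
    logged notice.  Anchors and labels are attached separately via
    :func:`read_labels` / :func:`attach_metadata`.
    """
    records = []
    seen = set()
    lowercased = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if raw != raw.upper():
            lowercased += 1
        records.append(SequenceRecord(id=rec.id, seq=raw))
    if lowercased:
        logger.info("uppercased %d lowercase sequence(s) from %s", lowercased, path)
    return records


def write_fasta(records: list, path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_labels(path) -> dict:
    """Read a sidecar TSV (columns: id, and optionally anchor, label).

    Returns ``{id: (anchor or None, label or None)}``.  When the anchor
    column is absent, anchors default to the sequence start (None here;
    resolved to 0 on attachment).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    out = {}
    for _, row in df.iterrows():
        anchor = int(row["anchor"]) if "anchor" in df.columns and pd.notna(row["anchor"]) else None
        label = str(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else None
        out[str(row["id"])] = (anchor, label)
    return out


def attach_metadata(records: list, table: dict) -> list:
    """Attach anchors/labels from a label table to FASTA records.

    Every record id must be resolvable; missing ids are listed
    exhaustively in the error.  Absent anchors default to 0 (sequence
    start).
    """
    missing = [r.id for r in records if r.id not in table]
    if missing:
        raise ValueError(f"ids missing from label table: {missing}")
    out = []
    for r in records:
        anchor, label = table[r.id]
        out.append(
            SequenceRecord(
                id=r.id, seq=r.seq, label=label,
                anchor=anchor if anchor is not None else 0,
            )
        )
    return out


def write_labels(records: list, path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "anchor": [r.anchor if r.anchor is not None else "" for r in records],
            "label": [r.label if r.label is not None else "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices


def write_count_matrix(m: CountMatrix, path) -> None:
    """CountMatrix as TSV (sample ids in column 1) plus a JSON sidecar."""
    df = pd.DataFrame(m.to_dense(), index=m.sample_ids, columns=m.feature_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    sidecar = {"mode": m.mode, "n_samples": len(m.sample_ids),
               "n_features": len(m.feature_ids)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return CountMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(),
        mode=meta["mode"],
    )


def write_memberships(memberships, path) -> None:
    df = pd.DataFrame(
        memberships.theta,
        index=memberships.sample_ids,
        columns=[f"topic{t}" for t in range(memberships.n_topics)],
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_memberships(path):
    from .lda import MembershipMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return MembershipMatrix([str(i) for i in df.index], df.to_numpy())


# ---------------------------------------------------------------------------
# run manifests


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, params: dict, inputs: list) -> None:
    """Record command line, parameters and input hashes for reproduction."""
    manifest = {
        "argv": sys.argv,
        "params": {k: v for k, v in params.items() if not k.startswith("_")},
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(str(out_path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
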