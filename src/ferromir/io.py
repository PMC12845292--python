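"""File-format helpers: FASTA, count/metadata TSV, manifest JSON."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datagen import CountData, GroundTruthManifest

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_manifest",
    "read_manifest",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_counts(counts_path, meta_path) -> CountData:
    """Counts TSV (first column feature id) + sample-metadata TSV sidecar."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "group" not in meta.columns:
        meta["group"] = meta["treatment"].astype(str) + "_" + meta["organ"].astype(str)
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return CountData(counts, meta.loc[counts.columns])


def write_manifest(manifest: GroundTruthManifest, path) -> None:
    Path(path).write_text(manifest.to_json())


def read_manifest(path) -> GroundTruthManifest:
    return GroundTruthManifest.from_json(Path(path).read_text())
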