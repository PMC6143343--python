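"""Sequence and table I/O helpers (FASTA/FASTQ via Biopython, metadata TSV)."""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str) -> Dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence dict."""
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate scaffold name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> List[Tuple[str, str]]:
    """Load reads as (read_id, sequence) pairs; qualities are ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_fastq(reads: Iterable[Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tsv(df: pd.DataFrame, path: str, meta: Dict[str, object] | None = None) -> None:
    """Write a TSV with leading ``# key=value`` metadata lines."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta
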