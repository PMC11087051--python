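"""Shared readers/writers for the standard formats the pipeline touches."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_signal_annotations",
    "write_csv",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein FASTA into (id, sequence) pairs.

    Sequences are uppercased; trailing '*' stop characters are stripped
    with a warning; duplicate ids are suffixed ``.1``, ``.2``, ... with a
    warning so ids stay unique.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"{rid}: stripping '*' stop character(s)", stacklevel=2)
            seq = seq.replace("*", "")
        if rid in seen:
            seen[rid] += 1
            new = f"{rid}.{seen[rid]}"
            warnings.warn(f"duplicate id {rid!r} renamed to {new!r}", stacklevel=2)
            rid = new
        else:
            seen[rid] = 0
        records.append((rid, seq))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_signal_annotations(path) -> dict[str, int]:
    """Read tab-separated ``id<TAB>signal_end`` annotations (0-based index
    of the first mature residue)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "signal_end"])
    return dict(zip(df["id"].astype(str), df["signal_end"].astype(int)))


def write_csv(df: pd.DataFrame, path) -> int:
    """Write a CSV (UTF-8, '.' decimal, header row); returns the row count."""
    df.to_csv(path, index=False)
    return len(df)
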