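"""Readers and writers: FASTA sequences, TSV datasets, design outputs.

Datasets are tab-separated with a mandatory header; matched tables carry
``sequence`` and ``indel_frequency`` columns, mismatched tables ``guide``,
``target`` and ``indel_frequency``.  Validation errors always name the
offending row or line.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encodings import MismatchRecord, TargetRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_dataset",
    "write_dataset",
]

_VALID_FASTA_CHARS = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Ordered name -> sequence map from a FASTA file.

    Names are the description line up to the first whitespace; sequences
    are upper-cased.  Duplicate names, empty files and characters outside
    A/C/G/T/N are rejected.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_FASTA_CHARS
        if bad:
            raise ValueError(
                f"record {name!r} contains illegal characters: {sorted(bad)}"
            )
        sequences[name] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write name -> sequence pairs as FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_dataset(path, kind: str):
    """Read a matched or mismatched dataset from TSV.

    kind="matched" expects columns ``sequence``, ``indel_frequency`` (plus
    optional ``context``); kind="mismatched" expects ``guide``, ``target``,
    ``indel_frequency``.  Returns a list of TargetRecord or MismatchRecord;
    any invalid row is reported with its (1-based, header-exclusive) row
    number.
    """
    if kind not in ("matched", "mismatched"):
        raise ValueError(f"kind must be 'matched' or 'mismatched', got {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = (
        ["sequence", "indel_frequency"] if kind == "matched"
        else ["guide", "target", "indel_frequency"]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            freq = float(getattr(row, "indel_frequency"))
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {i}: non-numeric indel_frequency "
                f"{getattr(row, 'indel_frequency')!r}"
            ) from None
        try:
            if kind == "matched":
                context = getattr(row, "context", None)
                if isinstance(context, float):  # NaN from pandas
                    context = None
                records.append(TargetRecord(
                    sequence=row.sequence, indel_frequency=freq, context=context
                ))
            else:
                records.append(MismatchRecord(
                    guide=row.guide, target=row.target, indel_frequency=freq
                ))
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from None
    return records


def write_dataset(records: Iterable, path) -> None:
    """Write TargetRecord or MismatchRecord lists back to TSV."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    if isinstance(records[0], TargetRecord):
        df = pd.DataFrame(
            {"sequence": [r.sequence for r in records],
             "indel_frequency": [r.indel_frequency for r in records]}
        )
        if any(r.context for r in records):
            df["context"] = [r.context or "" for r in records]
    else:
        df = pd.DataFrame(
            {"guide": [r.guide for r in records],
             "target": [r.target for r in records],
             "indel_frequency": [r.indel_frequency for r in records]}
        )
    df.to_csv(path, sep="\t", index=False)
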