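"""Thin FASTA helpers over Biopython's SeqIO."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(source: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(source), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], sink, descriptions=None) -> None:
    """Write (id, sequence) pairs as FASTA; optional id -> description map."""
    descriptions = descriptions or {}
    seq_records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        SeqIO.write(seq_records, sink, "fasta")
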