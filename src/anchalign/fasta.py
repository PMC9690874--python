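"""FASTA input/output (thin wrappers over Bio.SeqIO).

Record ids are the FASTA header up to the first whitespace; sequences are
upper-cased on read so lower-case soft-masked input is accepted.
"""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .store import Sequence

__all__ = ["read_fasta", "write_fasta", "write_alignment_fasta"]


def read_fasta(path) -> list[Sequence]:
    return [
        Sequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[Sequence], path) -> int:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    return SeqIO.write(records, str(path), "fasta")


def write_alignment_fasta(id_a: str, row_a: str, id_b: str, row_b: str, handle) -> None:
    """Append one aligned pair as a two-record FASTA block ('-' gaps kept)."""
    handle.write(f">{id_a}\n{row_a}\n>{id_b}\n{row_b}\n")
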