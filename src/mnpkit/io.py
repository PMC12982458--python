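"""Sequence-file helpers (FASTA/FASTQ via Biopython) and digests."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = (SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA not found: {path}")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (read_id, sequence) pairs as FASTQ with uniform Q40 qualities.

    Returns the number of reads written.
    """
    n = 0
    with open(path, "w") as handle:
        for name, seq in reads:
            record = SeqRecord(Seq(seq), id=name, description="")
            record.letter_annotations["phred_quality"] = [40] * len(seq)
            SeqIO.write(record, handle, "fastq")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTQ not found: {path}")
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def sha256_of_file(path: str | Path, chunk: int = 1 << 20) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        while block := handle.read(chunk):
            digest.update(block)
    return digest.hexdigest()
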