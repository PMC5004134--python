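"""Sequence and artifact I/O helpers (FASTA/FASTQ via Biopython, GFA, TSV)."""

from __future__ import annotations

import hashlib
import os
from typing import Iterable, Iterator

from Bio import SeqIO

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file.

    The record id is the first whitespace-delimited token of the header;
    wrapped records are joined by Biopython.
    """
    for rec in SeqIO.parse(path, "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file; qualities are ignored."""
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper()


def sniff_reads(path: str) -> Iterator[tuple[str, str]]:
    """Read long reads from FASTA or FASTQ, deciding by the first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, records: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def n50(lengths: Iterable[int], genome_size: int | None = None) -> int:
    """N50 of the given lengths, or NG50 when genome_size is supplied."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        return 0
    total = genome_size if genome_size is not None else sum(ls)
    acc = 0
    for length in ls:
        acc += length
        if 2 * acc >= total:
            return length
    return 0  # NG50 undefined: assembly covers < half the genome


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
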