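"""Small sequence and file helpers shared across the package.

FASTA/FASTQ parsing goes through Biopython; writers keep the plain-text
conventions used throughout (60-column FASTA, Sanger-quality FASTQ).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence name in FASTA: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs from a FASTQ file; qualities ignored.

    Parse failures are re-raised with the approximate line number.
    """
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec.id, str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence, quality-string) records as FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
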