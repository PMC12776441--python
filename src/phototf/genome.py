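"""Genome sequences and FASTA I/O.

Sequences are held in memory as uppercase strings over {A,C,G,T,N}; a cached
integer encoding (A=0, C=1, G=2, T=3, anything else 255) backs the vectorised
k-mer machinery used by the damage background models.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "PYRIMIDINE_CODES",
    "BASE_TO_CODE",
    "CODE_TO_BASE",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: A=0, C=1, G=2, T=3; N (or anything else) = 255.
BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_TO_CODE[ord(_b)] = _i
CODE_TO_BASE = np.array(list("ACGT"), dtype="U1")

#: codes of C and T, the UV-damageable bases.
PYRIMIDINE_CODES = (1, 3)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """An in-memory genome: chrom name -> uppercase nucleotide string."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in seqs.items()}
        self._codes: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        """0-based half-open slice of a chromosome ('' outside bounds)."""
        s = self._seqs[chrom]
        if start is None:
            return s
        if start < 0 or end is None or end > len(s):
            raise IndexError(f"slice [{start}, {end}) outside {chrom} (len {len(s)})")
        return s[start:end]

    def base(self, chrom: str, pos: int) -> str:
        s = self._seqs[chrom]
        if not 0 <= pos < len(s):
            raise IndexError(f"position {pos} outside {chrom} (len {len(s)})")
        return s[pos]

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of a chromosome (A=0,C=1,G=2,T=3, N=255)."""
        if chrom not in self._codes:
            raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = BASE_TO_CODE[raw]
        return self._codes[chrom]

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence({name: revcomp(s) for name, s in self._seqs.items()})

    def with_sequence(self, chrom: str, seq: str) -> None:
        """Replace one chromosome (invalidates its cached encoding)."""
        self._seqs[chrom] = seq.upper()
        self._codes.pop(chrom, None)


def read_fasta(path: str | Path | io.TextIOBase) -> GenomeSequence:
    """Parse a FASTA file into a :class:`GenomeSequence`.

    Lowercase bases are folded to uppercase. An empty file, or a file whose
    first non-blank line is not a ``>`` header, is a parse error.
    """
    if isinstance(path, (str, Path)):
        handle = open(path)
        name = str(path)
    else:
        handle, name = path, "<stream>"
    try:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first:
            raise ValueError(f"{name}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{name}: malformed FASTA, first line {first.strip()!r} is not a header")
        handle.seek(0)
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError(f"{name}: no sequences parsed")
        return GenomeSequence(seqs)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(chrom)), id=chrom, description="")
        for chrom in genome.chroms
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
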