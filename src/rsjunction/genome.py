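"""Strand-aware access to genome sequence.

All coordinates handled here are 0-based half-open.  GTF records are 1-based
closed; the conversion happens in :mod:`rsjunction.annotation`, never here.
"""

from __future__ import annotations

from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeOutOfBounds(ValueError):
    """Requested slice extends beyond the chromosome."""


class GenomeSequence:
    """Per-chromosome nucleotide sequences with strand-aware slicing.

    Minus-strand lookups return the reverse complement of the plus-strand
    slice.  Sequences may be held in memory (``dict`` of strings) or backed
    by an indexed FASTA via pyfaidx; both expose the same interface.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        """Load from a FASTA file (indexed with pyfaidx)."""
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        obj = cls.__new__(cls)
        obj._seqs = fa  # FastaRecord supports len() and slicing to str
        return obj

    def chroms(self) -> list[str]:
        return list(self._seqs.keys())

    def __contains__(self, chrom: str) -> bool:
        try:
            self._seqs[chrom]
        except KeyError:
            return False
        return True

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``chrom``; revcomp when ``strand`` is '-'.

        Raises :class:`GenomeOutOfBounds` when the interval does not lie
        within chromosome bounds.
        """
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise GenomeOutOfBounds(
                f"slice {chrom}:{start}-{end} outside chromosome bounds [0, {n})"
            )
        seq = str(self._seqs[chrom][start:end]).upper()
        if strand == "-":
            return reverse_complement(seq)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return seq


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
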