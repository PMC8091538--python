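"""Genome sequence access and splice-site dinucleotide extraction.

All coordinates are 0-based half-open on the forward (reference) strand.
Sequences handed back to callers are uppercase strings; minus-strand
windows are reverse-complemented into transcription orientation.
"""

from __future__ import annotations

import os

import pyfaidx

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Random-access wrapper around an indexed FASTA file.

    Parameters
    ----------
    path
        FASTA file; a ``.fai`` index is created on first open if missing.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = str(path)
        self._fasta = pyfaidx.Fasta(self.path, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '-'."""
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} absent from {self.path}")
        if start < 0 or end > len(self._fasta[chrom]):
            raise ValueError(
                f"window [{start}, {end}) outside contig {chrom!r} "
                f"(length {len(self._fasta[chrom])})"
            )
        seq = self._fasta[chrom][start:end].seq
        return reverse_complement(seq) if strand == "-" else seq

    def close(self) -> None:
        self._fasta.close()


def splice_dinucleotides(intron, strand: str, genome: Genome) -> tuple[str, str]:
    """Donor/acceptor dinucleotides of an intron read in transcription orientation.

    On the plus strand the donor pair is the first two intronic bases and the
    acceptor pair the last two; on the minus strand the roles of the genomic
    ends swap and both pairs are reverse-complemented.  A GT-AG intron on the
    minus strand therefore reads CT..AC on the forward genome.
    """
    if intron.end - intron.start < 4:
        raise ValueError("intron too short for dinucleotide extraction")
    if strand == "+":
        donor = genome.fetch(intron.chrom, intron.start, intron.start + 2)
        acceptor = genome.fetch(intron.chrom, intron.end - 2, intron.end)
    elif strand == "-":
        donor = reverse_complement(genome.fetch(intron.chrom, intron.end - 2, intron.end))
        acceptor = reverse_complement(genome.fetch(intron.chrom, intron.start, intron.start + 2))
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return donor, acceptor
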