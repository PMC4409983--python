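"""Genome FASTA access and spliced-sequence extraction."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .intervals import MINUS, Transcript

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into a dict of upper-case strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def spliced_sequence(genome: dict[str, str], transcript: Transcript) -> str:
    """Concatenate exon substrings 5'->3' in transcript orientation.

    Minus strand yields the reverse complement of the plus-strand
    concatenation; unknown strand is treated as plus.
    """
    chrom_seq = genome.get(transcript.chrom)
    if chrom_seq is None:
        raise KeyError(f"chromosome {transcript.chrom} not in genome")
    for e in transcript.exons:
        if e.end > len(chrom_seq):
            raise IndexError(
                f"exon [{e.start},{e.end}) beyond end of {transcript.chrom} "
                f"(length {len(chrom_seq)})"
            )
    seq = "".join(chrom_seq[e.start : e.end] for e in transcript.exons)
    if transcript.strand == MINUS:
        seq = reverse_complement(seq)
    return seq
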