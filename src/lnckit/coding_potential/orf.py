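"""Six-frame open-reading-frame scanning on spliced transcript sequences."""

from __future__ import annotations

from dataclasses import dataclass

from ..annotation_io.genome import reverse_complement
from .models import STOP_CODONS

START_CODON = "ATG"


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ORF in one of six translational frames.

    ``start``/``end`` are nucleotide offsets on the frame's reading
    orientation: the spliced sequence itself for frames 0-2, its reverse
    complement for frames 3-5.  ``end - start`` is divisible by 3 and
    includes the terminal stop codon when ``has_stop``.
    """

    frame: int
    start: int
    end: int
    has_stop: bool
    requires_start: bool  # anchored at ATG

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a codon multiple")
        if not 0 <= self.frame <= 5:
            raise ValueError("frame must be 0..5")

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def peptide_length(self) -> int:
        n = self.nt_length // 3
        return n - 1 if self.has_stop else n

    def forward_offsets(self, spliced_length: int) -> tuple[int, int]:
        """Offsets on the forward spliced sequence."""
        if self.frame < 3:
            return self.start, self.end
        return spliced_length - self.end, spliced_length - self.start


def _is_stop(codon: str) -> bool:
    # codons containing N translate as unknown and do not terminate
    return codon in STOP_CODONS


def _scan_oriented(seq: str, frame_offset: int, frame_id: int) -> list[OpenReadingFrame]:
    orfs: list[OpenReadingFrame] = []
    n = len(seq)
    seg_start = frame_offset  # start of current stop-free segment
    atg: int | None = None
    best_stretch: tuple[int, int] | None = None
    pos = frame_offset
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if _is_stop(codon):
            if atg is not None:
                orfs.append(
                    OpenReadingFrame(frame_id, atg, pos + 3, has_stop=True, requires_start=True)
                )
                atg = None
            stretch = (seg_start, pos)
            if best_stretch is None or stretch[1] - stretch[0] > best_stretch[1] - best_stretch[0]:
                best_stretch = stretch
            seg_start = pos + 3
        else:
            if codon == START_CODON and atg is None:
                atg = pos
        pos += 3
    # trailing stop-free segment
    stretch = (seg_start, pos)
    if best_stretch is None or stretch[1] - stretch[0] > best_stretch[1] - best_stretch[0]:
        best_stretch = stretch
    if best_stretch[1] > best_stretch[0]:
        orfs.append(
            OpenReadingFrame(
                frame_id, best_stretch[0], best_stretch[1], has_stop=False, requires_start=False
            )
        )
    return orfs


def scan_orfs(spliced_sequence: str) -> list[OpenReadingFrame]:
    """All maximal ATG-to-stop ORFs plus the maximal stop-free stretch, per frame.

    Frames 0-2 read the sequence forward with offsets 0/1/2; frames 3-5 read
    the reverse complement with offsets 0/1/2.
    """
    seq = spliced_sequence.upper().replace("U", "T")
    out: list[OpenReadingFrame] = []
    rc = reverse_complement(seq)
    for off in range(3):
        out.extend(_scan_oriented(seq, off, off))
        out.extend(_scan_oriented(rc, off, off + 3))
    return out


def atg_orfs(orfs: list[OpenReadingFrame]) -> list[OpenReadingFrame]:
    return [o for o in orfs if o.requires_start and o.has_stop]


def max_peptide_length(orfs: list[OpenReadingFrame]) -> int:
    """Longest ATG-to-stop peptide (aa, stop excluded); 0 if none."""
    anchored = atg_orfs(orfs)
    if not anchored:
        return 0
    return max(o.peptide_length for o in anchored)


def orf_fraction(orf: OpenReadingFrame | None, spliced_length: int) -> float:
    """Nucleotide length of the ORF (incl. stop) over the transcript length."""
    if spliced_length <= 0:
        raise ValueError("spliced_length must be positive")
    if orf is None:
        return 0.0
    return orf.nt_length / spliced_length
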