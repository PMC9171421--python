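"""Three-frame open reading frame discovery.

An ORF is a segment beginning at an AUG codon and ending at the first
in-frame stop codon (UAA/UAG/UGA), read 5'->3'.  All three forward reading
frames are scanned; the reverse complement never is, because ribosomes
translate mRNA 5'->3'.  An AUG with no downstream in-frame stop does not
open an ORF.  Within one frame, scanning resumes at the codon following
each stop, so the ORFs of a frame are non-overlapping: internal AUGs inside
an open ORF do not start nested ORFs.

ORF length is counted in amino acids, excluding the stop codon, so the
shortest possible ORF ("AUGUAA" etc.) has length 1 (a single methionine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "START_CODON",
    "STOP_CODONS",
    "IUPAC_ALPHABET",
    "Transcript",
    "Orf",
    "OrfSet",
    "normalize_sequence",
    "scan_frames",
]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: unambiguous bases plus the IUPAC ambiguity codes
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

VALID_LABELS = ("coding", "noncoding", "unlabeled")


def normalize_sequence(raw: str) -> str:
    """Return ``raw`` uppercased with U replaced by T.

    Both DNA and RNA spellings are accepted; IUPAC ambiguity codes are
    retained.  Any other character raises ``ValueError`` naming the
    character and its 0-based position.
    """
    if not raw:
        raise ValueError("empty sequence")
    bases = raw.upper().replace("U", "T")
    for pos, ch in enumerate(bases):
        if ch not in IUPAC_ALPHABET:
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in sequence"
            )
    return bases


@dataclass
class Transcript:
    """An identified nucleotide sequence with an optional coding label."""

    id: str
    bases: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be nonempty")
        if not self.bases:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Orf:
    """One predicted ORF.

    ``frame`` is the 5' offset (0/1/2) of the reading frame, ``start`` the
    0-based position of the A of AUG, and ``aa_length`` the number of amino
    acids excluding the stop codon.
    """

    frame: int
    start: int
    aa_length: int

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.aa_length < 1:
            raise ValueError("aa_length must be >= 1")
        if self.start % 3 != self.frame:
            raise ValueError("start must be congruent to frame modulo 3")

    @property
    def stop_start(self) -> int:
        """0-based position of the first base of the stop codon."""
        return self.start + 3 * self.aa_length

    @property
    def end(self) -> int:
        """Half-open end of the full ORF span, stop codon included."""
        return self.stop_start + 3


@dataclass
class OrfSet:
    """All ORFs of one transcript, sorted by (frame, start)."""

    transcript_id: str
    orfs: list[Orf] = field(default_factory=list)
    transcript_length: int = 0

    def aa_lengths(self) -> list[int]:
        return [o.aa_length for o in self.orfs]


def _is_start(codon: str) -> bool:
    # a codon containing any non-ACGT character matches neither AUG nor a stop
    return codon == START_CODON


def _is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def scan_frames(transcript: Transcript) -> OrfSet:
    """Enumerate the ORFs of all three forward reading frames.

    Expects normalized bases (see :func:`normalize_sequence`).  Returns an
    empty :class:`OrfSet` when the sequence contains no complete ORF.
    """
    bases = transcript.bases
    n = len(bases)
    orfs: list[Orf] = []
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if _is_start(bases[i : i + 3]):
                j = i + 3
                while j + 3 <= n and not _is_stop(bases[j : j + 3]):
                    j += 3
                if j + 3 <= n:  # closed at an in-frame stop
                    orfs.append(
                        Orf(frame=frame, start=i, aa_length=(j - i) // 3)
                    )
                    i = j + 3  # resume after the stop codon
                    continue
                # AUG running into the 3' end without a stop: not an ORF,
                # and no later AUG in this frame can find a stop either.
                break
            i += 3
    orfs.sort(key=lambda o: (o.frame, o.start))
    return OrfSet(transcript_id=transcript.id, orfs=orfs, transcript_length=n)
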