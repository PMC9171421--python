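"""vORF score: ORF dominance extended to multi-ORF viral genomes.

(+)ssRNA viral genomes encode several bona fide ORFs (vORFs) translated by
the host machinery.  The vORF score generalizes dominance by pooling the
annotated vORF lengths in the numerator:

    vORF score = sum(l_vORF) / (sum(l_vORF) + sum(l_secORF))

where the secORFs are every predicted ORF that is not an annotated vORF.
Viruses relying on frameshifting, RNA editing or alternative initiation
are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .orfscan import Transcript, scan_frames

__all__ = ["ViralAnnotation", "ViralScore", "vorf_score"]


@dataclass
class ViralAnnotation:
    """Bona fide ORFs of one viral genome.

    Either ``spans`` — (frame, start, aa_length) triples in genome
    coordinates — or, when coordinates are unavailable, ``lengths`` — the
    bare amino-acid lengths of the vORFs.
    """

    genome_id: str
    spans: list[tuple[int, int, int]] | None = None
    lengths: list[int] | None = None

    def __post_init__(self) -> None:
        if self.spans is not None:
            if not self.spans:
                raise ValueError("annotation must contain at least one vORF")
            for frame, start, aa in self.spans:
                if aa < 1:
                    raise ValueError("vORF lengths must be >= 1 amino acid")
                if start % 3 != frame:
                    raise ValueError(
                        f"span start {start} is not congruent to frame {frame} mod 3"
                    )
        elif self.lengths is not None:
            if not self.lengths:
                raise ValueError("annotation must contain at least one vORF")
            if any(l < 1 for l in self.lengths):
                raise ValueError("vORF lengths must be >= 1 amino acid")
        else:
            raise ValueError("annotation needs either spans or lengths")

    def vorf_lengths(self) -> list[int]:
        if self.spans is not None:
            return [aa for _, _, aa in self.spans]
        return list(self.lengths)


@dataclass
class ViralScore:
    """vORF score of one genome with its length sums (amino acids)."""

    genome_id: str
    sum_vorf: int
    sum_secorf: int
    score: float
    n_vorfs_matched: int = 0
    n_secorfs: int = 0


def vorf_score(genome: Transcript, annotation: ViralAnnotation) -> ViralScore:
    """Score a viral genome against its bona fide ORF annotation.

    All ORFs are enumerated with the three-frame scan.  A predicted ORF
    sharing frame and stop-codon position with an annotated span is a vORF
    and leaves the secORF pool (annotated CDSs may begin at an internal AUG
    relative to the scan's first-AUG convention, so matching is on the
    shared stop).  For a lengths-only annotation, each annotated length
    consumes the first predicted ORF of that amino-acid length.  The
    numerator always uses the annotated lengths; unmatched annotations
    trigger a warning, not an error.
    """
    if genome.id != annotation.genome_id:
        raise ValueError(
            f"genome id {genome.id!r} does not match annotation "
            f"{annotation.genome_id!r}"
        )
    predicted = scan_frames(genome).orfs
    consumed = [False] * len(predicted)

    if annotation.spans is not None:
        by_stop = {(o.frame, o.stop_start): i for i, o in enumerate(predicted)}
        for frame, start, aa in annotation.spans:
            stop_start = start + 3 * aa
            idx = by_stop.get((frame, stop_start))
            if idx is None:
                warnings.warn(
                    f"annotated vORF (frame={frame}, start={start}, aa={aa}) "
                    f"matches no predicted ORF in {genome.id}",
                    stacklevel=2,
                )
            else:
                consumed[idx] = True
    else:
        for aa in annotation.lengths:
            for i, o in enumerate(predicted):
                if not consumed[i] and o.aa_length == aa:
                    consumed[i] = True
                    break
            else:
                warnings.warn(
                    f"annotated vORF length {aa} aa matches no predicted ORF "
                    f"in {genome.id}",
                    stacklevel=2,
                )

    sum_vorf = sum(annotation.vorf_lengths())
    secorfs = [o.aa_length for o, used in zip(predicted, consumed) if not used]
    sum_secorf = sum(secorfs)
    n_matched = sum(consumed)
    return ViralScore(
        genome_id=genome.id,
        sum_vorf=sum_vorf,
        sum_secorf=sum_secorf,
        score=sum_vorf / (sum_vorf + sum_secorf),
        n_vorfs_matched=n_matched,
        n_secorfs=len(secorfs),
    )
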