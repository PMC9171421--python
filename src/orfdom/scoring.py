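"""Per-transcript ORF dominance and coverage scores, and transcript filters.

ORF dominance is the fraction of the longest ORF (the primary ORF, pORF)
in the summed length of all ORFs of a transcript:

    dominance = l_pORF / (l_pORF + sum_i l_secORF_i)

It lies in (0, 1]: 1 for a single-ORF transcript, 0.5 when the secondary
ORFs sum exactly to the pORF length, and it is undefined (None) for a
transcript without any ORF.  Ties for the longest ORF need no special
handling because the denominator is the sum of all ORF lengths and the
numerator is the (shared) maximum length.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

from .orfscan import OrfSet

__all__ = [
    "OrfProfile",
    "profile_transcript",
    "compute_coverage",
    "apply_noncoding_filters",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, for display alongside full precision."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class OrfProfile:
    """Per-transcript summary of ORF content and scores.

    ``dominance`` and ``coverage`` are ``None`` when the transcript has no
    ORF; such transcripts are excluded from all population statistics.
    """

    transcript_id: str
    transcript_length: int
    porf_length: int  # 0 when no ORF
    secorf_lengths: list[int] = field(default_factory=list)
    dominance: float | None = None
    coverage: float | None = None
    label: str = "unlabeled"

    @property
    def n_orfs(self) -> int:
        return (1 if self.porf_length else 0) + len(self.secorf_lengths)

    @property
    def sum_secorf(self) -> int:
        return sum(self.secorf_lengths)


def compute_coverage(porf_length: int, transcript_length: int) -> float:
    """Fraction of the transcript spanned by the pORF, stop codon included.

    ``(3 * l_pORF + 3) / transcript_length``, capped at 1.
    """
    if porf_length < 1:
        raise ValueError("coverage is undefined for a transcript without ORFs")
    return min(1.0, (3 * porf_length + 3) / transcript_length)


def profile_transcript(orf_set: OrfSet, label: str = "unlabeled") -> OrfProfile:
    """Summarize an :class:`~orfdom.orfscan.OrfSet` into an :class:`OrfProfile`."""
    lengths = sorted(orf_set.aa_lengths(), reverse=True)
    if not lengths:
        return OrfProfile(
            transcript_id=orf_set.transcript_id,
            transcript_length=orf_set.transcript_length,
            porf_length=0,
            label=label,
        )
    porf = lengths[0]
    secorfs = lengths[1:]
    dominance = porf / (porf + sum(secorfs))
    return OrfProfile(
        transcript_id=orf_set.transcript_id,
        transcript_length=orf_set.transcript_length,
        porf_length=porf,
        secorf_lengths=secorfs,
        dominance=dominance,
        coverage=compute_coverage(porf, orf_set.transcript_length),
        label=label,
    )


def apply_noncoding_filters(
    profiles: list[OrfProfile],
    min_nt: int = 200,
    min_porf_aa: int = 20,
) -> list[OrfProfile]:
    """Apply the small-RNA / short-pORF exclusions.

    Noncoding transcripts shorter than ``min_nt`` nucleotides or with a
    pORF shorter than ``min_porf_aa`` amino acids are removed (strict
    less-than on both thresholds).  Transcripts without any ORF are removed
    regardless of label; coding transcripts otherwise pass unchanged.
    Idempotent.
    """
    kept = []
    for p in profiles:
        if p.dominance is None:
            continue
        if p.label == "noncoding" and (
            p.transcript_length < min_nt or p.porf_length < min_porf_aa
        ):
            continue
        kept.append(p)
    return kept
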