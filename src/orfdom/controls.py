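"""Null-sequence controls and synthetic transcript generation.

Two randomizations serve as null models for the dominance distributions:
uniform-random sequences (each base i.i.d. over A/C/G/T, one control per
input transcript with the same length) and per-transcript shuffles that
preserve base composition exactly.  Both push ORF dominance toward low
values relative to genuine coding transcripts.

`synthesize_fixture` builds labeled test sets: coding-like transcripts
carry one long, clean ORF over at least half of their length inside random
background, while noncoding-like transcripts are uniform random.
`embed_orfs` deterministically constructs a transcript with an exact,
user-chosen set of ORF lengths per frame, for worked examples and tests.
"""

from __future__ import annotations

import math

import numpy as np

from .orfscan import STOP_CODONS, Transcript

__all__ = [
    "uniform_random_control",
    "shuffle_control",
    "synthesize_fixture",
    "embed_orfs",
]

_BASES = np.array(list("ACGT"))

# the 61 codons that are neither a stop nor reserved for it
_NON_STOP_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
)


def uniform_random_control(
    transcripts: list[Transcript], seed: int, suffix: str = "_random"
) -> list[Transcript]:
    """One length-matched control per input, bases i.i.d. uniform over ACGT."""
    rng = np.random.default_rng(seed)
    controls = []
    for t in transcripts:
        bases = "".join(rng.choice(_BASES, size=len(t.bases)))
        controls.append(Transcript(id=t.id + suffix, bases=bases, label=t.label))
    return controls


def shuffle_control(
    transcripts: list[Transcript], seed: int, suffix: str = "_shuffled"
) -> list[Transcript]:
    """Per-transcript base permutation; base composition is preserved exactly."""
    rng = np.random.default_rng(seed)
    controls = []
    for t in transcripts:
        bases = "".join(rng.permutation(list(t.bases)))
        controls.append(Transcript(id=t.id + suffix, bases=bases, label=t.label))
    return controls


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def synthesize_fixture(
    n_coding: int,
    n_noncoding: int,
    length_range: tuple[int, int] = (200, 3000),
    seed: int = 0,
) -> list[Transcript]:
    """Generate a labeled coding-like / noncoding-like transcript set.

    Coding-like transcripts embed a single stop-free ORF (AUG + non-stop
    codons + stop) spanning at least 50% of the transcript inside uniform
    random background; noncoding-like transcripts are uniform random.
    Lengths are drawn uniformly from ``length_range`` (inclusive); the
    minimum must be at least 200 nt so an ORF can be embedded and the
    transcripts clear the small-RNA filter.
    """
    lo, hi = length_range
    if lo < 200:
        raise ValueError(
            f"minimum length must be >= 200 nt to embed an ORF, got {lo}"
        )
    if hi < lo:
        raise ValueError("length_range must be (low, high) with high >= low")
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    for k in range(n_coding):
        length = int(rng.integers(lo, hi + 1))
        aa = math.ceil(0.5 * length / 3)  # ORF span >= half the transcript
        orf = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=aa - 1)) + "TAA"
        start = int(rng.integers(0, length - len(orf) + 1))
        bases = (
            _random_bases(rng, start)
            + orf
            + _random_bases(rng, length - start - len(orf))
        )
        transcripts.append(
            Transcript(id=f"synth_coding_{k:04d}", bases=bases, label="coding")
        )
    for k in range(n_noncoding):
        length = int(rng.integers(lo, hi + 1))
        transcripts.append(
            Transcript(
                id=f"synth_noncoding_{k:04d}",
                bases=_random_bases(rng, length),
                label="noncoding",
            )
        )
    return transcripts


def embed_orfs(
    orf_plan: dict[int, list[int]],
    id: str = "constructed",
    label: str = "unlabeled",
    filler: str = "C",
) -> Transcript:
    """Construct a transcript whose ORFs are exactly those in ``orf_plan``.

    ``orf_plan`` maps frame (0/1/2) to the amino-acid lengths of the ORFs
    to embed in that frame.  ORFs are laid out sequentially, separated by a
    C filler that contains no AUG or stop codon in any frame, so a scan
    recovers exactly the planned lengths.  The ORF bodies are CCC codons.
    """
    if filler not in ("C", "G"):
        # A or T filler could complete AUG/stop motifs across junctions
        raise ValueError("filler must be 'C' or 'G'")
    pieces: list[str] = []
    pos = 0
    for frame, aa_lengths in sorted(orf_plan.items()):
        if frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
        for aa in aa_lengths:
            if aa < 1:
                raise ValueError("ORF lengths must be >= 1 amino acid")
            pad = (frame - pos) % 3
            pad += 3  # keep ORFs separated even within a frame
            pieces.append(filler * pad)
            pos += pad
            orf = "ATG" + "CCC" * (aa - 1) + "TAA"
            pieces.append(orf)
            pos += len(orf)
    pieces.append(filler * 3)
    return Transcript(id=id, bases="".join(pieces), label=label)
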