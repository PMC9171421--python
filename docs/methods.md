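# Methods

## ORF model

An ORF is a segment that begins at an AUG codon and ends at the first
in-frame stop codon (UAA, UAG or UGA), read 5'→3'. All three forward
reading frames are scanned; the reverse complement is not, since ribosomes
translate mRNA 5'→3'. An AUG that reaches the 3' terminus without an
in-frame stop opens no ORF. ORF length is the amino-acid count excluding
the stop codon, so the minimal ORF (AUG directly followed by a stop) has
length 1. Only the standard genetic code is supported.

Within a frame, scanning resumes at the codon after each stop, so ORFs of
one frame are non-overlapping and internal AUGs inside an open ORF do not
start nested ORFs. This convention is consistent with the NCYM reference
layout (one ORF in one frame, three in another) and makes enumeration
deterministic; the alternative — every AUG opens an ORF ending at the
shared stop — is not implemented.

IUPAC ambiguity codes are accepted and retained; a codon containing one is
treated as a regular codon that matches neither AUG nor a stop. This keeps
real transcripts with occasional Ns scoreable without guessing at their
content. Coordinates are 0-based half-open; frames are numbered 0/1/2 by
5' offset.

## Scores

**Dominance.** `l_pORF / (l_pORF + Σ l_secORF)`, in (0, 1]. Ties for the
longest ORF need no tie-break: the numerator is the shared maximum and the
denominator the sum of all ORF lengths. Transcripts with no ORF have
undefined dominance and are excluded from every population statistic.

**Coverage.** The span of the pORF including its stop codon over the
transcript length, `(3·l_pORF + 3) / L`, capped at 1. The cap only matters
for the degenerate case of an ORF span nominally exceeding the sequence.
Whether the original convention includes the stop codon is unknowable from
the score definitions alone; the choice is isolated in `compute_coverage`
so the other convention is a one-line change.

**Filters.** Noncoding transcripts shorter than 200 nt or with a pORF
under 20 aa are removed before binning (strict less-than on both bounds);
coding transcripts are not filtered. Defaults live in
`apply_noncoding_filters(min_nt=200, min_porf_aa=20)`.

## Binned statistics

Scores are binned into ten equal-width classes [0, 0.1), …, [0.9, 1.0]
represented by their medians 0.05 … 0.95. A score on an internal edge goes
to the higher bin and 1.0 to the last bin. Because many edge values (0.1,
0.3, …) are not exactly representable as doubles, the bin index is
computed as `int(score·10 + 1e-9)`: a score that is mathematically on an
edge but stored just below it still lands in the higher bin. A genuine
score within 1e-10 below an edge would be mis-binned; at the precision of
length-ratio scores this has no practical effect.

F(x) is f/(f+g) per bin, undefined (NaN) where both frequencies are zero.
The overlap O sums the per-bin minimum of the two frequency vectors; it is
0 for disjoint and 1 for identical histograms, and requires at least 3
noncoding transcripts (`min_noncoding`, configurable) — populations with
fewer lncRNAs are too sparse for a meaningful g(x).

The F(x) regression is unweighted ordinary least squares of F(x) on the
bin medians, restricted to x ≤ `x_max` (default 0.65, where the linear
relation holds in human and mouse), to bins with defined F(x), and — when
per-bin noncoding counts are supplied — to bins holding at least
`min_bin_count` (default 5) noncoding transcripts; under-populated bins
are eliminated rather than imputed. At least 3 usable bins are required.
R² is 1 − SSres/SStot with R² = 1 when SStot = 0 (a constant fitted
exactly), keeping it in [0, 1]. Prediction clamps to [0, 1] and warns
(does not fail) above `x_max`.

**Negative selection.** h(x) is, per dominance bin, the fraction of
transcripts with Ka/Ks < 0.5 (threshold configurable). Records with
Ka > 1 or Ks > 1 are excluded first as alignment outliers; records with
Ks = 0 have an undefined ratio and are dropped with a logged warning.
Ka/Ks values are inputs — estimating them from alignments is out of scope.

**Stratification.** Any mapping of transcript id → group key yields one
dominance histogram per group (e.g. by the number of tissues a transcript
is expressed in); unknown ids are an error listing the first ten.

## Viral ORF score

For (+)ssRNA genomes encoding several bona fide ORFs (vORFs), the score is
`Σ l_vORF / (Σ l_vORF + Σ l_secORF)`. All ORFs are enumerated with the
same three-frame scan; a predicted ORF is reclassified from secORF to vORF
when it shares frame and stop-codon position with an annotated span —
matching on the stop rather than the start, because annotated CDSs may
begin at an internal AUG relative to the scan's first-AUG convention. For
lengths-only annotations, each annotated length consumes the first
predicted ORF of that amino-acid length. The numerator always uses the
annotated lengths; an annotation matching no prediction warns rather than
fails. Overlapping annotated vORFs are all counted in the numerator.
Genomes translated through frameshifting, RNA editing or alternative
initiation are out of scope.

## Null models and synthetic data

Two randomizations serve as controls, one control sequence per input
transcript with per-transcript length matching (the stronger,
deterministic pairing): uniform-random sequences (bases i.i.d. over
A/C/G/T) and composition-preserving per-transcript shuffles. Both use a
single `numpy` Generator stream per call with a mandatory seed and are
bit-reproducible.

`synthesize_fixture` emulates the qualitative structure of real
coding/noncoding sets: a coding-like transcript embeds one stop-free ORF
(AUG + codons drawn from the 61 non-stop codons + stop) spanning at least
half its length inside uniform random background; a noncoding-like
transcript is entirely uniform random. Lengths are drawn uniformly from
`length_range` (default 200–3000 nt, the lncRNA length scale; the minimum
must be ≥ 200 nt so the transcripts clear the small-RNA filter). This
generator reproduces the directional facts the method rests on — coding
transcripts right-shifted in dominance, random controls left-shifted — but
not the codon usage, GC content, UTR structure or hexamer statistics of
real transcriptomes. Tests passing on fixtures therefore validate the
formulas and the direction of the class separation, not genome-scale
frequency values, which require real RefSeq/Ensembl downloads.

`embed_orfs` deterministically builds a transcript carrying an exact,
user-chosen set of ORF lengths per frame: ORFs (AUG + CCC codons + UAA)
are laid out sequentially with a C filler that can complete no start or
stop motif in any frame, so a scan recovers exactly the planned lengths.
It is the backbone of the worked examples and of tests that need known
ORF content.

## Numerical and reporting choices

Scores are kept at full double precision internally; displayed values are
rounded half-up to 3 decimals (`round_half_up`), matching the convention
of the reference values (0.568, 0.183). Tables are TSV with headers and
`NA` for undefined entries. Unlabeled transcripts are scored but excluded
from f/g/F/O, which are defined only over the coding/noncoding classes.

Test problem sizes: oracle-equivalence runs 1,000 random sequences of
6–600 nt against a brute-force enumerator; distribution properties use a
seeded fixture of 500 coding-like + 500 noncoding-like transcripts of
200–2,000 nt, sizes at which the coding/noncoding dominance shift is
detectable at p < 0.01 by Mann–Whitney while the suite stays fast.

## Limitations

- Reverse-strand and splice-aware scanning, non-standard genetic codes and
  Ka/Ks estimation are out of scope.
- The synthetic generator does not model real sequence composition (see
  above); genome-scale published frequencies are not reproducible from it.
- The nested-ORF convention is an inference from the reference ORF layout,
  not an explicitly stated rule.
- Lengths-only vORF matching is by amino-acid length and can in principle
  consume the wrong ORF when two predicted ORFs share a length; span-based
  annotations are unambiguous and preferred.
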