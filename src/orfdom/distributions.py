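"""Population-level statistics over ORF dominance (or coverage) scores.

Scores in (0, 1] are binned into ten equal-width classes represented by
their medians x = 0.05, 0.15, ..., 0.95.  Writing f(x) and g(x) for the
relative frequencies of coding and noncoding transcripts per bin:

* protein-coding potential  F(x) = f(x) / (f(x) + g(x)),
* distribution overlap      O = sum_x min(f(x), g(x))  (O_dom or O_cov),
* negative-selection rate   h(x) = N_ns(x) / N_or(x), the per-bin fraction
  of transcripts under purifying selection (Ka/Ks < 0.5).

F(x) is approximately linear in x for x <= 0.65 in human and mouse, which
motivates the ordinary least-squares fit and prediction helpers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scoring import OrfProfile

__all__ = [
    "BIN_MEDIANS",
    "BinnedDistribution",
    "CodingPotentialTable",
    "OverlapResult",
    "RegressionFit",
    "KaKsRecord",
    "NegativeSelectionTable",
    "bin_scores",
    "bin_index",
    "coding_potential",
    "overlap_score",
    "fit_potential_regression",
    "predict_potential",
    "negative_selection_frequency",
    "stratify_distributions",
]

logger = logging.getLogger(__name__)

#: medians of the ten equal-width score classes
BIN_MEDIANS = np.round(np.arange(0.05, 1.0, 0.1), 2)

N_BINS = 10

# Tolerance absorbing binary representation error for scores that are
# mathematically on an internal bin edge (e.g. 0.3 stored as the nearest
# double just below 0.3); such scores go to the higher bin.
_EDGE_EPS = 1e-9


def bin_index(score: float) -> int:
    """Index (0-9) of the dominance/coverage class a score falls in.

    Bins are [0, 0.1), [0.1, 0.2), ..., [0.9, 1.0]; a score exactly on an
    internal edge goes to the higher bin, and 1.0 to the last bin.
    """
    if not 0.0 < score <= 1.0 + _EDGE_EPS:
        raise ValueError(f"score must lie in (0, 1], got {score}")
    return min(int(score * N_BINS + _EDGE_EPS), N_BINS - 1)


@dataclass
class BinnedDistribution:
    """Ten-bin relative-frequency histogram of dominance or coverage scores."""

    score_kind: str  # "dominance" or "coverage"
    counts: np.ndarray  # int, shape (10,)
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"counts must have shape ({N_BINS},)")
        if int(self.counts.sum()) != self.total:
            raise ValueError("counts must sum to total")

    @property
    def bin_medians(self) -> np.ndarray:
        return BIN_MEDIANS.copy()

    @property
    def freqs(self) -> np.ndarray:
        """Relative frequencies; all-NaN when the distribution is empty."""
        if self.total == 0:
            return np.full(N_BINS, np.nan)
        return self.counts / self.total


def bin_scores(scores, score_kind: str = "dominance") -> BinnedDistribution:
    """Bin scores in (0, 1] into the ten dominance/coverage classes."""
    counts = np.zeros(N_BINS, dtype=int)
    n = 0
    for s in scores:
        counts[bin_index(float(s))] += 1
        n += 1
    return BinnedDistribution(score_kind=score_kind, counts=counts, total=n)


@dataclass
class CodingPotentialTable:
    """Per-bin protein-coding potential F(x); NaN where f(x) + g(x) = 0."""

    values: np.ndarray  # float, shape (10,), NaN = undefined

    @property
    def bin_medians(self) -> np.ndarray:
        return BIN_MEDIANS.copy()


@dataclass
class OverlapResult:
    """Per-bin overlap o(x) = min(f(x), g(x)) and the overlap score O."""

    score_kind: str
    o: np.ndarray
    O: float


@dataclass
class RegressionFit:
    """OLS fit of F(x) on x over the bins at or below ``x_max``."""

    slope: float
    intercept: float
    r_squared: float
    x_max: float = 0.65
    bins_used: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class KaKsRecord:
    """Nonsynonymous/synonymous substitution rates for one transcript."""

    transcript_id: str
    ka: float
    ks: float

    def __post_init__(self) -> None:
        if self.ka < 0 or self.ks < 0:
            raise ValueError("ka and ks must be nonnegative")

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks = 0 (ratio undefined)."""
        return None if self.ks == 0 else self.ka / self.ks


@dataclass
class NegativeSelectionTable:
    """Per-bin fraction of transcripts with Ka/Ks below the selection threshold."""

    h: np.ndarray  # NaN where no transcript falls in the bin
    n_selected: np.ndarray
    n_total: np.ndarray

    @property
    def bin_medians(self) -> np.ndarray:
        return BIN_MEDIANS.copy()


def _check_same_kind(f: BinnedDistribution, g: BinnedDistribution) -> None:
    if f.score_kind != g.score_kind:
        raise ValueError(
            f"score kinds differ: {f.score_kind!r} vs {g.score_kind!r}"
        )


def coding_potential(
    f: BinnedDistribution, g: BinnedDistribution
) -> CodingPotentialTable:
    """F(x) = f(x) / (f(x) + g(x)) per bin; NaN where both frequencies are 0."""
    _check_same_kind(f, g)
    ff, gg = f.freqs, g.freqs
    values = np.full(N_BINS, np.nan)
    with np.errstate(invalid="ignore"):
        denom = ff + gg
        mask = np.isfinite(denom) & (denom > 0)
        values[mask] = ff[mask] / denom[mask]
    return CodingPotentialTable(values=values)


def overlap_score(
    f: BinnedDistribution,
    g: BinnedDistribution,
    min_noncoding: int = 3,
) -> OverlapResult:
    """Overlap O = sum_x min(f(x), g(x)) of two relative-frequency histograms.

    Raises when either distribution is empty, or when the noncoding
    distribution ``g`` holds fewer than ``min_noncoding`` transcripts
    (species with too few lncRNAs are not scored).
    """
    _check_same_kind(f, g)
    if f.total == 0 or g.total == 0:
        raise ValueError("overlap requires both distributions to be non-empty")
    if g.total < min_noncoding:
        raise ValueError(
            f"need at least {min_noncoding} noncoding transcripts, got {g.total}"
        )
    o = np.minimum(f.freqs, g.freqs)
    return OverlapResult(score_kind=f.score_kind, o=o, O=float(o.sum()))


def fit_potential_regression(
    table: CodingPotentialTable,
    bin_counts=None,
    x_max: float = 0.65,
    min_bin_count: int = 5,
) -> RegressionFit:
    """Ordinary least squares of F(x) on x over the usable bins.

    Usable bins have x <= x_max, a defined F(x) and, when per-bin noncoding
    counts are given, at least ``min_bin_count`` noncoding transcripts
    (under-populated bins are eliminated rather than imputed).
    """
    x = BIN_MEDIANS
    y = table.values
    mask = (x <= x_max + _EDGE_EPS) & np.isfinite(y)
    if bin_counts is not None:
        mask &= np.asarray(bin_counts) >= min_bin_count
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 usable bins for the fit, got {int(mask.sum())}"
        )
    xs, ys = x[mask], y[mask]
    design = np.column_stack([xs, np.ones_like(xs)])
    (slope, intercept), *_ = np.linalg.lstsq(design, ys, rcond=None)
    resid = ys - (slope * xs + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        x_max=x_max,
        bins_used=[float(v) for v in xs],
    )


def predict_potential(fit: RegressionFit, x: float) -> float:
    """Evaluate the fitted F(x) at a dominance x, clamped to [0, 1].

    The linear relation holds only up to ``fit.x_max``; evaluation above it
    warns rather than fails.
    """
    if x > fit.x_max + _EDGE_EPS:
        warnings.warn(
            f"x={x} exceeds the fitted range (x_max={fit.x_max}); "
            "the linear relation may not hold",
            stacklevel=2,
        )
    return float(min(1.0, max(0.0, fit.slope * x + fit.intercept)))


def negative_selection_frequency(
    records: list[KaKsRecord],
    profiles: list[OrfProfile],
    threshold: float = 0.5,
) -> NegativeSelectionTable:
    """h(x): per dominance bin, the fraction of transcripts with Ka/Ks < threshold.

    Records with Ka > 1 or Ks > 1 are excluded first as outliers; records
    with Ks = 0 (undefined ratio) are dropped with a logged warning.  Bins
    holding no transcripts get h(x) = NaN.
    """
    dominance = {
        p.transcript_id: p.dominance for p in profiles if p.dominance is not None
    }
    n_total = np.zeros(N_BINS, dtype=int)
    n_selected = np.zeros(N_BINS, dtype=int)
    n_zero_ks = 0
    for rec in records:
        if rec.ka > 1 or rec.ks > 1:
            continue
        if rec.transcript_id not in dominance:
            continue
        if rec.ratio is None:
            n_zero_ks += 1
            continue
        idx = bin_index(dominance[rec.transcript_id])
        n_total[idx] += 1
        if rec.ratio < threshold:
            n_selected[idx] += 1
    if n_zero_ks:
        logger.warning("dropped %d Ka/Ks records with Ks = 0", n_zero_ks)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_total > 0, n_selected / np.maximum(n_total, 1), np.nan)
    return NegativeSelectionTable(h=h, n_selected=n_selected, n_total=n_total)


def stratify_distributions(
    profiles: list[OrfProfile],
    groups: dict[str, object],
    score_kind: str = "dominance",
) -> dict[object, BinnedDistribution]:
    """One dominance (or coverage) histogram per group of transcripts.

    ``groups`` maps transcript id to an arbitrary group key (e.g. the
    number of tissues a transcript is detected in).  Ids absent from
    ``profiles`` raise an error listing the first offenders.
    """
    by_id = {p.transcript_id: p for p in profiles}
    unknown = [tid for tid in groups if tid not in by_id]
    if unknown:
        shown = ", ".join(sorted(unknown)[:10])
        raise KeyError(
            f"{len(unknown)} grouped transcript id(s) not found in profiles: {shown}"
        )
    collected: dict[object, list[float]] = {}
    for tid, key in groups.items():
        p = by_id[tid]
        score = p.dominance if score_kind == "dominance" else p.coverage
        if score is None:
            continue
        collected.setdefault(key, []).append(score)
    return {
        key: bin_scores(scores, score_kind=score_kind)
        for key, scores in collected.items()
    }
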