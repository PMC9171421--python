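"""Independent oracles, kept deliberately naive and separate from the package.

Each oracle re-derives an expected result from first principles (position
lists, direct tallies, closed-form normal equations) so the implementation
under test never checks itself.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(bases: str) -> list[tuple[int, int, int]]:
    """All (frame, start, aa_length) triples under the scan rule.

    Works from explicit per-frame position lists of AUGs and stops: the
    next ORF opens at the first AUG at or after the cursor and closes at
    the first stop after it; the cursor then jumps past that stop.
    """
    n = len(bases)
    triples = []
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        atg_positions = [i for i in codon_starts if bases[i : i + 3] == "ATG"]
        stop_positions = [i for i in codon_starts if bases[i : i + 3] in STOPS]
        cursor = frame
        for a in atg_positions:
            if a < cursor:
                continue  # inside the previous ORF: no nested ORFs
            downstream = [s for s in stop_positions if s > a]
            if not downstream:
                break
            s = min(downstream)
            triples.append((frame, a, (s - a) // 3))
            cursor = s + 3
    return triples


def tally_bins(scores) -> np.ndarray:
    """Direct per-bin tally of scores in (0,1] over [0,.1),...,[0.9,1]."""
    counts = np.zeros(10, dtype=int)
    for s in scores:
        for k in range(10):
            lo, hi = k / 10, (k + 1) / 10
            # match on the exact rational edges, higher bin on a tie
            if (lo <= s < hi) or (k == 9 and s == 1.0):
                counts[k] += 1
                break
    return counts


def ols_closed_form(x, y) -> tuple[float, float]:
    """Slope and intercept from the normal equations, written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
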