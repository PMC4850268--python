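"""Cross-factor and cross-genotype peak-set comparison.

Two factors share a regulon when their peaks fall at the same genomic
positions (within a small tolerance, since summits live on a 25-bp grid)
and their significance values co-vary across targets.  Codependent
binding is read as presence/absence: a wild-type peak with no counterpart
in the partner-deletion strain depends on the partner.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "MatchedPeak",
    "DependenceCall",
    "match_peak_sets",
    "significance_correlation",
    "codependence",
    "dependent_fraction",
    "match_table",
]

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 50
APV_FLOOR = 1e-300


@dataclass
class MatchedPeak:
    status: str  # "shared" | "a_only" | "b_only"
    pos_a: int | None = None
    pos_b: int | None = None
    idx_a: int | None = None
    idx_b: int | None = None

    @property
    def offset(self) -> int | None:
        if self.pos_a is None or self.pos_b is None:
            return None
        return self.pos_b - self.pos_a


@dataclass
class DependenceCall:
    peak_pos: int
    present_wt: bool
    present_mutant: bool

    @property
    def call(self) -> str:
        if not self.present_wt:
            return "absent"
        return "independent" if self.present_mutant else "dependent"


def _positions(peaks) -> np.ndarray:
    if hasattr(peaks, "positions"):
        return np.asarray(peaks.positions, dtype=np.int64)
    return np.asarray(peaks, dtype=np.int64)


def match_peak_sets(a, b, tolerance: int = DEFAULT_TOLERANCE) -> list[MatchedPeak]:
    """Greedy globally-closest matching of two summit-position sets.

    Candidate pairs within ``tolerance`` bases are taken in order of
    increasing |offset| (ties by position), each peak used at most once;
    leftovers become ``a_only`` / ``b_only``.
    """
    pos_a, pos_b = _positions(a), _positions(b)
    candidates = []
    for i, pa in enumerate(pos_a):
        lo = np.searchsorted(pos_b, pa - tolerance)
        hi = np.searchsorted(pos_b, pa + tolerance, side="right")
        for j in range(lo, hi):
            candidates.append((abs(int(pos_b[j]) - int(pa)), int(pa), i, j))
    candidates.sort()
    used_a = np.zeros(pos_a.size, dtype=bool)
    used_b = np.zeros(pos_b.size, dtype=bool)
    matches: list[MatchedPeak] = []
    for _, _, i, j in candidates:
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        matches.append(
            MatchedPeak("shared", int(pos_a[i]), int(pos_b[j]), i, j)
        )
    for i in np.flatnonzero(~used_a):
        matches.append(MatchedPeak("a_only", pos_a=int(pos_a[i]), idx_a=int(i)))
    for j in np.flatnonzero(~used_b):
        matches.append(MatchedPeak("b_only", pos_b=int(pos_b[j]), idx_b=int(j)))
    matches.sort(key=lambda m: m.pos_a if m.pos_a is not None else m.pos_b)
    return matches


def significance_correlation(matched, apv_a, apv_b) -> float:
    """Spearman rank correlation of -log10(apv) over shared peaks.

    ``apv_a``/``apv_b`` are indexed by each set's peak order; adjusted
    p-values are floored at 1e-300 before the log transform.
    """
    apv_a = np.asarray(apv_a, dtype=float)
    apv_b = np.asarray(apv_b, dtype=float)
    shared = [m for m in matched if m.status == "shared"]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared peaks for a rank correlation; got {len(shared)}"
        )
    x = -np.log10(np.maximum(apv_a[[m.idx_a for m in shared]], APV_FLOOR))
    y = -np.log10(np.maximum(apv_b[[m.idx_b for m in shared]], APV_FLOOR))
    rho = spearmanr(x, y).statistic
    return float(rho)


def codependence(
    peaks_wt, peaks_mutant, tolerance: int = DEFAULT_TOLERANCE
) -> list[DependenceCall]:
    """Presence/absence of each wild-type peak in the mutant's peak set."""
    pos_wt = _positions(peaks_wt)
    pos_mut = _positions(peaks_mutant)
    calls = []
    for pw in pos_wt:
        if pos_mut.size:
            j = np.searchsorted(pos_mut, pw)
            nearest = min(
                abs(int(pos_mut[k]) - int(pw))
                for k in (j - 1, j)
                if 0 <= k < pos_mut.size
            )
            present = nearest <= tolerance
        else:
            present = False
        calls.append(DependenceCall(int(pw), True, present))
    frac = dependent_fraction(calls)
    logger.info(
        "codependence: %d/%d wild-type peaks absent from mutant (fraction %.3f)",
        sum(c.call == "dependent" for c in calls),
        len(calls),
        frac,
    )
    return calls


def dependent_fraction(calls) -> float:
    """Fraction of wild-type peaks with no mutant counterpart."""
    wt = [c for c in calls if c.present_wt]
    if not wt:
        return float("nan")
    return sum(c.call == "dependent" for c in wt) / len(wt)


def match_table(matched) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "status": [m.status for m in matched],
            "pos_a": [m.pos_a for m in matched],
            "pos_b": [m.pos_b for m in matched],
            "offset": [m.offset for m in matched],
        }
    )
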