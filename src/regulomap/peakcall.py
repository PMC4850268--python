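"""Per-bin significance testing and peak calling.

Each 25-bp bin is tested for IP enrichment over the matched input with a
one-sided Poisson upper-tail test; the expected IP count is the
library-scaled input rate, floored at ``lambda_min`` so zero-input bins
cannot produce spurious significance.  Raw p-values are corrected
genome-wide by the Hochberg step-up procedure, which controls the
family-wise error rate; bins with adjusted p-value (apv) below ``alpha``
(1e-4 by default) are significant and are merged into peaks.  Peaks whose
summit coincides with a significant bin in the negative-control
immunoprecipitation are antibody-background artifacts and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .tracks import BinnedTrack, library_scale, local_normalize, smooth_rate, diff_track

__all__ = [
    "BinStats",
    "Peak",
    "PeakSet",
    "bin_pvalues",
    "hochberg_adjust",
    "compute_bin_stats",
    "call_peaks",
    "significant_bins",
    "exclude_control_peaks",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4
DEFAULT_LAMBDA_MIN = 0.25


def bin_pvalues(
    ip: BinnedTrack,
    input_track: BinnedTrack,
    *,
    lambda_min: float = DEFAULT_LAMBDA_MIN,
    scale: float | None = None,
) -> np.ndarray:
    """One-sided Poisson upper-tail p-value per bin.

    ``p_b = P(Poisson(e_b) >= ip_b)`` with expectation
    ``e_b = max(scale * input_b, lambda_min)``.  ``scale`` defaults to the
    library-size ratio of the two tracks; pass it explicitly when
    ``input_track`` is a smoothed rate rather than raw counts.
    """
    if ip.bin_size != input_track.bin_size or ip.genome_length != input_track.genome_length:
        raise ValueError("IP and input tracks are on different bin grids")
    s = library_scale(ip, input_track) if scale is None else scale
    e = np.maximum(s * input_track.counts, lambda_min)
    # P(X >= k) = sf(k - 1); fractional counts round up (conservative).
    k = np.ceil(ip.counts)
    return poisson.sf(k - 1, e)


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in the original order.

    With sorted p(1) <= ... <= p(m), ``adj(i) = min(1, min_{j>=i}
    (m - j + 1) * p(j))``.  Monotone in the input ranks.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sp = p[order]
    scaled = (m - np.arange(m)) * sp
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return adj


@dataclass
class BinStats:
    """Per-bin statistics for one IP/input dataset: diff, p, apv, pk."""

    sample_id: str
    genome_length: int
    bin_size: int
    diff: np.ndarray
    pval: np.ndarray
    apv: np.ndarray
    alpha: float = DEFAULT_ALPHA

    @property
    def n_bins(self) -> int:
        return self.diff.shape[0]

    @property
    def pk(self) -> np.ndarray:
        return self.apv < self.alpha

    @property
    def bin_centers(self) -> np.ndarray:
        starts = np.arange(self.n_bins, dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, self.genome_length)
        return (starts + 1 + ends) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "pos": self.bin_centers,
                "diff": self.diff,
                "pval": self.pval,
                "apv": self.apv,
                "pk": np.where(self.pk, "TRUE", "FALSE"),
            }
        )


def compute_bin_stats(
    ip: BinnedTrack,
    input_track: BinnedTrack,
    *,
    lnorm_window_bins: int = 401,
    rate_window_bins: int = 41,
    alpha: float = DEFAULT_ALPHA,
    lambda_min: float = DEFAULT_LAMBDA_MIN,
) -> BinStats:
    """Full per-dataset stage: diff statistic plus adjusted significance.

    The Poisson expectation uses the locally averaged input rate
    (:func:`~regulomap.tracks.smooth_rate`) scaled by the library-size
    ratio of the raw tracks; the diff statistic uses the local-normalized
    tracks.
    """
    s = library_scale(ip, input_track)
    rate = smooth_rate(input_track, rate_window_bins)
    pval = bin_pvalues(ip, rate, scale=s, lambda_min=lambda_min)
    apv = hochberg_adjust(pval)
    ip_n = local_normalize(ip, lnorm_window_bins)
    in_n = local_normalize(input_track, lnorm_window_bins)
    diff = diff_track(ip_n, in_n)
    return BinStats(
        sample_id=ip.sample_id,
        genome_length=ip.genome_length,
        bin_size=ip.bin_size,
        diff=diff,
        pval=pval,
        apv=apv,
        alpha=alpha,
    )


@dataclass
class Peak:
    """One called binding event.

    ``pos`` is the 1-based center of the summit bin (the member bin with
    the largest diff across test datasets, leftmost on ties).  ``stats``
    maps dataset id -> {"diff", "apv", "pk"}; diff and apv are taken at the
    summit bin, pk is TRUE iff that dataset has any significant bin in the
    run.
    """

    pos: int
    first_bin: int
    last_bin: int
    summit_bin: int
    stats: dict = field(default_factory=dict)


@dataclass
class PeakSet:
    peaks: list
    alpha: float
    dataset_ids: list
    genome_length: int
    bin_size: int

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.pos for p in self.peaks], dtype=np.int64)

    @property
    def summit_bins(self) -> np.ndarray:
        return np.array([p.summit_bin for p in self.peaks], dtype=np.int64)

    def summit_apv(self, dataset_id: str) -> np.ndarray:
        return np.array([p.stats[dataset_id]["apv"] for p in self.peaks], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            row = {"Pos": p.pos}
            for ds in self.dataset_ids:
                st = p.stats[ds]
                row[f"{ds}_diff"] = st["diff"]
                row[f"{ds}_apv"] = st["apv"]
                row[f"{ds}_pk"] = "TRUE" if st["pk"] else "FALSE"
            rows.append(row)
        cols = ["Pos"] + [
            f"{ds}_{c}" for ds in self.dataset_ids for c in ("diff", "apv", "pk")
        ]
        return pd.DataFrame(rows, columns=cols)


def call_peaks(
    stats: Mapping[str, BinStats],
    alpha: float = DEFAULT_ALPHA,
    max_gap_bins: int = 1,
) -> PeakSet:
    """Merge bins significant in ANY test dataset into peaks.

    Significant bins are partitioned into runs, tolerating gaps of at most
    ``max_gap_bins`` non-significant bins inside a run; each run becomes
    one peak.
    """
    if not stats:
        raise ValueError("at least one test dataset is required")
    items = list(stats.items())
    first = items[0][1]
    for _, st in items[1:]:
        if st.n_bins != first.n_bins or st.bin_size != first.bin_size:
            raise ValueError("datasets are on different bin grids")
    dataset_ids = [k for k, _ in items]
    sig_any = np.zeros(first.n_bins, dtype=bool)
    for _, st in items:
        sig_any |= st.apv < alpha
    sig_idx = np.flatnonzero(sig_any)
    peaks: list[Peak] = []
    if sig_idx.size:
        # split runs where the gap between consecutive significant bins
        # exceeds max_gap_bins
        breaks = np.flatnonzero(np.diff(sig_idx) > max_gap_bins + 1) + 1
        centers = first.bin_centers
        for run in np.split(sig_idx, breaks):
            lo, hi = int(run[0]), int(run[-1])
            span = np.arange(lo, hi + 1)
            max_diff = np.max(
                np.vstack([st.diff[span] for _, st in items]), axis=0
            )
            summit = int(span[int(np.argmax(max_diff))])  # leftmost on ties
            stats_map = {}
            for ds, st in items:
                stats_map[ds] = {
                    "diff": float(st.diff[summit]),
                    "apv": float(st.apv[summit]),
                    "pk": bool(np.any(st.apv[span] < alpha)),
                }
            peaks.append(
                Peak(
                    pos=int(centers[summit]),
                    first_bin=lo,
                    last_bin=hi,
                    summit_bin=summit,
                    stats=stats_map,
                )
            )
    return PeakSet(
        peaks=peaks,
        alpha=alpha,
        dataset_ids=dataset_ids,
        genome_length=first.genome_length,
        bin_size=first.bin_size,
    )


def significant_bins(stats: BinStats, alpha: float | None = None) -> np.ndarray:
    """Indices of bins with apv below alpha (defaults to the stats' alpha)."""
    a = stats.alpha if alpha is None else alpha
    return np.flatnonzero(stats.apv < a)


def exclude_control_peaks(
    peaks: PeakSet,
    control_sig_bins,
    tolerance_bins: int = 2,
) -> PeakSet:
    """Drop peaks whose summit bin lies near a control-significant bin.

    Models the removal of antibody-background peaks: any peak whose summit
    is within ``tolerance_bins`` of a bin significant in the
    negative-control IP is discarded (with a log line per removal).
    """
    control = np.sort(np.asarray(control_sig_bins, dtype=np.int64))
    if control.size == 0:
        return peaks
    kept = []
    for p in peaks:
        j = np.searchsorted(control, p.summit_bin)
        nearest = min(
            abs(int(control[k]) - p.summit_bin)
            for k in (j - 1, j)
            if 0 <= k < control.size
        )
        if nearest <= tolerance_bins:
            logger.info(
                "excluding peak at %d: control-significant bin within %d bins",
                p.pos,
                nearest,
            )
        else:
            kept.append(p)
    return PeakSet(
        peaks=kept,
        alpha=peaks.alpha,
        dataset_ids=peaks.dataset_ids,
        genome_length=peaks.genome_length,
        bin_size=peaks.bin_size,
    )
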