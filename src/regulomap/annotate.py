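"""Peak-to-gene assignment and the 300-bp upstream filter.

A peak is assigned to the nearest gene whose start codon lies downstream
of the peak in that gene's own orientation (start coordinate for + genes,
end coordinate for - genes), provided the peak does not fall inside the
gene body.  Divergent promoters therefore resolve to the closer start
codon.  Peaks more than 300 bases upstream of the nearest start codon are
flagged as not retained and dropped from the regulon.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

__all__ = [
    "PeakAnnotation",
    "flanking_genes",
    "assign_target",
    "annotate_peaks",
    "filter_retained",
]

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_MAX = 300


@dataclass
class PeakAnnotation:
    peak_pos: int
    left_gene: str | None
    right_gene: str | None
    target_gene: str | None
    distance: int | None
    target_start: int | None
    target_end: int | None
    target_strand: str | None
    product: str | None
    retained: bool


def _check_sorted(genes: pd.DataFrame) -> None:
    starts = genes["start"].to_numpy()
    if starts.size and np.any(np.diff(starts) < 0):
        raise ValueError("genes must be sorted by start")


def flanking_genes(
    peak_pos: int, genes: pd.DataFrame
) -> tuple[str | None, str | None]:
    """Gene immediately left of (end < pos) and right of (start > pos) a peak.

    A gene containing the peak is reported as both flanks.  Assumes
    non-overlapping genes sorted by start.
    """
    if len(genes) == 0:
        return None, None
    _check_sorted(genes)
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    ids = genes["gene_id"].to_numpy()
    k = np.searchsorted(starts, peak_pos, side="right") - 1
    if k >= 0 and ends[k] >= peak_pos:  # containment
        return ids[k], ids[k]
    i = np.searchsorted(ends, peak_pos, side="left") - 1  # greatest end < pos
    j = np.searchsorted(starts, peak_pos, side="right")  # least start > pos
    left = ids[i] if i >= 0 else None
    right = ids[j] if j < len(ids) else None
    return left, right


def assign_target(
    peak_pos: int,
    genes: pd.DataFrame,
    distance_max: int = DEFAULT_DISTANCE_MAX,
) -> PeakAnnotation:
    """Assign the downstream target gene and start-codon distance.

    Candidates are genes for which the peak is upstream of the start codon
    in the gene's orientation and outside the gene body; the minimal
    start-codon distance wins, ties broken toward the + strand and then
    the lexicographically smaller gene id.  ``retained`` is true when a
    target exists at distance <= ``distance_max``.
    """
    left, right = flanking_genes(peak_pos, genes)
    best = None  # (distance, strand_rank, gene_id, row)
    for row in genes.itertuples(index=False):
        if row.start <= peak_pos <= row.end:
            continue
        if row.strand == "+":
            if row.start >= peak_pos:
                cand = (row.start - peak_pos, 0, row.gene_id, row)
            else:
                continue
        else:
            if row.end <= peak_pos:
                cand = (peak_pos - row.end, 1, row.gene_id, row)
            else:
                continue
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return PeakAnnotation(
            peak_pos, left, right, None, None, None, None, None, None, False
        )
    distance, _, gene_id, row = best
    return PeakAnnotation(
        peak_pos=peak_pos,
        left_gene=left,
        right_gene=right,
        target_gene=gene_id,
        distance=int(distance),
        target_start=int(row.start),
        target_end=int(row.end),
        target_strand=row.strand,
        product=row.product,
        retained=distance <= distance_max,
    )


def annotate_peaks(
    peak_positions,
    genes: pd.DataFrame,
    distance_max: int = DEFAULT_DISTANCE_MAX,
) -> pd.DataFrame:
    """Annotate every peak position; returns the Table-S1-style frame.

    Columns: peak_pos, left_gene, right_gene, target_gene, distance,
    target_start, target_end, target_strand (+1/-1), product, retained.
    """
    _check_sorted(genes)
    rows = []
    for pos in peak_positions:
        a = assign_target(int(pos), genes, distance_max)
        rows.append(
            {
                "peak_pos": a.peak_pos,
                "left_gene": a.left_gene,
                "right_gene": a.right_gene,
                "target_gene": a.target_gene,
                "distance": a.distance,
                "target_start": a.target_start,
                "target_end": a.target_end,
                "target_strand": {"+": 1, "-": -1}.get(a.target_strand),
                "product": a.product,
                "retained": a.retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_pos",
            "left_gene",
            "right_gene",
            "target_gene",
            "distance",
            "target_start",
            "target_end",
            "target_strand",
            "product",
            "retained",
        ],
    )


def filter_retained(annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep peaks with a target within the distance cutoff (order preserved)."""
    kept = annotations.loc[annotations["retained"].astype(bool)].reset_index(drop=True)
    removed = len(annotations) - len(kept)
    if removed:
        logger.info("distance filter removed %d of %d peaks", removed, len(annotations))
    return kept
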