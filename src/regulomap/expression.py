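"""Time-course expression: normalization, fold changes, target classes.

The expression module consumes already-normalized log2 abundance matrices
(genes x timepoints, one per strain).  Per-gene normalization subtracts
each gene's mean over all strains and timepoints jointly, so wild-type and
mutant levels stay on a common, comparable scale.  Mutant-minus-wild-type
log2 fold changes at the sporulation-onset timepoints (16 h and later)
classify each gene: expression that falls more than 2-fold in the mutant
means the factor activates the gene; a rise of more than 2-fold means the
factor represses it.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "per_gene_normalize",
    "logfc_profile",
    "classify_targets",
    "integrate",
    "read_expression_tsv",
    "write_expression_tsv",
]

logger = logging.getLogger(__name__)

ASSESSED_TIMEPOINTS = (16.0, 18.0, 20.0)
LOG2FC_THRESHOLD = 1.0  # |log2 FC| >= 1, i.e. the 2-fold rule


@dataclass
class ExpressionMatrix:
    """Log2 abundance per gene x timepoint for one strain.

    ``data`` has gene ids as the index and timepoints (hours, float) as
    columns, strictly ascending.
    """

    data: pd.DataFrame
    strain: str = ""

    def __post_init__(self) -> None:
        cols = [float(c) for c in self.data.columns]
        if cols != sorted(cols) or len(set(cols)) != len(cols):
            raise ValueError("timepoints must be strictly ascending")
        self.data = self.data.copy()
        self.data.columns = cols
        if self.data.isna().any().any():
            raise ValueError("expression matrix has missing values")

    @property
    def genes(self) -> list:
        return self.data.index.tolist()

    @property
    def timepoints(self) -> list:
        return list(self.data.columns)


def _check_aligned(mats: Mapping[str, ExpressionMatrix]) -> None:
    items = list(mats.items())
    ref_name, ref = items[0]
    ref_genes = set(ref.genes)
    for name, m in items[1:]:
        missing = ref_genes.symmetric_difference(m.genes)
        if missing:
            raise ValueError(
                f"strains {ref_name!r} and {name!r} disagree on genes: "
                f"{sorted(missing)[:10]}"
            )
        if m.timepoints != ref.timepoints:
            raise ValueError(f"strains {ref_name!r} and {name!r} disagree on timepoints")


def per_gene_normalize(
    mats: Mapping[str, ExpressionMatrix],
) -> dict[str, ExpressionMatrix]:
    """Subtract each gene's pooled mean (all strains and timepoints jointly).

    After normalization the pooled per-gene mean is zero, so profiles from
    different strains are directly superimposable.
    """
    if not mats:
        raise ValueError("at least one strain is required")
    _check_aligned(mats)
    genes = next(iter(mats.values())).genes
    pooled = pd.concat([m.data.loc[genes] for m in mats.values()], axis=1)
    gene_means = pooled.mean(axis=1)
    return {
        name: ExpressionMatrix(m.data.sub(gene_means, axis=0), strain=m.strain)
        for name, m in mats.items()
    }


def logfc_profile(mutant: ExpressionMatrix, wt: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene, per-timepoint mutant-minus-wild-type log2 fold change."""
    _check_aligned({"wt": wt, "mutant": mutant})
    return mutant.data.loc[wt.genes] - wt.data


def classify_targets(
    logfc: pd.DataFrame,
    assessed_timepoints: Iterable[float] = ASSESSED_TIMEPOINTS,
    threshold: float = LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Classify each gene from its assessed-timepoint fold changes.

    ``activated``: expression drops >= 2-fold in the mutant at any
    assessed timepoint (the factor activates the gene); ``repressed``:
    rises >= 2-fold; if both thresholds are crossed the larger magnitude
    wins (an exact tie stays unclassified, keeping the classification
    antisymmetric under sign flip); otherwise ``unclassified``.
    """
    assessed = [float(t) for t in assessed_timepoints]
    missing = [t for t in assessed if t not in logfc.columns]
    if missing:
        raise ValueError(f"assessed timepoints not in matrix: {missing}")
    sub = logfc[assessed]
    minv = sub.min(axis=1)
    maxv = sub.max(axis=1)
    act = minv <= -threshold
    rep = maxv >= threshold
    cls = np.full(len(logfc), "unclassified", dtype=object)
    only_act = act & ~rep
    only_rep = rep & ~act
    both = act & rep
    cls[only_act] = "activated"
    cls[only_rep] = "repressed"
    cls[both & (minv.abs() > maxv)] = "activated"
    cls[both & (maxv > minv.abs())] = "repressed"
    out = pd.DataFrame({"class": cls}, index=logfc.index)
    for t in assessed:
        out[f"logfc_{t:g}h"] = sub[t]
    return out


def integrate(
    annotated_peaks: pd.DataFrame,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """Left-join retained peak annotations with expression target classes.

    Peak rows whose target gene has no classified expression keep
    ``class == 'unclassified'``.  Activated/repressed counts are logged.
    """
    joined = annotated_peaks.merge(
        classes, how="left", left_on="target_gene", right_index=True
    )
    joined["class"] = joined["class"].fillna("unclassified")
    counts = joined["class"].value_counts()
    logger.info(
        "integrated %d peaks: %d activated, %d repressed, %d unclassified",
        len(joined),
        counts.get("activated", 0),
        counts.get("repressed", 0),
        counts.get("unclassified", 0),
    )
    return joined


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.columns = [f"{c:g}" for c in out.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path, strain: str = "") -> ExpressionMatrix:
    data = pd.read_csv(path, sep="\t", index_col="gene_id")
    data.columns = [float(c) for c in data.columns]
    return ExpressionMatrix(data, strain=strain)
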