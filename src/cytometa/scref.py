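"""Cell-type reference statistics from a clustered single-cell/nucleus matrix.

Given a cells x genes matrix with cluster labels and a cluster -> cell
type annotation, this module derives (a) per-type average expression on
the linear scale, (b) cluster marker genes under a joint detection-rate
and log-fold-change rule, and (c) a specificity matrix: each gene's
expression share per cell type, the statistic averaged by the
expression-weighted cell-type enrichment bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusteredCellMatrix", "average_by_type", "find_markers", "specificity"]

_PSEUDO = 1e-9


@dataclass
class ClusteredCellMatrix:
    """Cells x genes expression with cluster labels and type annotations.

    ``expr`` may hold normalized counts (``log_scale=False``) or logged
    values (``log_scale=True``; un-logged internally where linear-scale
    means are required).  Every cell must have a cluster label and every
    cluster exactly one cell-type annotation.
    """

    expr: pd.DataFrame
    clusters: pd.Series
    annotation: dict[str, str] = field(default_factory=dict)
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.clusters.index.equals(self.expr.index):
            self.clusters = self.clusters.reindex(self.expr.index)
        if self.clusters.isna().any():
            raise ValueError("every cell needs a cluster label")
        missing = set(self.clusters.unique()) - set(self.annotation)
        if self.annotation and missing:
            raise ValueError(f"clusters without a cell-type annotation: {sorted(missing)}")
        if not self.annotation:
            self.annotation = {c: c for c in self.clusters.unique()}

    @property
    def linear(self) -> pd.DataFrame:
        return 2.0**self.expr - 1.0 if self.log_scale else self.expr

    @property
    def cell_types(self) -> pd.Series:
        return self.clusters.map(self.annotation)


def average_by_type(m: ClusteredCellMatrix) -> pd.DataFrame:
    """Arithmetic mean expression per annotated cell type (linear scale)."""
    types = m.cell_types
    counts = types.value_counts()
    if (counts < 1).any():
        raise ValueError("annotated cell type with zero cells")
    avg = m.linear.groupby(types).mean()
    avg.index.name = "cell_type"
    return avg.sort_index()


def find_markers(
    m: ClusteredCellMatrix,
    min_frac: float = 0.30,
    min_lfc: float = 0.5,
    log_base: float = np.e,
) -> dict[str, list[str]]:
    """Marker genes per cluster.

    A gene is a marker of cluster c iff it is detected (value > 0) in at
    least ``min_frac`` of c's cells AND the log fold change of its mean
    in c over its mean in all other cells exceeds ``min_lfc``.  The fold
    change is a ratio of linear-scale means with a small pseudo-count;
    the log base defaults to natural log and is configurable.
    """
    labels = m.clusters
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to contrast")
    linear = m.linear
    detected = (linear > 0).groupby(labels).mean()  # clusters x genes
    means = linear.groupby(labels).mean()
    n_cells = labels.value_counts()

    markers: dict[str, list[str]] = {}
    total_sum = linear.sum(axis=0)
    for c in clusters:
        other_mean = (total_sum - means.loc[c] * n_cells[c]) / (len(labels) - n_cells[c])
        lfc = (np.log(means.loc[c] + _PSEUDO) - np.log(other_mean + _PSEUDO)) / np.log(log_base)
        hit = (detected.loc[c] >= min_frac) & (lfc > min_lfc)
        markers[str(c)] = sorted(linear.columns[hit.to_numpy()])
    return markers


def specificity(avg: pd.DataFrame) -> pd.DataFrame:
    """Expression share per cell type: s[t, g] = avg[t, g] / sum_t' avg[t', g].

    Genes with zero total expression are dropped (their share is
    undefined); each retained gene's column sums to 1.
    """
    if (avg.to_numpy() < 0).any():
        raise ValueError("average expression must be non-negative")
    total = avg.sum(axis=0)
    keep = total > 0
    dropped = sorted(avg.columns[~keep])
    if dropped:
        import warnings

        warnings.warn(f"dropping {len(dropped)} all-zero genes from specificity", stacklevel=2)
    s = avg.loc[:, keep].div(total[keep], axis=1)
    s.attrs["dropped_genes"] = dropped
    return s
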