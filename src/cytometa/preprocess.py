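"""Cross-study preprocessing: probe collapse, quantile normalization, sex imputation.

Merging multi-platform microarray studies needs three steps before any
joint modeling: (1) collapsing multiple probes per gene to one row,
keeping the probe with maximal variance + connectivity; (2) quantile
normalization of the merged matrix, aware of genes missing on some
platforms; (3) imputing missing sex labels from Y-linked gene
expression, by 2-means clustering of samples on the most variable
Y-linked genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

__all__ = ["collapse_probes", "quantile_normalize", "impute_gender", "GenderCall"]


def collapse_probes(matrix: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene.

    For genes measured by several probes, the kept probe maximizes
    ``rank(variance across samples) + rank(connectivity)``, where
    connectivity is the sum of absolute Pearson correlations with the
    gene's other probes (0 for singleton probes).  Rank ties are broken
    by keeping the lexicographically smallest probe id.  Probes without
    a map entry are dropped.  The output is indexed by gene id.
    """
    if not probe_map:
        raise ValueError("probe map is empty")
    present = [p for p in matrix.index if p in probe_map]
    if not present:
        raise ValueError("no probe of the matrix appears in the probe map")

    sub = matrix.loc[present]
    genes = pd.Series({p: probe_map[p] for p in present})
    rows: dict[str, str] = {}  # gene -> winning probe
    for gene, probes in genes.groupby(genes).groups.items():
        probes = sorted(probes)
        if len(probes) == 1:
            rows[str(gene)] = probes[0]
            continue
        block = sub.loc[probes]
        var = block.var(axis=1, ddof=1)
        corr = np.corrcoef(block.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        conn = pd.Series(np.abs(corr).sum(axis=1), index=probes)
        score = var.rank(method="average") + conn.rank(method="average")
        best = score[score == score.max()].index.min()
        rows[str(gene)] = best

    out = sub.loc[[rows[g] for g in sorted(rows)]].copy()
    out.index = pd.Index(sorted(rows), name="gene")
    return out


def _reference_distribution(matrix: np.ndarray) -> np.ndarray:
    """Mean quantile function across columns, on a grid of length
    max observed count.  For complete equal-length columns this is the
    across-column mean of order statistics."""
    n_obs = (~np.isnan(matrix)).sum(axis=0)
    n_ref = int(n_obs.max())
    probs = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    qs = []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        qs.append(np.quantile(col[~np.isnan(col)], probs))
    return np.mean(qs, axis=0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a genes x samples matrix.

    Missing values (genes absent on a study's platform) are excluded
    from that column's quantile computation and remain missing.  For
    complete data every column's sorted values become the across-column
    mean of order statistics; within-column ties receive the mean of the
    target values at their tied ranks.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    arr = matrix.to_numpy(dtype=float)
    ref = _reference_distribution(arr)
    n_ref = ref.size
    out = np.full_like(arr, np.nan)
    for j in range(arr.shape[1]):
        obs = ~np.isnan(arr[:, j])
        vals = arr[obs, j]
        n = vals.size
        if n == 0:
            continue
        # target value for each integer rank of this column
        pos = np.linspace(0.0, n_ref - 1.0, n) if n > 1 else np.array([(n_ref - 1) / 2.0])
        targets_sorted = np.interp(pos, np.arange(n_ref), ref)
        order = np.argsort(vals, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = targets_sorted
        # ties: average the targets over each tied group's occupied ranks
        ranks = rankdata(vals, method="average")
        if np.unique(vals).size < n:
            df = pd.Series(mapped).groupby(pd.Series(vals)).transform("mean")
            mapped = df.to_numpy()
            del ranks
        out[obs, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class GenderCall:
    """Per-sample sex labels with a separation-confidence flag."""

    labels: pd.Series
    low_confidence: bool
    used_genes: list[str]


def impute_gender(
    matrix: pd.DataFrame,
    y_genes: list[str],
    variable_fraction: float = 0.75,
    known: pd.Series | None = None,
) -> GenderCall:
    """Label samples F/M from Y-linked gene expression.

    Keeps the top ``variable_fraction`` of present Y-linked genes by
    variance, 2-means clusters the samples on them, and labels the
    cluster with lower mean Y expression as female.  Samples whose sex
    is already annotated in ``known`` (values "F"/"M") are returned
    unchanged.  When the two clusters' mean Y expression differs by less
    than 10% of the pooled within-cluster standard deviation (or the
    samples are indistinguishable), the call is flagged low-confidence.
    """
    present = [g for g in y_genes if g in matrix.index]
    if len(present) < 2:
        raise ValueError("need at least 2 Y-linked genes present in the matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    sub = matrix.loc[present]
    n_keep = max(2, int(np.ceil(variable_fraction * len(present))))
    keep = sub.var(axis=1, ddof=1).sort_values(ascending=False).index[:n_keep]
    ydata = sub.loc[keep].to_numpy().T  # samples x genes
    sample_means = ydata.mean(axis=1)

    if np.ptp(sample_means) == 0.0:
        labels = pd.Series("F", index=matrix.columns)
        low_conf = True
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(ydata)
        lab = km.labels_
        if len(np.unique(lab)) < 2:
            raise ValueError("degenerate clustering: a cluster is empty")
        m0, m1 = sample_means[lab == 0].mean(), sample_means[lab == 1].mean()
        female_cluster = 0 if m0 < m1 else 1
        labels = pd.Series(
            np.where(lab == female_cluster, "F", "M"), index=matrix.columns
        )
        sd0 = sample_means[lab == 0].std(ddof=1) if (lab == 0).sum() > 1 else 0.0
        sd1 = sample_means[lab == 1].std(ddof=1) if (lab == 1).sum() > 1 else 0.0
        pooled_sd = np.sqrt(
            (
                ((lab == 0).sum() - 1) * sd0**2 + ((lab == 1).sum() - 1) * sd1**2
            )
            / max((lab == 0).sum() + (lab == 1).sum() - 2, 1)
        )
        low_conf = bool(abs(m0 - m1) < 0.1 * pooled_sd) or pooled_sd == 0.0 and m0 == m1

    if known is not None:
        for s, v in known.items():
            if s in labels.index and v in ("F", "M"):
                labels.loc[s] = v
    return GenderCall(labels=labels, low_confidence=low_conf, used_genes=[str(g) for g in keep])
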