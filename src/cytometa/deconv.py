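"""Marker-guided, reference-light cell-type deconvolution of bulk expression.

Proportions are estimated per study from a small marker panel per cell
type (20 genes per type by default; a 2-gene TH/SLC6A3-style panel
serves for dopaminergic neurons).  The estimator is an alternating
non-negative least squares scheme: marker profiles per type and sample
proportion vectors are refined in turn, proportions being projected to
the probability simplex by sum-normalization at every step.  It is
marker-guided and reference-light: only the marker-to-type assignment
is assumed, not a quantitative external signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MarkerPanel",
    "DeconvolutionResult",
    "select_markers",
    "estimate_proportions",
    "compare_estimates",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerPanel:
    """Cell type -> ordered marker gene list (ranked by confidence)."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for t, genes in self.markers.items():
            for g in genes:
                if g in seen and seen[g] != t:
                    raise ValueError(f"gene {g} assigned to both {seen[g]} and {t}")
                seen[g] = t

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)


def select_markers(panel: MarkerPanel, study_genes: set[str], k: int = 20) -> MarkerPanel:
    """Realize a per-study panel: the top-k ranked markers present on the platform.

    Absent genes are skipped (rank order preserved); if fewer than k
    survive, all survivors are kept and a warning is logged.  A cell
    type left with zero present markers is an error.
    """
    if not panel.markers:
        raise ValueError("empty marker panel")
    realized: dict[str, list[str]] = {}
    for t, genes in panel.markers.items():
        present = [g for g in genes if g in study_genes]
        if not present:
            raise ValueError(f"no marker of cell type {t!r} is measured in this study")
        if len(present) < k:
            logger.warning(
                "cell type %s: only %d of the requested %d markers present", t, len(present), k
            )
        realized[t] = present[:k]
    return MarkerPanel(realized)


@dataclass
class DeconvolutionResult:
    """Simplex proportions (samples x cell types) plus convergence info."""

    proportions: pd.DataFrame
    converged: bool
    n_iter: int
    max_delta: float
    profiles: pd.DataFrame = field(repr=False, default=None)


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every column b of B; stack solutions as rows."""
    out = np.empty((B.shape[1], A.shape[1]))
    for j in range(B.shape[1]):
        out[j], _ = nnls(A, B[:, j])
    return out


def estimate_proportions(
    expr: pd.DataFrame,
    panel: MarkerPanel,
    max_iter: int = 100,
    tol: float = 1e-6,
    constrain_profiles: bool = True,
) -> DeconvolutionResult:
    """Estimate per-sample cell-type proportions from log2 bulk expression.

    Algorithm: (1) un-log the marker rows; (2) initialize each type's
    marker profile at the across-sample mean of its own markers divided
    by an abundance estimate (see below), with cross-type entries at
    the global marker baseline (the dimmest marker's mean); (3)
    alternate two NNLS updates -- sample proportions against the
    current profiles, projected to the simplex by sum-normalization,
    then marker-gene profiles against the current proportions -- until
    the largest absolute proportion change drops below ``tol`` or
    ``max_iter`` is reached.

    With ``constrain_profiles`` (default) the profile update honors the
    marker structure: a marker gene's profile is re-estimated only in
    its own cell type (cross-type entries stay at zero).  This is what
    makes the factorization well-posed with small per-study sample
    sizes; the unconstrained update (``constrain_profiles=False``) is
    retained for comparison but is unstable for rare cell types.
    """
    types = panel.cell_types
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    marker_genes = [g for t in types for g in panel.markers[t]]
    missing = [g for g in marker_genes if g not in expr.index]
    if missing:
        raise KeyError(f"markers absent from the expression matrix: {missing[:5]}...")

    M = 2.0 ** expr.loc[marker_genes].to_numpy()  # markers x samples, linear
    if np.any(M.sum(axis=1) == 0):
        raise ValueError("all-zero marker rows")

    gene_means = M.mean(axis=1)
    # noise on logged data is multiplicative on the linear scale
    # (variance ~ mean^2), so plain least squares would be dominated by
    # the few brightest markers; scaling each row by its mean weights
    # all markers of a panel equally
    M = M / gene_means[:, None]
    baseline = float(gene_means.min())
    # A marker's bulk level confounds its cell type's abundance with its
    # own brightness.  Assuming marker brightness is exchangeable across
    # panels, the mean own-marker level per type is proportional to that
    # type's average abundance; dividing it out puts the initial
    # profiles on a common per-cell scale (the "identity" scaling).
    bounds = np.cumsum([0] + [len(panel.markers[t]) for t in types])
    type_level = np.array(
        [gene_means[bounds[i] : bounds[i + 1]].mean() for i in range(len(types))]
    )
    abundance = np.maximum(type_level / type_level.sum(), 1e-3)
    # cross-type entries start at the global marker baseline (the
    # dimmest marker's mean); the constrained update keeps them there,
    # so off-target leakage is modeled as a flat floor rather than
    # re-estimated from the weak residual signal
    profiles = np.full((len(marker_genes), len(types)), baseline) / gene_means[:, None]
    for t_i in range(len(types)):
        sl = slice(bounds[t_i], bounds[t_i + 1])
        profiles[sl, t_i] = 1.0 / abundance[t_i]

    n_samples = M.shape[1]
    W = np.full((n_samples, len(types)), 1.0 / len(types))
    converged = False
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        W_new = _nnls_rows(profiles, M)
        sums = W_new.sum(axis=1, keepdims=True)
        zero = sums[:, 0] == 0
        W_new[zero] = 1.0 / len(types)
        sums[zero] = 1.0
        W_new /= sums
        if constrain_profiles:
            for t_i in range(len(types)):
                sl = slice(bounds[t_i], bounds[t_i + 1])
                w = W_new[:, t_i]
                denom = w @ w
                if denom > 0:
                    profiles[sl, t_i] = np.maximum(M[sl, :] @ w / denom, 0.0)
        else:
            profiles = _nnls_rows(W_new, M.T)  # genes x types
        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("deconvolution stopped after %d iterations (max delta %.2e)", it, delta)

    props = pd.DataFrame(W, index=expr.columns, columns=types)
    prof = pd.DataFrame(profiles * gene_means[:, None], index=marker_genes, columns=types)
    return DeconvolutionResult(
        proportions=props, converged=converged, n_iter=it, max_delta=delta, profiles=prof
    )


def estimate_proportions_per_study(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    panel: MarkerPanel,
    k: int = 20,
    **kwargs,
) -> pd.DataFrame:
    """Run deconvolution independently per study and concatenate.

    Each study uses its own realized marker panel (top-k markers present
    on its platform, i.e. genes not all-missing in that study's
    columns).
    """
    blocks = []
    for study, rows in meta.groupby("study", sort=False):
        cols = [s for s in expr.columns if s in rows.index]
        sub = expr[cols].dropna(axis=0, how="any")
        realized = select_markers(panel, set(sub.index), k=k)
        blocks.append(estimate_proportions(sub, realized, **kwargs).proportions)
    out = pd.concat(blocks)
    return out.reindex(meta.index)


def compare_estimates(
    p1: pd.Series, p2: pd.Series, studies: pd.Series
) -> tuple[pd.Series, float, float]:
    """Per-study Pearson correlation of two proportion estimates.

    Returns (per-study r, mean r, sd of r across studies).  Studies in
    which either vector has zero variance are excluded with a warning.
    """
    if not p1.index.equals(p2.index):
        p2 = p2.reindex(p1.index)
    rs = {}
    for study, idx in studies.groupby(studies).groups.items():
        a, b = p1.loc[idx].to_numpy(), p2.loc[idx].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            logger.warning("study %s: zero variance, correlation undefined", study)
            continue
        rs[str(study)] = float(np.corrcoef(a, b)[0, 1])
    r = pd.Series(rs, name="pearson_r")
    return r, float(r.mean()), float(r.std(ddof=1)) if len(r) > 1 else 0.0
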