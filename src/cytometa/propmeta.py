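"""Per-study proportion contrasts and DerSimonian-Laird random-effects pooling.

For one cell type, each study contributes (a) a covariate-adjusted
linear-model p-value for the case/control status term and (b) a Hedges
g standardized mean difference with its sampling variance.  Study
effects are pooled with the DerSimonian-Laird method-of-moments
random-effects model; p-values across cell types are Benjamini-Hochberg
adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaEffect",
    "per_study_effect",
    "random_effects_pool",
    "bh_adjust",
    "meta_analyze_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyEffect:
    study: str
    g: float
    var_g: float
    n_control: int
    n_case: int
    lm_p: float  # covariate-adjusted linear-model p for the status term
    covariates_used: tuple[str, ...]


@dataclass
class MetaEffect:
    smd: float
    se: float
    tau2: float
    z: float
    p: float
    k_studies: int
    p_adj: float = np.nan


def _ols_status_p(y: np.ndarray, X: np.ndarray) -> float:
    """Two-sided t-test p for the last-but-intercept status column (index 1)."""
    n, p = X.shape
    if n <= p:
        return np.nan
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return np.nan
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    return float(2.0 * stats.t.sf(abs(t), n - p))


def hedges_g(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Hedges g (small-sample-corrected SMD) and its sampling variance.

    g = J * (mean_case - mean_control) / s_pooled with
    J = 1 - 3/(4 N - 9), var_g = N/(n1 n2) + g^2 / (2 N), N = n1 + n2.
    """
    n1, n2 = len(case), len(control)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 samples per group")
    N = n1 + n2
    sp2 = ((n1 - 1) * np.var(case, ddof=1) + (n2 - 1) * np.var(control, ddof=1)) / (N - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    J = 1.0 - 3.0 / (4.0 * N - 9.0)
    g = J * (case.mean() - control.mean()) / np.sqrt(sp2)
    var_g = N / (n1 * n2) + g**2 / (2.0 * N)
    return float(g), float(var_g)


def per_study_effect(
    props: pd.Series,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("gender", "age", "braak"),
) -> list[StudyEffect]:
    """Per-study status effect on one cell type's proportions.

    Fits ``proportion ~ status + <available covariates>`` by OLS within
    each study (covariates that are entirely missing or constant in a
    study are dropped, logged) and computes Hedges g between cases and
    controls.  Studies with fewer than 2 samples in either group are
    excluded with a warning.
    """
    out: list[StudyEffect] = []
    for study, rows in meta.groupby("study", sort=False):
        y = props.loc[rows.index].to_numpy(dtype=float)
        status = (rows["status"] == "case").to_numpy(dtype=float)
        n_case, n_ctrl = int(status.sum()), int((1 - status).sum())
        if min(n_case, n_ctrl) < 2:
            logger.warning("study %s: a group has < 2 samples, excluded", study)
            continue
        cols = [np.ones_like(y), status]
        used = []
        for cov in covariates:
            if cov not in rows.columns:
                continue
            v = rows[cov]
            if cov == "gender":
                v = v.map({"F": 0.0, "M": 1.0})
            v = pd.to_numeric(v, errors="coerce")
            if v.isna().all() or v.nunique(dropna=True) < 2:
                logger.info("study %s: covariate %s dropped (missing or constant)", study, cov)
                continue
            if v.isna().any():
                logger.info("study %s: covariate %s dropped (partially missing)", study, cov)
                continue
            cols.append(v.to_numpy(dtype=float))
            used.append(cov)
        X = np.column_stack(cols)
        lm_p = _ols_status_p(y, X)
        g, var_g = hedges_g(y[status == 1], y[status == 0])
        out.append(
            StudyEffect(
                study=str(study),
                g=g,
                var_g=var_g,
                n_control=n_ctrl,
                n_case=n_case,
                lm_p=lm_p,
                covariates_used=tuple(used),
            )
        )
    return out


def random_effects_pool(effects: list[tuple[float, float]]) -> MetaEffect:
    """DerSimonian-Laird random-effects pooling of (g, var_g) pairs.

    Q = sum w_i (g_i - g_FE)^2 with fixed-effect weights w_i = 1/var_i;
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); the pooled
    SMD uses weights 1/(var_i + tau^2); z = smd/se with a two-sided
    normal p.
    """
    if not effects:
        raise ValueError("no effects to pool")
    g = np.array([e[0] for e in effects], dtype=float)
    v = np.array([e[1] for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("effect variances must be positive")
    k = g.size
    w = 1.0 / v
    g_fe = np.sum(w * g) / np.sum(w)
    Q = np.sum(w * (g - g_fe) ** 2)
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    smd = float(np.sum(ws * g) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    z = smd / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaEffect(smd=smd, se=se, tau2=float(tau2), z=float(z), p=p, k_studies=int(k))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def meta_analyze_proportions(
    proportions: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("gender", "age", "braak"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-study + pooled analysis for every cell type.

    Returns (per-study effects table, pooled table with BH-adjusted p
    across cell types).
    """
    study_rows, pooled_rows = [], []
    for ct in proportions.columns:
        effs = per_study_effect(proportions[ct], meta, covariates=covariates)
        for e in effs:
            study_rows.append({"cell_type": ct, **e.__dict__})
        pooled = random_effects_pool([(e.g, e.var_g) for e in effs])
        pooled_rows.append({"cell_type": ct, **pooled.__dict__})
    pooled_df = pd.DataFrame(pooled_rows).set_index("cell_type")
    pooled_df["p_adj"] = bh_adjust(pooled_df["p"].to_numpy())
    study_df = pd.DataFrame(study_rows)
    return study_df, pooled_df
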