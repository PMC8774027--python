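"""Per-gene mixed-model differential expression across studies, two ways.

Each gene probed by two or more studies is fitted with a random
intercept per study and fixed effects for case/control status and sex
(composition-unaware mode), optionally adding the estimated neuronal
(NEU) and oligodendrocyte (ODC) proportions as fixed effects
(composition-aware mode):

    unaware:  expr ~ status + gender + (1 | study)
    aware:    expr ~ status + NEU + ODC + gender + (1 | study)

Only two of the six proportion estimates enter the aware model, to
avoid collinear predictors on the simplex; a diagnostic reports the
proportion-estimate correlation matrix so this choice can be validated
on any dataset.  DEGs are called at BH-adjusted p < 0.05 and fold
change > 1.2, i.e. |beta_status| > log2(1.2) on the log2 scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept_many
from .propmeta import bh_adjust

__all__ = ["fit_gene_lmm", "run_de", "call_degs", "overlap_report", "proportion_correlations"]

logger = logging.getLogger(__name__)

AWARE_COVARIATES = ("NEU", "ODC")


def _design(
    meta: pd.DataFrame, proportions: pd.DataFrame | None, mode: str
) -> tuple[np.ndarray, list[str]]:
    if mode not in ("unaware", "aware"):
        raise ValueError(f"mode must be 'unaware' or 'aware', got {mode!r}")
    cols = [np.ones(len(meta)), (meta["status"] == "case").to_numpy(dtype=float)]
    names = ["intercept", "status"]
    if mode == "aware":
        if proportions is None:
            raise ValueError("aware mode requires a proportion matrix with NEU and ODC")
        for ct in AWARE_COVARIATES:
            if ct not in proportions.columns:
                raise ValueError(f"aware mode requires proportion column {ct!r}")
            cols.append(proportions.loc[meta.index, ct].to_numpy(dtype=float))
            names.append(ct)
    gender = meta["gender"].map({"F": 0.0, "M": 1.0})
    if gender.isna().any():
        raise ValueError("gender must be F/M for all samples (impute first)")
    cols.append(gender.to_numpy())
    names.append("gender")
    X = np.column_stack(cols)
    # covariates constant across samples carry no information and would be
    # collinear with the intercept; drop them so both modes agree exactly
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0 or names[j] == "status"]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropping constant design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def fit_gene_lmm(
    y: pd.Series,
    meta: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    mode: str = "unaware",
) -> dict:
    """Fit one gene's mixed model; returns beta_status, se, df, p, method.

    ``y`` is log2 expression indexed by sample; samples with missing
    values are dropped; the remaining ones must span >= 2 studies.
    """
    obs = y.dropna()
    m = meta.loc[obs.index]
    if m["study"].nunique() < 2:
        raise ValueError("gene observed in fewer than 2 studies")
    X, names = _design(m, proportions, mode)
    fit = fit_random_intercept_many(
        obs.to_numpy()[None, :], X, m["study"].to_numpy(), target=names.index("status"),
        column_names=names,
    )
    return {
        "beta_status": float(fit.beta[0]),
        "se": float(fit.se[0]),
        "df": float(fit.df[0]),
        "p": float(fit.p[0]),
        "sigma2_study": float(fit.sigma2_b[0]),
        "sigma2_resid": float(fit.sigma2_e[0]),
        "method": str(fit.method[0]),
        "n_studies": int(m["study"].nunique()),
    }


def run_de(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    mode: str = "unaware",
    alpha: float = 0.05,
    fc: float = 1.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the chosen mixed model for every eligible gene.

    Genes probed by fewer than 2 studies are skipped and listed in the
    returned skip report.  Genes sharing a missingness pattern share one
    vectorized REML fit.  BH correction runs across all fitted genes
    within the mode; the table is sorted by adjusted p.
    Returns (result table, skip report).
    """
    if not set(expr.columns) <= set(meta.index):
        raise ValueError("expression columns missing from metadata")
    meta = meta.loc[list(expr.columns)]
    if proportions is not None and not set(expr.columns) <= set(proportions.index):
        raise ValueError("expression columns missing from the proportion matrix")

    arr = expr.to_numpy(dtype=float)
    observed = ~np.isnan(arr)
    study_codes = pd.Categorical(meta["study"]).codes

    results: list[pd.DataFrame] = []
    skipped: list[dict] = []
    patterns: dict[bytes, list[int]] = {}
    for i in range(arr.shape[0]):
        patterns.setdefault(observed[i].tobytes(), []).append(i)

    for key, gene_rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        genes = expr.index[gene_rows]
        n_studies = len(np.unique(study_codes[mask]))
        if mask.sum() == 0 or n_studies < 2:
            skipped.extend(
                {"gene": g, "reason": f"probed by {n_studies} study(ies)"} for g in genes
            )
            continue
        m = meta.loc[mask]
        X, names = _design(m, proportions, mode)
        fit = fit_random_intercept_many(
            arr[np.ix_(gene_rows, np.where(mask)[0])],
            X,
            m["study"].to_numpy(),
            target=names.index("status"),
            column_names=names,
        )
        block = fit.to_frame(genes).rename(columns={"beta": "beta_status"})
        block["n_studies_probing"] = n_studies
        results.append(block)

    if not results:
        raise ValueError("no gene probed by 2 or more studies")
    table = pd.concat(results)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["mode"] = mode
    table = call_degs(table, alpha=alpha, fc=fc)
    table = table.sort_values(["p_adj", "p", "beta_status"]).rename_axis("gene")
    skip_report = pd.DataFrame(skipped, columns=["gene", "reason"])
    return table, skip_report


def call_degs(table: pd.DataFrame, alpha: float = 0.05, fc: float = 1.2) -> pd.DataFrame:
    """Flag DEGs: adjusted p strictly below ``alpha`` AND |beta| strictly
    above log2(``fc``)."""
    t = table.copy()
    thr = np.log2(fc)
    t["deg_call"] = (t["p_adj"] < alpha) & (t["beta_status"].abs() > thr)
    t["direction"] = np.where(t["beta_status"] > 0, "up", "down")
    return t


def overlap_report(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """DEG overlap between two result tables: |A∩B|, |A\\B|, |B\\A|."""
    sa = set(a.index[a["deg_call"]])
    sb = set(b.index[b["deg_call"]])
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "overlap": len(sa & sb),
        "only_a": len(sa - sb),
        "only_b": len(sb - sa),
    }


def proportion_correlations(proportions: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the proportion estimates.

    Diagnostic for choosing which cell types may enter the aware model
    without introducing collinearity."""
    return proportions.corr()
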