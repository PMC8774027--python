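"""Random-intercept linear mixed models, fitted by REML, many responses at once.

The model for one response y (one gene) over n samples grouped into k
studies is

    y = X beta + Z u + e,   u ~ N(0, sigma_b^2 I_k),  e ~ N(0, sigma_e^2 I_n)

with Z the study indicator matrix.  Writing lambda = sigma_b^2 /
sigma_e^2, the marginal covariance is sigma_e^2 (I + lambda Z Z'),
which is block diagonal, so all REML quantities reduce to closed forms
in per-study sufficient statistics:

    A(lambda)  = X'X     - sum_i c_i s_i s_i',        c_i = lambda / (1 + n_i lambda)
    b(lambda)  = X'y     - sum_i c_i s_i t_i,         s_i = column sums of X in study i
    q(lambda)  = y'y     - sum_i c_i t_i^2,           t_i = sum of y in study i

with beta = A^-1 b, RSS = q - b'beta, sigma_e^2 = RSS/(n-p), and the
profiled REML criterion

    (n - p) log RSS + sum_i log(1 + n_i lambda) + log |A(lambda)|.

These forms cost O(k p^2) per evaluation and vectorize over thousands
of responses sharing one design matrix, which is what makes per-gene
REML fits over a whole transcriptome cheap.

Inference on one coefficient uses a t-test with Satterthwaite-
approximated degrees of freedom: with theta = (sigma_e^2, sigma_b^2) and
f(theta) = Var(beta_j) = sigma_e^2 [A(lambda)^-1]_jj,

    df = 2 f(theta)^2 / (grad f' V_theta grad f),

where V_theta is the inverse observed REML information, both obtained by
central finite differences of the closed forms above.  When the
between-study variance is estimated at the boundary (sigma_b^2 = 0) the
fit is ordinary least squares and df = n - p; when the information
matrix is not positive definite the p-value falls back to a Wald z test
and the fit is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fit_random_intercept_many", "LMMFitTable"]

_LAM_GRID = np.concatenate(([0.0], np.logspace(-6, 3, 28)))
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class _Suff:
    """Shared sufficient statistics for one design matrix."""

    X: np.ndarray
    n: int
    p: int
    n_i: np.ndarray  # (k,)
    sx: np.ndarray  # (k, p) per-study column sums of X
    XtX: np.ndarray
    Xty: np.ndarray  # (p, G)
    sy: np.ndarray  # (k, G) per-study sums of Y
    yty: np.ndarray  # (G,)


def _prepare(Y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> _Suff:
    n, p = X.shape
    k = int(codes.max()) + 1
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    return _Suff(
        X=X,
        n=n,
        p=p,
        n_i=onehot.sum(axis=0),
        sx=onehot.T @ X,
        XtX=X.T @ X,
        Xty=X.T @ Y.T,
        sy=onehot.T @ Y.T,
        yty=np.einsum("gn,gn->g", Y, Y),
    )


def _components(s: _Suff, lam: np.ndarray):
    """A, b, q for per-gene lambda values. lam: (G,) -> A (G,p,p), b (G,p), q (G,)."""
    c = lam[None, :] * s.n_i[:, None] / (1.0 + s.n_i[:, None] * lam[None, :]) / s.n_i[:, None]
    # c_i = lam / (1 + n_i lam); shape (k, G)
    A = s.XtX[None, :, :] - np.einsum("kg,kp,kq->gpq", c, s.sx, s.sx)
    b = s.Xty.T - np.einsum("kg,kg,kp->gp", c, s.sy, s.sx)
    q = s.yty - np.einsum("kg,kg->g", c, s.sy**2)
    return A, b, q


def _crit(s: _Suff, lam: np.ndarray) -> np.ndarray:
    """Profiled REML criterion per gene at per-gene lambda."""
    A, b, q = _components(s, lam)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = np.maximum(q - np.einsum("gp,gp->g", b, beta), 1e-300)
    _, logdetA = np.linalg.slogdet(A)
    logdetV = np.log1p(np.outer(s.n_i, lam)).sum(axis=0)
    return (s.n - s.p) * np.log(rss) + logdetV + logdetA


def _reml_neg2(s: _Suff, sig_e: np.ndarray, sig_b: np.ndarray) -> np.ndarray:
    """-2 restricted log-likelihood (up to a constant) at full theta."""
    lam = sig_b / sig_e
    A, b, q = _components(s, lam)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = np.maximum(q - np.einsum("gp,gp->g", b, beta), 1e-300)
    _, logdetA = np.linalg.slogdet(A)
    logdetV = np.log1p(np.outer(s.n_i, lam)).sum(axis=0)
    return (s.n - s.p) * np.log(sig_e) + logdetV + logdetA + rss / sig_e


def _var_target(s: _Suff, sig_e: np.ndarray, sig_b: np.ndarray, j: int) -> np.ndarray:
    lam = sig_b / sig_e
    A, _, _ = _components(s, lam)
    Ainv = np.linalg.inv(A)
    return sig_e * Ainv[:, j, j]


def _optimize_lambda(s: _Suff) -> np.ndarray:
    """Per-gene REML lambda by coarse grid + vectorized golden section."""
    G = s.Xty.shape[1]
    grid_crit = np.empty((_LAM_GRID.size, G))
    for i, lam in enumerate(_LAM_GRID):
        grid_crit[i] = _crit(s, np.full(G, lam))
    best = grid_crit.argmin(axis=0)

    lam_hat = np.empty(G)
    at_zero = best == 0
    lam_hat[at_zero] = 0.0

    interior = ~at_zero
    if interior.any():
        lo_i = np.maximum(best[interior] - 1, 0)
        hi_i = np.minimum(best[interior] + 1, _LAM_GRID.size - 1)
        # work in log space; lower bracket edge 0 -> tiny positive
        lo = np.log(np.maximum(_LAM_GRID[lo_i], 1e-10))
        hi = np.log(_LAM_GRID[hi_i])
        sub = _SuffView(s, interior)
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1 = _crit(sub, np.exp(x1))
        f2 = _crit(sub, np.exp(x2))
        for _ in range(60):
            take1 = f1 < f2  # minimum in [lo, x2]: x1 becomes the new x2
            hi = np.where(take1, x2, hi)
            lo = np.where(take1, lo, x1)
            x2n = np.where(take1, x1, lo + _GOLDEN * (hi - lo))
            x1n = np.where(take1, hi - _GOLDEN * (hi - lo), x2)
            fresh = np.where(take1, x1n, x2n)
            fn = _crit(sub, np.exp(fresh))
            f1n = np.where(take1, fn, f2)
            f2n = np.where(take1, f1, fn)
            x1, x2, f1, f2 = x1n, x2n, f1n, f2n
            if np.max(hi - lo) < 1e-10:
                break
        lam_int = np.exp((lo + hi) / 2.0)
        # a fit driven to the tiny lower edge is a boundary fit
        lam_int[lam_int < 2e-10] = 0.0
        lam_hat[interior] = lam_int
    return lam_hat


class _SuffView(_Suff):
    """View of a _Suff restricted to a gene subset (no data copied for X)."""

    def __init__(self, s: _Suff, mask: np.ndarray):
        self.X, self.n, self.p = s.X, s.n, s.p
        self.n_i, self.sx, self.XtX = s.n_i, s.sx, s.XtX
        self.Xty = s.Xty[:, mask]
        self.sy = s.sy[:, mask]
        self.yty = s.yty[mask]


@dataclass
class LMMFitTable:
    """Per-response estimates for the target coefficient."""

    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray
    p: np.ndarray
    sigma2_e: np.ndarray
    sigma2_b: np.ndarray
    method: np.ndarray  # "satterthwaite" | "boundary_ols" | "wald_z"

    def to_frame(self, index) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "df": self.df,
                "p": self.p,
                "sigma2_e": self.sigma2_e,
                "sigma2_b": self.sigma2_b,
                "method": self.method,
            },
            index=index,
        )


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                bad.append(names[j])
        raise ValueError(f"singular fixed-effect design; collinear columns: {bad}")


def fit_random_intercept_many(
    Y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    target: int,
    column_names: list[str] | None = None,
) -> LMMFitTable:
    """REML-fit ``y_g = X beta + (1|group) + e`` for every row of Y.

    Returns the target coefficient's estimate, standard error,
    Satterthwaite df, and two-sided p per response.  Boundary fits
    (sigma_b^2 = 0) reduce to OLS with df = n - p; responses where the
    Satterthwaite information matrix is not positive definite fall back
    to a Wald z test, flagged in ``method``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    names = column_names or [f"x{j}" for j in range(X.shape[1])]
    _check_design(X, names)
    codes = np.unique(np.asarray(groups), return_inverse=True)[1]
    if np.unique(codes).size < 2:
        raise ValueError("all samples come from a single group; no random effect identifiable")

    s = _prepare(Y, X, codes)
    G = Y.shape[0]
    lam = _optimize_lambda(s)

    A, b, q = _components(s, lam)
    Ainv = np.linalg.inv(A)
    beta_all = np.einsum("gpq,gq->gp", Ainv, b)
    rss = np.maximum(q - np.einsum("gp,gp->g", b, beta_all), 1e-300)
    sig_e = rss / (s.n - s.p)
    sig_b = lam * sig_e
    beta = beta_all[:, target]
    se = np.sqrt(sig_e * Ainv[:, target, target])

    df = np.full(G, float(s.n - s.p))
    method = np.full(G, "boundary_ols", dtype=object)

    interior = lam > 0
    if interior.any():
        sub = _SuffView(s, interior)
        e, v = sig_e[interior], sig_b[interior]
        he, hb = 1e-4 * e, 1e-4 * np.maximum(v, 1e-3 * e)

        def fvar(de, dv):
            return _var_target(sub, e + de, np.maximum(v + dv, 0.0), target)

        g_e = (fvar(he, 0) - fvar(-he, 0)) / (2 * he)
        g_b = (fvar(0, hb) - fvar(0, -hb)) / (2 * hb)

        He, Hb = 1e-3 * e, 1e-3 * np.maximum(v, 1e-3 * e)

        def ll(de, dv):
            return _reml_neg2(sub, e + de, np.maximum(v + dv, 0.0))

        l0 = ll(0, 0)
        h_ee = (ll(He, 0) - 2 * l0 + ll(-He, 0)) / He**2
        h_bb = (ll(0, Hb) - 2 * l0 + ll(0, -Hb)) / Hb**2
        h_eb = (ll(He, Hb) - ll(He, -Hb) - ll(-He, Hb) + ll(-He, -Hb)) / (4 * He * Hb)
        # V_theta = 2 * H^-1 with H the Hessian of -2 l_R
        det = h_ee * h_bb - h_eb**2
        ok = (h_ee > 0) & (h_bb > 0) & (det > 0)
        var_f = np.full(e.shape, np.nan)
        var_f[ok] = (
            2.0
            * (
                g_e[ok] ** 2 * h_bb[ok]
                - 2 * g_e[ok] * g_b[ok] * h_eb[ok]
                + g_b[ok] ** 2 * h_ee[ok]
            )
            / det[ok]
        )
        f0 = fvar(0, 0)
        df_int = 2.0 * f0**2 / var_f
        good = ok & np.isfinite(df_int) & (df_int > 0)
        idx = np.where(interior)[0]
        df[idx[good]] = df_int[good]
        method[idx[good]] = "satterthwaite"
        method[idx[~good]] = "wald_z"

    t = beta / se
    p = np.where(
        method == "wald_z",
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df),
    )
    return LMMFitTable(
        beta=beta, se=se, df=df, p=p, sigma2_e=sig_e, sigma2_b=sig_b, method=method
    )
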