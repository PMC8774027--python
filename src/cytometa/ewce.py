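"""Expression-weighted cell-type enrichment (EWCE) bootstrap test.

Given a specificity matrix (cell types x genes; each gene's expression
share per type) and a gene list, the observed statistic per cell type
is the mean specificity of the list's genes.  The null is built from
``n_boot`` equal-sized gene sets sampled uniformly without replacement
from all genes in the matrix; the one-sided p counts null means at or
above the observed one (with a +1 pseudo-count so p is never zero), and
the z-score reports how many bootstrap standard deviations the observed
mean lies above the bootstrap mean.  P-values are BH-adjusted across
cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .propmeta import bh_adjust

__all__ = ["ewce_test"]


def ewce_test(
    genes: list[str],
    specificity: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Bootstrap enrichment of a gene list per cell type.

    Input genes are deduplicated; genes absent from the specificity
    matrix are dropped and counted in ``n_dropped``.  Returns one row
    per cell type with observed mean specificity, bootstrap mean/sd,
    z, one-sided p, and BH-adjusted p.  A zero bootstrap sd leaves z
    undefined (NaN) and is flagged.
    """
    uniq = list(dict.fromkeys(genes))
    used = [g for g in uniq if g in specificity.columns]
    n_dropped = len(uniq) - len(used)
    if not used:
        raise ValueError("no input gene is present in the specificity matrix")
    m = len(used)
    S = specificity.to_numpy(dtype=float)  # types x genes
    n_genes = S.shape[1]
    if m > n_genes:
        raise ValueError("gene list larger than the specificity universe")

    observed = specificity[used].mean(axis=1).to_numpy()

    rng = substream(seed, "ewce", m)
    boot_sum = np.zeros(S.shape[0])
    boot_sumsq = np.zeros(S.shape[0])
    ge_count = np.zeros(S.shape[0])
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        keys = rng.random((b, n_genes))
        pos = np.argpartition(keys, m - 1, axis=1)[:, :m]  # (b, m) w/o replacement
        means = S[:, pos].mean(axis=2)  # types x b
        # accumulate moments of (mean - observed): numerically exact in
        # the degenerate case where every bootstrap set equals the list
        delta = means - observed[:, None]
        boot_sum += delta.sum(axis=1)
        boot_sumsq += (delta**2).sum(axis=1)
        ge_count += (delta >= -1e-12).sum(axis=1)
        done += b

    d_mean = boot_sum / n_boot
    boot_mean = observed + d_mean
    boot_var = np.maximum(boot_sumsq / n_boot - d_mean**2, 0.0)
    boot_sd = np.sqrt(boot_var)
    sd_zero = boot_sd <= 1e-12  # degenerate null (e.g. list == universe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~sd_zero, (observed - boot_mean) / boot_sd, np.nan)
    p = (1.0 + ge_count) / (1.0 + n_boot)

    out = pd.DataFrame(
        {
            "observed": observed,
            "boot_mean": boot_mean,
            "boot_sd": boot_sd,
            "z": z,
            "p": p,
            "n_used": m,
            "n_dropped": n_dropped,
            "sd_zero": sd_zero,
        },
        index=specificity.index.rename("cell_type"),
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
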