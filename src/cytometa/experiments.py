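"""Reproducible simulation studies exercising the whole pipeline.

Each function generates synthetic data with known ground truth, runs
the relevant pipeline stages, and returns summary metrics.  They are
the package's validation experiments: the confounding-collapse study
(composition-unaware vs -aware differential expression), the
deconvolution parameter-recovery benchmark, the calibration of the
random-effects proportion meta-analysis, and the dopaminergic-proxy
concordance check.  All are deterministic given a seed.
"""

from __future__ import annotations

import logging

import numpy as np

from .deconv import MarkerPanel, estimate_proportions, estimate_proportions_per_study, compare_estimates
from .de import overlap_report, run_de
from .propmeta import per_study_effect, random_effects_pool
from .synthetic import SimulationConfig, simulate_bulk, simulate_reference

logger = logging.getLogger(__name__)

__all__ = [
    "confounding_study",
    "deconvolution_benchmark",
    "meta_calibration",
    "da_neuron_concordance",
    "small_proportions_config",
]


def confounding_study(n_reps: int = 20, seed: int = 1) -> dict:
    """Composition-unaware vs -aware DEG calling over seeded replicates.

    For each replicate: simulate the default nine-study cohort, estimate
    proportions per study by marker-guided deconvolution, fit both
    mixed models, and call DEGs.  Returns pooled counts, the
    unaware/aware call ratio, both models' empirical FDR, the aware
    model's recovery of planted DEGs, and the DEG overlap of the last
    replicate.
    """
    tot = {"unaware_calls": 0, "aware_calls": 0, "unaware_fp": 0, "aware_fp": 0, "aware_tp": 0}
    mae = []
    overlap = None
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed * 100_003 + rep)
        data, truth = simulate_bulk(cfg, simulate_reference(cfg))
        props = estimate_proportions_per_study(
            data.expr, data.meta, MarkerPanel(truth.marker_map)
        )
        mae.append(float((props - truth.true_proportions).abs().to_numpy().mean()))
        unaware, _ = run_de(data.expr, data.meta, mode="unaware")
        aware, _ = run_de(data.expr, data.meta, proportions=props, mode="aware")
        true_degs = set(truth.true_deg_ids)
        calls_u = set(unaware.index[unaware["deg_call"]])
        calls_a = set(aware.index[aware["deg_call"]])
        tot["unaware_calls"] += len(calls_u)
        tot["aware_calls"] += len(calls_a)
        tot["unaware_fp"] += len(calls_u - true_degs)
        tot["aware_fp"] += len(calls_a - true_degs)
        tot["aware_tp"] += len(calls_a & true_degs)
        overlap = overlap_report(unaware, aware)
    n_true_total = n_reps * SimulationConfig().n_true_degs
    return {
        **tot,
        "n_reps": n_reps,
        "call_ratio": tot["unaware_calls"] / max(tot["aware_calls"], 1),
        "unaware_fdr": tot["unaware_fp"] / max(tot["unaware_calls"], 1),
        "aware_fdr": tot["aware_fp"] / max(tot["aware_calls"], 1),
        "aware_recovery": tot["aware_tp"] / n_true_total,
        "deconv_mae_mean": float(np.mean(mae)),
        "last_overlap": overlap,
    }


def deconvolution_benchmark(seed: int = 1, n_samples: int = 50, noise_sd: float = 0.1) -> dict:
    """Parameter recovery on flat-Dirichlet mixtures (alpha = 1).

    One batch of ``n_samples`` mixtures of 6 cell types with 20 markers
    each, log-scale noise ``noise_sd``; reports the mean absolute error
    of the estimated against the planted proportions.
    """
    half = n_samples // 2
    cfg = SimulationConfig(
        n_studies=1,
        n_per_group=((half, n_samples - half),),
        dirichlet_alpha_control=(1.0,) * 6,
        dirichlet_alpha_case=(1.0,) * 6,
        study_sd=0.0,
        noise_sd=noise_sd,
        n_true_degs=1,
        deg_effect=0.0,
        seed=seed,
    )
    data, truth = simulate_bulk(cfg, simulate_reference(cfg))
    res = estimate_proportions(data.expr, MarkerPanel(truth.marker_map))
    mae = float((res.proportions - truth.true_proportions).abs().to_numpy().mean())
    return {"mae": mae, "converged": bool(res.converged), "n_iter": res.n_iter}


def small_proportions_config(seed: int, null: bool) -> SimulationConfig:
    """A light config (few genes) for proportion-only replicates.

    Under the alternative, cases keep the default Dirichlet shift
    (neuronal proportion down by about one pooled SD)."""
    alpha = (12.0, 9.0, 4.8, 1.8, 1.5, 1.2)
    return SimulationConfig(
        seed=seed,
        n_genes=150,
        n_markers_per_type=4,
        n_true_degs=1,
        deg_effect=0.0,
        dirichlet_alpha_case=alpha if null else SimulationConfig().dirichlet_alpha_case,
    )


def meta_calibration(
    n_null: int = 200, n_planted: int = 100, seed: int = 1, alpha: float = 0.05
) -> dict:
    """Type-I error and power/sign recovery of the pooled SMD test.

    Null replicates use identical Dirichlet parameters in both groups;
    planted replicates use the default neuronal decrease (true pooled
    SMD about -1).  Pools per-study Hedges g for the neuronal
    proportion with DerSimonian-Laird weights.
    """

    def pooled(cfg):
        data, truth = simulate_bulk(cfg, simulate_reference(cfg))
        effs = per_study_effect(truth.true_proportions["NEU"], data.meta)
        return random_effects_pool([(e.g, e.var_g) for e in effs])

    base = seed * 1_000_003
    null_rej = 0
    for rep in range(n_null):
        m = pooled(small_proportions_config(base + rep, null=True))
        null_rej += m.p < alpha
    detected = 0
    smds = []
    for rep in range(n_planted):
        m = pooled(small_proportions_config(base + 500_000 + rep, null=False))
        smds.append(m.smd)
        detected += (m.p < alpha) and (m.smd < 0)
    return {
        "null_rejection_rate": null_rej / n_null,
        "n_null": n_null,
        "sign_power": detected / n_planted,
        "n_planted": n_planted,
        "mean_pooled_smd": float(np.mean(smds)),
    }


def da_neuron_concordance(seed: int = 1) -> dict:
    """Concordance of a 2-marker neuronal estimate with the 20-marker one.

    Mirrors the use of a tiny dopaminergic panel (TH/SLC6A3-style) in
    place of the general neuronal panel: proportions are re-estimated
    per study with the neuronal panel truncated to its two top markers,
    and the per-study Pearson correlation between the two neuronal
    estimates is reported as mean +/- sd across studies.
    """
    cfg = SimulationConfig(seed=seed)
    data, truth = simulate_bulk(cfg, simulate_reference(cfg))
    full_panel = MarkerPanel(truth.marker_map)
    da_markers = dict(truth.marker_map)
    da_markers["NEU"] = da_markers["NEU"][:2]
    da_panel = MarkerPanel(da_markers)
    p_full = estimate_proportions_per_study(data.expr, data.meta, full_panel)
    p_da = estimate_proportions_per_study(data.expr, data.meta, da_panel)
    per_study, mean_r, sd_r = compare_estimates(
        p_full["NEU"], p_da["NEU"], data.meta["study"]
    )
    return {"mean_r": mean_r, "sd_r": sd_r, "n_studies": int(len(per_study))}
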