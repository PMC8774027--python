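import numpy as np
import pandas as pd
import pytest

from cytometa import (
    MarkerPanel,
    SimulationConfig,
    compare_estimates,
    estimate_proportions,
    select_markers,
    simulate_bulk,
    simulate_reference,
)


class TestMarkerPanel:
    def test_gene_in_two_types_rejected(self):
        with pytest.raises(ValueError, match="assigned to both"):
            MarkerPanel({"A": ["g1", "g2"], "B": ["g2"]})


class TestSelectMarkers:
    def test_all_present_takes_top_k(self):
        panel = MarkerPanel({"A": [f"g{i}" for i in range(30)]})
        realized = select_markers(panel, {f"g{i}" for i in range(30)}, k=20)
        assert realized.markers["A"] == [f"g{i}" for i in range(20)]

    def test_absent_rank_skipped(self):
        panel = MarkerPanel({"A": ["g1", "g2", "g3", "g4", "g5", "g6"]})
        realized = select_markers(panel, {"g1", "g2", "g4", "g5", "g6"}, k=5)
        assert realized.markers["A"] == ["g1", "g2", "g4", "g5", "g6"]

    def test_dropout_matches_filter_then_truncate_oracle(self):
        rng = np.random.default_rng(8)
        panel = MarkerPanel(
            {t: [f"{t}_g{i}" for i in range(40)] for t in ["A", "B", "C"]}
        )
        all_genes = [g for gs in panel.markers.values() for g in gs]
        present = {g for g in all_genes if rng.random() > 0.3}
        # ensure every type keeps at least one marker
        for t in panel.markers:
            present.add(f"{t}_g0")
        realized = select_markers(panel, present, k=20)
        for t, genes in panel.markers.items():
            oracle = [g for g in genes if g in present][:20]
            assert realized.markers[t] == oracle

    def test_type_with_no_present_markers_raises(self):
        panel = MarkerPanel({"A": ["g1"], "B": ["g2"]})
        with pytest.raises(ValueError, match="B"):
            select_markers(panel, {"g1"}, k=5)


def _pure_mixture_cfg():
    return SimulationConfig(
        n_studies=1, n_per_group=((10, 10),), n_genes=200, n_markers_per_type=6,
        study_sd=0.0, noise_sd=0.0, n_true_degs=1, deg_effect=0.0, gender_effect=0.0,
        seed=31,
    )


class TestEstimateProportions:
    def test_rows_on_simplex_and_nonnegative(self, tiny_cohort):
        _, data, truth = tiny_cohort
        res = estimate_proportions(data.expr, MarkerPanel(truth.marker_map))
        w = res.proportions.to_numpy()
        assert (w >= 0).all()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_pure_signatures_assigned_to_true_type(self):
        cfg = _pure_mixture_cfg()
        ref = simulate_reference(cfg)
        # build bulk columns that are exact pure cell-type signatures
        sig = np.log2(ref.signatures.to_numpy())
        expr = pd.DataFrame(
            np.repeat(sig, 3, axis=0).T,
            index=ref.signatures.columns,
            columns=[f"s{i}" for i in range(3 * len(ref.signatures))],
        )
        res = estimate_proportions(expr, MarkerPanel(ref.marker_map))
        types = list(ref.signatures.index)
        # off-target marker leakage is modeled as a flat floor, so a
        # sliver of weight lands on the other types even in the
        # noise-free one-hot case
        for i, col in enumerate(expr.columns):
            assert res.proportions.loc[col, types[i // 3]] >= 0.95

    def test_recovery_on_noisy_mixtures(self):
        cfg = SimulationConfig(
            n_studies=1, n_per_group=((25, 25),), dirichlet_alpha_control=(1.0,) * 6,
            dirichlet_alpha_case=(1.0,) * 6, study_sd=0.0, noise_sd=0.1,
            n_true_degs=1, deg_effect=0.0, seed=41,
        )
        data, truth = simulate_bulk(cfg, simulate_reference(cfg))
        res = estimate_proportions(data.expr, MarkerPanel(truth.marker_map))
        mae = (res.proportions - truth.true_proportions).abs().to_numpy().mean()
        assert mae <= 0.05

    def test_invariant_to_sample_and_marker_order(self, tiny_cohort):
        _, data, truth = tiny_cohort
        base = estimate_proportions(data.expr, MarkerPanel(truth.marker_map))
        shuffled_cols = list(data.expr.columns[::-1])
        reordered_markers = {
            t: genes for t, genes in reversed(list(truth.marker_map.items()))
        }
        res = estimate_proportions(
            data.expr[shuffled_cols], MarkerPanel(reordered_markers)
        )
        a = base.proportions.loc[data.expr.columns].sort_index(axis=1)
        b = res.proportions.loc[data.expr.columns].sort_index(axis=1)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_per_sample_scaling_absorbed_by_sum_normalization(self, tiny_cohort):
        """For fixed profiles, rescaling a sample's linear-scale marker
        vector scales its NNLS weights uniformly, so the simplex
        projection returns identical proportions."""
        from scipy.optimize import nnls

        _, data, truth = tiny_cohort
        panel = MarkerPanel(truth.marker_map)
        fit = estimate_proportions(data.expr, panel)
        profiles = fit.profiles.to_numpy()
        m = 2.0 ** data.expr.loc[fit.profiles.index, data.expr.columns[0]].to_numpy()
        w1, _ = nnls(profiles, m)
        w3, _ = nnls(profiles, 3.0 * m)
        assert np.allclose(w1 / w1.sum(), w3 / w3.sum(), atol=1e-9)

    def test_rank_correlation_recovery_over_replicates(self):
        """Median per-type Spearman correlation of estimated vs true
        proportions stays high across seeded replicates."""
        from scipy.stats import spearmanr

        cors = []
        for rep in range(5):
            cfg = SimulationConfig(
                n_studies=1, n_per_group=((20, 20),), n_genes=500,
                n_markers_per_type=20, seed=600 + rep,
            )
            data, truth = simulate_bulk(cfg, simulate_reference(cfg))
            res = estimate_proportions(data.expr, MarkerPanel(truth.marker_map))
            for ct in res.proportions.columns:
                cors.append(
                    spearmanr(res.proportions[ct], truth.true_proportions[ct]).statistic
                )
        assert np.median(cors) >= 0.8

    def test_too_few_types_rejected(self, tiny_cohort):
        _, data, truth = tiny_cohort
        single = {"NEU": truth.marker_map["NEU"]}
        with pytest.raises(ValueError):
            estimate_proportions(data.expr, MarkerPanel(single))


class TestCompareEstimates:
    def test_identity_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(20)]
        p1 = pd.Series(rng.uniform(size=20), index=idx)
        studies = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        per_study, mean_r, sd_r = compare_estimates(p1, p1.copy(), studies)
        assert np.allclose(per_study.to_numpy(), 1.0)
        assert mean_r == pytest.approx(1.0)

    def test_anti_identity_gives_minus_one(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(10)]
        p1 = pd.Series(rng.uniform(size=10), index=idx)
        studies = pd.Series(["A"] * 10, index=idx)
        _, mean_r, _ = compare_estimates(p1, 1.0 - p1, studies)
        assert mean_r == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        idx = ["a", "b", "c", "d", "e", "f"]
        p1 = pd.Series([0.1, 0.2, 0.4, 0.3, 0.5, 0.9], index=idx)
        p2 = pd.Series([0.2, 0.1, 0.5, 0.2, 0.4, 0.8], index=idx)
        studies = pd.Series(["s1"] * 3 + ["s2"] * 3, index=idx)
        per_study, mean_r, sd_r = compare_estimates(p1, p2, studies)
        for s, sl in [("s1", slice(0, 3)), ("s2", slice(3, 6))]:
            expected = np.corrcoef(p1.iloc[sl], p2.iloc[sl])[0, 1]
            assert per_study[s] == pytest.approx(expected)
        assert mean_r == pytest.approx(per_study.mean())

    def test_zero_variance_study_excluded(self):
        idx = [f"s{i}" for i in range(6)]
        p1 = pd.Series([0.5] * 3 + [0.1, 0.2, 0.3], index=idx)
        p2 = pd.Series([0.4, 0.5, 0.6, 0.1, 0.25, 0.28], index=idx)
        studies = pd.Series(["flat"] * 3 + ["ok"] * 3, index=idx)
        per_study, _, _ = compare_estimates(p1, p2, studies)
        assert list(per_study.index) == ["ok"]
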