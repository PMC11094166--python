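import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from utrkit import perturb as pt
from utrkit.synth import make_planted_effect_matrix


def simple_inputs(n_nt=4, n_pert=6, n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    perts = [f"nt{i}" for i in range(n_nt)] + [f"kd{i}" for i in range(n_pert)]
    genes = [f"g{i}" for i in range(n_genes)]
    wui = pd.DataFrame(rng.uniform(0.3, 0.7, (len(perts), n_genes)),
                       index=perts, columns=genes)
    tpm = pd.DataFrame(rng.uniform(10, 100, (len(perts), n_genes)),
                       index=perts, columns=genes)
    cells = pd.Series(50, index=perts)
    return wui, tpm, cells, [p for p in perts if p.startswith("nt")]


class TestComputeEffects:
    def test_dwui_is_deviation_from_weighted_baseline(self):
        wui = pd.DataFrame({"g": [0.6, 0.6, 0.45]}, index=["nt1", "nt2", "kd"])
        tpm = pd.DataFrame({"g": [50.0, 50.0, 50.0]}, index=wui.index)
        cells = pd.Series([100, 100, 40], index=wui.index)
        eff = pt.compute_effects(wui, tpm, cells, ["nt1", "nt2"])
        assert eff.baseline_wui["g"] == pytest.approx(0.6)
        assert eff.dwui.loc["kd", "g"] == pytest.approx(-0.15)
        assert eff.avg_dwui["kd"] == pytest.approx(-0.15)

    def test_low_tpm_and_extreme_wui_genes_excluded_from_averages(self):
        wui = pd.DataFrame({"lo": [0.5, 0.4], "hi": [0.95, 0.8], "ok": [0.5, 0.3]},
                           index=["nt", "kd"])
        tpm = pd.DataFrame({"lo": [4.0, 4.0], "hi": [50.0, 50.0], "ok": [50.0, 50.0]},
                           index=wui.index)
        cells = pd.Series([100, 50], index=wui.index)
        eff = pt.compute_effects(wui, tpm, cells, ["nt"])
        # only 'ok' passes: TPM 4 fails > 5; baseline 0.95 outside [0.1, 0.9]
        assert eff.avg_dwui["kd"] == pytest.approx(-0.2)

    def test_small_perturbations_dropped(self):
        wui, tpm, cells, nt = simple_inputs()
        cells["kd0"] = 10
        eff = pt.compute_effects(wui, tpm, cells, nt, min_cells=30)
        assert "kd0" not in eff.dwui.index

    def test_requires_non_targeting(self):
        wui, tpm, cells, _ = simple_inputs()
        with pytest.raises(ValueError):
            pt.compute_effects(wui, tpm, cells, [])

    def test_non_targeting_mean_effect_near_zero(self):
        rng = np.random.default_rng(1)
        perts = [f"nt{i}" for i in range(40)]
        genes = [f"g{i}" for i in range(200)]
        base = rng.uniform(0.2, 0.8, len(genes))
        wui = pd.DataFrame(base + rng.normal(0, 0.01, (len(perts), len(genes))),
                           index=perts, columns=genes)
        tpm = pd.DataFrame(50.0, index=perts, columns=genes)
        cells = pd.Series(100, index=perts)
        eff = pt.compute_effects(wui, tpm, cells, perts)
        assert abs(eff.avg_dwui.mean()) < 0.005


class TestZscaleImpute:
    def _effects(self, dwui):
        return pt.EffectMatrix(
            dwui=dwui, baseline_wui=pd.Series(0.5, index=dwui.columns),
            cell_counts=pd.Series(100, index=dwui.index),
            avg_dwui=pd.Series(0.0, index=dwui.index))

    def test_row_scaled_to_unit_uncentered_variance(self):
        dwui = pd.DataFrame([[0.1, -0.1, 0.2, -0.2]], index=["p"],
                            columns=list("abcd"))
        z = pt.zscale_impute(self._effects(dwui))
        row = z.loc["p"].to_numpy()
        assert np.mean(row**2) == pytest.approx(1.0, abs=1e-9)
        assert np.sign(row).tolist() == [1, -1, 1, -1]

    def test_all_missing_row_becomes_zeros(self):
        dwui = pd.DataFrame([[np.nan] * 3, [0.1, 0.2, -0.1]],
                            index=["empty", "p"], columns=list("abc"))
        eff = self._effects(dwui)
        z = pt.zscale_impute(eff)
        assert (z.loc["empty"] == 0.0).all()
        assert "empty" in eff.zero_variance_rows

    def test_imputed_entries_exactly_zero(self):
        dwui = pd.DataFrame([[0.1, np.nan, -0.3]], index=["p"], columns=list("abc"))
        z = pt.zscale_impute(self._effects(dwui))
        assert z.loc["p", "b"] == 0.0

    def test_idempotent_on_unit_variance_rows(self):
        dwui = pd.DataFrame([[0.3, -0.4, 0.5, 0.1]], index=["p"], columns=list("abcd"))
        eff = self._effects(dwui)
        z1 = pt.zscale_impute(eff)
        z2 = pt.zscale_impute(self._effects(z1))
        pd.testing.assert_frame_equal(z1, z2)

    def test_gene_filters_applied_before_scaling(self):
        dwui = pd.DataFrame([[0.1, 0.5]], index=["p"], columns=["keep", "drop"])
        z = pt.zscale_impute(self._effects(dwui),
                             control_tpm=pd.Series({"keep": 30.0, "drop": 5.0}))
        assert list(z.columns) == ["keep"]


class TestClustering:
    def test_planted_modules_recovered(self):
        mat, plab, _ = make_planted_effect_matrix(60, 300, 3, noise_sd=0.3, seed=0)
        labels = pt.knn_walktrap(mat.to_numpy(), n_pcs=30, k=5)
        assert adjusted_rand_score(plab, labels) > 0.9

    def test_identical_rows_single_cluster(self):
        mat = np.tile([[1.0, -1.0, 0.5]], (8, 1))
        labels = pt.knn_walktrap(mat, n_pcs=2, k=3)
        assert len(set(labels)) == 1

    def test_permutation_equivariance(self):
        mat, _, _ = make_planted_effect_matrix(30, 100, 3, noise_sd=0.2, seed=3)
        labels = pt.knn_walktrap(mat.to_numpy(), n_pcs=10, k=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        labels_perm = pt.knn_walktrap(mat.to_numpy()[perm], n_pcs=10, k=5)
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_multi_round_pipeline_returns_labels(self):
        mat, plab, glab = make_planted_effect_matrix(60, 120, 3, noise_sd=0.2, seed=1)
        res = pt.cluster_perturbations(
            mat, rounds=(
                {"axis": "perturbations", "n_pcs": 20, "k": 5, "drop_patternless": False},
                {"axis": "genes", "n_pcs": 20, "k": 4, "drop_patternless": False},
                {"axis": "both", "n_pcs": 20, "k": 3, "drop_patternless": False},
            ))
        assert adjusted_rand_score(
            plab, res.perturbation_labels.to_numpy()) > 0.9
        assert res.gene_labels is not None
        assert set(res.retained_perturbations) == set(mat.index)

    def test_patternless_cluster_removal(self):
        rng = np.random.default_rng(5)
        strong, _, _ = make_planted_effect_matrix(40, 100, 2, noise_sd=0.2,
                                                  signal=2.0, seed=2)
        flat = pd.DataFrame(rng.normal(0, 0.02, (20, 100)),
                            index=[f"flat{i}" for i in range(20)],
                            columns=strong.columns)
        mat = pd.concat([strong, flat])
        res = pt.cluster_perturbations(
            mat, rounds=(
                {"axis": "perturbations", "n_pcs": 10, "k": 5,
                 "drop_patternless": True},
            ), patternless_quantile=0.34)
        dropped = set(mat.index) - set(res.retained_perturbations)
        assert dropped and dropped <= set(flat.index)


class TestClusterDiffTests:
    def test_exact_mannwhitney_worked_example(self):
        p = pt._mannwhitney_p(pd.Series([0.2, 0.25, 0.3]), pd.Series([0.6, 0.65, 0.7]))
        assert p == pytest.approx(0.1)

    def test_all_tied_values_p_one(self):
        p = pt._mannwhitney_p(pd.Series([0.5, 0.5]), pd.Series([0.5, 0.5]))
        assert p == 1.0

    def test_planted_shortening_detected(self):
        rng = np.random.default_rng(7)
        n_nt, n_kd, n_genes = 30, 20, 60
        genes = [f"g{i}" for i in range(n_genes)]
        nt_ids = [f"nt{i}" for i in range(n_nt)]
        kd_ids = [f"kd{i}" for i in range(n_kd)]
        base = rng.uniform(0.4, 0.6, n_genes)
        wui_nt = base + rng.normal(0, 0.03, (n_nt, n_genes))
        wui_kd = base + rng.normal(0, 0.03, (n_kd, n_genes))
        wui_kd[:, :50] -= 0.25  # planted shortening in 50 genes
        wui = pd.DataFrame(np.vstack([wui_nt, wui_kd]), index=nt_ids + kd_ids,
                           columns=genes)
        tpm = pd.DataFrame(50.0, index=wui.index, columns=genes)
        labels = pd.Series("c1", index=kd_ids)
        res = pt.cluster_diff_tests(wui, tpm, labels, nt_ids)
        hits = res[(res["dul_sig"]) & (res["direction"] == "shortening")]
        assert len(hits) >= 45
        assert set(hits["gene_id"]) <= set(genes[:50])


class TestCompensation:
    def test_balanced_shift_is_coordinated(self):
        r = pt.compensation_classify("g", "c", 100.0, 0.3, 100.0, 0.5)
        assert (r.dtpm_su, r.dtpm_lu) == pytest.approx((20.0, -20.0))
        assert r.category == "coordinated"

    def test_su_only_shift(self):
        r = pt.compensation_classify("g", "c", 120.0, 5 / 12, 100.0, 0.5)
        assert r.dtpm_su == pytest.approx(20.0)
        assert r.dtpm_lu == pytest.approx(0.0, abs=1e-9)
        assert r.category == "SU-specific"

    def test_ratio_minus_two_boundary_inclusive(self):
        # dSU = +10, dLU = -20 -> ratio exactly -2
        r = pt.compensation_classify("g", "c", 90.0, 4 / 9, 100.0, 0.6)
        assert r.dtpm_lu / r.dtpm_su == pytest.approx(-2.0)
        assert r.category == "coordinated"

    def test_no_change_is_uncategorized(self):
        r = pt.compensation_classify("g", "c", 100.0, 0.5, 100.0, 0.5)
        assert r.category is None

    def test_su_lu_symmetry_on_random_records(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            tc, tn = rng.uniform(10, 200, 2)
            wc, wn = rng.uniform(0.05, 0.95, 2)
            a = pt.compensation_classify("g", "c", tc, wc, tn, wn)
            b = pt.compensation_classify("g", "c", tc, 1 - wc, tn, 1 - wn)
            mapping = {"SU-specific": "LU-specific", "LU-specific": "SU-specific",
                       "coordinated": "coordinated", None: None}
            assert b.category == mapping[a.category]
            assert {a.category, b.category} <= {"SU-specific", "coordinated",
                                                "LU-specific", None}


class TestOverlap:
    def test_zero_overlap_enrichment_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {("c1", "shortening"): {f"g{i}" for i in range(10)},
                ("c2", "shortening"): {f"g{i}" for i in range(10, 20)}}
        res = pt.cluster_overlap(sets, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_identical_sets_vanishingly_small_p(self):
        universe = {f"g{i}" for i in range(100)}
        shared = {f"g{i}" for i in range(10)}
        sets = {("c1", "shortening"): shared, ("c2", "shortening"): shared}
        res = pt.cluster_overlap(sets, universe)
        assert res.loc[0, "neg_log10_p"] > 10

    def test_symmetry(self):
        universe = {f"g{i}" for i in range(50)}
        a = {f"g{i}" for i in range(15)}
        b = {f"g{i}" for i in range(8, 30)}
        p1 = pt.cluster_overlap({("c1", "shortening"): a, ("c2", "shortening"): b},
                                universe).loc[0, "p"]
        p2 = pt.cluster_overlap({("c1", "shortening"): b, ("c2", "shortening"): a},
                                universe).loc[0, "p"]
        assert p1 == pytest.approx(p2)

    def test_antagonistic_pairs_labeled(self):
        universe = {f"g{i}" for i in range(50)}
        sets = {("c1", "shortening"): {"g1"}, ("c2", "lengthening"): {"g1"}}
        res = pt.cluster_overlap(sets, universe)
        assert res.loc[0, "type"] == "antagonistic"


class TestValidateReplicates:
    def test_exact_replicate_correlates_perfectly(self):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        avg = pd.Series(rng.normal(0, 1, 30), index=genes)
        reps = pd.DataFrame([avg.to_numpy(), (-avg).to_numpy()],
                            index=["same", "neg"], columns=genes)
        nt = pd.DataFrame(rng.normal(0, 1, (10, 30)),
                          index=[f"nt{i}" for i in range(10)], columns=genes)
        res = pt.validate_replicates(
            {"c1": avg}, reps, {"same": "c1", "neg": "other"}, nt)
        assert res.loc[0, "median_replicate_r"] == pytest.approx(1.0)

    def test_planted_attenuation(self):
        """Replicates sharing half the variance correlate near 1/sqrt(2)."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(400)]
        signal = rng.normal(0, 1, 400)
        avg = pd.Series(signal, index=genes)
        reps = pd.DataFrame(
            signal + rng.normal(0, 1, (20, 400)),
            index=[f"r{i}" for i in range(20)], columns=genes)
        nt = pd.DataFrame(rng.normal(0, 1, (20, 400)),
                          index=[f"nt{i}" for i in range(20)], columns=genes)
        res = pt.validate_replicates({"c1": avg}, reps,
                                     {f"r{i}": "c1" for i in range(20)}, nt)
        assert res.loc[0, "median_replicate_r"] == pytest.approx(0.71, abs=0.06)
        assert abs(res.loc[0, "median_control_r"]) < 0.1
        assert res.loc[0, "p"] < 0.01


class TestFeatureCorrelation:
    def _dwui(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(100)]
        return pd.DataFrame(rng.normal(0, 0.2, (2, 100)),
                            index=["c1", "c2"], columns=genes)

    def test_self_feature_correlates_perfectly(self):
        dwui = self._dwui()
        features = pd.DataFrame({"self": dwui.loc["c1"]})
        res = pt.feature_correlation(dwui, features)
        r = res[(res["cluster"] == "c1") & (res["feature"] == "self")]["r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_independent_feature_uncorrelated(self):
        dwui = self._dwui()
        rng = np.random.default_rng(3)
        features = pd.DataFrame({"noise": rng.normal(0, 1, 100)},
                                index=dwui.columns)
        res = pt.feature_correlation(dwui, features)
        assert res["r"].abs().max() < 0.3

    def test_negative_feature_significant(self):
        dwui = self._dwui()
        rng = np.random.default_rng(4)
        features = pd.DataFrame(
            {"anti": -dwui.loc["c1"] + rng.normal(0, 0.05, 100)},
            index=dwui.columns)
        res = pt.feature_correlation(dwui, features)
        row = res[(res["cluster"] == "c1") & (res["feature"] == "anti")].iloc[0]
        assert row["r"] < -0.9 and row["significant"]

    def test_constant_feature_nan(self):
        dwui = self._dwui()
        features = pd.DataFrame({"const": 1.0}, index=dwui.columns)
        res = pt.feature_correlation(dwui, features)
        assert res["r"].isna().all()


class TestHalfLife:
    TIMEPOINTS = np.array([0.0, 120.0, 240.0, 360.0])

    @pytest.mark.parametrize("k", [0.002, 0.005, 0.01])
    def test_recovers_rate_on_noiseless_curves(self, k):
        c = 0.25 * (1 - np.exp(-k * self.TIMEPOINTS))
        fit = pt.fit_half_life(self.TIMEPOINTS, c)
        assert fit.k == pytest.approx(k, rel=0.05)
        assert fit.half_life == pytest.approx(np.log(2) / k, rel=0.05)

    def test_worked_half_life_value(self):
        c = 0.3 * (1 - np.exp(-0.005 * self.TIMEPOINTS))
        fit = pt.fit_half_life(self.TIMEPOINTS, c)
        assert fit.half_life == pytest.approx(138.63, abs=0.1)

    def test_weighted_mean_of_replicates(self):
        rates = np.array([[0.1, 0.1, 0.1, 0.1], [0.3, 0.3, 0.3, 0.3]])
        weights = np.array([1.0, 3.0])
        fit = pt.fit_half_life(self.TIMEPOINTS, rates, weights=weights)
        # weighted mean conversion is flat 0.25: degenerate, flagged
        assert fit.reliable is False or fit.half_life < 120

    def test_saturated_curve_flagged(self):
        c = 0.3 * (1 - np.exp(-0.05 * self.TIMEPOINTS))  # saturates by t=120
        fit = pt.fit_half_life(self.TIMEPOINTS, c)
        assert fit.half_life < 120
        assert fit.reliable is False

    def test_zero_conversion_infinite_half_life(self):
        fit = pt.fit_half_life(self.TIMEPOINTS, np.zeros(4))
        assert np.isinf(fit.half_life) and not fit.reliable

    def test_non_increasing_conversion_flagged(self):
        fit = pt.fit_half_life(self.TIMEPOINTS, np.array([0.0, 0.2, 0.15, 0.25]))
        assert fit.reliable is False
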