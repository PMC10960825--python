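import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from crossomic.containers import ModuleRecord, MultiOmicDataset, OmicTable, ScaleState
from crossomic.evaluation import (
    _null_stat_summary,
    classify_module,
    cross_omic_correlation,
    differential_direction,
    evaluate_module,
    ModuleEvaluation,
    module_pc1,
    modules_pc_rf,
    NullSummary,
    null_distributions,
    pc1_auc,
    sample_null_module,
)


def _dataset(t_vals, m_vals, labels):
    n = len(labels)
    samples = [f"s{i}" for i in range(n)]
    t = pd.DataFrame(np.asarray(t_vals, dtype=float), index=samples,
                     columns=[f"T:f{j}" for j in range(np.asarray(t_vals).shape[1])])
    m = pd.DataFrame(np.asarray(m_vals, dtype=float), index=samples,
                     columns=[f"M:g{j}" for j in range(np.asarray(m_vals).shape[1])])
    return MultiOmicDataset(
        omics=[OmicTable("T", t, ScaleState.LOG), OmicTable("M", m, ScaleState.LOG)],
        labels=pd.Series(labels, index=samples),
    )


class TestModulePc1:
    def test_perfectly_correlated_pair_explains_everything(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 3.0])
        ds = _dataset(np.column_stack([x, x]), np.ones((6, 1)) * np.arange(6)[:, None],
                      [0, 0, 0, 1, 1, 1])
        scores, evr = module_pc1(ds, ["T:f0", "T:f1"], return_evr=True)
        assert evr == pytest.approx(1.0)

    def test_uncorrelated_pair_splits_variance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000)
        ds = _dataset(np.column_stack([a, b]), rng.standard_normal((2000, 1)),
                      [0, 1] * 1000)
        _scores, evr = module_pc1(ds, ["T:f0", "T:f1"], return_evr=True)
        assert evr == pytest.approx(0.5, abs=0.03)

    def test_matches_hand_eigendecomposition(self):
        # small matrix; PC1 from the closed-form eigenvector of the 2x2
        # correlation matrix [[1, r], [r, 1]]: (1, sign(r))/sqrt(2)
        X = np.array([[1.0, 2.0], [2.0, 1.0], [6.0, 4.0], [3.0, 9.0]])
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        r = (Z[:, 0] @ Z[:, 1]) / 3
        v = np.array([1.0, 1.0 if r > 0 else -1.0]) / np.sqrt(2)
        expected = Z @ v
        ds = _dataset(X, np.arange(4.0).reshape(-1, 1), [0, 0, 1, 1])
        scores = module_pc1(ds, ["T:f0", "T:f1"])
        assert np.allclose(scores, expected) or np.allclose(scores, -expected)

    def test_constant_feature_dropped_with_warning(self, caplog):
        X = np.column_stack([np.ones(4), [1.0, 2.0, 3.0, 4.0]])
        ds = _dataset(X, np.arange(4.0).reshape(-1, 1), [0, 0, 1, 1])
        with caplog.at_level("WARNING"):
            scores = module_pc1(ds, ["T:f0", "T:f1"])
        assert "constant" in caplog.text
        assert len(scores) == 4


class TestPc1Auc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([4, 3, 2, 1], [0, 0, 1, 1], 1.0),  # sign-flip orientation
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),  # 3 of 4 case-control pairs concordant
        ],
    )
    def test_hand_enumerated_examples(self, scores, labels, expected):
        assert pc1_auc(np.array(scores, dtype=float), labels) == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        base = pc1_auc(s, y)
        assert pc1_auc(np.exp(s), y) == pytest.approx(base)
        assert pc1_auc(-3 * s + 7, y) == pytest.approx(base)

    def test_single_class_fails(self):
        with pytest.raises(ValueError):
            pc1_auc(np.arange(4.0), [1, 1, 1, 1])


class TestSampleNullModule:
    def _ds(self):
        rng = np.random.default_rng(2)
        return _dataset(rng.random((10, 12)), rng.random((10, 6)), [0] * 5 + [1] * 5)

    def test_matches_per_omic_counts(self):
        ds = self._ds()
        rng = np.random.default_rng(0)
        feats = sample_null_module(ds, {"T": 2, "M": 1}, rng)
        assert sum(f.startswith("T:") for f in feats) == 2
        assert sum(f.startswith("M:") for f in feats) == 1

    def test_oversized_request_fails(self):
        with pytest.raises(ValueError, match="cannot draw"):
            sample_null_module(self._ds(), {"M": 7}, np.random.default_rng(0))

    def test_different_rng_states_differ(self):
        ds = self._ds()
        a = sample_null_module(ds, {"T": 5}, np.random.default_rng(1))
        b = sample_null_module(ds, {"T": 5}, np.random.default_rng(2))
        assert a != b


class TestCrossOmicCorrelation:
    def test_monotone_transform_pair_has_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        ds = _dataset(x.reshape(-1, 1), np.exp(x).reshape(-1, 1), [0, 0, 0, 1, 1, 1])
        rho, table = cross_omic_correlation(ds, [("T", "T:f0"), ("M", "M:g0")])
        assert rho == pytest.approx(1.0)
        assert len(table) == 1

    def test_single_omic_module_undefined(self):
        rng = np.random.default_rng(3)
        ds = _dataset(rng.random((8, 3)), rng.random((8, 2)), [0] * 4 + [1] * 4)
        rho, table = cross_omic_correlation(ds, [("T", "T:f0"), ("T", "T:f1")])
        assert np.isnan(rho) and table.empty

    def test_mean_matches_manual_rank_computation(self):
        rng = np.random.default_rng(4)
        T = rng.random((5, 2))
        M = rng.random((5, 2))
        ds = _dataset(T, M, [0, 0, 1, 1, 1])
        members = [("T", "T:f0"), ("T", "T:f1"), ("M", "M:g0"), ("M", "M:g1")]
        rho, table = cross_omic_correlation(ds, members)
        manual = []
        for i in range(2):
            for j in range(2):
                ra, rb = rankdata(T[:, i]), rankdata(M[:, j])
                manual.append(np.corrcoef(ra, rb)[0, 1])
        assert rho == pytest.approx(np.mean(manual))
        assert len(table) == 4

    def test_fast_path_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        ds = _dataset(rng.random((12, 3)), rng.random((12, 2)), [0] * 6 + [1] * 6)
        members = [("T", "T:f0"), ("T", "T:f2"), ("M", "M:g0"), ("M", "M:g1")]
        slow, _ = cross_omic_correlation(ds, members, with_pvalues=True)
        fast, _ = cross_omic_correlation(ds, members, with_pvalues=False)
        assert fast == pytest.approx(slow)


def _evaluation(auc, auc_exc, rho_exc, multi):
    mk = lambda obs, exc: NullSummary(100, 0.5, 0.05, obs, exc)
    return ModuleEvaluation(
        auc=auc, auc_null=mk(auc, auc_exc), cross_omic_rho=0.3,
        rho_null=mk(0.3, rho_exc), pairwise_stats=pd.DataFrame(),
        is_multi_omic=multi, is_disease_associated=False,
    )


class TestClassifyModule:
    def test_paper_style_pass(self):
        # e.g. AUC 0.86 with both exceedances on a multi-omic module
        assert classify_module(_evaluation(0.86, True, True, True))

    def test_auc_below_threshold_fails(self):
        assert not classify_module(_evaluation(0.69, True, True, True))

    def test_single_omic_gate(self):
        assert not classify_module(_evaluation(0.9, True, True, False))

    @pytest.mark.parametrize("auc_exc,rho_exc", [(False, True), (True, False)])
    def test_exceedance_gates(self, auc_exc, rho_exc):
        assert not classify_module(_evaluation(0.85, auc_exc, rho_exc, True))

    def test_monotone_in_auc(self):
        # improving the AUC can never flip associated -> not associated
        lo = classify_module(_evaluation(0.75, True, True, True))
        hi = classify_module(_evaluation(0.95, True, True, True))
        assert hi >= lo


class TestNullSummary:
    def test_exceedance_mean_rule_matches_observed_vs_null_mean(self):
        # observed AUC 0.72 vs null mean 0.63 -> exceedance
        s = _null_stat_summary(0.72, np.array([0.63, 0.60, 0.66]), rule="mean")
        assert s.exceedance and s.null_mean == pytest.approx(0.63)
        s2 = _null_stat_summary(0.55, np.array([0.63, 0.60, 0.66]), rule="mean")
        assert not s2.exceedance

    def test_p95_rule_stricter(self):
        null = np.linspace(0.5, 0.8, 100)
        assert _null_stat_summary(0.75, null, "mean").exceedance
        assert not _null_stat_summary(0.75, null, "p95").exceedance


class TestNullDistributions:
    def test_planted_module_beats_null(self, small_synthetic):
        from crossomic.pipeline import preprocess_dataset
        from crossomic.containers import PipelineConfig

        dataset, truth = small_synthetic
        pp, _ = preprocess_dataset(dataset, PipelineConfig())
        present = set(pp.feature_frame().columns)
        members = [(f.split(":")[0], f) for f in sorted(truth.member_features("planted0"))
                   if f in present]
        module = ModuleRecord("planted", members, [])
        auc_s, rho_s = null_distributions(pp, module, n_null=50,
                                          rng=np.random.default_rng(0))
        assert auc_s.exceedance and rho_s.exceedance
        assert auc_s.observed > 0.8

    def test_whole_feature_space_module_not_exceeding(self):
        rng = np.random.default_rng(7)
        ds = _dataset(rng.random((30, 3)), rng.random((30, 2)), [0] * 15 + [1] * 15)
        members = [("T", f"T:f{j}") for j in range(3)] + [("M", f"M:g{j}") for j in range(2)]
        module = ModuleRecord("all", members, [])
        auc_s, rho_s = null_distributions(ds, module, n_null=20,
                                          rng=np.random.default_rng(1))
        # nulls redraw the full feature set: identical statistic, no exceedance
        assert not auc_s.exceedance and not rho_s.exceedance
        assert auc_s.null_sd == pytest.approx(0.0, abs=1e-12)


class TestDifferentialDirection:
    def _module(self):
        return ModuleRecord("m", [("T", "T:f0"), ("T", "T:f1"), ("M", "M:g0")], [])

    def test_directions_and_ns(self):
        rng = np.random.default_rng(8)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        up = y * 3.0 + rng.normal(0, 0.1, n)
        same = rng.normal(0, 1, n)
        down = -y * 2.0 + rng.normal(0, 0.1, n)
        ds = _dataset(np.column_stack([up, same]), down.reshape(-1, 1), y)
        table = differential_direction(ds, self._module()).set_index("feature")
        assert table.loc["T:f0", "direction"] == "up"
        assert table.loc["T:f1", "direction"] == "ns"
        assert table.loc["M:g0", "direction"] == "down"

    def test_u_statistic_matches_hand_enumeration(self):
        # 3 cases (5,6,7) vs 3 controls (1,2,3): every case beats every
        # control, U = 9, exact two-sided p = 0.1
        y = [0, 0, 0, 1, 1, 1]
        vals = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        ds = _dataset(np.column_stack([vals, vals[::-1]]), vals.reshape(-1, 1), y)
        table = differential_direction(ds, self._module()).set_index("feature")
        assert table.loc["T:f0", "U"] == 9.0
        assert table.loc["T:f0", "p"] == pytest.approx(0.1)


class TestModulesPcRf:
    def test_separating_module_reaches_high_auc(self, small_synthetic):
        from crossomic.pipeline import preprocess_dataset
        from crossomic.containers import PipelineConfig

        dataset, truth = small_synthetic
        pp, _ = preprocess_dataset(dataset, PipelineConfig())
        present = set(pp.feature_frame().columns)
        members = [(f.split(":")[0], f) for f in sorted(truth.member_features("planted0"))
                   if f in present]
        module = ModuleRecord("planted", members, [])
        out = modules_pc_rf(pp, [module], folds=5, repeats=1, seed=0, n_estimators=100)
        assert out["mean_auc"] > 0.9

    def test_noise_modules_near_chance(self):
        rng = np.random.default_rng(9)
        ds = _dataset(rng.standard_normal((60, 6)), rng.standard_normal((60, 4)),
                      [0] * 30 + [1] * 30)
        module = ModuleRecord(
            "noise", [("T", f"T:f{j}") for j in range(4)] + [("M", "M:g0")], []
        )
        out = modules_pc_rf(ds, [module], folds=5, repeats=2, seed=1, n_estimators=100)
        assert abs(out["mean_auc"] - 0.5) < 0.2
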