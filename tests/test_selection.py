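"""Feature reduction: chi-squared primitive vs the scipy oracle, stability
screening behaviour, the logistic Wald filter, and PCA vs an eigendecomposition
oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aspredict import selection

CFG = selection.SelectionConfig()


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

class TestChi2:
    def test_worked_example(self):
        # [[30, 70], [10, 90]]: stat = 200*(30*90-70*10)^2/(100*100*40*160)
        stat, p = selection.chi2_2x2(30, 70, 10, 90)
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(4.0695e-4, rel=1e-3)

    def test_equal_rates_give_zero_statistic(self):
        stat, p = selection.chi2_2x2(25, 75, 25, 75)
        assert stat == 0.0 and p == 1.0

    def test_degenerate_margin_flagged(self):
        stat, p, degenerate = selection.chi2_tables(0, 0, 10, 90)
        assert degenerate.all() and stat == 0.0 and p == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            selection.chi2_2x2(-1, 5, 5, 5)

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        tables = rng.integers(1, 500, size=(300, 4))
        stat, p, _ = selection.chi2_tables(*tables.T)
        for i, (a, b, c, d) in enumerate(tables):
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat[i] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-300)

    @given(st.integers(0, 1000), st.integers(0, 1000),
           st.integers(0, 1000), st.integers(0, 1000))
    @settings(max_examples=80, deadline=None)
    def test_statistic_nonnegative_and_p_in_unit_interval(self, a, b, c, d):
        stat, p = selection.chi2_2x2(a, b, c, d)
        assert stat >= 0.0 and 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# stability screening
# ---------------------------------------------------------------------------

def _matrices(case_rates, control_rates, n_case=100, n_ctl=100, n_sets=10,
              seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"f{i}" for i in range(len(case_rates))]
    case = pd.DataFrame((rng.random((n_case, len(cols)))
                         < np.array(case_rates)).astype(np.uint8), columns=cols)
    ctls = [pd.DataFrame((rng.random((n_ctl, len(cols)))
                          < np.array(control_rates)).astype(np.uint8),
                         columns=cols) for _ in range(n_sets)]
    return case, ctls


class TestStability:
    def test_extreme_signal_selected_and_null_not(self):
        case, ctls = _matrices([0.9, 0.3], [0.1, 0.3], n_sets=10)
        cfg = selection.SelectionConfig(n_cohorts=10)
        res = selection.stability_screen(case, ctls, cfg)
        assert res.selected == ["f0"]
        row = res.table.set_index("feature_key")
        assert row.loc["f0", "direction"] == 1
        assert row.loc["f0", "n_pass"] == 10

    def test_control_enriched_feature_kept_with_negative_direction(self):
        case, ctls = _matrices([0.1], [0.9], n_sets=10)
        cfg = selection.SelectionConfig(n_cohorts=10)
        res = selection.stability_screen(case, ctls, cfg)
        assert res.selected == ["f0"]
        assert res.table.loc[0, "direction"] == -1

    def test_threshold_rounds_up(self):
        # 0.90 of 10 -> 9; 0.75 of 10 -> 8 (ceil)
        case, ctls = _matrices([0.5], [0.5], n_sets=10)
        res = selection.stability_screen(
            case, ctls, selection.SelectionConfig(n_cohorts=10,
                                                  stability_fraction=0.75))
        assert res.threshold == 8

    def test_selection_monotone_in_stability_fraction(self):
        case, ctls = _matrices([0.7, 0.45, 0.3], [0.3, 0.35, 0.3],
                               n_sets=20, seed=5)
        selected = []
        for frac in (0.5, 0.75, 1.0):
            cfg = selection.SelectionConfig(n_cohorts=20, stability_fraction=frac)
            selected.append(set(selection.stability_screen(case, ctls, cfg).selected))
        assert selected[2] <= selected[1] <= selected[0]

    def test_mismatched_columns_rejected(self):
        case, ctls = _matrices([0.5], [0.5], n_sets=2)
        ctls[1] = ctls[1].rename(columns={"f0": "g0"})
        with pytest.raises(ValueError, match="mismatch"):
            selection.stability_screen(
                case, ctls, selection.SelectionConfig(n_cohorts=2))

    def test_wrong_number_of_control_sets_rejected(self):
        case, ctls = _matrices([0.5], [0.5], n_sets=3)
        with pytest.raises(ValueError, match="control matrices"):
            selection.stability_screen(case, ctls,
                                       selection.SelectionConfig(n_cohorts=5))

    def test_type_one_error_by_simulation(self):
        """Under the null, a single test rejects at ~alpha; demanding 90% of
        20 independent tests drives selection to (essentially) zero."""
        rng = np.random.default_rng(99)
        n_feat, n_sets = 200, 20
        cols = [f"f{i}" for i in range(n_feat)]
        case = pd.DataFrame(rng.integers(0, 2, (100, n_feat)).astype(np.uint8),
                            columns=cols)
        ctls = [pd.DataFrame(rng.integers(0, 2, (100, n_feat)).astype(np.uint8),
                             columns=cols) for _ in range(n_sets)]
        cfg = selection.SelectionConfig(n_cohorts=n_sets)
        res = selection.stability_screen(case, ctls, cfg)
        # per-test rejection rate close to alpha = 0.01
        rate = res.table["n_pass"].sum() / (n_feat * n_sets)
        assert rate < 0.03
        assert len(res.selected) == 0


# ---------------------------------------------------------------------------
# logistic filter
# ---------------------------------------------------------------------------

def _design(seed=0, n=400):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    strong = (rng.random(n) < np.where(y == 1, 0.7, 0.2)).astype(np.uint8)
    noise = rng.integers(0, 2, n).astype(np.uint8)
    return pd.DataFrame({"strong": strong, "noise": noise}), y


class TestLRFilter:
    def test_strong_effect_retained_noise_dropped(self):
        X, y = _design(seed=1)
        res = selection.lr_filter(X, y, CFG)
        t = res.table.set_index("feature_key")
        assert t.loc["strong", "retained"]
        assert not t.loc["noise", "retained"]

    def test_duplicate_column_flagged_not_fit(self):
        X, y = _design(seed=2)
        X["copy"] = X["strong"]
        res = selection.lr_filter(X, y, CFG)
        t = res.table.set_index("feature_key")
        assert t.loc["copy", "flag"] == "duplicate"
        assert not t.loc["copy", "retained"]
        assert t.loc["strong", "retained"]

    def test_complete_separation_flagged_and_retained(self):
        y = np.repeat([1, 0], 50)
        X = pd.DataFrame({"sep": y.astype(np.uint8)})
        res = selection.lr_filter(X, y, CFG)
        row = res.table.iloc[0]
        assert row["flag"] in ("separation",)
        assert row["retained"]

    def test_empty_matrix_returns_empty_result(self):
        res = selection.lr_filter(pd.DataFrame(index=range(10)),
                                  np.repeat([1, 0], 5), CFG)
        assert res.retained == []

    def test_joint_mode_matches_glm_oracle(self):
        """On a well-conditioned design the joint Wald p-values agree with an
        independent GLM-Binomial fit to high precision."""
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        n = 600
        X = pd.DataFrame({
            "x1": rng.integers(0, 2, n).astype(np.uint8),
            "x2": rng.integers(0, 2, n).astype(np.uint8),
        })
        logit_p = -0.5 + 1.2 * X["x1"] - 0.4 * X["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit_p))).astype(float)
        cfg = selection.SelectionConfig(lr_mode="joint")
        res = selection.lr_filter(X, y, cfg)
        glm = sm.GLM(y, sm.add_constant(X.to_numpy(dtype=float)),
                     family=sm.families.Binomial()).fit()
        t = res.table.set_index("feature_key")
        for j, c in enumerate(["x1", "x2"]):
            beta, se = glm.params.iloc[j + 1], glm.bse.iloc[j + 1]
            assert t.loc[c, "coef"] == pytest.approx(beta, abs=1e-6)
            oracle_p = 2 * stats.norm.sf(abs(beta / se))
            assert t.loc[c, "p_value"] == pytest.approx(oracle_p, abs=1e-6)

    def test_univariable_mode_matches_scalar_refits(self):
        X, y = _design(seed=3)
        res = selection.lr_filter(X, y, CFG)
        t = res.table.set_index("feature_key")
        for c in X.columns:
            solo = selection.lr_filter(X[[c]], y, CFG).table.iloc[0]
            assert t.loc[c, "p_value"] == pytest.approx(solo["p_value"], abs=1e-12)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _binary_matrix(seed=0, n=120, p=8):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, (n, 3)).astype(np.uint8)
    extra = np.column_stack([
        base[:, i % 3] ^ (rng.random(n) < 0.1) for i in range(p - 3)
    ]).astype(np.uint8)
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(np.column_stack([base, extra]), columns=cols)


class TestPCA:
    def test_single_dominant_axis(self):
        rng = np.random.default_rng(4)
        shared = rng.integers(0, 2, 200).astype(np.uint8)
        m = pd.DataFrame({"f0": shared, "f1": shared, "f2": shared})
        model = selection.fit_pca(m, selection.SelectionConfig(
            pca_variance_target=0.8))
        assert model.n_retained == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_of_training_data_have_zero_mean(self):
        m = _binary_matrix(seed=5)
        model = selection.fit_pca(m)
        scores = selection.project(model, m)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        m = _binary_matrix(seed=6)
        model = selection.fit_pca(m)
        X = m.to_numpy(dtype=float)
        cov = np.cov(X, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        assert np.allclose(model.explained_variance_ratio, w / w.sum(),
                           atol=1e-8)
        for i in range(model.components.shape[0]):
            # loading vectors agree up to sign
            dot = abs(model.components[i] @ v[:, i])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_are_orthonormal(self):
        model = selection.fit_pca(_binary_matrix(seed=7))
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_full_projection_reconstructs_the_data(self):
        m = _binary_matrix(seed=8)
        model = selection.fit_pca(m)
        k = model.components.shape[0]
        scores = selection.project(model, m, n_components=k)
        recon = scores @ model.components + model.mean
        assert np.allclose(recon, m.to_numpy(dtype=float), atol=1e-8)

    def test_retention_reaches_the_variance_target(self):
        cfg = selection.SelectionConfig(pca_variance_target=0.8)
        model = selection.fit_pca(_binary_matrix(seed=9), cfg)
        cum = np.cumsum(model.explained_variance_ratio)
        assert cum[model.n_retained - 1] >= 0.8 - 1e-9
        if model.n_retained > 1:
            assert cum[model.n_retained - 2] < 0.8

    @pytest.mark.parametrize("bad", [
        pd.DataFrame({"f0": [1, 0, 1]}),                        # one feature
        pd.DataFrame({"f0": [1, 0], "f1": [0, 1]}),             # two rows
        pd.DataFrame({"f0": [1] * 5, "f1": [0] * 5}),           # constant
    ])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            selection.fit_pca(bad)

    def test_alignment_fills_missing_and_drops_unknown_features(self):
        m = _binary_matrix(seed=10)
        model = selection.fit_pca(m)
        new = m.drop(columns=["f0"]).assign(unknown=1)
        X = selection.align_features(model.feature_names, new)
        assert X.shape[1] == len(model.feature_names)
        assert (X[:, model.feature_names.index("f0")] == 0).all()

    def test_model_round_trip(self, tmp_path):
        m = _binary_matrix(seed=11)
        model = selection.fit_pca(m)
        selection.write_pc_model(model, tmp_path)
        back = selection.read_pc_model(tmp_path)
        assert back.feature_names == model.feature_names
        assert back.n_retained == model.n_retained
        assert np.allclose(back.components, model.components, atol=1e-12)
        assert np.allclose(
            selection.project(back, m), selection.project(model, m), atol=1e-10)
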