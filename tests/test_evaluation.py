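"""Diagnostics and concordance metrics against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from megharm.evaluation import (
    age_bin_site_maps,
    bh_fdr,
    concordance_report,
    condition_effect_tests,
    cv_delta_r2,
    icc_3k,
    levene_test,
    lin_ccc,
    mean_abs_log_vr,
    partial_r2_study,
    poly_age_fit,
    residualize,
    study_anova,
)

from conftest import make_table


class TestResidualize:
    def test_exact_cubic_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        n = 60
        age = rng.uniform(18, 80, n)
        y = 0.2 + 0.001 * age - 2e-5 * age**2 + 1e-7 * age**3
        t = make_table(y[:, None], study=["a"] * n, age=age)
        resid = residualize(t)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residual_means_zero(self, synthetic_small):
        table, _, _ = synthetic_small
        resid = residualize(table)
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(1)
        n = 10
        age = rng.uniform(20, 70, n)
        sex = np.array(["F", "M"] * 5)
        cond = np.array(["eyes-open"] * 4 + ["eyes-closed"] * 6)
        y = rng.uniform(0.1, 0.9, (n, 2))
        t = make_table(y, study=["a"] * n, age=age, sex=sex, condition=cond)
        resid = residualize(t)
        D = np.column_stack([
            np.ones(n), age, age**2, age**3,
            (sex == "M").astype(float), (cond == "eyes-open").astype(float),
        ])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(resid, y - D @ beta, atol=1e-8)


class TestStudyAnova:
    def test_hand_computed_f(self):
        resid = np.array([[0.0], [1.0], [2.0], [3.0]])
        out = study_anova(resid, np.array(["a", "a", "b", "b"]))
        assert out["F"][0] == pytest.approx(8.0)
        assert out["df_between"][0] == 1 and out["df_within"][0] == 2
        assert out["p"][0] == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_equal_groups_give_f_zero(self):
        resid = np.array([[0.0], [1.0], [0.0], [1.0]])
        out = study_anova(resid, np.array(["a", "a", "b", "b"]))
        assert out["F"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"][0] == pytest.approx(1.0)

    def test_null_calibration_by_permutation(self):
        """Rejection rate ~ alpha across many pure-noise parcel replicates."""
        rng = np.random.default_rng(2)
        n, reps = 120, 2000
        labels = np.repeat([f"g{i}" for i in range(4)], n // 4)
        X = rng.standard_normal((n, reps))
        out = study_anova(X, labels)
        rate = float((out["p"] < 0.05).mean())
        assert 0.04 < rate < 0.06

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        labels = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        out = study_anova(X, labels)
        for j in range(4):
            F, p = stats.f_oneway(*(X[labels == g, j] for g in "abc"))
            assert out["F"][j] == pytest.approx(F, abs=1e-10)
            assert out["p"][j] == pytest.approx(p, abs=1e-12)


class TestLevene:
    def test_identical_value_multisets_give_zero(self):
        resid = np.array([[-1.0], [0.0], [1.0], [-1.0], [0.0], [1.0]])
        out = levene_test(resid, np.array(["a"] * 3 + ["b"] * 3))
        assert out["W"][0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_levene_mean_center(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.standard_normal(24), 2 * rng.standard_normal(24)])
        labels = np.array(["a"] * 10 + ["b"] * 14)
        out = levene_test(X, labels, center="mean")
        for j in range(2):
            W, p = stats.levene(X[labels == "a", j], X[labels == "b", j], center="mean")
            assert out["W"][j] == pytest.approx(W, abs=1e-10)
            assert out["p"][j] == pytest.approx(p, abs=1e-12)

    def test_explicit_deviation_oracle(self):
        """W equals a hand-run ANOVA on absolute deviations."""
        x = np.array([-1.0, 0.0, 1.0, -3.0, 0.0, 3.0])[:, None]
        labels = np.array(["a"] * 3 + ["b"] * 3)
        dev = np.array([1.0, 0.0, 1.0, 3.0, 0.0, 3.0])[:, None]
        expected = study_anova(dev, labels)
        out = levene_test(x, labels, center="mean")
        assert out["W"][0] == pytest.approx(expected["F"][0], abs=1e-12)

    def test_brown_forsythe_variant(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 1))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        out = levene_test(X, labels, center="median")
        W, p = stats.levene(X[labels == "a", 0], X[labels == "b", 0], center="median")
        assert out["W"][0] == pytest.approx(W, abs=1e-10)


class TestPartialR2:
    def test_hand_computed_value(self):
        t = make_table(
            [[0.0], [1.0], [10.0], [11.0]],
            study=["a", "a", "b", "b"],
            age=[30.0, 30.0, 30.0, 30.0],
            sex=["F"] * 4,
            condition=["eyes-closed"] * 4,
        )
        # intercept-only reduced model: SSE around grand mean 5.5 = 101
        out = _partial_r2_intercept_only(t)
        assert out[0] == pytest.approx(100.0 / 101.0)

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(6)
        n = 2000
        t = make_table(
            rng.standard_normal((n, 1)) * 0.05 + 0.5,
            study=rng.choice(["a", "b", "c"], n),
            age=rng.uniform(20, 70, n),
            sex=rng.choice(["F", "M"], n),
            condition=rng.choice(["eyes-open", "eyes-closed"], n),
        )
        assert partial_r2_study(t)[0] < 0.01

    def test_equal_study_means_give_zero(self):
        t = make_table(
            [[0.0], [1.0], [0.0], [1.0]],
            study=["a", "a", "b", "b"],
            age=[30.0] * 4, sex=["F"] * 4, condition=["eyes-closed"] * 4,
        )
        assert _partial_r2_intercept_only(t)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_small_instance(self):
        rng = np.random.default_rng(7)
        n = 10
        age = rng.uniform(20, 60, n)
        sex = rng.choice(["F", "M"], n)
        cond = rng.choice(["eyes-open", "eyes-closed"], n)
        study = np.array(["a"] * 5 + ["b"] * 5)
        y = rng.uniform(0.2, 0.8, (n, 2))
        t = make_table(y, study=study, age=age, sex=sex, condition=cond)
        got = partial_r2_study(t)
        D_red = np.column_stack([
            np.ones(n), age, age**2, age**3,
            (sex == "M").astype(float), (cond == "eyes-open").astype(float),
        ])
        D_full = np.column_stack([D_red, (study == "b").astype(float)])
        def sse(D):
            b, *_ = np.linalg.lstsq(D, y, rcond=None)
            return ((y - D @ b) ** 2).sum(axis=0)
        expected = (sse(D_red) - sse(D_full)) / sse(D_red)
        np.testing.assert_allclose(got, expected, atol=1e-8)


def _partial_r2_intercept_only(t):
    """Partial R^2 with degenerate covariates collapsed to the intercept."""
    from megharm.evaluation import partial_r2_study

    return partial_r2_study(t)


class TestLogVR:
    def test_identical_multisets_small_sample_offset(self):
        # identical multisets: study variances equal, but the pooled (n-1)
        # variance of the concatenation differs at tiny n (2 vs 4/3)
        resid = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        out = mean_abs_log_vr(resid, np.array(["a", "a", "b", "b"]))
        assert out[0] == pytest.approx(abs(np.log(2 / (4 / 3))))

    def test_hand_computed_example(self):
        resid = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        out = mean_abs_log_vr(resid, np.array(["a", "a", "b", "b"]))
        expected = (abs(np.log(2 / (10 / 3))) + abs(np.log(8 / (10 / 3)))) / 2
        assert out[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.693, abs=5e-4)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(8)
        resid = rng.standard_normal((40, 3))
        labels = np.array(["a"] * 15 + ["b"] * 25)
        a = mean_abs_log_vr(resid, labels)
        b = mean_abs_log_vr(c * resid, labels)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_iff_study_variances_equal_pooled(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(20)
        resid = np.concatenate([x, x])[:, None]  # identical multisets
        labels = np.array(["a"] * 20 + ["b"] * 20)
        # var_a = var_b but pooled (ddof=1 over 40) differs slightly -> near zero
        out = mean_abs_log_vr(resid, labels)
        assert out[0] < 0.05
        assert out[0] > 0  # strictly positive unless exactly equal to pooled


class TestConditionTests:
    def _paired_table(self, effect, n=50, seed=10):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.5, n)
        rows_ec = base + 0.01 * rng.standard_normal(n)
        rows_eo = base + effect + 0.01 * rng.standard_normal(n)
        vals = np.concatenate([rows_ec, rows_eo])[:, None]
        return make_table(
            vals,
            study=["a"] * (2 * n),
            subject_id=[f"s{i}" for i in range(n)] * 2,
            condition=["eyes-closed"] * n + ["eyes-open"] * n,
            age=np.tile(rng.uniform(20, 60, n), 2),
            sex=np.tile(rng.choice(["F", "M"], n), 2),
            parcel_names=["pericalcarine-lh"],
        )

    def test_identical_conditions_give_t_zero(self):
        t = self._paired_table(effect=0.0)
        t.data.loc[t.data["condition"] == "eyes-open", "pericalcarine-lh"] = (
            t.data.loc[t.data["condition"] == "eyes-closed", "pericalcarine-lh"].to_numpy()
        )
        out = condition_effect_tests(t, rois=("pericalcarine-lh",), mode="paired")
        assert out.loc["pericalcarine-lh", "t"] == pytest.approx(0.0, abs=1e-10)

    def test_paired_t_matches_analytic_expectation(self):
        """EC > EO effect of known size: |t| within 3 SE of d*sqrt(n)."""
        n, effect, noise = 332, -0.02, 0.01
        t = self._paired_table(effect=effect, n=n, seed=11)
        out = condition_effect_tests(t, rois=("pericalcarine-lh",), mode="paired")
        tval = out.loc["pericalcarine-lh", "t"]
        d = effect / (noise * np.sqrt(2.0))
        expected = d * np.sqrt(n)
        assert tval < 0
        assert abs(tval - expected) < 3 * np.sqrt(n) / np.sqrt(n - 1) * 3

    def test_paired_matches_scipy(self):
        t = self._paired_table(effect=-0.015, n=40, seed=12)
        out = condition_effect_tests(t, rois=("pericalcarine-lh",), mode="paired")
        ec = t.data[t.data["condition"] == "eyes-closed"]["pericalcarine-lh"]
        eo = t.data[t.data["condition"] == "eyes-open"]["pericalcarine-lh"]
        tv, pv = stats.ttest_rel(eo.to_numpy(), ec.to_numpy())
        assert out.loc["pericalcarine-lh", "t"] == pytest.approx(tv, abs=1e-10)
        assert out.loc["pericalcarine-lh", "p"] == pytest.approx(pv, abs=1e-12)

    def test_independent_matches_scipy(self):
        rng = np.random.default_rng(13)
        n = 60
        t = make_table(
            rng.uniform(0.3, 0.5, (n, 1)),
            study=["a"] * n,
            condition=["eyes-open"] * 25 + ["eyes-closed"] * 35,
            parcel_names=["lateraloccipital-lh"],
        )
        out = condition_effect_tests(t, rois=("lateraloccipital-lh",), mode="independent")
        a = t.data[t.data["condition"] == "eyes-open"]["lateraloccipital-lh"]
        b = t.data[t.data["condition"] == "eyes-closed"]["lateraloccipital-lh"]
        tv, pv = stats.ttest_ind(a, b)
        assert out.loc["lateraloccipital-lh", "t"] == pytest.approx(tv, abs=1e-10)


class TestPolyFit:
    def test_exact_cubic_r2_one(self):
        rng = np.random.default_rng(14)
        age = rng.uniform(18, 80, 50)
        y = 0.3 - 0.002 * age + 1e-5 * age**2 + 2e-7 * age**3
        t = make_table(y[:, None], study=["a"] * 50, age=age)
        assert poly_age_fit(t, 3)[0] == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_r2_small(self):
        rng = np.random.default_rng(15)
        n = 1000
        t = make_table(rng.standard_normal((n, 1)) * 0.02 + 0.4,
                       study=["a"] * n, age=rng.uniform(18, 80, n))
        assert poly_age_fit(t, 3)[0] < 0.01

    def test_odd_cubic_orthogonal_to_quadratic(self):
        """Pure odd cubic on a symmetric age grid: quadratic fit captures none."""
        age = np.linspace(-1, 1, 201) * 30 + 45  # symmetric around 45
        s = (age - 45.0) / 30.0
        y = 0.4 + 0.05 * (s**3 - 0.6 * s)  # orthogonal to {1, s, s^2} on the grid
        t = make_table(y[:, None], study=["a"] * len(age), age=age)
        r2_quad = poly_age_fit(t, 2)
        r2_cubic = poly_age_fit(t, 3)
        assert r2_quad[0] < 0.2
        assert r2_cubic[0] == pytest.approx(1.0, abs=1e-8)


class TestCvDeltaR2:
    def _pair(self, n=300, noise=0.1, seed=16):
        rng = np.random.default_rng(seed)
        age = rng.uniform(18, 80, n)
        s = (age - 45) / 35
        signal = 0.4 - 0.08 * s**3 + 0.03 * s**2
        clean = signal[:, None] + 0.01 * rng.standard_normal((n, 4))
        noisy = clean + noise * rng.standard_normal((n, 4))
        study = np.repeat(["a", "b", "c"], n // 3)
        ta = make_table(clean, study=study, age=age)
        tb = make_table(noisy, study=study, age=age)
        return ta, tb

    def test_identical_tables_give_zero_delta(self):
        ta, _ = self._pair()
        out = cv_delta_r2(ta, ta, k=5, repeats=2, seed=0)
        np.testing.assert_array_equal(out["mean_delta_r2"], 0.0)
        np.testing.assert_array_equal(out["t"], 0.0)
        np.testing.assert_array_equal(out["p"], 1.0)

    def test_noisy_table_loses_and_is_flagged(self):
        ta, tb = self._pair()
        out = cv_delta_r2(ta, tb, k=5, repeats=5, seed=1)
        assert (out["mean_delta_r2"] > 0).all()
        assert (out["q"] < 0.05).all()

    def test_same_seed_reproducible(self):
        ta, tb = self._pair()
        o1 = cv_delta_r2(ta, tb, k=5, repeats=3, seed=2)
        o2 = cv_delta_r2(ta, tb, k=5, repeats=3, seed=2)
        pd.testing.assert_frame_equal(o1, o2)

    def test_record_mismatch_rejected(self):
        ta, tb = self._pair()
        tb.data.loc[0, "age"] = 99.0
        with pytest.raises(ValueError, match="identical records"):
            cv_delta_r2(ta, tb)


class TestBhFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20))
    def test_permutation_equivariance_and_dominance(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        q2 = bh_fdr(np.asarray(ps)[perm])
        np.testing.assert_allclose(np.sort(q2), np.sort(q), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSiteMaps:
    def _table(self):
        rng = np.random.default_rng(17)
        n = 200
        ages = np.concatenate([
            rng.uniform(20, 30, 120),    # study a well represented
            rng.uniform(20, 45, 60),     # study b partially in bin
            rng.uniform(50, 70, 20),     # study c outside the bin
        ])
        study = np.array(["a"] * 120 + ["b"] * 60 + ["c"] * 20)
        return make_table(rng.uniform(0.3, 0.5, (n, 3)), study=study, age=ages)

    def test_min_n_filtering_and_means(self):
        t = self._table()
        maps = age_bin_site_maps(t, (20.0, 30.0), min_n=30)
        assert "c" not in maps.index
        mask = (t.data["study"] == "a") & (t.data["age"] >= 20) & (t.data["age"] < 30)
        np.testing.assert_allclose(
            maps.loc["a"].to_numpy(),
            t.values[mask.to_numpy()].mean(axis=0),
            atol=1e-12,
        )

    def test_half_open_interval(self):
        t = make_table(
            [[0.1], [0.9]], study=["a", "a"], age=[20.0, 30.0],
            subject_id=["x", "y"],
        )
        maps = age_bin_site_maps(t, (20.0, 30.0), min_n=1)
        assert maps.loc["a"].iloc[0] == pytest.approx(0.1)  # age 30 excluded

    def test_no_qualifying_study_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="no study"):
            age_bin_site_maps(t, (90.0, 99.0), min_n=30)


class TestConcordance:
    def test_identical_maps_perfect_agreement(self):
        maps = pd.DataFrame([[1.0, 2.0, 3.0]] * 3, index=["a", "b", "c"])
        rep = concordance_report(maps)
        assert rep["median_pearson"] == pytest.approx(1.0)
        assert rep["median_ccc"] == pytest.approx(1.0)
        assert rep["icc_3k"] == pytest.approx(1.0)
        assert rep["median_cv"] == pytest.approx(0.0)

    def test_shifted_maps_ccc_hand_value(self):
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0)
        maps = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]], index=["a", "b"])
        rep = concordance_report(maps)
        assert rep["median_pearson"] == pytest.approx(1.0)
        assert rep["median_ccc"] == pytest.approx(4.0 / 7.0)

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            x = rng.standard_normal(30)
            y = 0.5 * x + rng.standard_normal(30)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12

    def test_icc_matches_brute_force_anova(self):
        """ICC(3,k) on a 4-parcel x 3-study grid vs explicit mean squares."""
        maps = np.array([
            [0.30, 0.40, 0.50, 0.35],
            [0.32, 0.43, 0.49, 0.36],
            [0.28, 0.38, 0.52, 0.33],
        ])
        got = icc_3k(maps)
        X = maps.T  # parcels x studies
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        mse = (
            ((X - X.mean(axis=1, keepdims=True) - X.mean(axis=0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        assert got == pytest.approx((msr - mse) / msr, abs=1e-12)

    def test_icc_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(19)
        maps = rng.uniform(0.2, 0.6, (4, 10))  # 4 studies x 10 parcels
        long = pd.DataFrame({
            "targets": np.tile(np.arange(10), 4),
            "raters": np.repeat(np.arange(4), 10),
            "score": maps.ravel(),
        })
        icc = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="score"
        )
        mask = icc["Type"].isin(["ICC3k", "ICC(C,k)"])  # label differs by version
        ref = float(icc.loc[mask, "ICC"].iloc[0])
        assert icc_3k(maps) == pytest.approx(ref, abs=1e-8)
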