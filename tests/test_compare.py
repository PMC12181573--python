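"""Outlier fences, reference regression, residuals, and group inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaging import (
    SampleSheet,
    StatsError,
    anova_oneway,
    build_residual_table,
    compute_residuals,
    contrast_groups,
    fit_reference_model,
    pearson_correlation,
    remove_outliers,
    run_contrasts,
    tukey_fences,
)


class TestTukeyFences:
    def test_hand_computed_example(self):
        lo, hi = tukey_fences([1, 2, 3, 4, 100])
        assert (lo, hi) == (-1.0, 7.0)

    def test_constant_vector_flags_nothing(self):
        lo, hi = tukey_fences([5.0] * 6)
        assert lo == hi == 5.0
        trimmed, log = remove_outliers(pd.DataFrame({"b": [5.0] * 6}))
        assert log.empty  # strict inequality: points on the fence stay

    def test_symmetric_about_median_for_symmetric_data(self):
        v = np.array([-4, -2, -1, 0, 1, 2, 4], dtype=float)
        lo, hi = tukey_fences(v)
        assert lo + hi == pytest.approx(2 * np.median(v))

    def test_too_few_values(self):
        with pytest.raises(StatsError, match=">= 4"):
            tukey_fences([1, 2, 3])

    def test_matches_brute_force_quantiles(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.normal(size=rng.integers(4, 30))
            s = np.sort(v)

            def q(p):
                h = (len(s) - 1) * p
                lo_i = int(np.floor(h))
                hi_i = min(lo_i + 1, len(s) - 1)
                return s[lo_i] + (h - lo_i) * (s[hi_i] - s[lo_i])

            iqr = q(0.75) - q(0.25)
            lo, hi = tukey_fences(v)
            assert lo == pytest.approx(q(0.25) - 1.5 * iqr)
            assert hi == pytest.approx(q(0.75) + 1.5 * iqr)


class TestRemoveOutliers:
    def test_single_extreme_cell_masked(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0, 100.0], "b": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=[f"s{i}" for i in range(5)],
        )
        trimmed, log = remove_outliers(table)
        assert np.isnan(trimmed.loc["s4", "a"])
        assert trimmed.loc["s4", "b"] == 5.0  # sample kept for other biomarkers
        assert len(log) == 1
        assert log.iloc[0]["biomarker"] == "a" and log.iloc[0]["value"] == 100.0

    def test_identity_when_no_outliers(self):
        table = pd.DataFrame({"a": np.linspace(0, 1, 8)})
        trimmed, log = remove_outliers(table)
        pd.testing.assert_frame_equal(trimmed, table)
        assert log.empty

    def test_exactly_one_pass_is_performed(self):
        """The rule is not idempotent; removal must use the original fences only.

        Search (seeded) for a vector where re-fencing the trimmed data flags
        additional points, then verify remove_outliers stops after one pass.
        """
        rng = np.random.default_rng(0)
        found = None
        for _ in range(2000):
            v = np.round(rng.normal(0, 1, 12), 2)
            v[-1] = rng.uniform(10, 50)  # force one gross outlier
            lo, hi = tukey_fences(v)
            first = (v < lo) | (v > hi)
            if not first.any() or first.all():
                continue
            kept = v[~first]
            if len(kept) < 4:
                continue
            lo2, hi2 = tukey_fences(kept)
            if (((kept < lo2) | (kept > hi2))).any():
                found = v
                break
        assert found is not None, "search failed to construct a two-pass example"
        table = pd.DataFrame({"b": found})
        trimmed, log = remove_outliers(table)
        lo, hi = tukey_fences(found)
        expected_mask = (found < lo) | (found > hi)
        assert list(trimmed["b"].isna()) == list(expected_mask)
        # and a second application removes strictly more: not idempotent
        trimmed2, log2 = remove_outliers(trimmed)
        assert len(log2) > 0

    def test_per_group_fencing(self, tiny_sheet):
        # one group's values are extreme relative to the other but internally tight
        table = pd.DataFrame(
            {"b": [100.0, 101.0, 1.0, 2.0, 1.5, 150.0]},
            index=tiny_sheet.sample_ids,
        )
        pooled, pooled_log = remove_outliers(table)
        with pytest.raises(StatsError):
            # per-group fences need >= 4 values per group; 2 per group here
            remove_outliers(table, per_group=True, sheet=tiny_sheet)
        assert isinstance(pooled_log, pd.DataFrame)


class TestReferenceModel:
    @staticmethod
    def _sheet(n, seed=0, group="PLDN"):
        rng = np.random.default_rng(seed)
        return SampleSheet(pd.DataFrame(
            {"group": [group] * n,
             "age": rng.uniform(40, 85, n),
             "sex": rng.integers(0, 2, n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        ))

    def test_exact_plane_interpolated(self):
        sheet = self._sheet(10, seed=1)
        y = 2.0 + 0.5 * sheet.data["age"] + 0.0 * sheet.data["sex"]
        model = fit_reference_model(y.to_frame("b"), sheet, "b", "PLDN")
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.age_slope == pytest.approx(0.5, abs=1e-10)
        assert model.sex_effect == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self):
        sheet = self._sheet(10, seed=2)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=10), index=sheet.sample_ids, name="b")
        model = fit_reference_model(y.to_frame(), sheet, "b", "PLDN")
        X = np.column_stack([
            np.ones(10), sheet.data["age"], sheet.data["sex"]])
        coef = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert np.allclose([model.intercept, model.age_slope, model.sex_effect],
                           coef, atol=1e-10)
        assert model.n_fit == 10

    def test_single_sex_group_drops_sex_with_warning(self):
        sheet = self._sheet(8, seed=4)
        sheet.data["sex"] = 1
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=8), index=sheet.sample_ids, name="b")
        with pytest.warns(UserWarning, match="single-sex"):
            model = fit_reference_model(y.to_frame(), sheet, "b", "PLDN")
        assert model.sex_dropped and model.sex_effect == 0.0
        # coefficients must match the sex-free normal equations
        X = np.column_stack([np.ones(8), sheet.data["age"]])
        coef = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert np.allclose([model.intercept, model.age_slope], coef, atol=1e-10)

    def test_constant_age_is_degenerate(self):
        sheet = self._sheet(6, seed=6)
        sheet.data["age"] = 60.0
        y = pd.Series(np.arange(6.0), index=sheet.sample_ids, name="b")
        with pytest.raises(StatsError, match="'age'"):
            fit_reference_model(y.to_frame(), sheet, "b", "PLDN")

    def test_too_small_reference_group(self):
        sheet = self._sheet(2, seed=7)
        y = pd.Series([1.0, 2.0], index=sheet.sample_ids, name="b")
        with pytest.raises(StatsError, match=">= 3"):
            fit_reference_model(y.to_frame(), sheet, "b", "PLDN")


class TestResiduals:
    @staticmethod
    def _cohort(seed=0, n=24):
        rng = np.random.default_rng(seed)
        groups = ["PLDN"] * (n // 2) + ["PDN"] * (n - n // 2)
        sheet = SampleSheet(pd.DataFrame(
            {"group": groups,
             "age": rng.uniform(40, 85, n),
             "sex": rng.integers(0, 2, n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        ))
        y = (5.0 + 0.3 * sheet.data["age"] + 1.2 * sheet.data["sex"]
             + rng.normal(0, 2, n))
        return sheet, y.rename("b").to_frame()

    def test_reference_group_residuals_sum_to_zero(self):
        sheet, table = self._cohort(seed=8)
        model = fit_reference_model(table, sheet, "b", "PLDN")
        res = compute_residuals(model, table, sheet)
        ref = res[sheet.data["group"] == "PLDN"]
        assert ref.sum() == pytest.approx(0.0, abs=1e-8)

    def test_sample_on_plane_has_zero_residual(self):
        sheet, table = self._cohort(seed=9)
        model = fit_reference_model(table, sheet, "b", "PLDN")
        sid = table.index[0]
        table.loc[sid, "b"] = model.predict(
            sheet.data.loc[sid, "age"], sheet.data.loc[sid, "sex"])
        res = compute_residuals(model, table, sheet)
        assert res[sid] == pytest.approx(0.0, abs=1e-10)

    def test_matches_predict_and_subtract(self):
        sheet, table = self._cohort(seed=10, n=8)
        model = fit_reference_model(table, sheet, "b", "PLDN")
        res = compute_residuals(model, table, sheet)
        for sid in table.index:
            manual = table.loc[sid, "b"] - (
                model.intercept
                + model.age_slope * sheet.data.loc[sid, "age"]
                + model.sex_effect * sheet.data.loc[sid, "sex"])
            assert res[sid] == pytest.approx(manual, abs=1e-12)


class TestContrasts:
    @staticmethod
    def _two_group_sheet(na, nb):
        return SampleSheet(pd.DataFrame(
            {"group": ["A"] * na + ["B"] * nb,
             "age": 60.0 + np.arange(na + nb),
             "sex": [0, 1] * ((na + nb) // 2) + [0] * ((na + nb) % 2)},
            index=pd.Index([f"s{i}" for i in range(na + nb)], name="sample_id"),
        ))

    def test_identical_groups(self):
        sheet = self._two_group_sheet(3, 3)
        res = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=sheet.sample_ids)
        r = contrast_groups(res, sheet, "A", "B")
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        sheet = self._two_group_sheet(3, 3)
        res = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=sheet.sample_ids)
        r = contrast_groups(res, sheet, "A", "B")
        # pooled sd = 1, t = -3 / sqrt(2/3), df = 4
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        assert r.mean_difference == pytest.approx(-3.0)
        assert r.t == pytest.approx(t_expected, abs=1e-9)
        assert r.df == 4
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), abs=1e-12)
        assert r.p == pytest.approx(0.0214, abs=5e-4)
        assert r.significant

    def test_swapping_groups_negates_t(self):
        sheet = self._two_group_sheet(4, 4)
        rng = np.random.default_rng(11)
        res = pd.Series(rng.normal(size=8), index=sheet.sample_ids)
        r1 = contrast_groups(res, sheet, "A", "B")
        r2 = contrast_groups(res, sheet, "B", "A")
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_zero_variance_behaviour(self):
        sheet = self._two_group_sheet(3, 3)
        same = pd.Series([2.0] * 6, index=sheet.sample_ids)
        r = contrast_groups(same, sheet, "A", "B")
        assert r.t == 0.0 and r.p == 1.0
        shifted = pd.Series([2.0] * 3 + [3.0] * 3, index=sheet.sample_ids)
        with pytest.raises(StatsError, match="zero variance"):
            contrast_groups(shifted, sheet, "A", "B")

    def test_needs_two_per_group(self):
        sheet = self._two_group_sheet(1, 5)
        res = pd.Series(np.arange(6.0), index=sheet.sample_ids)
        with pytest.raises(StatsError, match=">= 2"):
            contrast_groups(res, sheet, "A", "B")

    def test_welch_flag(self):
        sheet = self._two_group_sheet(5, 5)
        rng = np.random.default_rng(12)
        res = pd.Series(np.concatenate([rng.normal(0, 1, 5), rng.normal(1, 5, 5)]),
                        index=sheet.sample_ids)
        rw = contrast_groups(res, sheet, "A", "B", welch=True)
        a, b = res[:5], res[5:]
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert rw.t == pytest.approx(t_ref) and rw.p == pytest.approx(p_ref)
        assert rw.welch and rw.df != 8


class TestAnova:
    @staticmethod
    def _sheet(groups, ages):
        n = len(groups)
        return SampleSheet(pd.DataFrame(
            {"group": groups, "age": ages, "sex": [0] * n},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        ))

    def test_identical_groups_give_f_zero(self):
        sheet = self._sheet(["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                            [1.0, 2.0, 3.0] * 3)
        f_stat, p = anova_oneway(sheet)
        assert f_stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(13)
        ages = rng.uniform(40, 80, 12)
        sheet = self._sheet(["A"] * 6 + ["B"] * 6, ages)
        f_stat, p_f = anova_oneway(sheet)
        t_stat, p_t = stats.ttest_ind(ages[:6], ages[6:], equal_var=True)
        assert f_stat == pytest.approx(t_stat ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_matches_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(14)
        ages = rng.uniform(40, 80, 9)
        sheet = self._sheet(["A"] * 3 + ["B"] * 3 + ["C"] * 3, ages)
        f_stat, p = anova_oneway(sheet)
        groups = [ages[:3], ages[3:6], ages[6:]]
        grand = ages.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_manual = (ssb / 2) / (ssw / 6)
        assert f_stat == pytest.approx(f_manual, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(f_manual, 2, 6), rel=1e-12)

    def test_small_group_errors(self):
        sheet = self._sheet(["A", "B", "B"], [50.0, 60.0, 70.0])
        with pytest.raises(StatsError, match=">= 2 samples"):
            anova_oneway(sheet)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, p = pearson_correlation(x, -2 * x + 7)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_manual = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        t_manual = r_manual * np.sqrt(8 / (1 - r_manual ** 2))
        assert r == pytest.approx(r_manual, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_manual), 8), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(StatsError, match=">= 3"):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])


class TestEquivariance:
    """Shifting a biomarker by c, or by c*age, must leave every contrast alone."""

    @staticmethod
    def _cohort(seed=21):
        rng = np.random.default_rng(seed)
        n = 30
        groups = ["PLDN"] * 12 + ["PDN"] * 10 + ["CTRL"] * 8
        sheet = SampleSheet(pd.DataFrame(
            {"group": groups,
             "age": rng.uniform(41, 84, n),
             "sex": rng.integers(0, 2, n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        ))
        table = pd.DataFrame(
            {"b": 10 + 0.4 * sheet.data["age"] + rng.normal(0, 2, n)},
            index=sheet.sample_ids,
        )
        return sheet, table

    @pytest.mark.parametrize("mode", ["constant", "age_slope"])
    def test_contrast_invariance(self, mode):
        sheet, table = self._cohort()
        pairs = [("PDN", "PLDN"), ("CTRL", "PLDN")]
        # constant shifts commute with Tukey fencing; age-proportional shifts
        # are absorbed by the age slope, checked from the regression stage on
        fence = mode == "constant"

        def analyze(tab):
            if fence:
                tab, _ = remove_outliers(tab)
            residuals, _ = build_residual_table(tab, sheet, "PLDN")
            return residuals, run_contrasts(residuals, sheet, pairs)

        res0, base = analyze(table)
        c = 7.3
        shift = c if mode == "constant" else c * sheet.data["age"]
        res1, moved = analyze(table.add(shift, axis=0))
        assert np.allclose(res0["b"], res1["b"], atol=1e-10)
        for col in ("t", "p", "mean_difference"):
            assert np.allclose(base[col], moved[col], atol=1e-10)

    def test_reference_group_mean_residual_is_zero(self):
        sheet, table = self._cohort(seed=22)
        residuals, _ = build_residual_table(table, sheet, "PLDN")
        ref = residuals.loc[sheet.data["group"] == "PLDN", "b"]
        assert ref.mean() == pytest.approx(0.0, abs=1e-10)
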