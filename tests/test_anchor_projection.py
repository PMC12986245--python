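import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from rfharmonize.anchor_projection import (CubicRegressionSpline,
                                           SplineConfig, compare_projections,
                                           fit_gam_projection,
                                           fit_lm_projection, project_study,
                                           ss_res)
from rfharmonize.exceptions import ValidationError


def series(values, prefix="c"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def roles_for(index, suspect_from=None):
    roles = pd.Series("calibrant", index=index)
    if suspect_from is not None:
        roles.iloc[suspect_from:] = "suspect"
    return roles


class TestSSRes:
    def test_examples(self):
        assert ss_res([1.0, -1.0]) == 1.0
        assert ss_res([0.0, 0.0, 0.0]) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = rng.normal(size=rng.integers(1, 30))
            acc = 0.0
            for v in r:
                acc += v * v
            assert ss_res(r) == pytest.approx(acc / len(r), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ss_res([])


class TestLMProjection:
    def test_identity_when_dataset_equals_anchor(self):
        vals = series(np.linspace(11, 15, 12))
        fit = fit_lm_projection(vals, vals, roles_for(vals.index))
        assert fit.coefficients["slope"] == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert fit.range_ratio == pytest.approx(1.0, rel=1e-12)
        assert fit.ss_res == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_affine_inversion(self):
        anchor = series(np.linspace(11, 15, 10))
        dataset = 2.0 * anchor - 5.0
        fit = fit_lm_projection(dataset, anchor, roles_for(anchor.index))
        np.testing.assert_allclose(fit.projected, anchor, rtol=1e-12)
        assert fit.ss_res == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(15))
    def test_coefficients_match_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = series(rng.uniform(10, 16, 20))
        y = pd.Series(2.0 + 0.8 * x.to_numpy() + rng.normal(0, 0.3, 20),
                      index=x.index)
        fit = fit_lm_projection(x, y, roles_for(x.index))
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.coefficients["slope"] == pytest.approx(slope, rel=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(intercept, rel=1e-10)

    def test_min_overlap_enforced(self):
        vals = series(np.linspace(11, 15, 4))
        with pytest.raises(ValidationError, match="overlap"):
            fit_lm_projection(vals, vals, roles_for(vals.index), min_overlap=6)

    def test_attenuation_projected_range_is_slope_times_raw(self):
        rng = np.random.default_rng(42)
        x = series(rng.uniform(10, 16, 30))
        y = pd.Series(rng.normal(13, 1.0, 30), index=x.index)  # uncorrelated
        fit = fit_lm_projection(x, y, roles_for(x.index))
        expected = abs(fit.coefficients["slope"]) * fit.raw_range
        assert fit.projected_range == pytest.approx(expected, rel=1e-10)
        # near-zero correlation compresses the scale
        assert fit.range_ratio > 1.0


class TestGAMProjection:
    def test_large_lambda_limit_reproduces_lm(self):
        rng = np.random.default_rng(1)
        x = series(np.sort(rng.uniform(10, 16, 25)))
        y = pd.Series(1.5 + 0.9 * x.to_numpy() + rng.normal(0, 0.2, 25),
                      index=x.index)
        roles = roles_for(x.index)
        lm = fit_lm_projection(x, y, roles)
        gam = fit_gam_projection(x, y, roles,
                                 config=SplineConfig(fixed_lambda=1e8))
        np.testing.assert_allclose(gam.projected, lm.projected, atol=1e-3)

    def test_zero_lambda_interpolates_at_n_equals_k(self):
        x = np.array([10.0, 11.0, 12.5, 13.0, 14.2, 16.0])
        rng = np.random.default_rng(2)
        y = 13.0 + rng.normal(0, 1, 6)
        spline = CubicRegressionSpline(SplineConfig(fixed_lambda=0.0)).fit(x, y)
        rss = np.sum((y - spline.predict(x)) ** 2)
        assert rss < 1e-8

    def test_interpolant_matches_unpenalized_solve(self):
        """lambda=0, n=k: fitted values equal the direct solution of the
        basis linear system computed with an independent solver."""
        x = np.array([10.0, 11.0, 12.5, 13.0, 14.2, 16.0])
        rng = np.random.default_rng(3)
        y = 13.0 + rng.normal(0, 1, 6)
        spline = CubicRegressionSpline(SplineConfig(fixed_lambda=0.0)).fit(x, y)
        from rfharmonize.anchor_projection import _cr_design, _cr_penalty
        F, _ = _cr_penalty(spline.knots_)
        X = _cr_design(x, spline.knots_, F)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(spline.predict(x), X @ beta, atol=1e-6)

    def test_cubic_relation_fits_better_than_lm(self):
        rng = np.random.default_rng(4)
        x = series(np.sort(rng.uniform(-1.5, 1.5, 40)))
        y = pd.Series(13 + x.to_numpy() ** 3 + rng.normal(0, 0.05, 40),
                      index=x.index)
        roles = roles_for(x.index)
        lm = fit_lm_projection(x, y, roles)
        gam = fit_gam_projection(x, y, roles)
        assert gam.ss_res < lm.ss_res

    def test_too_few_points_refused(self):
        x = series(np.linspace(10, 15, 5))
        with pytest.raises(ValidationError, match="k\\+1"):
            fit_gam_projection(x, x, roles_for(x.index))

    def test_duplicate_x_falls_back_to_lm(self):
        x = series(np.repeat([11.0, 13.0], 6))
        y = series(np.repeat([11.5, 13.5], 6))
        fit = fit_gam_projection(x, y, roles_for(x.index))
        assert fit.method == "LM"


def f_pdf(t, d1, d2):
    """F-distribution density written out, for independent p integration."""
    c = (gamma_fn((d1 + d2) / 2) / (gamma_fn(d1 / 2) * gamma_fn(d2 / 2))
         * (d1 / d2) ** (d1 / 2))
    return c * t ** (d1 / 2 - 1) * (1 + d1 * t / d2) ** (-(d1 + d2) / 2)


class TestCompareProjections:
    def make_fit(self, residuals, method="LM"):
        from rfharmonize.anchor_projection import ProjectionFit
        res = pd.Series(residuals)
        return ProjectionFit(
            dataset_id="D", anchor_id="A", method=method, coefficients={},
            n_overlap=len(res), residuals=res,
            ss_res=float(np.mean(res**2)),
            suspect_rmse=float(np.sqrt(np.mean(res**2))), r_squared=1.0,
            raw_range=1.0, projected_range=1.0, range_ratio=1.0,
            projected=res, suspect_residuals=res)

    def test_identical_residuals_give_f_one_p_one(self):
        r = np.array([0.1, -0.2, 0.3, -0.1, 0.2])
        out = compare_projections(self.make_fit(r), self.make_fit(r, "GAM"))
        assert out["statistic"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["preferred"] == "LM"

    def test_variance_ratio_four_matches_integrated_f_tail(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 20)
        base = base / np.sqrt(np.mean(base**2))  # unit mean square
        out = compare_projections(self.make_fit(2.0 * base),
                                  self.make_fit(base, "GAM"))
        assert out["statistic"] == pytest.approx(4.0, rel=1e-12)
        tail, _ = quad(f_pdf, 4.0, np.inf, args=(19, 19))
        assert out["p_value"] == pytest.approx(2 * tail, rel=1e-6)

    def test_under_three_suspects_defaults_to_lm(self):
        out = compare_projections(self.make_fit([0.1, 0.2]),
                                  self.make_fit([0.1, 0.2], "GAM"))
        assert out["preferred"] == "LM"
        assert not out["tested"]


class TestProjectStudy:
    def make_table(self, rng, n_ds=5, n_comp=25):
        base = rng.uniform(11, 15, n_comp)
        rows = {}
        rows["ANCH"] = base
        for i in range(n_ds - 1):
            a, b = rng.normal(0, 1), np.exp(rng.normal(0, 0.15))
            rows[f"L{i}"] = a + b * base + rng.normal(0, 0.1, n_comp)
        wide = pd.DataFrame(rows, index=[f"c{j}" for j in range(n_comp)]).T
        roles = pd.Series("calibrant", index=wide.columns)
        roles.iloc[-5:] = "suspect"
        return wide, roles

    def test_anchor_self_projection_is_identity(self):
        rng = np.random.default_rng(8)
        wide, roles = self.make_table(rng)
        projected, diag, fits = project_study(wide, roles, "ANCH", method="lm")
        np.testing.assert_allclose(projected.loc["ANCH"].dropna(),
                                   wide.loc["ANCH"].dropna(), rtol=1e-12)
        anchor_row = diag[diag["dataset_id"] == "ANCH"].iloc[0]
        assert anchor_row["slope"] == pytest.approx(1.0, abs=1e-10)
        assert anchor_row["ss_res"] == pytest.approx(0.0, abs=1e-18)

    def test_refused_dataset_flagged_not_projected(self):
        rng = np.random.default_rng(9)
        wide, roles = self.make_table(rng)
        sparse = wide.copy()
        sparse.loc["L0", sparse.columns[3:]] = np.nan  # only 3 overlaps left
        projected, diag, fits = project_study(sparse, roles, "ANCH",
                                              method="lm", min_overlap=6)
        row = diag[diag["dataset_id"] == "L0"].iloc[0]
        assert row["method"] == "refused"
        assert "L0" not in projected.index or projected.loc["L0"].isna().all()

    def test_both_mode_prefers_lm_on_linear_truth(self):
        rng = np.random.default_rng(10)
        wide, roles = self.make_table(rng, n_ds=4, n_comp=30)
        _, diag, fits = project_study(wide, roles, "ANCH", method="both")
        assert (diag.loc[diag["dataset_id"] != "ANCH", "method"] == "LM").mean() >= 0.5
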