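"""Two-stage prevalence smoothing: per-wave fits, pooling, derivatives,
and the coefficient sampling distribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import previnc as pv
from previnc.smoothing import AGE_OFFSET, WaveFit, _stage2_knot_vector

SEXES = ("male", "female")


def _logistic_survey(n, year, coef_age=0.075, intercept=-6.0, seed=0,
                     weights="lognormal"):
    """Records with logistic-in-age truth, both sexes."""
    rng = np.random.default_rng(seed)
    age = rng.integers(20, 80, n)
    sex = np.where(rng.integers(0, 2, n) == 0, "male", "female")
    eta = intercept + coef_age * (age + AGE_OFFSET)
    disease = (rng.random(n) < expit(eta)).astype(int)
    if weights == "lognormal":
        w = rng.lognormal(-0.125, 0.5, n)
    else:
        w = np.full(n, float(weights))
    return pd.DataFrame(
        {"id": np.arange(n), "age": age, "sex": sex,
         "survey_year": np.full(n, year), "disease": disease, "weight": w}
    )


def _wavefit_from_eta(year, eta_fn, sexes=SEXES):
    """Synthetic stage-1 output with exact logit values and zero covariance."""
    ages = np.arange(20, 80)
    x = ages + AGE_OFFSET
    return WaveFit(
        survey_year=year, ages=ages,
        logit_prev={s: eta_fn(x, year, si) for si, s in enumerate(sexes)},
        logit_cov={s: np.zeros((len(ages), len(ages))) for s in sexes},
        n_effective={s: 1e4 for s in sexes}, knots=np.array([]),
    )


class TestFitWave:
    def test_recovers_logistic_truth_at_large_n(self):
        df = _logistic_survey(100_000, 2006, seed=1)
        wf = pv.fit_wave(df)
        x = wf.ages + AGE_OFFSET
        for sex in SEXES:
            p_true = expit(-6.0 + 0.075 * x)
            sel = (wf.ages >= 25) & (wf.ages <= 75)
            assert np.max(np.abs(wf.prevalence(sex)[sel] - p_true[sel])) < 0.01

    def test_constant_weights_equal_unweighted(self):
        df = _logistic_survey(5_000, 2006, seed=2, weights=3.7)
        df_unw = df.assign(weight=1.0)
        a = pv.fit_wave(df)
        b = pv.fit_wave(df_unw)
        for sex in SEXES:
            np.testing.assert_allclose(a.logit_prev[sex], b.logit_prev[sex], atol=1e-6)

    def test_weight_mass_invariance(self):
        """Duplicating every record with halved weight leaves the fit fixed."""
        df = _logistic_survey(4_000, 2012, seed=3)
        dup = pd.concat([df.assign(weight=df["weight"] / 2)] * 2, ignore_index=True)
        a = pv.fit_wave(df)
        b = pv.fit_wave(dup)
        for sex in SEXES:
            np.testing.assert_allclose(a.logit_prev[sex], b.logit_prev[sex], atol=1e-6)

    def test_single_class_raises_naming_wave_and_sex(self):
        df = _logistic_survey(500, 2000, seed=4)
        df.loc[df["sex"] == "male", "disease"] = 0
        with pytest.raises(ValueError, match="2000.*male"):
            pv.fit_wave(df)

    def test_nonpositive_weights_rejected(self):
        df = _logistic_survey(500, 2000, seed=5)
        df.loc[3, "weight"] = 0.0
        with pytest.raises(ValueError, match="weight"):
            pv.fit_wave(df)

    def test_multiple_years_rejected(self):
        df = pd.concat(
            [_logistic_survey(100, 2000, seed=6), _logistic_survey(100, 2006, seed=7)]
        )
        with pytest.raises(ValueError, match="single survey wave"):
            pv.fit_wave(df)


class TestPoolWaves:
    def test_exact_representability(self):
        """Logit values generated from a surface of exact model form are
        reproduced with zero residual."""
        knots = _stage2_knot_vector((20.0, 79.0))
        from scipy.interpolate import BSpline

        nb = len(knots) - 4
        rng = np.random.default_rng(8)
        c_base = rng.normal(-3, 0.5, nb)
        c_year = rng.normal(0, 0.01, nb)
        c_sex = rng.normal(0, 0.2, nb)
        B = BSpline(knots, np.eye(nb), 3)

        def eta_fn(x, year, s):
            u = year - 2009.0
            return B(x) @ (c_base + u * c_year + s * c_sex)

        fits = [_wavefit_from_eta(y, eta_fn) for y in (2000, 2006, 2012, 2018)]
        surf = pv.pool_waves(fits)
        for year in (2000, 2006, 2012, 2018):
            for si, sex in enumerate(SEXES):
                x = np.arange(20, 80) + AGE_OFFSET
                pred = surf.predict(x, np.full_like(x, year), sex)
                np.testing.assert_allclose(pred, expit(eta_fn(x, year, si)), atol=1e-6)

    def test_identical_waves_zero_year_terms(self):
        def eta_fn(x, year, s):
            return -4.0 + 0.03 * x + 0.3 * s

        fits = [_wavefit_from_eta(y, eta_fn) for y in (2000, 2012)]
        surf = pv.pool_waves(fits)
        # year-slope columns (indices 4j+1 and 4j+3) vanish
        year_cols = surf.coef.reshape(-1, 4)[:, [1, 3]]
        np.testing.assert_allclose(year_cols, 0.0, atol=1e-8)

    def test_identical_sexes_zero_sex_terms(self):
        def eta_fn(x, year, s):
            return -4.0 + 0.03 * x + 0.01 * (year - 2009)

        fits = [_wavefit_from_eta(y, eta_fn) for y in (2000, 2006, 2012)]
        surf = pv.pool_waves(fits)
        sex_cols = surf.coef.reshape(-1, 4)[:, [2, 3]]
        np.testing.assert_allclose(sex_cols, 0.0, atol=1e-8)

    def test_requires_two_waves(self):
        fits = [_wavefit_from_eta(2000, lambda x, y, s: -4 + 0.03 * x)]
        with pytest.raises(ValueError, match="two"):
            pv.pool_waves(fits)

    def test_two_stage_recovery(self, default_scenario, default_truth):
        """fit_wave -> pool_waves recovers the forward-solved prevalence."""
        fits = []
        for k, year in enumerate(default_scenario.wave_years):
            rec = pv.generate_survey(default_scenario, year, n=30_000,
                                     seed=900 + k, truth=default_truth)
            fits.append(pv.fit_wave(rec))
        surf = pv.pool_waves(fits)
        x = np.arange(20, 80) + AGE_OFFSET
        for iy, year in enumerate(default_scenario.wave_years):
            for sex in SEXES:
                pred = surf.predict(x, np.full_like(x, year), sex)
                err = np.abs(pred - default_truth.prevalence[sex][:, iy])
                # ages > 75 are data-sparse under the tilted age pyramid, so
                # the check covers 20-75 at ~3x the worst-point prediction SE
                assert err[: 75 - 20 + 1].max() < 0.035


class TestDirectionalDerivative:
    def test_flat_surface_zero_derivative(self):
        fits = [_wavefit_from_eta(y, lambda x, yr, s: np.full_like(x, -3.0))
                for y in (2000, 2006)]
        surf = pv.pool_waves(fits)
        d = surf.directional_derivative(np.array([50.0]), np.array([2003.0]), "male")
        assert abs(d[0]) < 1e-10

    def test_time_constant_surface_has_age_only_derivative(self):
        def eta_fn(x, year, s):
            return -5.0 + 0.05 * x

        fits = [_wavefit_from_eta(y, eta_fn) for y in (2000, 2006, 2012)]
        surf = pv.pool_waves(fits)
        a = np.array([40.0, 55.0, 70.0])
        t = np.full_like(a, 2006.0)
        p = surf.predict(a, t, "male")
        np.testing.assert_allclose(
            surf.directional_derivative(a, t, "male"), p * (1 - p) * 0.05, atol=1e-8
        )

    def test_analytic_agrees_with_finite_difference(self, fitted_surface):
        rng = np.random.default_rng(12)
        a = rng.uniform(22, 77, 100)
        t = rng.uniform(2001, 2017, 100)
        for sex in SEXES:
            ana = fitted_surface.directional_derivative(a, t, sex)
            fd = fitted_surface.directional_derivative(a, t, sex,
                                                       method="finite_difference")
            assert np.max(np.abs(ana - fd)) < 1e-6


class TestSampling:
    def test_zero_covariance_draw_is_point_estimate(self):
        fits = [_wavefit_from_eta(y, lambda x, yr, s: -4 + 0.03 * x)
                for y in (2000, 2006)]
        surf = pv.pool_waves(fits)  # zero stage-1 covariance propagates to zero
        draw = pv.sample_surface(surf, seed=0)
        np.testing.assert_allclose(draw.coef, surf.coef, atol=1e-12)

    def test_seed_determinism(self, fitted_surface):
        d1 = pv.sample_surface(fitted_surface, seed=42)
        d2 = pv.sample_surface(fitted_surface, seed=42)
        np.testing.assert_array_equal(d1.coef, d2.coef)

    def test_draw_mean_matches_estimate(self, fitted_surface):
        rng = np.random.default_rng(77)
        draws = np.array([fitted_surface.sample(rng).coef for _ in range(10_000)])
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - fitted_surface.coef) < 4 * mc_se)

    def test_asymmetric_covariance_rejected(self, fitted_surface):
        cov = fitted_surface.cov.copy()
        cov[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            pv.PrevalenceSurface(
                coef=fitted_surface.coef, cov=cov, knots=fitted_surface.knots,
                year_center=fitted_surface.year_center,
                age_range=fitted_surface.age_range,
                year_range=fitted_surface.year_range,
            )

    def test_non_psd_covariance_rejected_at_construction(self, fitted_surface):
        cov = fitted_surface.cov.copy()
        cov[0, 0] = -1.0
        with pytest.raises(ValueError, match="semi-definite"):
            pv.PrevalenceSurface(
                coef=fitted_surface.coef, cov=cov, knots=fitted_surface.knots,
                year_center=fitted_surface.year_center,
                age_range=fitted_surface.age_range,
                year_range=fitted_surface.year_range,
            )


def test_logit_round_trip_machine_precision():
    p = np.concatenate([np.geomspace(1e-12, 0.5, 25), 1 - np.geomspace(1e-12, 0.5, 25)])
    np.testing.assert_allclose(expit(logit(p)), p, rtol=0, atol=1e-15)
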