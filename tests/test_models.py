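"""Cardiac models: splitting, robust regression, global constants, prediction."""

import numpy as np
import pytest
from sklearn.base import clone

from pacmri import models
from pacmri.systole import SystoleSample


def _samples(hr, systole, subject_id="s1", valid=None):
    hr = np.asarray(hr, float)
    systole = np.asarray(systole, float)
    valid = np.ones(len(hr), bool) if valid is None else valid
    return [
        SystoleSample(i, float(h), float(s), 0.0, bool(v), subject_id)
        for i, (h, s, v) in enumerate(zip(hr, systole, valid))
    ]


def _line_samples(n, slope, intercept, sd=0.0, seed=0, subject_id="s1"):
    rng = np.random.default_rng(seed)
    hr = rng.uniform(50.0, 100.0, n)
    y = intercept + slope * hr + (rng.normal(0.0, sd, n) if sd else 0.0)
    return _samples(hr, y, subject_id)


class TestSplit:
    @pytest.mark.parametrize("n,n_train,n_holdout", [(10, 8, 2), (135, 108, 27), (105, 84, 21)])
    def test_floor_rule(self, n, n_train, n_holdout):
        split = models.split_train_holdout(_line_samples(n, -0.0018, 0.456))
        assert len(split.train) == n_train
        assert len(split.holdout) == n_holdout

    def test_frac_one_empty_holdout(self):
        split = models.split_train_holdout(_line_samples(10, 0.0, 0.3), frac=1.0)
        assert len(split.holdout) == 0

    def test_train_precedes_holdout_chronologically(self):
        split = models.split_train_holdout(_line_samples(20, 0.0, 0.3))
        assert max(s.cycle_index for s in split.train) < min(
            s.cycle_index for s in split.holdout
        )

    def test_small_subject_flagged(self):
        split = models.split_train_holdout(_line_samples(4, 0.0, 0.3, subject_id="tiny"))
        assert split.flagged_subjects == ["tiny"]
        assert not split.train


class TestFitPacm:
    def test_exact_fit_on_noiseless_line(self):
        m = models.fit_pacm(_line_samples(50, -0.0018, 0.456))
        assert m.slope == pytest.approx(-0.0018, abs=1e-10)
        assert m.intercept == pytest.approx(0.456, abs=1e-8)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert m.quality_ok

    def test_robust_to_gross_outlier(self):
        samples = _line_samples(100, -0.0018, 0.456)
        samples[50].systole_s += 0.5  # gross outlier
        fit_robust = models.fit_pacm(samples)
        oracle = models.fit_pacm(samples[:50] + samples[51:])  # outlier removed
        assert abs(fit_robust.slope - oracle.slope) < 1e-4
        assert abs(fit_robust.intercept - oracle.intercept) < 1e-3

    def test_quality_gate_on_noisy_subject(self):
        m = models.fit_pacm(_line_samples(300, -0.0018, 0.456, sd=0.023, seed=1))
        assert not m.quality_ok
        m2 = models.fit_pacm(_line_samples(300, -0.0018, 0.456, sd=0.005, seed=1))
        assert m2.quality_ok

    def test_constant_hr_degenerates_to_robust_location(self):
        samples = _samples(np.full(20, 67.0), np.full(20, 0.31))
        m = models.fit_pacm(samples)
        assert m.slope == 0.0
        assert m.intercept == pytest.approx(0.31)
        assert m.r_squared is None
        assert np.allclose(m.predict([55.0, 90.0]), 0.31)

    def test_huber_equals_ols_on_noiseless_data(self):
        samples = _line_samples(80, -0.002, 0.47)
        robust = models.fit_pacm(samples, method="huber")
        ols = models.fit_pacm(samples, method="ols")
        assert robust.slope == pytest.approx(ols.slope, abs=1e-10)
        assert robust.intercept == pytest.approx(ols.intercept, abs=1e-10)

    def test_recovery_at_cohort_scale(self):
        # One 3324-cycle cohort: estimates within 3 SE of the generating values.
        m = models.fit_pacm(_line_samples(3324, -0.0018, 0.456, sd=0.014, seed=2))
        assert abs(m.slope + 0.0018) < 3 * m.slope_se
        assert abs(m.intercept - 0.456) < 3 * m.intercept_se
        assert m.residual_sd == pytest.approx(0.014, rel=0.05)


class TestSystoleRegressorEstimator:
    def test_sklearn_protocol(self):
        est = models.SystoleRegressor(method="ols")
        cloned = clone(est)
        assert cloned.get_params()["method"] == "ols"
        X = np.linspace(50, 100, 30)[:, None]
        y = 0.46 - 0.0018 * X[:, 0]
        cloned.fit(X, y)
        assert cloned.slope_ == pytest.approx(-0.0018)
        assert np.allclose(cloned.predict(X), y)

    def test_rejects_multifeature_input(self):
        est = models.SystoleRegressor()
        with pytest.raises(ValueError):
            est.fit(np.ones((10, 2)), np.ones(10))


class TestPopulationModel:
    def test_single_subject_pool_equals_pacm(self):
        samples = _line_samples(60, -0.0018, 0.456, sd=0.005, seed=3)
        pacm = models.fit_pacm(samples)
        pooled = models.fit_population_model(samples, sex="M")
        assert pooled.slope == pytest.approx(pacm.slope)
        assert pooled.intercept == pytest.approx(pacm.intercept)
        assert pooled.kind == "pacm_averaged"

    def test_two_subjects_on_same_line_recovered(self):
        s1 = _line_samples(40, -0.0016, 0.441, seed=4, subject_id="a")
        s2 = _line_samples(40, -0.0016, 0.441, seed=5, subject_id="b")
        pooled = models.fit_population_model(s1 + s2)
        assert pooled.slope == pytest.approx(-0.0016, abs=1e-9)
        assert pooled.intercept == pytest.approx(0.441, abs=1e-7)

    def test_pooled_matches_least_squares_oracle(self):
        # Equal slopes, different intercepts: pooled fit equals closed-form OLS.
        rng = np.random.default_rng(6)
        hr1, hr2 = rng.uniform(50, 80, 50), rng.uniform(70, 100, 50)
        y1 = 0.45 - 0.0018 * hr1
        y2 = 0.48 - 0.0018 * hr2
        samples = _samples(hr1, y1, "a") + _samples(hr2, y2, "b")
        pooled = models.fit_population_model(samples, method="ols", subject_means=False)
        hr = np.concatenate([hr1, hr2])
        y = np.concatenate([y1, y2])
        slope_ols = np.cov(hr, y, bias=True)[0, 1] / np.var(hr)
        assert pooled.slope == pytest.approx(slope_ols, abs=1e-12)
        assert pooled.intercept == pytest.approx(y.mean() - slope_ols * hr.mean(), abs=1e-12)

    def test_subject_mean_r_squared_reported(self):
        pools = []
        for k, icpt in enumerate([0.44, 0.45, 0.46, 0.47]):
            pools += _line_samples(30, -0.0018, icpt, sd=0.004, seed=10 + k,
                                   subject_id=f"s{k}")
        pooled = models.fit_population_model(pools)
        assert pooled.r_squared_subject_means is not None
        assert pooled.r_squared is not None


class TestGlobalModels:
    def test_weissler_constants(self):
        m = models.weissler_model("M")
        assert (m.slope, m.intercept) == (-0.0018, 0.456)
        f = models.weissler_model("F")
        assert (f.slope, f.intercept) == (-0.0016, 0.461)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            models.weissler_model("X")

    @pytest.mark.parametrize("hr,expected", [(60.0, 0.348), (100.0, 0.276)])
    def test_weissler_male_predictions(self, hr, expected):
        m = models.weissler_model("M")
        assert models.predict_end_systole(m, hr) == pytest.approx(expected, abs=1e-12)

    def test_prediction_is_affine(self):
        m = models.weissler_model("F")
        a, b = 55.0, 95.0
        lhs = models.predict_end_systole(m, a) + models.predict_end_systole(m, b)
        rhs = 2 * models.predict_end_systole(m, (a + b) / 2)
        assert lhs == pytest.approx(rhs)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            models.predict_end_systole(models.weissler_model("M"), 0.0)
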