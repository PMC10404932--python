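"""Descriptive analyses: psychometric, curve fits, weights, quantile tables."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from headrace.analysis import (
    analyze_trials,
    confidence_by_rt_quantile,
    fit_curve,
    fit_psychometric,
    mle_comparison,
    weights_from_conflict,
)
from headrace.synthetic_data import ExperimentDesign, SubjectParams, generate_dataset


class TestPsychometric:
    def test_parameter_recovery_from_cumulative_gaussian_draws(self, rng):
        pse, sigma, n = 1.0, 3.0, 10_000
        h = rng.choice([-12, -6, -3, -1.5, 0, 1.5, 3, 6, 12], size=n).astype(float)
        y = (rng.random(n) < norm.cdf((h - pse) / sigma)).astype(int)
        fit = fit_psychometric(h, y)
        assert fit.pse == pytest.approx(pse, abs=0.2)
        assert fit.sigma == pytest.approx(sigma, rel=0.10)
        assert not fit.flagged

    def test_mirror_symmetric_data_has_zero_bias(self):
        h = np.array([-6, -3, -1.5, 1.5, 3, 6], dtype=float)
        # exactly mirrored choice proportions around 0
        p = np.array([0.05, 0.2, 0.4, 0.6, 0.8, 0.95])
        hh = np.repeat(h, 40)
        yy = np.concatenate([
            np.r_[np.ones(int(40 * q)), np.zeros(40 - int(40 * q))] for q in p
        ])
        fit = fit_psychometric(hh, yy)
        assert fit.pse == pytest.approx(0.0, abs=0.15)

    def test_single_response_type_rejected(self):
        h = np.repeat([-3.0, 3.0], 20)
        with pytest.raises(ValueError, match="both responses"):
            fit_psychometric(h, np.ones(40))

    def test_complete_separation_flagged(self):
        h = np.repeat([-3.0, 3.0], 50)
        y = (h > 0).astype(int)
        fit = fit_psychometric(h, y)
        assert fit.flagged

    def test_single_heading_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric(np.zeros(10), np.r_[np.ones(5), np.zeros(5)])

    def test_lapse_bounded_when_fitted(self, rng):
        h = rng.choice([-6, -3, 3, 6], size=2000).astype(float)
        y = (rng.random(2000) < 0.04 + 0.92 * norm.cdf(h / 2.0)).astype(int)
        fit = fit_psychometric(h, y, fit_lapse=True)
        assert 0.0 <= fit.lapse <= 0.1


class TestCurveFit:
    def test_noiseless_gaussian_center_recovered_exactly(self):
        x = np.linspace(-12, 12, 9)
        y = 0.9 + 0.5 * np.exp(-0.5 * ((x - 0.8) / 3.0) ** 2)
        fit = fit_curve(x, y)
        assert fit.center == pytest.approx(0.8, abs=1e-6)
        assert fit.width == pytest.approx(3.0, abs=1e-6)
        assert fit.rmse < 1e-9

    def test_inverted_fit_constrains_trough(self):
        x = np.linspace(-12, 12, 9)
        y = 0.9 - 0.4 * np.exp(-0.5 * ((x + 0.5) / 4.0) ** 2)
        fit = fit_curve(x, y, inverted=True)
        assert fit.amplitude < 0
        assert fit.center == pytest.approx(-0.5, abs=1e-6)

    def test_constant_data_flagged_with_undefined_center(self):
        fit = fit_curve(np.linspace(-6, 6, 7), np.full(7, 1.3))
        assert fit.flagged
        assert fit.amplitude == 0.0
        assert np.isnan(fit.center)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve([0, 1, 2], [1, 2, 1])

    def test_low_coherence_rt_curve_is_wider(self, subject):
        design = ExperimentDesign(
            n_subjects=1, modalities=("vis",), coherences=(0.4, 0.7),
            deltas_deg=(0.0,), trials_per_cell=2000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = generate_dataset(design, [subject], seed=8, map_n_sims=30_000)
        width = {}
        for coh, g in t.groupby("coherence"):
            ok = g[g["censored"] == 0]
            m = ok.groupby("heading_deg")["rt_s"].mean()
            width[coh] = fit_curve(m.index.values, m.values).width
        assert width[0.4] > width[0.7]


class TestConflictWeights:
    @pytest.mark.parametrize(
        "pse,delta,w_ves",
        [(0.0, 3.0, 0.5), (-1.5, 3.0, 1.0), (1.5, 3.0, 0.0), (0.75, -3.0, 0.75)],
    )
    def test_bias_to_weight_conversion(self, pse, delta, w_ves):
        w = weights_from_conflict(pse, delta)
        assert w.w_ves == pytest.approx(w_ves)
        assert w.w_ves + w.w_vis == pytest.approx(1.0)

    def test_zero_conflict_rejected(self):
        with pytest.raises(ValueError):
            weights_from_conflict(0.3, 0.0)


class TestMLEComparison:
    def test_prediction_from_unimodal_fits(self):
        from headrace.analysis import PsychometricFit

        mk = lambda s: PsychometricFit(0.0, s, 0.0, -10.0, 100)
        cmp_ = mle_comparison(mk(3.0), mk(4.0), mk(2.4))
        assert cmp_.sigma_pred == pytest.approx(2.4)
        assert cmp_.w_ves_pred == pytest.approx(0.64)
        assert cmp_.ratio == pytest.approx(1.0)

    def test_equal_sigmas_give_root_two_gain(self):
        from headrace.analysis import PsychometricFit

        mk = lambda s: PsychometricFit(0.0, s, 0.0, -10.0, 100)
        cmp_ = mle_comparison(mk(2.0), mk(2.0), mk(2.0))
        assert cmp_.sigma_pred == pytest.approx(2.0 / np.sqrt(2))

    def test_flagged_fit_rejected(self):
        from headrace.analysis import PsychometricFit

        good = PsychometricFit(0.0, 2.0, 0.0, -10.0, 100)
        bad = PsychometricFit(0.0, 2.0, 0.0, -10.0, 100, flagged=True)
        with pytest.raises(ValueError):
            mle_comparison(good, bad, good)


class TestQuantileTable:
    @staticmethod
    def toy_trials(conf_fn, n=200, rng=None):
        rng = rng or np.random.default_rng(5)
        rt = rng.uniform(0.5, 2.0, n)
        return pd.DataFrame(
            {
                "modality": "ves",
                "heading_deg": np.r_[np.full(n // 2, 1.5), np.full(n - n // 2, -1.5)],
                "rt_s": rt,
                "conf": conf_fn(rt),
                "censored": 0,
            }
        )

    def test_decreasing_confidence_yields_decreasing_means(self):
        t = self.toy_trials(lambda rt: 1.0 - 0.4 * (rt - 0.5) / 1.5)
        qt = confidence_by_rt_quantile(t, n_quantiles=5)
        v = qt.sort_values("quantile")["mean_conf"].to_numpy()
        assert np.all(np.diff(v) < 0)
        assert qt["n"].sum() == len(t)

    def test_left_right_pooled_by_magnitude(self):
        t = self.toy_trials(lambda rt: np.full_like(rt, 0.7))
        qt = confidence_by_rt_quantile(t, n_quantiles=4)
        assert set(qt["abs_heading"]) == {1.5}

    def test_constant_confidence_gives_flat_table(self):
        t = self.toy_trials(lambda rt: np.full_like(rt, 0.7))
        qt = confidence_by_rt_quantile(t, n_quantiles=5)
        assert np.allclose(qt["mean_conf"], 0.7)

    def test_undersized_group_skipped_with_warning(self):
        t = self.toy_trials(lambda rt: np.full_like(rt, 0.7), n=3)
        with pytest.warns(UserWarning, match="skipped"):
            qt = confidence_by_rt_quantile(t, n_quantiles=5)
        assert qt.empty


class TestBattery:
    def test_analyze_trials_returns_complete_tables(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze_trials(small_table)
        assert set(res) == {"psychometric", "curves", "weights", "quantiles"}
        assert not res["psychometric"].empty
        # conflict cells produce cue weights
        assert set(res["weights"]["delta_deg"]) == {-3.0, 3.0}
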