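"""Stimulus profiles, static optimal combination, and drift schedules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headrace.evidence import (
    Modality,
    TrialCondition,
    drift_schedule,
    make_profile,
    mle_combined_sigma,
    mle_weights,
    static_mle,
)

POS_SIGMA = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestProfile:
    def test_velocity_peaks_at_midpoint_with_value_one(self):
        prof = make_profile(duration=2.0, dt=0.001, sigma_frac=1 / 6)
        i = np.argmax(prof.v)
        assert prof.t[i] == pytest.approx(1.0)
        assert prof.v[i] == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(prof.a)) == pytest.approx(1.0, abs=1e-9)

    def test_acceleration_vanishes_at_velocity_peak(self):
        prof = make_profile(duration=1.4, dt=0.002, sigma_frac=0.2)
        assert prof.a[np.argmax(prof.v)] == pytest.approx(0.0, abs=1e-9)

    def test_acceleration_sign_is_biphasic_around_peak(self):
        prof = make_profile(duration=2.0, dt=0.001, sigma_frac=1 / 6)
        mid = np.argmax(prof.v)
        assert np.all(prof.a[1:mid] > 0)
        assert np.all(prof.a[mid + 1:] < 0)

    def test_uneven_grid_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            prof = make_profile(duration=1.0, dt=0.0003)
        assert len(prof.t) == 3333

    @pytest.mark.parametrize(
        "kwargs",
        [dict(duration=-1.0), dict(dt=-0.1), dict(dt=3.0), dict(sigma_frac=0.7)],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_profile(**{"duration": 2.0, "dt": 0.001, "sigma_frac": 1 / 6, **kwargs})


class TestStaticMLE:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 1.0, 1 / np.sqrt(2)), (1.0, 1e9, 1.0), (3.0, 4.0, 2.4)],
    )
    def test_combined_sigma_printed_formula(self, a, b, expected):
        assert mle_combined_sigma(a, b) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 1.0, (0.5, 0.5)), (1e-9, 1.0, (1.0, 0.0)), (3.0, 4.0, (0.64, 0.36))],
    )
    def test_weights_inverse_variance(self, a, b, expected):
        w = mle_weights(a, b)
        assert w[0] == pytest.approx(expected[0], abs=1e-6)
        assert w[1] == pytest.approx(expected[1], abs=1e-6)

    def test_exact_values_at_printed_precision(self):
        assert abs(mle_combined_sigma(3.0, 4.0) - 2.4) < 1e-12
        w = mle_weights(3.0, 4.0)
        assert abs(w[0] - 0.64) < 1e-12 and abs(w[1] - 0.36) < 1e-12

    @given(a=POS_SIGMA, b=POS_SIGMA)
    @settings(derandomize=True, max_examples=200)
    def test_combined_never_exceeds_best_cue_and_is_symmetric(self, a, b):
        sc = mle_combined_sigma(a, b)
        assert sc <= min(a, b) + 1e-12
        assert sc == pytest.approx(mle_combined_sigma(b, a), rel=1e-12)
        wa, wb = mle_weights(a, b)
        wb2, wa2 = mle_weights(b, a)
        assert wa == pytest.approx(wa2, rel=1e-9)
        assert wa + wb == pytest.approx(1.0, abs=1e-12)

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            mle_combined_sigma(0.0, 1.0)
        with pytest.raises(ValueError):
            mle_weights(1.0, -2.0)

    def test_static_mle_container_invariants(self):
        m = static_mle(2.0, 5.0)
        assert m.sigma_c <= min(m.sigma_a, m.sigma_b)
        assert m.w_a + m.w_b == pytest.approx(1.0)


class TestTrialCondition:
    def test_conflict_requires_combined_modality(self):
        with pytest.raises(ValueError):
            TrialCondition("ves", 3.0, 0.0, delta_deg=3.0)

    def test_cue_positions_straddle_heading(self):
        c = TrialCondition("comb", 2.0, 0.4, delta_deg=3.0)
        assert c.heading_vis_deg == pytest.approx(0.5)
        assert c.heading_ves_deg == pytest.approx(3.5)


class TestDriftSchedule:
    def test_zero_coherence_combined_equals_vestibular(self, profile):
        comb = drift_schedule(
            TrialCondition("comb", 4.0, 0.0), profile, k_vis=50.0, k_ves=30.0
        )
        ves = drift_schedule(
            TrialCondition("ves", 4.0), profile, k_vis=50.0, k_ves=30.0
        )
        np.testing.assert_allclose(comb.mu, ves.mu, atol=1e-12)

    def test_congruent_cues_collapse_to_root_sum_square(self, profile):
        h = 5.0
        s = drift_schedule(TrialCondition("comb", h, 0.6), profile, 40.0, 25.0)
        expect = np.sqrt(s.s_vis**2 + s.s_ves**2) * np.sin(np.radians(h))
        np.testing.assert_allclose(s.mu, expect, atol=1e-12)

    def test_conflict_at_zero_heading_follows_dominant_cue(self, profile):
        # vestibular envelope dominant, cue at +1.5 deg: drift biased rightward
        s = drift_schedule(
            TrialCondition("comb", 0.0, 0.01, delta_deg=3.0), profile,
            k_vis=1.0, k_ves=100.0,
        )
        active = s.s_ves > 0
        assert np.all(s.mu[active] > 0)

    def test_schedule_is_odd_in_heading_and_conflict(self, profile):
        a = drift_schedule(TrialCondition("comb", 3.0, 0.4, 3.0), profile, 80.0, 40.0)
        b = drift_schedule(TrialCondition("comb", -3.0, 0.4, -3.0), profile, 80.0, 40.0)
        np.testing.assert_allclose(a.mu, -b.mu, atol=1e-12)

    def test_combined_snr2_is_sum_of_unimodal_snr2(self, profile):
        kv, kve, h, c = 60.0, 35.0, 4.0, 0.5
        comb = drift_schedule(TrialCondition("comb", h, c), profile, kv, kve)
        vis = drift_schedule(TrialCondition("vis", h, c), profile, kv, kve)
        ves = drift_schedule(TrialCondition("ves", h), profile, kv, kve)
        np.testing.assert_allclose(
            comb.mu**2, vis.mu**2 + ves.mu**2, atol=1e-9
        )
        assert comb.integrated_snr2() >= vis.integrated_snr2()
        assert comb.integrated_snr2() >= ves.integrated_snr2()

    def test_zero_heading_zero_conflict_gives_null_drift(self, profile):
        s = drift_schedule(TrialCondition("comb", 0.0, 0.5), profile, 50.0, 30.0)
        assert np.all(s.mu == 0.0)

    def test_negative_sensitivity_rejected(self, profile):
        with pytest.raises(ValueError):
            drift_schedule(TrialCondition("ves", 1.0), profile, k_vis=-1.0, k_ves=5.0)

    def test_modality_enum_coercion(self):
        assert TrialCondition("VES", 1.0).modality is Modality.VES

    def test_profile_config_from_yaml(self, tmp_path):
        from headrace.evidence import profile_from_yaml

        cfg = tmp_path / "stim.yaml"
        cfg.write_text("duration_s: 1.0\ndt_s: 0.002\nsigma_frac: 0.2\nk_vis: 80\n")
        prof, k_vis, k_ves = profile_from_yaml(cfg)
        assert prof.duration == 1.0
        assert prof.dt == pytest.approx(0.002)
        assert k_vis == 80.0 and k_ves == 42.0
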