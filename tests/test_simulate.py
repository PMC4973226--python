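"""Synthetic closed-loop generator: determinism, profiles, cohorts, gain."""

import numpy as np
import pytest

from tmsalpha import (
    SimulationConfig,
    make_gain_fixture,
    simulate_cohort,
    simulate_session,
    trial_envelope_profile,
)
from tmsalpha.spectral import alpha_envelope


class TestSession:
    def test_same_seed_and_config_bit_identical(self):
        cfg = SimulationConfig(seed=7, n_trials_target=5, rest_duration=60.0)
        rec1, truth1 = simulate_session(cfg, "SPL")
        rec2, truth2 = simulate_session(cfg, "SPL")
        np.testing.assert_array_equal(rec1.data, rec2.data)
        np.testing.assert_array_equal(truth1.trigger_times, truth2.trigger_times)

    def test_reaches_trial_target_and_isi(self, small_session, small_config):
        rec, truth = small_session
        usable = truth.pulse_times[truth.pulse_times >= 2.0]
        assert usable.size >= small_config.n_trials_target
        assert np.all(np.diff(truth.trigger_times) >= small_config.min_isi - 1e-9)

    def test_low_burst_rate_fails_with_shortfall_message(self):
        cfg = SimulationConfig(
            seed=1, burst_rate=0.2, n_trials_target=30, max_session=120.0,
            rest_duration=60.0,
        )
        with pytest.raises(RuntimeError, match="burst_rate"):
            simulate_session(cfg, "MPFC")

    def test_unknown_condition_rejected(self, small_config):
        with pytest.raises(ValueError, match="condition"):
            simulate_session(small_config, "M1")

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="alpha_band"):
            SimulationConfig(alpha_band=(13.0, 8.0))


class TestNoiselessEnvelope:
    def test_embedded_profile_recovered_pointwise(self, noiseless_session, noiseless_config):
        # extract the Hilbert envelope of the raw occipital channel around a
        # pulse and compare with the configured ERD -> ERS profile
        rec, truth = noiseless_session
        cfg = noiseless_config
        fs = rec.sampling_rate
        i_ch = rec.channel_names.index("POz")
        k = 2  # any mid-session trial
        i0 = int(round(truth.pulse_times[k] * fs))
        profile = trial_envelope_profile(
            truth.pre_trigger_envelopes[k],
            truth.rest_anchors[k],
            truth.true_ers_amp_pct,
            truth.true_ers_duration,
            cfg,
        )
        seg = rec.data[i_ch, i0 - 2000 : i0 + profile.size + 2000]
        (env_tc,) = alpha_envelope(
            seg[None, :], np.arange(seg.size) / fs, fs
        )
        measured = env_tc.values[2000 : 2000 + profile.size]
        # ignore the artifact/TEP additive span (0..0.5 s) where the envelope
        # mixes the evoked response with the alpha carrier, and the final
        # 0.1 s ramp, which is faster than the alpha-band envelope bandwidth
        sl = slice(int(0.7 * fs), profile.size - int((cfg.ers_rise + 0.15) * fs))
        np.testing.assert_allclose(measured[sl], profile[sl], rtol=0.05)

    def test_pre_trigger_envelope_matches_ground_truth(self, noiseless_session):
        rec, truth = noiseless_session
        assert truth.pre_trigger_envelopes.min() > 0
        # triggers fired on high alpha: pre-pulse envelope above ambient level
        assert truth.pre_trigger_envelopes.mean() > truth.true_rest_envelope

    def test_trial_profile_half_height_width_equals_duration(self, noiseless_config):
        cfg = noiseless_config
        fs = cfg.sampling_rate
        profile = trial_envelope_profile(8.0, 4.0, 50.0, 1.0, cfg)
        rest, peak = 4.0, 4.0 * 1.5
        half = rest + (peak - rest) / 2
        # width of the ERS bump at half height, measured after the dip
        post = profile[int(cfg.ers_onset * fs) - 50 :]
        width = np.sum(post > half) / fs
        assert width == pytest.approx(1.0, abs=2.5 / fs)


class TestBaselineElevation:
    def test_trial_mean_pre_pulse_alpha_exceeds_rest_level(self, small_session):
        # alpha-triggered stimulation conditions the pre-TMS baseline on a
        # burst, inflating it above the ambient rest-state level
        rec, truth = small_session
        fs = rec.sampling_rate
        i_ch = rec.channel_names.index("POz")
        pre, restw = [], []
        for t0 in truth.pulse_times:
            i0 = int(round(t0 * fs))
            if i0 < int(2 * fs):
                continue
            seg = np.abs(rec.data[i_ch, i0 - int(0.25 * fs) : i0])
            pre.append(np.sqrt(np.mean(seg**2)))
            segr = np.abs(rec.data[i_ch, i0 - int(1.9 * fs) : i0 - int(0.5 * fs)])
            restw.append(np.sqrt(np.mean(segr**2)))
        assert np.mean(pre) > np.mean(restw)


class TestCohort:
    def test_zero_between_subject_sd_gives_identical_subjects(self):
        cfg = SimulationConfig(seed=3)
        coh = simulate_cohort(cfg, n_subjects=4, between_subject_sd=0.0,
                              within_subject_sd=0.0, amp_between_sd=0.0,
                              amp_within_sd=0.0, seed=3)
        for cond in ("MPFC", "SPL"):
            sub = coh.params[coh.params.condition == cond]
            assert sub.ers_duration.nunique() == 1
            assert sub.ers_amp_pct.nunique() == 1
            assert sub.ers_duration.iloc[0] == cfg.conditions[cond].ers_duration

    def test_fixed_seed_reproducible_parameter_table(self):
        cfg = SimulationConfig(seed=3)
        a = simulate_cohort(cfg, n_subjects=10, seed=42).params
        b = simulate_cohort(cfg, n_subjects=10, seed=42).params
        assert a.equals(b)

    def test_draws_are_truncated_positive(self):
        cfg = SimulationConfig(seed=3)
        coh = simulate_cohort(cfg, n_subjects=30, between_subject_sd=0.9, seed=9)
        assert (coh.params.ers_duration > 0).all()
        assert (coh.params.ers_amp_pct > 0).all()
        assert coh.n_redraws > 0  # wide spread forces some redraws

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            simulate_cohort(SimulationConfig(), n_subjects=1)

    def test_trace_mode_is_deterministic_and_positive(self):
        cfg = SimulationConfig(seed=3)
        coh = simulate_cohort(cfg, n_subjects=3, seed=5)
        t1 = coh.trace(0, "MPFC")
        t2 = coh.trace(0, "MPFC")
        np.testing.assert_array_equal(t1.values, t2.values)
        assert (t1.values >= 0).all()
        assert t1.times[0] == pytest.approx(-2.0)


class TestGainFixture:
    def test_identity_option(self):
        g = make_gain_fixture(8, 8, identity=True)
        np.testing.assert_array_equal(g, np.eye(8))

    def test_identity_requires_square(self):
        with pytest.raises(ValueError, match="identity"):
            make_gain_fixture(8, 9, identity=True)

    def test_random_gain_full_rank_heterogeneous_columns(self):
        g = make_gain_fixture(32, 200, seed=0)
        assert g.shape == (32, 200)
        assert np.linalg.matrix_rank(g) == 32
        norms = np.linalg.norm(g, axis=0)
        assert norms.min() > 0
        assert norms.max() / norms.min() > 5  # depth weighting is non-trivial

    def test_condition_number_finite_default_sizes(self):
        g = make_gain_fixture(32, 200, seed=1)
        assert np.isfinite(np.linalg.cond(g))
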