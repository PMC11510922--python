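"""Synthetic gait session generator: schedules, waveforms, EMG structure."""

import numpy as np
import pytest

import emgait as eg
from emgait.simulate import activation_envelopes

from conftest import truth_states


class TestParams:
    @pytest.mark.parametrize("kw", [
        {"stance_fraction": 0.0}, {"stance_fraction": 1.2},
        {"emg_rate_hz": 0}, {"imu_rate_hz": -100},
        {"step_duration_s": 0}, {"knee_swing_peak_deg": -5},
        {"activation_lead_ms": -1}, {"cycle_jitter_cv": -0.1},
        {"standing_interludes": ((0, 5.0),)},
        {"standing_interludes": ((3, -1.0),), "n_steps": 5},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            eg.GaitSimParams(**kw)

    def test_empty_session(self):
        ha, ka, truth = eg.simulate_kinematics(eg.GaitSimParams(n_steps=0))
        assert ha.n_samples == 0 and ka.n_samples == 0
        assert truth.hs_times_s.size == 0 and truth.to_times_s.size == 0
        assert truth.activity_intervals == []


class TestKinematics:
    def test_event_schedule(self, clean_session):
        params, ha, ka, truth = clean_session
        assert len(truth.hs_times_s) == 20
        assert len(truth.to_times_s) == 20
        # stance occupies stance_fraction of each 1.2 s cycle
        np.testing.assert_allclose(truth.to_times_s - truth.hs_times_s,
                                   0.72, atol=1e-9)

    def test_knee_peak_and_toe_off_angle(self, clean_session):
        params, ha, ka, truth = clean_session
        assert ka.values.max() == pytest.approx(65.0, abs=0.5)
        idx = np.round(truth.to_times_s * ka.rate_hz).astype(int)
        np.testing.assert_allclose(ka.values[idx], 39.0, atol=0.5)

    def test_hip_max_precedes_hs_minimum(self, clean_session):
        params, ha, ka, truth = clean_session
        rate = ha.rate_hz
        for hs in truth.hs_times_s[1:]:
            i = int(round(hs * rate))
            pre = ha.values[i - int(0.4 * rate):i]
            # rising to a flexion max then descending into the HS minimum
            assert pre.max() > ha.values[i]
            assert ha.values[i + 1] > ha.values[i] - 1e-9

    def test_standing_interlude_angles_flat(self, noisy_wo_session):
        params, ha, ka, truth = noisy_wo_session
        stand = [iv for iv in truth.activity_intervals if iv[2] == "standing"]
        assert len(stand) == 1
        s, e, _ = stand[0]
        i0 = int((s + 0.5) * ha.rate_hz)
        i1 = int((e - 0.5) * ha.rate_hz)
        # flat up to noise: range of ~900 Gaussian draws is < 8 sigma
        assert np.ptp(ha.values[i0:i1]) < 8 * params.angle_noise_deg
        # intervals tile the session without overlap
        ivs = truth.activity_intervals
        assert ivs[0][0] == 0.0
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a[1] == pytest.approx(b[0])

    def test_ground_truth_alternation(self, noisy_wo_session):
        _, _, _, truth = noisy_wo_session
        hs, to = truth.hs_times_s, truth.to_times_s
        for k in range(len(hs) - 1):
            between = to[(to > hs[k]) & (to < hs[k + 1])]
            # last step of a bout has no following HS; otherwise exactly one
            assert between.size <= 1

    def test_determinism(self):
        p = eg.GaitSimParams(n_steps=5, cycle_jitter_cv=0.05, seed=77)
        a = eg.simulate_session(p)
        b = eg.simulate_session(eg.GaitSimParams(n_steps=5,
                                                 cycle_jitter_cv=0.05, seed=77))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[2].values, b[2].values)

    def test_jitter_perturbs_cycles(self):
        p = eg.GaitSimParams(n_steps=30, cycle_jitter_cv=0.05, seed=5)
        _, _, truth = eg.simulate_kinematics(p)
        cv = truth.cycle_durations_s.std() / truth.cycle_durations_s.mean()
        assert 0.01 < cv < 0.12


class TestEmg:
    def test_null_activation_is_baseline_noise(self):
        p = eg.GaitSimParams(n_steps=5, noise_sd=0.1, seed=2)
        _, _, truth = eg.simulate_kinematics(p)
        emg = eg.simulate_emg(truth, p, burst_gain=0.0)
        for m in eg.MUSCLES:
            x = emg.channel(m)
            assert abs(x.mean()) < 0.01
            assert x.std() == pytest.approx(p.noise_sd, rel=0.15)

    def test_unknown_muscle_rejected(self, clean_session):
        params, _, _, truth = clean_session
        with pytest.raises(ValueError, match="unknown muscle"):
            eg.simulate_emg(truth, params, channels=("TA", "GAS"))

    def test_activation_lead(self, clean_session):
        """The generating envelope leads its no-lead anchor by 120 ms."""
        params, _, _, truth = clean_session
        lead = activation_envelopes(truth, params)["SOL"]
        anchored = activation_envelopes(truth, params, lead_s=0.0)["SOL"]
        n = lead.size
        xc = np.correlate(lead - lead.mean(), anchored - anchored.mean(),
                          mode="full")
        lag_s = (np.argmax(xc) - (n - 1)) / params.emg_rate_hz
        assert lag_s == pytest.approx(-0.120, abs=2 / params.emg_rate_hz)

    def test_envelope_round_trip(self, clean_session):
        """Conditioning recovers the generating envelope shape."""
        params, _, _, truth = clean_session
        emg = eg.simulate_emg(truth, params)
        env = eg.extract_envelope(eg.filter_emg(emg))
        for m in ("TA", "SOL"):
            r = np.corrcoef(env.channel(m), truth.activation_envelopes[m])[0, 1]
            assert r > 0.9

    def test_stance_fraction_of_labels(self, clean_session):
        """Truth-derived labels over complete strides match stance_fraction."""
        params, ha, ka, truth = clean_session
        rate = ha.rate_hz
        stance = swing = 0
        hs, to = truth.hs_times_s, truth.to_times_s
        for k in range(len(hs) - 1):
            stance += int(round(to[k] * rate)) - int(round(hs[k] * rate))
            swing += int(round(hs[k + 1] * rate)) - int(round(to[k] * rate))
        frac = stance / (stance + swing)
        assert frac == pytest.approx(params.stance_fraction,
                                     abs=len(hs) / (stance + swing))


class TestMvic:
    def test_invalid_force(self):
        with pytest.raises(ValueError):
            eg.simulate_mvic(0.0, eg.GaitSimParams(n_steps=1))

    def test_plateau_gives_exact_aef(self):
        p = eg.GaitSimParams(n_steps=1, seed=3)
        trials = eg.simulate_mvic(100.0, p, trial_peak_factors=(1.0,))
        force, emg = trials[0]
        assert force.duration_s == pytest.approx(5.0)
        assert eg.compute_aef(force) == pytest.approx(100.0, rel=1e-6)

    def test_max_aef_trial_selected(self):
        p = eg.GaitSimParams(n_steps=1, seed=3)
        trials = eg.simulate_mvic(100.0, p, trial_peak_factors=(0.8, 1.0, 0.9))
        aefs = [eg.compute_aef(f) for f, _ in trials]
        assert int(np.argmax(aefs)) == 1
        assert max(aefs) == pytest.approx(100.0, rel=1e-6)

    def test_zero_modulation_reference_is_baseline(self):
        p = eg.GaitSimParams(n_steps=1, noise_sd=0.05, seed=3)
        rec = eg.mvic_record_from_trials(
            "TA", eg.simulate_mvic(100.0, p, emg_scale=0.0))
        assert rec.emg_reference > 0
        # baseline-noise envelope level: mean |N(0, sd)| through the 5 Hz LP
        assert rec.emg_reference < 3 * p.noise_sd


class TestRoundTrip:
    def test_detectors_recover_all_events(self, clean_session):
        """Noise-free kinematics -> every HS and TO within one sample."""
        params, ha, ka, truth = clean_session
        hs = eg.detect_heel_strikes(ha)
        to = eg.detect_toe_offs(ka)
        assert len(hs) == len(truth.hs_times_s)
        assert len(to) == len(truth.to_times_s)
        np.testing.assert_allclose(hs, truth.hs_times_s, atol=0.02)
        np.testing.assert_allclose(to, truth.to_times_s, atol=0.02)

    def test_activity_truth_tracks_walkable(self, noisy_wo_session):
        params, ha, _, truth = noisy_wo_session
        ts = truth_states(truth, ha.rate_hz, ha.n_samples)
        walking_s = ts.sum() / ha.rate_hz
        expected = sum(e - s for (s, e, st) in truth.activity_intervals
                       if st == "walking")
        assert walking_s == pytest.approx(expected, abs=0.05)
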