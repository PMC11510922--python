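"""Synthetic exoskeleton-gait session generator.

The reference recordings (26 subjects walking overground and on a treadmill
inside a lower-limb exoskeleton) are private, so this module generates
seeded stand-in sessions with the statistical structure the rest of the
pipeline assumes:

* hip (HA) and knee (KA) angle traces at the inertial-sensor rate (100 Hz)
  built from per-cycle shape-preserving cubic (PCHIP) templates through
  anchor points, with a nominal step duration of 1.2 s and a knee swing
  peak of 65 deg whose 60%-of-peak crossing (39 deg) is anchored exactly at
  the toe-off instant;
* four-channel surface EMG (TA, VL, SOL, BF) at 1500 Hz: band-limited
  Gaussian carrier noise amplitude-modulated by phase-anchored activation
  bursts, every burst leading its kinematic anchor by ~120 ms (the
  physiological electromechanical lead);
* quiet-standing interludes (overground scenario only) during which the
  angles are near constant and the EMG drops to baseline;
* maximal voluntary isometric contraction (MVIC) trials: a dynamometer
  force ramp to a plateau plus a single-channel EMG whose envelope tracks
  the force.

Cycle template anchors (cycle phase 0 = heel strike):

====  =====================================================================
HA    max flexion late in swing (phase 0.9), a local minimum *below the
      cycle mean* at heel strike (the event the high-pass/rectify detector
      locks onto), a small loading-response rebound, and the extension
      trough mid stance (phase 0.5).
KA    small flexion at heel strike, a ~20 deg stance flexion wavelet, a
      pre-swing minimum, the 60%-of-peak value exactly at toe off
      (phase = stance fraction), and the swing peak at phase 0.75.
====  =====================================================================

Walking bouts start with a partial lead-in cycle (phase 0.62 -> 1) so the
first heel strike is preceded by a hip-flexion maximum, and end truncated
at phase 0.88 of the last cycle so no spurious extra heel strike appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .signals import MUSCLES, JointAngleTrace, SignalTrace

log = logging.getLogger(__name__)

# phase of a bout's lead-in start / truncated tail end; the lead-in starts
# at the toe-off phase so nominal cycle anchors land on the 100 Hz grid
_LEAD_IN_PHASE = 0.60
_TAIL_PHASE = 0.88
_STAND_RAMP_S = 0.3  # posture transition into/out of quiet standing

# HA template in degrees for a 40 deg range-of-motion; scaled by hip_rom_deg/40
_HA_KNOTS = ((0.0, 2.0), (0.12, 14.0), (0.5, -8.0), (0.9, 32.0), (1.0, 2.0))
_HA_STAND_40 = 12.0
_KA_STAND = 8.0

# activation bursts per muscle: (anchor, phase offset, amplitude, width_s)
# anchor "hs" = heel strike of the cycle, phase offsets are fractions of the
# cycle duration.  TA fires around contact and through swing, VL in early
# stance, SOL in late stance, BF around contact and in late swing.
_BURSTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "TA": ((0.00, 1.0, 0.05), (0.80, 0.6, 0.08)),
    "VL": ((0.08, 1.0, 0.07),),
    "SOL": ((0.48, 1.0, 0.08),),
    "BF": ((0.00, 0.8, 0.05), (0.90, 0.9, 0.06)),
}


@dataclass
class GaitSimParams:
    """Stated world of one synthetic gait session.

    Defaults follow the reference protocol: 1.2 s exoskeleton-driven steps,
    60% stance, 65 deg knee swing peak, EMG at 1500 Hz, joint angles at
    100 Hz, and muscle activation leading kinematics by 120 ms.
    """

    n_steps: int = 20
    step_duration_s: float = 1.2
    stance_fraction: float = 0.60
    knee_swing_peak_deg: float = 65.0
    hip_rom_deg: float = 40.0
    emg_rate_hz: float = 1500.0
    imu_rate_hz: float = 100.0
    activation_lead_ms: float = 120.0
    noise_sd: float = 0.05
    angle_noise_deg: float = 0.5
    standing_interludes: tuple[tuple[int, float], ...] = ()
    cycle_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.emg_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.step_duration_s <= 0:
            raise ValueError("step_duration_s must be positive")
        if self.knee_swing_peak_deg <= 0:
            raise ValueError("knee_swing_peak_deg must be positive")
        if self.activation_lead_ms < 0:
            raise ValueError("activation_lead_ms must be >= 0")
        if self.cycle_jitter_cv < 0:
            raise ValueError("cycle_jitter_cv must be >= 0")
        self.standing_interludes = tuple(
            (int(a), float(d)) for a, d in self.standing_interludes
        )
        for after, dur in self.standing_interludes:
            if not 1 <= after <= self.n_steps or dur <= 0:
                raise ValueError("standing interludes must follow an existing "
                                 "step and have positive duration")

    def rng(self, stream: int) -> np.random.Generator:
        """Per-purpose random stream split off the shared seed."""
        return np.random.default_rng([self.seed % (2 ** 31), stream])


@dataclass
class GroundTruth:
    """Generator-side truth for a session."""

    hs_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    to_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    activity_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    activation_envelopes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def session_end_s(self) -> float:
        return self.activity_intervals[-1][1] if self.activity_intervals else 0.0


def _ka_knots(peak: float, stance_fraction: float):
    return (
        (0.0, 5.0),
        (0.15, 20.0),
        (0.42, 5.0),
        (stance_fraction, 0.6 * peak),
        (0.75, peak),
        (0.92, 8.0),
        (1.0, 5.0),
    )


class _Template:
    def __init__(self, knots) -> None:
        p = np.array([k[0] for k in knots])
        v = np.array([k[1] for k in knots])
        self._interp = PchipInterpolator(p, v)
        self.knot_phases = p

    def __call__(self, phase):
        return self._interp(phase)


def _schedule(params: GaitSimParams):
    """Lay out bouts and standing interludes on the session time axis.

    Returns (bouts, activity) where each bout is a dict with the lead-in
    start, the per-cycle (start, duration) list and the bout end time.
    """
    rng = params.rng(1)
    T = params.step_duration_s
    if params.cycle_jitter_cv > 0:
        factors = np.clip(
            1.0 + params.cycle_jitter_cv * rng.standard_normal(params.n_steps),
            0.2, 3.0,
        )
    else:
        factors = np.ones(params.n_steps)
    durations = T * factors

    interludes = dict(params.standing_interludes)
    # split steps into bouts after the requested step indices
    bout_steps: list[list[int]] = [[]]
    for i in range(params.n_steps):
        bout_steps[-1].append(i)
        if (i + 1) in interludes and (i + 1) < params.n_steps:
            bout_steps.append([])

    bouts = []
    activity: list[tuple[float, float, str]] = []
    t = 0.0
    for b, steps in enumerate(bout_steps):
        start = t
        t += (1.0 - _LEAD_IN_PHASE) * T  # lead-in
        cycles = []
        for j, i in enumerate(steps):
            dur = durations[i]
            cycles.append((t, dur))
            if j < len(steps) - 1:
                t += dur
            else:
                t += _TAIL_PHASE * dur  # truncated final cycle
        end = t
        bouts.append({"start": start, "cycles": cycles, "end": end})
        activity.append((start, end, "walking"))
        last_step = steps[-1] + 1
        if last_step in interludes:
            t = end + interludes[last_step]
            activity.append((end, t, "standing"))
    return bouts, activity


def simulate_kinematics(params: GaitSimParams):
    """Generate hip and knee angle traces plus the ground-truth schedule.

    Returns ``(ha, ka, truth)``.  With zero angle noise the knee trace hits
    exactly ``knee_swing_peak_deg`` once per cycle and passes through 60% of
    that value at the true toe-off instant on the rising limb.
    """
    rate = params.imu_rate_hz
    if params.n_steps == 0:
        empty = JointAngleTrace(np.empty(0), rate, "HA")
        return empty, JointAngleTrace(np.empty(0), rate, "KA"), GroundTruth()

    bouts, activity = _schedule(params)
    ha_scale = params.hip_rom_deg / 40.0
    ha_tmpl = _Template(_HA_KNOTS)
    ka_tmpl = _Template(_ka_knots(params.knee_swing_peak_deg,
                                  params.stance_fraction))

    def collect(tmpl, scale, stand_value):
        times: list[float] = []
        vals: list[float] = []

        def add(t, v):
            times.append(t)
            vals.append(v)

        for b, bout in enumerate(bouts):
            T0 = bout["cycles"][0][1]
            # lead-in: phase LEAD_IN..1 of a nominal cycle
            add(bout["start"], scale * tmpl(_LEAD_IN_PHASE))
            for p in tmpl.knot_phases:
                if _LEAD_IN_PHASE < p < 1.0:
                    add(bout["start"] + (p - _LEAD_IN_PHASE) * params.step_duration_s,
                        scale * tmpl(p))
            for j, (cstart, dur) in enumerate(bout["cycles"]):
                last = j == len(bout["cycles"]) - 1
                top = _TAIL_PHASE if last else 1.0
                for p in tmpl.knot_phases:
                    if p < top and not (p == 1.0):
                        add(cstart + p * dur, scale * tmpl(p))
                if last:
                    add(cstart + _TAIL_PHASE * dur, scale * tmpl(_TAIL_PHASE))
        # standing anchors
        for (s, e, state) in activity:
            if state != "standing":
                continue
            t0 = s + min(_STAND_RAMP_S, 0.45 * (e - s))
            t1 = e - min(_STAND_RAMP_S, 0.45 * (e - s))
            for t in np.arange(t0, t1 + 1e-9, 0.5):
                add(float(t), stand_value)
            add(t1, stand_value)
        order = np.argsort(times)
        times_a = np.asarray(times)[order]
        vals_a = np.asarray(vals)[order]
        keep = np.concatenate([[True], np.diff(times_a) > 1e-9])
        return times_a[keep], vals_a[keep]

    session_end = activity[-1][1]
    n = int(round(session_end * rate))
    t_grid = np.arange(n) / rate

    rng = params.rng(0)
    traces = {}
    for joint, tmpl, scale, stand in (
        ("HA", ha_tmpl, ha_scale, ha_scale * _HA_STAND_40),
        ("KA", ka_tmpl, 1.0, _KA_STAND),
    ):
        at, av = collect(tmpl, scale, stand)
        interp = PchipInterpolator(at, av, extrapolate=True)
        x = interp(t_grid)
        if params.angle_noise_deg > 0:
            x = x + params.angle_noise_deg * rng.standard_normal(n)
        traces[joint] = JointAngleTrace(x, rate, joint)

    hs, to, dur = [], [], []
    for bout in bouts:
        for cstart, d in bout["cycles"]:
            hs.append(cstart)
            to.append(cstart + params.stance_fraction * d)
            dur.append(d)
    truth = GroundTruth(
        hs_times_s=np.asarray(hs),
        to_times_s=np.asarray(to),
        cycle_durations_s=np.asarray(dur),
        activity_intervals=activity,
    )
    return traces["HA"], traces["KA"], truth


def _carrier(rng: np.random.Generator, n: int, rate: float,
             band_limit: bool) -> np.ndarray:
    x = rng.standard_normal(n)
    if band_limit and rate > 900:
        b, a = butter(4, [30.0, min(400.0, 0.45 * rate)],
                      btype="bandpass", fs=rate)
        x = filtfilt(b, a, x, padlen=min(3 * int(rate) // 10, n - 1))
        sd = x.std()
        if sd > 0:
            x = x / sd
    return x


def activation_envelopes(truth: GroundTruth, params: GaitSimParams,
                         lead_s: float | None = None,
                         channels=MUSCLES) -> dict[str, np.ndarray]:
    """Per-muscle generating envelopes at the EMG rate.

    Bursts are Gaussians anchored at cycle-phase instants and shifted
    *earlier* by the activation lead (unless ``lead_s`` overrides it).
    """
    if lead_s is None:
        lead_s = params.activation_lead_ms / 1000.0
    rate = params.emg_rate_hz
    n = int(round(truth.session_end_s * rate))
    t = np.arange(n) / rate
    env = {m: np.zeros(n) for m in channels}
    for m in channels:
        if m not in _BURSTS:
            raise ValueError(f"unknown muscle {m!r}; known: {sorted(_BURSTS)}")
    for hs, dur in zip(truth.hs_times_s, truth.cycle_durations_s):
        for m in channels:
            for phase, amp, width in _BURSTS[m]:
                tc = hs + phase * dur - lead_s
                lo = np.searchsorted(t, tc - 5 * width)
                hi = np.searchsorted(t, tc + 5 * width)
                if hi > lo:
                    seg = t[lo:hi]
                    env[m][lo:hi] += amp * np.exp(-0.5 * ((seg - tc) / width) ** 2)
    return env


def simulate_emg(truth: GroundTruth, params: GaitSimParams,
                 channels=MUSCLES, band_limit_carrier: bool = True,
                 burst_gain: float = 1.0) -> SignalTrace:
    """Synthesize the four-muscle surface EMG for a session.

    Each channel is zero-mean broadband Gaussian noise (band-limited to the
    30-400 Hz conditioning passband by default) amplitude-modulated by
    ``noise_sd + burst_gain * envelope``; the baseline noise persists
    through quiet standing.  The generating envelopes are recorded in
    ``truth.activation_envelopes``.
    """
    channels = tuple(channels)
    env = activation_envelopes(truth, params, channels=channels)
    rate = params.emg_rate_hz
    n = int(round(truth.session_end_s * rate))
    rng = params.rng(2)
    cols = []
    for m in channels:
        carrier = _carrier(rng, n, rate, band_limit_carrier)
        cols.append((params.noise_sd + burst_gain * env[m]) * carrier)
    truth.activation_envelopes = {m: burst_gain * env[m] for m in channels}
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return SignalTrace(values, rate, channels, units="mV")


def simulate_mvic(peak_force_n: float, params: GaitSimParams,
                  trial_peak_factors=(0.92, 1.0, 0.96),
                  dyn_rate_hz: float = 75.0, trial_s: float = 5.0,
                  emg_scale: float = 1.5):
    """Three 5 s maximal-contraction trials.

    Returns a list of ``(force, emg)`` :class:`SignalTrace` pairs.  The
    force ramps up from 0.5 s and sits on its plateau from second 3, so the
    average expressed force over the 4th second equals the plateau value.
    The EMG channel is carrier noise modulated by the (normalized) force
    profile times ``emg_scale`` plus the ``noise_sd`` baseline.
    """
    if peak_force_n <= 0:
        raise ValueError("peak_force_n must be positive")
    rng = params.rng(3)
    trials = []
    for k, fac in enumerate(trial_peak_factors):
        peak = peak_force_n * fac
        tf = np.arange(int(round(trial_s * dyn_rate_hz))) / dyn_rate_hz
        s = np.clip((tf - 0.5) / 2.5, 0.0, 1.0)
        force = peak * (3 * s ** 2 - 2 * s ** 3)
        te_n = int(round(trial_s * params.emg_rate_hz))
        te = np.arange(te_n) / params.emg_rate_hz
        mod = np.interp(te, tf, force / peak)
        carrier = _carrier(rng, te_n, params.emg_rate_hz, True)
        emg = (params.noise_sd + emg_scale * mod) * carrier
        trials.append((
            SignalTrace(force, dyn_rate_hz, ("force_N",), units="N"),
            SignalTrace(emg, params.emg_rate_hz, ("emg",), units="mV"),
        ))
    return trials


def simulate_session(params: GaitSimParams, channels=MUSCLES):
    """Convenience: kinematics plus EMG in one call."""
    ha, ka, truth = simulate_kinematics(params)
    if params.n_steps == 0:
        emg = SignalTrace(np.empty((0, len(channels))), params.emg_rate_hz,
                          tuple(channels), units="mV")
        return ha, ka, emg, truth
    emg = simulate_emg(truth, params, channels=channels)
    return ha, ka, emg, truth
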