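"""Stance/swing labeling from hip and knee angle kinematics.

The labeling computation has three stages:

1. **Activity segmentation** (overground sessions only): a 2-state hidden
   Markov model with categorical emissions separates walking from quiet
   standing.  The hip angle is converted into an 8-symbol alphabet by
   quantile-binning a short-window activity proxy (the magnitude of the
   smoothed first difference); the decoded state with the larger emission
   variance is "walking".
2. **Gait event detection**:

   * heel strike (HS, stance onset): the hip trace is high-pass filtered
     (2nd order Butterworth, 0.5 Hz, zero phase), its positive part zeroed
     and the remainder rectified; inside each window running from a
     cycle's hip-flexion maximum to the following deepest minimum, the
     first local maximum of the processed trace is the HS instant.
   * toe off (TO, stance end): for each knee swing peak, the window from
     the preceding local minimum to the peak is searched for the first
     crossing of 60% of the peak value on the rising limb (about 39 deg
     for a 65 deg swing peak).

3. **Label track construction**: samples in [HS, TO) are stance (0),
   [TO, next HS) are swing (1); quiet-standing samples, the full stride on
   either side of every standing bout, and samples outside any complete
   stride are excluded (-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from scipy.signal import butter, filtfilt, find_peaks, peak_prominences

from .signals import JointAngleTrace

log = logging.getLogger(__name__)

STANDING, WALKING = 0, 1
EXCLUDED, STANCE, SWING = -1, 0, 1

# below this peak activity (deg/s) a hip trace cannot contain gait
_WALKING_FLOOR_DEG_S = 5.0


@dataclass
class ActivityStateTrack:
    """Per-sample walking(1)/standing(0) assignment."""

    states: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    def walking_bouts(self) -> list[tuple[int, int]]:
        """Half-open [i0, i1) sample ranges of contiguous walking."""
        return _runs(self.states == WALKING)


@dataclass
class GaitEventSet:
    """Detected heel-strike and toe-off instants, in seconds."""

    hs_times_s: np.ndarray
    to_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.hs_times_s = np.sort(np.asarray(self.hs_times_s, dtype=float))
        self.to_times_s = np.sort(np.asarray(self.to_times_s, dtype=float))


@dataclass
class PhaseLabelTrack:
    """Per-sample labels: 0 stance, 1 swing, -1 excluded."""

    labels: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _activity_proxy(ha: JointAngleTrace, window_s: float) -> np.ndarray:
    """Smoothed |dHA/dt| in deg/s: large while walking, near zero standing."""
    x = ha.values
    rate = ha.rate_hz
    if rate > 24:  # tame broadband angle noise before differencing
        b, a = butter(2, 10.0, btype="low", fs=rate)
        x = filtfilt(b, a, x, padlen=min(int(rate), x.size - 1))
    d = np.abs(np.diff(x, prepend=x[:1])) * rate
    w = max(1, int(round(window_s * rate)))
    kernel = np.ones(w) / w
    padded = np.pad(d, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def segment_activity(ha: JointAngleTrace, n_symbols: int = 8,
                     window_s: float = 1.2, n_iter: int = 25,
                     seed: int = 0) -> ActivityStateTrack:
    """Walking/standing segmentation of a hip-angle trace via an HMM.

    The activity proxy is binned into ``n_symbols`` equal-width categorical
    emissions between zero and its 95th percentile (gait saturates the top
    symbol, quiescence sits in the bottom one) and a 2-state HMM
    (self-transition 0.99 held fixed, deterministic low/high-symbol
    emission initialization) is fitted by EM and decoded by the most
    likely state path.  The state whose fitted emission distribution has
    the larger mean symbol maps to walking.

    ``window_s`` defaults to one nominal gait cycle: shorter windows let
    the within-cycle dips of |dHA/dt| (at the angle extrema) masquerade as
    quiescence.
    """
    if ha.n_samples < 2 * ha.rate_hz:
        raise ValueError("need at least 2 s of samples to segment activity")
    proxy = _activity_proxy(ha, window_s)
    if proxy.max() < _WALKING_FLOOR_DEG_S:
        # no gait-scale motion anywhere: degenerate single-state session
        return ActivityStateTrack(np.full(ha.n_samples, STANDING), ha.rate_hz)

    top = np.quantile(proxy, 0.95)
    edges = np.linspace(0.0, top, n_symbols)[1:]
    symbols = np.digitize(proxy, edges).astype(int)

    model = CategoricalHMM(
        n_components=2, n_features=n_symbols, init_params="", params="se",
        n_iter=n_iter, tol=1e-3, random_state=seed,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    k = np.arange(n_symbols, dtype=float)
    low = (n_symbols - k)
    high = (k + 1.0)
    model.emissionprob_ = np.vstack([low / low.sum(), high / high.sum()])
    obs = symbols[:, None]
    model.fit(obs)
    path = model.predict(obs)

    mean_symbol = model.emissionprob_ @ k
    walking_state = int(np.argmax(mean_symbol))
    states = np.where(path == walking_state, WALKING, STANDING)
    return ActivityStateTrack(states, ha.rate_hz)


def _extrema(x: np.ndarray, rate: float, min_separation_s: float):
    dist = max(1, int(round(min_separation_s * rate)))
    maxima, _ = find_peaks(x, distance=dist)
    minima, _ = find_peaks(-x, distance=dist)
    return maxima, minima


def _cycle_peaks(x: np.ndarray, rate: float, min_separation_s: float,
                 rel_prominence: float = 0.5) -> np.ndarray:
    """Dominant once-per-cycle peaks: prominence >= rel * best prominence."""
    maxima, _ = _extrema(x, rate, min_separation_s)
    if maxima.size == 0:
        return maxima
    prom = peak_prominences(x, maxima)[0]
    return maxima[prom >= rel_prominence * prom.max()]


def detect_heel_strikes(ha: JointAngleTrace,
                        min_separation_s: float = 0.25) -> np.ndarray:
    """Heel-strike instants (s) from a walking-only hip-angle trace."""
    x = ha.values
    rate = ha.rate_hz
    if x.size < 3 or np.ptp(x) == 0:
        return np.empty(0)
    cyc_max = _cycle_peaks(x, rate, min_separation_s)
    _, minima = _extrema(x, rate, min_separation_s)
    if cyc_max.size == 0 or minima.size == 0:
        return np.empty(0)

    b, a = butter(2, 0.5, btype="high", fs=rate)
    hp = filtfilt(b, a, x, padlen=min(int(rate), x.size - 1))
    proc = np.where(hp < 0, -hp, 0.0)  # zero the positive part, rectify
    proc_peaks, _ = _extrema(proc, rate, min_separation_s)

    events = []
    bounds = np.concatenate([cyc_max, [x.size]])
    for j, m in enumerate(cyc_max):
        window_min = minima[(minima > m) & (minima < bounds[j + 1])]
        if window_min.size == 0:
            continue
        end = window_min[np.argmin(x[window_min])]  # the deepest minimum
        inside = proc_peaks[(proc_peaks >= m) & (proc_peaks <= end)]
        if inside.size == 0:
            continue
        events.append(inside[0] / rate)  # first local maximum in the window
    return np.asarray(events)


def detect_toe_offs(ka: JointAngleTrace, threshold: float = 0.60,
                    min_separation_s: float = 0.25) -> np.ndarray:
    """Toe-off instants (s) from a walking-only knee-angle trace.

    For each swing peak, the first rising crossing of ``threshold`` times
    the peak value inside the window from the preceding local minimum is
    located by linear interpolation and reported at the nearer sample.
    """
    x = ka.values
    rate = ka.rate_hz
    if x.size < 3 or np.ptp(x) == 0:
        return np.empty(0)
    peaks = _cycle_peaks(x, rate, min_separation_s)
    _, minima = _extrema(x, rate, min_separation_s)
    events = []
    bounds = np.concatenate([[-1], peaks])
    for j, pk in enumerate(peaks):
        prev = minima[(minima < pk) & (minima > bounds[j])]
        if prev.size == 0:
            log.warning("swing peak at %.3f s has no preceding local minimum; "
                        "cycle skipped", pk / rate)
            continue
        m = prev[np.argmin(x[prev])]  # the deepest pre-swing minimum
        thr = threshold * x[pk]
        seg = x[m:pk + 1]
        above = np.nonzero(seg >= thr)[0]
        if above.size == 0:
            continue
        i = above[0]
        if i == 0:
            t = m / rate
        else:
            frac = (thr - seg[i - 1]) / (seg[i] - seg[i - 1])
            t = (m + i - 1 + frac) / rate
        events.append(round(t * rate) / rate)  # nearer sample time
    return np.asarray(events)


def build_phase_labels(events: GaitEventSet, activity: ActivityStateTrack,
                       n_samples: int | None = None) -> PhaseLabelTrack:
    """Per-sample stance/swing/excluded track from events and activity.

    Stance runs are half-open [HS, TO); swing runs [TO, next HS).  Standing
    samples, the strides immediately flanking each standing bout, and
    samples outside complete strides stay excluded.
    """
    rate = activity.rate_hz
    n = activity.n_samples if n_samples is None else n_samples
    labels = np.full(n, EXCLUDED, dtype=np.int8)
    bouts = activity.walking_bouts()
    for (i0, i1) in bouts:
        t0, t1 = i0 / rate, i1 / rate
        hs = events.hs_times_s[(events.hs_times_s >= t0) & (events.hs_times_s < t1)]
        to = events.to_times_s[(events.to_times_s >= t0) & (events.to_times_s < t1)]
        if hs.size < 2:
            continue
        # one TO strictly inside each consecutive HS pair
        strides = []
        for k in range(hs.size - 1):
            inside = to[(to > hs[k]) & (to < hs[k + 1])]
            if inside.size != 1:
                raise ValueError(
                    f"events violate HS/TO alternation between HS at "
                    f"{hs[k]:.3f} s and HS at {hs[k + 1]:.3f} s "
                    f"({inside.size} toe-offs in between)"
                )
            strides.append((hs[k], inside[0], hs[k + 1]))
        preceded_by_standing = i0 > 0
        followed_by_standing = i1 < activity.n_samples
        lo = 1 if preceded_by_standing else 0
        hi = len(strides) - 1 if followed_by_standing else len(strides)
        for (h0, t_off, h1) in strides[lo:hi]:
            a = int(round(h0 * rate))
            b = int(round(t_off * rate))
            c = int(round(h1 * rate))
            labels[a:min(b, n)] = STANCE
            labels[b:min(c, n)] = SWING
    return PhaseLabelTrack(labels, rate)


def label_session(ha: JointAngleTrace, ka: JointAngleTrace, scenario: str,
                  seed: int = 0):
    """Full labeling pipeline for one session.

    Overground (``"WO"``) sessions are first segmented into walking and
    quiet-standing bouts; treadmill (``"WT"``) sessions are continuous
    walking.  Detection runs separately on each walking bout.

    Returns ``(events, activity, labels)``.
    """
    if scenario not in ("WO", "WT"):
        raise ValueError("scenario must be 'WO' or 'WT'")
    if ha.n_samples != ka.n_samples or ha.rate_hz != ka.rate_hz:
        raise ValueError("HA and KA traces must share the sampling grid")
    if scenario == "WO":
        activity = segment_activity(ha, seed=seed)
    else:
        activity = ActivityStateTrack(np.full(ha.n_samples, WALKING), ha.rate_hz)
    hs_all, to_all = [], []
    for (i0, i1) in activity.walking_bouts():
        if (i1 - i0) < ha.rate_hz:  # ignore sub-second slivers
            continue
        off = i0 / ha.rate_hz
        hs_all.append(detect_heel_strikes(ha.slice(i0, i1)) + off)
        to_all.append(detect_toe_offs(ka.slice(i0, i1)) + off)
    events = GaitEventSet(
        np.concatenate(hs_all) if hs_all else np.empty(0),
        np.concatenate(to_all) if to_all else np.empty(0),
    )
    labels = build_phase_labels(events, activity)
    return events, activity, labels
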