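"""Surface-EMG conditioning and MVIC normalization.

The conditioning chain, applied per channel:

1. remove the channel mean;
2. 4th-order Butterworth band-pass 30-400 Hz, applied forward and backward
   (zero net phase; the squared magnitude response is accepted);
3. envelope: full-wave rectification followed by a zero-phase 4th-order
   5 Hz low-pass, clipped at zero;
4. normalization by the per-muscle MVIC envelope reference;
5. optional decimation to one third of the rate by keeping every 3rd
   sample (1500 Hz -> 500 Hz; the 5 Hz envelope filter has already removed
   everything aliasing could fold down).

The MVIC reference per muscle comes from the maximal-contraction trial
with the largest average expressed force (AEF: mean dynamometer force over
the 4th second of the contraction, after resampling the force to 1500 Hz);
the reference is the mean envelope amplitude over a 250 ms window centered
on the envelope peak of that trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .signals import SignalTrace

_FORCE_RESAMPLE_HZ = 1500.0


@dataclass
class MvicRecord:
    """Normalization reference for one muscle."""

    muscle: str
    aef_n: float
    emg_reference: float

    def __post_init__(self) -> None:
        if not self.emg_reference > 0:
            raise ValueError("emg_reference must be positive")


def _zero_phase(b, a, x: np.ndarray, rate: float) -> np.ndarray:
    # reflective padding of up to 1 s at each end
    padlen = min(int(rate), x.shape[0] - 1)
    return filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_emg(raw: SignalTrace, band=(30.0, 400.0), order: int = 4) -> SignalTrace:
    """Mean removal plus zero-phase Butterworth band-pass per channel."""
    if raw.rate_hz <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {raw.rate_hz} Hz too low for a {band[1]} Hz band edge"
        )
    x = raw.values - raw.values.mean(axis=0, keepdims=True)
    b, a = butter(order, band, btype="bandpass", fs=raw.rate_hz)
    return raw.replace_values(_zero_phase(b, a, x, raw.rate_hz))


def extract_envelope(filtered: SignalTrace, cutoff_hz: float = 5.0,
                     order: int = 4) -> SignalTrace:
    """Full-wave rectification + zero-phase low-pass; clipped at zero."""
    rect = np.abs(filtered.values)
    b, a = butter(order, cutoff_hz, btype="low", fs=filtered.rate_hz)
    env = _zero_phase(b, a, rect, filtered.rate_hz)
    return filtered.replace_values(np.clip(env, 0.0, None))


def compute_aef(force: SignalTrace, window=(3.0, 4.0)) -> float:
    """Average expressed force: mean over the 4th second of a contraction.

    The force trace is first resampled to 1500 Hz by linear interpolation.
    """
    if force.n_channels != 1:
        raise ValueError("force trace must be single-channel")
    if force.duration_s < window[1]:
        raise ValueError(
            f"trial of {force.duration_s:.2f} s is shorter than {window[1]} s"
        )
    t_new = np.arange(int(round(force.duration_s * _FORCE_RESAMPLE_HZ)))
    t_new = t_new / _FORCE_RESAMPLE_HZ
    f = np.interp(t_new, force.times(), force.values[:, 0])
    i0 = int(round(window[0] * _FORCE_RESAMPLE_HZ))
    i1 = int(round(window[1] * _FORCE_RESAMPLE_HZ))
    return float(f[i0:i1].mean())


def compute_mvic_reference(envelope: SignalTrace, window_s: float = 0.250) -> float:
    """Mean envelope over a 250 ms window centered on the global peak.

    The window is clipped at the trial edges when the peak sits near them.
    """
    if envelope.n_channels != 1:
        raise ValueError("MVIC envelope must be single-channel")
    x = envelope.values[:, 0]
    if x.size == 0:
        raise ValueError("empty envelope")
    peak = int(np.argmax(x))
    half = int(round(window_s / 2 * envelope.rate_hz))
    lo = max(0, peak - half)
    hi = min(x.size, peak + half + 1)
    ref = float(x[lo:hi].mean())
    if not ref > 0:
        raise ValueError("degenerate (non-positive) MVIC envelope reference")
    return ref


def mvic_record_from_trials(muscle: str, trials, band=(30.0, 400.0)) -> MvicRecord:
    """Pick the max-AEF trial and derive the normalization reference.

    ``trials`` is a sequence of ``(force, emg)`` single-channel traces as
    produced by the MVIC protocol (three 5 s maximal contractions).
    """
    aefs = [compute_aef(force) for force, _ in trials]
    best = int(np.argmax(aefs))
    _, emg = trials[best]
    env = extract_envelope(filter_emg(emg, band=band))
    return MvicRecord(muscle=muscle, aef_n=float(aefs[best]),
                      emg_reference=compute_mvic_reference(env))


def normalize_envelope(envelope: SignalTrace,
                       refs: MvicRecord | dict[str, MvicRecord]) -> SignalTrace:
    """Divide each channel by its muscle's MVIC envelope reference.

    Output units are fractions of MVIC; values above 1 are legitimate
    (dynamic contractions can exceed the isometric reference).
    """
    if isinstance(refs, MvicRecord):
        refs = {refs.muscle: refs}
    missing = [c for c in envelope.channels if c not in refs]
    if missing:
        raise ValueError(f"no MVIC reference for channel(s) {missing}")
    scale = np.array([refs[c].emg_reference for c in envelope.channels])
    return envelope.replace_values(envelope.values / scale, units="MVIC fraction")


def downsample_every3(signal: SignalTrace) -> SignalTrace:
    """Keep samples 0, 3, 6, ...; rate drops to one third."""
    if signal.rate_hz % 3 != 0:
        raise ValueError(f"rate {signal.rate_hz} Hz is not divisible by 3")
    return signal.replace_values(signal.values[::3], rate_hz=signal.rate_hz / 3)


def preprocess_emg(raw: SignalTrace, refs: dict[str, MvicRecord],
                   rate_out: float = 500.0) -> SignalTrace:
    """Full chain: filter -> envelope -> MVIC normalization -> decimation."""
    env = normalize_envelope(extract_envelope(filter_emg(raw)), refs)
    if rate_out == raw.rate_hz:
        return env
    if rate_out == raw.rate_hz / 3:
        return downsample_every3(env)
    raise ValueError(f"rate_out must be {raw.rate_hz} or {raw.rate_hz / 3}")
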