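"""Containers for uniformly sampled physiological time series.

Two in-memory containers are shared across the pipeline:

* :class:`SignalTrace` — a samples x channels real matrix with a sampling
  rate and channel names.  Used for multichannel surface EMG (TA, VL, SOL,
  BF), single-channel dynamometer force, and derived envelopes.
* :class:`JointAngleTrace` — a single joint-angle series in degrees
  (hip angle ``HA`` or knee angle ``KA``), positive = flexion.

CSV round-tripping follows the on-disk layout used by the command line
tools: a ``time_s`` column followed by one column per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUSCLES = ("TA", "VL", "SOL", "BF")


@dataclass
class SignalTrace:
    """Uniformly sampled multichannel real-valued time series."""

    values: np.ndarray
    rate_hz: float
    channels: tuple[str, ...]
    units: str = "a.u."

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError("values must be a (samples, channels) matrix")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        self.channels = tuple(self.channels)
        if len(self.channels) != v.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {v.shape[1]} columns"
            )
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {self.channels}")
        return self.values[:, self.channels.index(name)]

    def replace_values(self, values: np.ndarray, rate_hz: float | None = None,
                       units: str | None = None) -> "SignalTrace":
        return SignalTrace(
            values=values,
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            channels=self.channels,
            units=self.units if units is None else units,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channels))
        df.insert(0, "time_s", self.times())
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate_hz: float | None = None,
                 units: str = "a.u.") -> "SignalTrace":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("expected a time_s column")
        t = df["time_s"].to_numpy()
        if rate_hz is None:
            if len(t) < 2:
                raise ValueError("cannot infer rate from fewer than 2 samples")
            rate_hz = 1.0 / np.median(np.diff(t))
            rate_hz = float(np.round(rate_hz, 6))
        cols = [c for c in df.columns if c != "time_s"]
        return cls(df[cols].to_numpy(), rate_hz, tuple(cols), units)


@dataclass
class JointAngleTrace:
    """Single-channel joint angle series in degrees, positive = flexion.

    ``joint`` is ``"HA"`` (hip: sacrum-thigh) or ``"KA"`` (knee:
    thigh-shank), both computed from inertial sensors at 100 Hz in the
    reference protocol.
    """

    values: np.ndarray
    rate_hz: float
    joint: str = "HA"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("angle values must be finite")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.joint not in ("HA", "KA"):
            raise ValueError("joint must be 'HA' or 'KA'")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def slice(self, i0: int, i1: int) -> "JointAngleTrace":
        return JointAngleTrace(self.values[i0:i1], self.rate_hz, self.joint)


def angles_to_csv(ha: JointAngleTrace, ka: JointAngleTrace, path) -> None:
    if ha.n_samples != ka.n_samples or ha.rate_hz != ka.rate_hz:
        raise ValueError("HA and KA traces must share grid")
    pd.DataFrame(
        {"time_s": ha.times(), "HA_deg": ha.values, "KA_deg": ka.values}
    ).to_csv(path, index=False)


def angles_from_csv(path, rate_hz: float | None = None):
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if rate_hz is None:
        rate_hz = float(np.round(1.0 / np.median(np.diff(t)), 6))
    ha = JointAngleTrace(df["HA_deg"].to_numpy(), rate_hz, "HA")
    ka = JointAngleTrace(df["KA_deg"].to_numpy(), rate_hz, "KA")
    return ha, ka
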