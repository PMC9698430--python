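"""Labeled IMU stream container and its columnar text format.

A stream holds per-sample multichannel inertial data (one or two IMUs, each
a triaxial accelerometer plus a triaxial gyroscope, so 6 or 12 feature
columns), a per-sample locomotion-mode label track and a per-sample gait
event marker (``none`` / ``heel_strike`` / ``toe_off``).

On disk a stream is a UTF-8 CSV, one sample per row::

    time_s,acc1_x,acc1_y,acc1_z,gyr1_x,gyr1_y,gyr1_z[,acc2_x,...,gyr2_z],mode,event

Units are m/s^2 for accelerometers and rad/s for gyroscopes (documented,
not enforced).  The sample rate is recovered from the ``time_s`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import LocomotionMode

EVENT_NONE = "none"
EVENT_HEEL_STRIKE = "heel_strike"
EVENT_TOE_OFF = "toe_off"
_EVENTS = (EVENT_NONE, EVENT_HEEL_STRIKE, EVENT_TOE_OFF)

_AXES = ("x", "y", "z")


class FormatError(ValueError):
    """The file does not conform to the labeled-stream CSV dialect."""


def channel_names(n_features: int) -> list[str]:
    """Canonical channel column order for 6 (one IMU) or 12 (two IMUs)."""
    if n_features not in (6, 12):
        raise ValueError(f"n_features must be 6 or 12, got {n_features}")
    names = []
    for imu in range(1, n_features // 6 + 1):
        names += [f"acc{imu}_{a}" for a in _AXES]
        names += [f"gyr{imu}_{a}" for a in _AXES]
    return names


@dataclass
class ImuStream:
    """Per-sample labeled IMU time series.

    Attributes
    ----------
    sample_rate : float
        Sampling frequency in Hz (500 or 1000 typical).
    channels : ndarray of shape (n_samples, n_features)
        Sensor columns in canonical order; ``n_features`` is 6 or 12.
    mode : ndarray of str, shape (n_samples,)
        Locomotion-mode code per sample (``"S"``, ``"ST"``, ``"W"``, ...).
        After transition marking this track may also hold transition labels
        such as ``"W-S"``.
    event : ndarray of str, shape (n_samples,)
        Gait event marker per sample.
    """

    sample_rate: float
    channels: np.ndarray
    mode: np.ndarray
    event: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[1] not in (6, 12):
            raise ValueError(
                f"channels must be (n_samples, 6 or 12), got {self.channels.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.channels.shape[0]
        self.mode = np.asarray(self.mode, dtype=object)
        if self.event is None:
            self.event = np.full(n, EVENT_NONE, dtype=object)
        self.event = np.asarray(self.event, dtype=object)
        if len(self.mode) != n or len(self.event) != n:
            raise ValueError("mode/event tracks must match channels length")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def n_features(self) -> int:
        return self.channels.shape[1]

    @property
    def n_imus(self) -> int:
        return self.n_features // 6

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def event_indices(self, kind: str) -> np.ndarray:
        """Sample indices carrying a given event marker."""
        return np.flatnonzero(self.event == kind)


def _validate_labels(mode: np.ndarray, allow_transitions: bool) -> None:
    valid_modes = {m.code for m in LocomotionMode}
    for row, code in enumerate(mode):
        if code in valid_modes:
            continue
        if allow_transitions and "-" in str(code):
            a, _, b = str(code).partition("-")
            if a in valid_modes and b in valid_modes and a != b:
                continue
        raise FormatError(f"row {row}: unknown mode label {code!r}")


def read_stream(path: str | Path) -> ImuStream:
    """Read a labeled IMU stream from its CSV dialect.

    Raises :class:`FormatError` on missing columns, a non-monotone time
    column, an unknown mode code or an unknown event marker, naming the
    offending row where applicable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    for col in ("mode", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    feature_cols = [c for c in df.columns if c not in ("time_s", "mode", "event")]
    if len(feature_cols) not in (6, 12):
        raise FormatError(
            f"{path}: expected 6 or 12 feature columns, found {len(feature_cols)}"
        )
    expected = channel_names(len(feature_cols))
    if feature_cols != expected:
        raise FormatError(f"{path}: feature columns must be {expected}, got {feature_cols}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the sample rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise FormatError(f"{path}: row {row}: time column is not strictly increasing")
    sample_rate = 1.0 / float(np.median(dt))

    mode = df["mode"].to_numpy(dtype=object)
    try:
        _validate_labels(mode, allow_transitions=True)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    event = df["event"].to_numpy(dtype=object)
    bad = [i for i, e in enumerate(event) if e not in _EVENTS]
    if bad:
        raise FormatError(f"{path}: row {bad[0]}: unknown event marker {event[bad[0]]!r}")

    return ImuStream(
        sample_rate=round(sample_rate, 6),
        channels=df[feature_cols].to_numpy(dtype=float),
        mode=mode,
        event=event,
    )


def write_stream(stream: ImuStream, path: str | Path) -> None:
    """Write a stream in the canonical CSV dialect (fixed 6-decimal floats)."""
    path = Path(path)
    cols = channel_names(stream.n_features)
    df = pd.DataFrame(stream.channels, columns=cols)
    df.insert(0, "time_s", stream.times)
    df["mode"] = stream.mode
    df["event"] = stream.event
    df.to_csv(path, index=False, float_format="%.6f")
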