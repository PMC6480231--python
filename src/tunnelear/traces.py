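"""Pressure-time traces and their CSV dialect.

A :class:`PressureTrace` is a uniformly sampled gauge-pressure series (Pa,
zero = ambient) that plays both roles in the cabin-pressure problem: the
exterior transient measured on the train surface and the interior transient
felt in the cabin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MEASUREMENT_POINTS = ("MP-1", "MP-2", "MP-3", "MP-4", "MP-5")

#: Relative tolerance used to decide whether a time grid is uniform.
_GRID_RTOL = 1e-6

TRACE_CSV_COLUMNS = ("time_s", "pressure_pa")


@dataclass(frozen=True)
class TransitGeometry:
    """Geometry and kinematics of one tunnel transit.

    Parameters
    ----------
    tunnel_length : float
        Tunnel length in metres.
    train_length : float
        Train length in metres; must be shorter than the tunnel.
    speed : float
        Operating speed in km/h.
    point_id : str
        Measurement point, ``MP-1`` (head-car driver cabin) through
        ``MP-5`` (tail-car driver cabin), ordered against the running
        direction.
    """

    tunnel_length: float = 350.0
    train_length: float = 79.77
    speed: float = 250.0
    point_id: str = "MP-1"

    def __post_init__(self) -> None:
        if not self.train_length > 0:
            raise ValueError(f"train_length must be positive, got {self.train_length}")
        if not self.tunnel_length > self.train_length:
            raise ValueError(
                "tunnel_length must exceed train_length, got "
                f"{self.tunnel_length} <= {self.train_length}"
            )
        if not self.speed > 0:
            raise ValueError(f"speed must be positive (km/h), got {self.speed}")
        if self.point_id not in MEASUREMENT_POINTS:
            raise ValueError(
                f"point_id must be one of {MEASUREMENT_POINTS}, got {self.point_id!r}"
            )

    @property
    def speed_ms(self) -> float:
        """Speed in m/s."""
        return self.speed / 3.6

    @property
    def transit_duration(self) -> float:
        """Head-car entry to tail-car exit: (L_tunnel + L_train) / V, seconds."""
        return (self.tunnel_length + self.train_length) / self.speed_ms

    @property
    def point_index(self) -> int:
        """1-based index of the measurement point (MP-1 -> 1)."""
        return MEASUREMENT_POINTS.index(self.point_id) + 1


@dataclass(frozen=True)
class PressureTrace:
    """Uniformly sampled gauge pressure vs time.

    ``role`` distinguishes the exterior (train-surface) transient from the
    interior (cabin) transient produced by the seal filter.
    """

    time: np.ndarray
    pressure: np.ndarray
    role: str = "exterior"
    meta: TransitGeometry | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        pressure = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "pressure", pressure)
        if time.ndim != 1 or pressure.ndim != 1:
            raise ValueError("time and pressure must be one-dimensional")
        if time.size != pressure.size:
            raise ValueError("time and pressure must have equal length")
        if time.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(time)) or not np.all(np.isfinite(pressure)):
            raise ValueError("trace contains non-finite values")
        steps = np.diff(time)
        if np.any(steps <= 0):
            idx = int(np.argmax(steps <= 0))
            raise ValueError(f"time must be strictly increasing (violated at sample {idx + 1})")
        dt = steps[0]
        if not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * dt):
            raise ValueError("time grid is not uniform")
        if self.role not in ("exterior", "interior"):
            raise ValueError(f"role must be 'exterior' or 'interior', got {self.role!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def with_pressure(self, pressure: np.ndarray, role: str | None = None) -> "PressureTrace":
        return replace(self, pressure=np.asarray(pressure, dtype=float), role=role or self.role)


def max_pressure_difference(trace: PressureTrace) -> float:
    """Peak-to-peak pressure over the transit window, in Pa."""
    return float(np.max(trace.pressure) - np.min(trace.pressure))


def write_trace_csv(trace: PressureTrace, path) -> None:
    """Write a trace as ``time_s,pressure_pa`` CSV (UTF-8, '.' decimal)."""
    frame = pd.DataFrame({"time_s": trace.time, "pressure_pa": trace.pressure})
    frame.to_csv(path, index=False)


def read_trace_csv(path, role: str = "exterior") -> PressureTrace:
    """Read a ``time_s,pressure_pa`` CSV, rejecting malformed rows with line numbers."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    missing = [c for c in TRACE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must be "
                         f"{','.join(TRACE_CSV_COLUMNS)}")
    time = pd.to_numeric(frame["time_s"], errors="coerce").to_numpy()
    pressure = pd.to_numeric(frame["pressure_pa"], errors="coerce").to_numpy()
    bad = ~np.isfinite(time) | ~np.isfinite(pressure)
    if np.any(bad):
        # +2: one for the header row, one for 1-based numbering.
        line = int(np.argmax(bad)) + 2
        raise ValueError(f"{path}: malformed or non-finite value at line {line}")
    steps = np.diff(time)
    if np.any(steps <= 0):
        line = int(np.argmax(steps <= 0)) + 3
        raise ValueError(f"{path}: time not strictly increasing at line {line}")
    return PressureTrace(time=time, pressure=pressure, role=role)
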