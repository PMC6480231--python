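"""Interior cabin pressure via the dynamic-seal-index model.

The cabin tracks the exterior transient through a first-order relaxation

    dP_in/dt = (P_out - P_in) / ω,

where ω (seconds) is the dynamic seal index of the car body: the larger ω,
the tighter the car and the more the interior is smoothed and attenuated.
The filter is integrated exactly per sample assuming piecewise-linear
exterior pressure (an exponential integrator), so it is unconditionally
stable at any sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import PressureTrace


@dataclass(frozen=True)
class SealIndex:
    """Dynamic seal index ω in seconds (cabin pressure-relaxation time)."""

    omega: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"seal index omega must be positive, got {self.omega}")


def _as_omega(seal: "SealIndex | float") -> float:
    omega = seal.omega if isinstance(seal, SealIndex) else float(seal)
    if not omega > 0:
        raise ValueError(f"seal index omega must be positive, got {omega}")
    return omega


def exponential_filter(
    pressure: np.ndarray, dt: float, omega: float, p0: float = 0.0
) -> np.ndarray:
    """Exact first-order response to a piecewise-linear input.

    Over each step the input is linear, ``u(s) = u_n + Δu·s/h``; the update

        y_{n+1} = y_n·E + u_n·(1-E) + Δu·(1 - ω(1-E)/h),   E = e^{-h/ω}

    is the closed-form solution, hence exact for any step size.
    """
    u = np.asarray(pressure, dtype=float)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    decay = np.exp(-dt / omega)
    hold = 1.0 - decay
    ramp = 1.0 - omega * hold / dt
    du = np.diff(u)
    forcing = u[:-1] * hold + du * ramp
    y = np.empty_like(u)
    y[0] = p0
    # linear recurrence y[n+1] = decay*y[n] + forcing[n]
    from scipy.signal import lfilter

    y[1:], _ = lfilter([1.0], [1.0, -decay], forcing, zi=[decay * p0])
    return y


class SealFilter(BaseEstimator, TransformerMixin):
    """Transformer mapping exterior pressure series to interior series.

    Parameters
    ----------
    omega : float
        Dynamic seal index in seconds.  Service values for high-speed stock
        run 4–12 s.
    dt : float
        Sampling step, seconds, used when transforming bare arrays.
    p0 : float
        Interior gauge pressure at the first sample (0 = equilibrated).
    """

    def __init__(self, omega: float = 8.0, dt: float = 1e-3, p0: float = 0.0):
        self.omega = omega
        self.dt = dt
        self.p0 = p0

    def fit(self, X=None, y=None):
        _as_omega(self.omega)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        return self

    def transform(self, X):
        """Filter pressure series along axis 0 (columns are independent runs)."""
        self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return exponential_filter(X, self.dt, self.omega, self.p0)
        return np.column_stack(
            [exponential_filter(X[:, j], self.dt, self.omega, self.p0)
             for j in range(X.shape[1])]
        )

    def transform_trace(self, trace: PressureTrace) -> PressureTrace:
        interior = exponential_filter(trace.pressure, trace.dt, self.omega, self.p0)
        return replace(trace, pressure=interior, role="interior")


def interior_pressure(
    exterior: PressureTrace, seal: "SealIndex | float", p0: float = 0.0
) -> PressureTrace:
    """Exact interior response of a cabin with seal index ``seal``.

    The returned trace shares the exterior's time grid and carries the
    ``interior`` role flag.  ``p0`` is the cabin gauge pressure at the first
    sample (default 0: the cabin is equilibrated at tunnel entry).
    """
    omega = _as_omega(seal)
    return SealFilter(omega=omega, dt=exterior.dt, p0=p0).transform_trace(exterior)


def seal_relief_time(seal: "SealIndex | float", p_start: float, p_end: float) -> float:
    """Time for the cabin to relieve from ``p_start`` to ``p_end`` at P_out = 0.

    Under the first-order model the decay is exponential, so the relief takes
    ``ω·ln(p_start/p_end)`` seconds.  The 4000 → 1000 Pa relief quoted in
    airtightness standards therefore lasts ``ω·ln 4 ≈ 1.386·ω``.
    """
    omega = _as_omega(seal)
    if not (p_start > 0 and p_end > 0):
        raise ValueError("pressures must be positive")
    if p_start < p_end:
        raise ValueError(f"p_start must be >= p_end, got {p_start} < {p_end}")
    return omega * float(np.log(p_start / p_end))
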