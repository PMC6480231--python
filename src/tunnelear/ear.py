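"""Lumped-parameter middle-ear surrogate.

Maps an interior cabin-pressure trace to the three biomechanical discomfort
indicators:

* ``I1`` — displacement of the tympanic-membrane umbo, μm;
* ``I2`` — displacement of the stapes footplate, μm;
* ``I3`` — velocity of the stapes footplate, μm/s.

The model is two cascaded linear second-order stages: a tympanic-membrane
stage driven by cabin pressure, and an ossicle/annular-ligament stage driven
by umbo motion.  Both stages have unit static gain, so at tunnel-transit
timescales (≪ 1 Hz, against natural frequencies ≥ 100 Hz) the response is
quasi-static:

    i1 ≈ C·P_in,   i2 ≈ r·i1,   i3 = di2/dt ≈ r·C·dP_in/dt,

with C the umbo compliance (μm/Pa) and r the footplate/umbo displacement
ratio.  The full integration and the closed-form quasi-static path are both
exposed; the latter doubles as the oracle for the former.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.signal import lsim
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import PressureTrace

#: Minimum admissible stage natural frequency, Hz.  Anything this high is
#: quasi-static against seconds-scale tunnel loading.
MIN_NATURAL_FREQUENCY = 100.0


@dataclass(frozen=True)
class EarParameters:
    """Calibration constants of the lumped middle-ear surrogate.

    ``umbo_compliance`` is the quasi-static umbo displacement per unit
    pressure on the lateral tympanic-membrane surface (μm/Pa);
    ``ossicular_ratio`` the footplate/umbo quasi-static displacement ratio.
    The two (natural frequency, damping) pairs parameterise the
    tympanic-membrane and ossicle/annular-ligament stages.
    """

    umbo_compliance: float = 0.08       # μm/Pa
    ossicular_ratio: float = 0.41       # dimensionless
    tm_frequency: float = 1000.0        # Hz
    tm_damping: float = 0.7
    ossicle_frequency: float = 1000.0   # Hz
    ossicle_damping: float = 0.7

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("tm_frequency", "ossicle_frequency"):
            if getattr(self, name) < MIN_NATURAL_FREQUENCY:
                raise ValueError(
                    f"{name} must be >= {MIN_NATURAL_FREQUENCY} Hz so tunnel-band "
                    "loading stays quasi-static"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "EarParameters":
        return cls(**data)


def default_ear_parameters() -> EarParameters:
    """Documented default calibration (see docs/methods.md)."""
    return EarParameters()


@dataclass(frozen=True)
class EarResponse:
    """Indicator time series on a shared uniform grid.

    Sign convention: positive = inward (toward the inner ear).  Discomfort
    classification uses magnitudes; signed series are preserved here.
    """

    time: np.ndarray
    i1: np.ndarray  # μm
    i2: np.ndarray  # μm
    i3: np.ndarray  # μm/s

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time", "i1", "i2", "i3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            arrays[name] = arr
        n = arrays["time"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("all series must share the time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def indicator(self, indicator_id: str) -> np.ndarray:
        return {"I1": self.i1, "I2": self.i2, "I3": self.i3}[indicator_id]


class MiddleEarModel(BaseEstimator, TransformerMixin):
    """Transformer from a pressure series to the (I1, I2, I3) matrix.

    ``transform`` accepts a 1-D pressure array sampled at ``dt`` (or a
    single-column matrix) and returns an ``(n, 3)`` array of indicator
    samples.  ``simulate`` / ``quasi_static`` operate on traces and return
    :class:`EarResponse`.
    """

    def __init__(
        self,
        umbo_compliance: float = 0.08,
        ossicular_ratio: float = 0.41,
        tm_frequency: float = 1000.0,
        tm_damping: float = 0.7,
        ossicle_frequency: float = 1000.0,
        ossicle_damping: float = 0.7,
        dt: float = 1e-3,
        method: str = "lsim",
    ):
        self.umbo_compliance = umbo_compliance
        self.ossicular_ratio = ossicular_ratio
        self.tm_frequency = tm_frequency
        self.tm_damping = tm_damping
        self.ossicle_frequency = ossicle_frequency
        self.ossicle_damping = ossicle_damping
        self.dt = dt
        self.method = method

    # -- sklearn surface -------------------------------------------------
    def fit(self, X=None, y=None):
        self._params()  # validates
        if self.method not in ("lsim", "quasi_static"):
            raise ValueError(f"method must be 'lsim' or 'quasi_static', got {self.method!r}")
        return self

    def transform(self, X):
        self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single pressure column")
            X = X[:, 0]
        time = np.arange(X.size) * self.dt
        trace = PressureTrace(time=time, pressure=X, role="interior")
        resp = self.simulate(trace) if self.method == "lsim" else self.quasi_static(trace)
        return np.column_stack([resp.i1, resp.i2, resp.i3])

    # -- trace surface ---------------------------------------------------
    def _params(self) -> EarParameters:
        return EarParameters(
            umbo_compliance=self.umbo_compliance,
            ossicular_ratio=self.ossicular_ratio,
            tm_frequency=self.tm_frequency,
            tm_damping=self.tm_damping,
            ossicle_frequency=self.ossicle_frequency,
            ossicle_damping=self.ossicle_damping,
        )

    def _state_space(self):
        p = self._params()
        w1 = 2.0 * np.pi * p.tm_frequency
        w2 = 2.0 * np.pi * p.ossicle_frequency
        z1, z2 = p.tm_damping, p.ossicle_damping
        c, r = p.umbo_compliance, p.ossicular_ratio
        # state x = [x1, v1, x2, v2]; x1 umbo μm, x2 footplate μm
        A = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [-w1 * w1, -2.0 * z1 * w1, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
                [r * w2 * w2, 0.0, -w2 * w2, -2.0 * z2 * w2],
            ]
        )
        B = np.array([[0.0], [c * w1 * w1], [0.0], [0.0]])
        C = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],  # i1 = x1
                [0.0, 0.0, 1.0, 0.0],  # i2 = x2
                [0.0, 0.0, 0.0, 1.0],  # i3 = v2 (a state, not a difference)
            ]
        )
        D = np.zeros((3, 1))
        return A, B, C, D

    def simulate(self, interior: PressureTrace) -> EarResponse:
        """Integrate the cascaded stages driven by the pressure trace.

        Uses an exact first-order-hold discretisation of the linear system
        (piecewise-linear pressure between samples); the footplate velocity
        is a state of the integrator, never a finite difference.
        """
        system = self._state_space()
        _, y, _ = lsim(system, U=interior.pressure, T=interior.time)
        y = np.atleast_2d(y)
        return EarResponse(time=interior.time, i1=y[:, 0], i2=y[:, 1], i3=y[:, 2])

    def quasi_static(self, interior: PressureTrace) -> EarResponse:
        """Closed-form quasi-static path: i1 = C·P, i2 = r·C·P, i3 = r·C·dP/dt."""
        p = self._params()
        i1 = p.umbo_compliance * interior.pressure
        i2 = p.ossicular_ratio * i1
        i3 = np.gradient(i2, interior.time)
        return EarResponse(time=interior.time, i1=i1, i2=i2, i3=i3)


def simulate_response(interior: PressureTrace, params: EarParameters | None = None) -> EarResponse:
    """Full linear-system integration of the middle-ear surrogate."""
    params = params or default_ear_parameters()
    return MiddleEarModel(**params.to_dict()).simulate(interior)


def quasi_static_response(
    interior: PressureTrace, params: EarParameters | None = None
) -> EarResponse:
    """Quasi-static closed form; oracle for :func:`simulate_response` below 1 Hz."""
    params = params or default_ear_parameters()
    return MiddleEarModel(**params.to_dict()).quasi_static(interior)


def write_response_csv(resp: EarResponse, path) -> None:
    """Write an ear response as ``time_s,i1_um,i2_um,i3_um_s`` CSV."""
    pd.DataFrame(
        {"time_s": resp.time, "i1_um": resp.i1, "i2_um": resp.i2, "i3_um_s": resp.i3}
    ).to_csv(path, index=False)


def read_response_csv(path) -> EarResponse:
    frame = pd.read_csv(path)
    required = {"time_s", "i1_um", "i2_um", "i3_um_s"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return EarResponse(
        time=frame["time_s"].to_numpy(),
        i1=frame["i1_um"].to_numpy(),
        i2=frame["i2_um"].to_numpy(),
        i3=frame["i3_um_s"].to_numpy(),
    )
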