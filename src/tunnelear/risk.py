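"""Logistic exposure–response machinery for aural discomfort levels.

The four ordered discomfort levels (ideal < good < bad < worse) are separated
by thresholds derived from binary-coded logistic regressions between adjacent
levels.  The risk of crossing a boundary at indicator exposure ``x`` is

    p(x) = 1 / (1 + e^(α − βx)),

and the boundary threshold is the 50%-incidence point ``x = α/β``.  Four
boundaries are fit per indicator: T1 (ideal/good), T2 (good/bad), T3
(bad/worse) and T4, the critical comfort/discomfort boundary pooled over all
conditions.  Because T2 and T4 estimate the same physical boundary from
different sample sizes, their average Tc is used for classification, giving
the level intervals (0, T1), [T1, Tc), [Tc, T3), [T3, ∞).

Published regression coefficients and thresholds ship as packaged reference
data (``reference_tables``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

INDICATORS = ("I1", "I2", "I3")
BOUNDARIES = ("T1", "T2", "T3", "T4")
LEVELS = ("ideal", "good", "bad", "worse")

#: Tc must equal (T2+T4)/2 up to the precision thresholds are quoted at.
_TC_ATOL = 5.1e-3


class SeparationError(ValueError):
    """Raised when a logistic boundary fit is refused for complete separation."""


@dataclass(frozen=True)
class LogisticFit:
    """One fitted boundary: intercept α, slope β and the slope's Wald p-value."""

    alpha: float
    beta: float
    p_value: float
    boundary_id: str | None = None
    indicator_id: str | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(
                f"beta must be positive (risk must increase with exposure), got {self.beta}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if self.boundary_id is not None and self.boundary_id not in BOUNDARIES:
            raise ValueError(f"boundary_id must be one of {BOUNDARIES}")
        if self.indicator_id is not None and self.indicator_id not in INDICATORS:
            raise ValueError(f"indicator_id must be one of {INDICATORS}")


def logistic_risk(x, fit: LogisticFit):
    """Boundary-crossing risk p(x) = 1/(1 + e^(α − βx)); strictly increasing."""
    x = np.asarray(x, dtype=float)
    out = expit(fit.beta * x - fit.alpha)
    return float(out) if out.ndim == 0 else out


def threshold_from_fit(fit: LogisticFit) -> float:
    """The 50%-incidence exposure, α/β."""
    return fit.alpha / fit.beta


class LogisticBoundary(BaseEstimator):
    """Maximum-likelihood logistic fit of a binary outcome on one exposure.

    Fitted attributes: ``alpha_``, ``beta_``, ``p_value_`` (Wald test on the
    slope) and ``threshold_`` (= alpha_/beta_).  Complete separation is
    refused with :class:`SeparationError` rather than silently returning a
    divergent fit.
    """

    #: Newton–Raphson (IRLS) settings, fixed.
    MAX_ITER = 100
    TOL = 1e-10

    def __init__(self, boundary_id: str | None = None, indicator_id: str | None = None):
        self.boundary_id = boundary_id
        self.indicator_id = indicator_id

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("exposures and labels must have equal length")
        if not np.all(np.isfinite(x)):
            raise ValueError("exposures must be finite")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError(
                f"labels must contain both classes coded 0/1, got classes {classes}"
            )
        if x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min():
            raise SeparationError(
                "complete separation: the two classes do not overlap in exposure; "
                "the maximum-likelihood slope is unbounded"
            )
        design = sm.add_constant(x)
        result = sm.Logit(y, design).fit(
            disp=0, maxiter=self.MAX_ITER, tol=self.TOL, method="newton"
        )
        if not result.mle_retvals.get("converged", False):
            raise SeparationError("logistic fit did not converge (quasi-separation?)")
        intercept, slope = result.params
        if slope <= 0:
            raise ValueError(
                f"fitted slope is non-positive ({slope:.4g}); risk must increase "
                "with exposure"
            )
        self.alpha_ = float(-intercept)
        self.beta_ = float(slope)
        self.p_value_ = float(result.pvalues[1])
        self.threshold_ = self.alpha_ / self.beta_
        # standard errors kept for Wald intervals in recovery studies
        self.alpha_se_ = float(result.bse[0])
        self.beta_se_ = float(result.bse[1])
        return self

    def predict_proba(self, X):
        x = np.asarray(X, dtype=float).ravel()
        p = expit(self.beta_ * x - self.alpha_)
        return np.column_stack([1.0 - p, p])

    def to_fit(self) -> LogisticFit:
        return LogisticFit(
            alpha=self.alpha_,
            beta=self.beta_,
            p_value=self.p_value_,
            boundary_id=self.boundary_id,
            indicator_id=self.indicator_id,
        )


def fit_logistic(
    exposures,
    labels,
    boundary_id: str | None = None,
    indicator_id: str | None = None,
) -> LogisticFit:
    """Fit one boundary by maximum likelihood and return the (α, β, p) triple."""
    est = LogisticBoundary(boundary_id=boundary_id, indicator_id=indicator_id)
    est.fit(exposures, labels)
    return est.to_fit()


@dataclass(frozen=True)
class ThresholdSet:
    """The four boundary thresholds plus the classification boundary Tc.

    Tc is the mean of T2 and T4 (two estimates of the comfort/discomfort
    boundary).  Validation allows the quoted-precision rounding of published
    Tc cells.
    """

    t1: float
    t2: float
    t3: float
    t4: float
    tc: float | None = None
    indicator_id: str | None = None

    def __post_init__(self) -> None:
        mean = (self.t2 + self.t4) / 2.0
        if self.tc is None:
            object.__setattr__(self, "tc", mean)
        elif not math.isclose(self.tc, mean, abs_tol=_TC_ATOL, rel_tol=0.0):
            raise ValueError(
                f"tc must equal (t2+t4)/2 = {mean:.6g}, got {self.tc}"
            )
        if not self.t1 < self.tc < self.t3:
            raise ValueError(
                f"threshold ordering t1 < tc < t3 violated: {self.t1}, {self.tc}, {self.t3}"
            )


def derive_threshold_set(fits) -> ThresholdSet:
    """Build a ThresholdSet from the four boundary fits of one indicator."""
    by_boundary = {f.boundary_id: f for f in fits}
    if set(by_boundary) != set(BOUNDARIES):
        raise ValueError(f"need exactly one fit per boundary {BOUNDARIES}, got "
                         f"{sorted(b for b in by_boundary if b)}")
    indicators = {f.indicator_id for f in fits}
    if len(indicators) != 1:
        raise ValueError(f"fits mix indicators: {sorted(i for i in indicators if i)}")
    t = {b: threshold_from_fit(by_boundary[b]) for b in BOUNDARIES}
    return ThresholdSet(
        t1=t["T1"], t2=t["T2"], t3=t["T3"], t4=t["T4"],
        indicator_id=next(iter(indicators)),
    )


def relative_t2_t4_error(ts: ThresholdSet) -> float:
    """|T4 − T2| / Tc × 100: relative disagreement of the two comfort boundaries, %."""
    return abs(ts.t4 - ts.t2) / ts.tc * 100.0


@dataclass(frozen=True)
class LevelIntervals:
    """Half-open magnitude intervals partitioning (0, ∞) into the four levels.

    ideal (0, T1) · good [T1, Tc) · bad [Tc, T3) · worse [T3, ∞); boundaries
    are lower-closed (ties have measure zero on continuous responses).
    """

    t1: float
    tc: float
    t3: float
    indicator_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.tc < self.t3:
            raise ValueError(
                f"need 0 < t1 < tc < t3, got {self.t1}, {self.tc}, {self.t3}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.t1, self.tc, self.t3])

    def classify(self, magnitudes):
        """Map indicator magnitudes to level labels (vectorised, total)."""
        mags = np.abs(np.asarray(magnitudes, dtype=float))
        idx = np.searchsorted(self.edges, mags, side="right")
        return np.asarray(LEVELS, dtype=object)[idx]

    def as_table(self) -> dict[str, tuple[float, float]]:
        return {
            "ideal": (0.0, self.t1),
            "good": (self.t1, self.tc),
            "bad": (self.tc, self.t3),
            "worse": (self.t3, math.inf),
        }


def build_intervals(ts: ThresholdSet) -> LevelIntervals:
    """Classification intervals from a threshold set (T1, Tc, T3 edges)."""
    return LevelIntervals(t1=ts.t1, tc=ts.tc, t3=ts.t3, indicator_id=ts.indicator_id)


def _load_reference() -> dict:
    text = (
        resources.files("tunnelear").joinpath("data/reference_thresholds.json").read_text()
    )
    return json.loads(text)


def reference_tables() -> tuple[dict, dict]:
    """Packaged published constants.

    Returns ``(fits, thresholds)``: per-indicator dicts of the four boundary
    :class:`LogisticFit` objects and the published :class:`ThresholdSet`.
    The published coefficient and threshold tables are internally
    inconsistent for I1/I2 beyond printed rounding (α/β ≈ 79.3 vs quoted
    78.87 for I1 T2); the threshold table is authoritative for
    classification.  Values are returned verbatim.
    """
    raw = _load_reference()
    fits = {
        ind: {
            b: LogisticFit(boundary_id=b, indicator_id=ind, **coeffs)
            for b, coeffs in rows.items()
        }
        for ind, rows in raw["logistic_fits"].items()
    }
    thresholds = {
        ind: ThresholdSet(indicator_id=ind, **row)
        for ind, row in raw["thresholds"].items()
    }
    return fits, thresholds


def reference_intervals() -> dict[str, LevelIntervals]:
    """Classification intervals per indicator from the published thresholds."""
    _, thresholds = reference_tables()
    return {ind: build_intervals(ts) for ind, ts in thresholds.items()}
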