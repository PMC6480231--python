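"""Level classification of indicator series and duration statistics.

Each indicator sample is mapped (by magnitude) to one of the four discomfort
levels; per-transit duration summaries record the percentage of transit time
spent in each level, and control-variable aggregation pools those summaries
over the non-target factors to isolate the effect of speed, seal index or
car position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .ear import EarResponse
from .risk import LEVELS, LevelIntervals

FACTORS = ("speed", "seal_index", "point")

_SUM_TOL = 1e-6


class LevelClassifier(BaseEstimator, ClassifierMixin):
    """Classifier mapping indicator magnitudes to discomfort-level labels."""

    def __init__(self, intervals: LevelIntervals | None = None):
        self.intervals = intervals

    def fit(self, X=None, y=None):
        if self.intervals is None:
            raise ValueError("intervals must be provided")
        self.classes_ = np.asarray(LEVELS, dtype=object)
        return self

    def predict(self, X):
        self.fit()
        return self.intervals.classify(np.asarray(X, dtype=float).ravel())


def classify_series(
    resp: EarResponse, intervals: dict[str, LevelIntervals]
) -> dict[str, np.ndarray]:
    """Per-sample level labels for each indicator present in ``intervals``."""
    return {
        ind: iv.classify(resp.indicator(ind)) for ind, iv in intervals.items()
    }


@dataclass(frozen=True)
class DurationSummary:
    """Percent of transit time per level, plus the factor tags of the run."""

    percent: dict[str, float]
    n_samples: int
    dt: float
    indicator: str | None = None
    speed: float | None = None
    seal_index: float | None = None
    point: str | None = None

    def __post_init__(self) -> None:
        if set(self.percent) != set(LEVELS):
            raise ValueError(f"percent must cover exactly the levels {LEVELS}")
        if any(v < 0 for v in self.percent.values()):
            raise ValueError("percentages must be non-negative")
        total = sum(self.percent.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise ValueError(f"percentages must sum to 100, got {total}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def total_time(self) -> float:
        return self.n_samples * self.dt

    def factor_value(self, factor: str):
        if factor not in FACTORS:
            raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
        return getattr(self, factor)


def duration_summary(labels, dt: float, **tags) -> DurationSummary:
    """Percentage of samples per level from one label stream."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("label stream is empty")
    unknown = set(np.unique(labels)) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level label(s): {sorted(unknown)}")
    n = labels.size
    percent = {lvl: float(np.count_nonzero(labels == lvl)) * 100.0 / n for lvl in LEVELS}
    return DurationSummary(percent=percent, n_samples=n, dt=dt, **tags)


def discomfort_fraction(summary: DurationSummary) -> float:
    """Percent of transit time in the discomfort levels (bad + worse)."""
    return summary.percent["bad"] + summary.percent["worse"]


def _check_full_factorial(summaries, factor: str) -> None:
    others = [f for f in FACTORS if f != factor]
    groups: dict[object, set] = {}
    for s in summaries:
        key = s.factor_value(factor)
        groups.setdefault(key, set()).add(tuple(s.factor_value(f) for f in others))
    if len(summaries) > 1:
        all_combos = set().union(*groups.values())
        observed = {f: sorted({c[i] for c in all_combos}) for i, f in enumerate(others)}
        expected = {
            tuple(vals)
            for vals in itertools.product(*(observed[f] for f in others))
        }
        for key, combos in groups.items():
            if combos != expected:
                raise ValueError(
                    f"unbalanced factorial: {factor}={key} covers {len(combos)} of "
                    f"{len(expected)} combinations of {others}"
                )


def aggregate_by_factor(summaries, factor: str) -> list[DurationSummary]:
    """Pool duration summaries over the non-target factors.

    Pooling is time-weighted: level durations (percent × total time) are
    summed across runs, so transits of different lengths contribute in
    proportion to their actual duration.  Requires a full factorial of the
    other two factors for every level of the target factor (single summaries
    pass through).  Summaries must all describe the same indicator.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to aggregate")
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    indicators = {s.indicator for s in summaries}
    if len(indicators) > 1:
        raise ValueError(f"summaries mix indicators: {sorted(map(str, indicators))}")
    _check_full_factorial(summaries, factor)

    pooled: list[DurationSummary] = []
    keys = sorted({s.factor_value(factor) for s in summaries}, key=lambda v: (v is None, v))
    for key in keys:
        group = [s for s in summaries if s.factor_value(factor) == key]
        total = sum(s.total_time for s in group)
        percent = {
            lvl: sum(s.percent[lvl] * s.total_time for s in group) / total
            for lvl in LEVELS
        }
        # renormalise away float round-off so the invariant holds exactly
        scale = 100.0 / sum(percent.values())
        percent = {lvl: v * scale for lvl, v in percent.items()}
        n = sum(s.n_samples for s in group)
        tags = {factor: key, "indicator": next(iter(indicators))}
        pooled.append(DurationSummary(percent=percent, n_samples=n, dt=total / n, **tags))
    return pooled


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tidy export: one row per (summary, level)."""
    rows = []
    for s in summaries:
        for lvl in LEVELS:
            rows.append(
                {
                    "indicator": s.indicator,
                    "speed_kmh": s.speed,
                    "omega_s": s.seal_index,
                    "point": s.point,
                    "level": lvl,
                    "percent": s.percent[lvl],
                }
            )
    return pd.DataFrame(rows)
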