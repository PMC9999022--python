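"""Survival-curve container shared by every stage of the pipeline.

A :class:`SurvivalCurve` is a survivor function tabulated on an increasing
time grid in years, starting at ``S(0) = 1``.  It is the common currency
between curve construction (parametric fits, hazard-ratio adjustment,
background-mortality splicing) and the micro-simulation, which samples
event times from it by inverse-CDF interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: model cycle length in years (21 days)
CYCLE_YEARS = 21.0 / 365.25
#: default model horizon in years
HORIZON_YEARS = 20.0


def model_grid(horizon: float = HORIZON_YEARS, step: float = CYCLE_YEARS) -> np.ndarray:
    """Time grid from 0 to ``horizon`` in steps of one model cycle."""
    n = int(np.ceil(horizon / step))
    return np.minimum(np.arange(n + 1) * step, horizon)


@dataclass
class SurvivalCurve:
    """Survivor function S(t) on an increasing grid of times (years)."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, s = self.times, self.survival
        if t.ndim != 1 or t.shape != s.shape or len(t) < 2:
            raise ValueError("times and survival must be 1-d arrays of equal length >= 2")
        if t[0] != 0.0:
            raise ValueError("grid must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(s[0] - 1.0) > 1e-9:
            raise ValueError("S(0) must equal 1")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            raise ValueError("survival must be non-increasing")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation of S at times ``t`` (beyond grid: last value)."""
        return np.interp(t, self.times, self.survival)

    def interval_hazards(self) -> np.ndarray:
        """Per-interval constant hazards implied by the grid values."""
        s = np.clip(self.survival, 1e-300, 1.0)
        return np.diff(-np.log(s)) / np.diff(self.times)

    def cumulative_hazard(self) -> np.ndarray:
        return -np.log(np.clip(self.survival, 1e-300, 1.0))

    # -- summaries ----------------------------------------------------------

    def mean(self) -> float:
        """Restricted mean survival time over the grid (trapezoidal)."""
        return float(np.trapezoid(self.survival, self.times))

    def discounted_mean(self, rate: float) -> float:
        """Mean survival time with continuous discounting at annual ``rate``."""
        if rate == 0.0:
            return self.mean()
        df = (1.0 + rate) ** (-self.times)
        return float(np.trapezoid(self.survival * df, self.times))

    def median(self) -> float:
        s, t = self.survival, self.times
        if s[-1] > 0.5:
            return float("inf")
        return float(np.interp(-0.5, -s, t))

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_interval_hazards(cls, times: np.ndarray, hazards: np.ndarray) -> "SurvivalCurve":
        """Build a curve from per-interval hazards (len(times) - 1 values)."""
        times = np.asarray(times, dtype=float)
        H = np.concatenate([[0.0], np.cumsum(np.asarray(hazards) * np.diff(times))])
        return cls(times, np.exp(-H))

    def with_survival(self, survival: np.ndarray) -> "SurvivalCurve":
        return SurvivalCurve(self.times.copy(), survival)


@dataclass
class IPDSet:
    """Pseudo individual-patient data: event/censoring times with flags."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if len(self.times) == 0:
            raise ValueError("IPDSet must contain at least one record")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("all times must be > 0")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event flags must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())
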