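"""Smoothed environmental time series (sea-surface temperature, dissolved O2).

Raw series arrive as values averaged over 1 Myr intervals.  A natural cubic
smoothing spline is fitted (second derivative zero at the boundaries) and the
fitted curve is interpolated on a finer grid — 0.25 Myr by default — before
being coupled to trait models.  Evaluation outside the fitted age range is a
hard error: extrapolating palaeoclimate silently would fabricate data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = ["EnvCurve", "fit_smoothing_spline", "read_curve_csv"]

DEFAULT_STEP_MYR = 0.25


@dataclass
class EnvCurve:
    """A fitted, interpolable environmental curve indexed by age (Ma).

    Ages are stored increasing.  ``smoothing`` is the penalty weight used
    (``None`` means it was chosen by generalized cross-validation).
    """

    ages: np.ndarray
    values: np.ndarray
    spline: BSpline
    smoothing: float | None
    step_myr: float = DEFAULT_STEP_MYR

    @property
    def age_min(self) -> float:
        return float(self.ages.min())

    @property
    def age_max(self) -> float:
        return float(self.ages.max())

    def value_at(self, age) -> np.ndarray | float:
        """Spline evaluation at one or more ages (Ma); no extrapolation."""
        a = np.asarray(age, dtype=float)
        tol = 1e-9 * max(1.0, abs(self.age_max))
        if np.any(a < self.age_min - tol) or np.any(a > self.age_max + tol):
            raise ValueError(
                f"age outside fitted range [{self.age_min}, {self.age_max}] Ma; "
                "clip the tree or extend the curve explicitly"
            )
        a = np.clip(a, self.age_min, self.age_max)
        out = self.spline(a)
        return float(out) if np.isscalar(age) else out

    def resample(self, step: float | None = None) -> pd.DataFrame:
        """Evaluate the fitted curve on a regular age grid (default 0.25 Myr)."""
        step = self.step_myr if step is None else float(step)
        if step <= 0:
            raise ValueError("step must be positive")
        span = self.age_max - self.age_min
        if step > span:
            raise ValueError(f"step {step} exceeds the fitted range ({span} Myr)")
        n = int(round(span / step))
        grid = self.age_min + step * np.arange(n + 1)
        grid[-1] = self.age_max
        return pd.DataFrame({"age_ma": grid, "fitted_value": self.spline(grid)})

    def to_csv(self, path, step: float | None = None) -> None:
        self.resample(step).to_csv(path, index=False)


def fit_smoothing_spline(
    samples, smoothing: float | None = None, step_myr: float = DEFAULT_STEP_MYR
) -> EnvCurve:
    """Fit a natural cubic smoothing spline to (age, value) samples.

    Parameters
    ----------
    samples
        Iterable of (age_ma, value) pairs, a 2-column array, or a DataFrame
        with columns ``age_ma`` and ``value``.  Ages must be unique; >= 4
        samples are required.
    smoothing
        Non-negative penalty on curvature.  ``0`` interpolates the samples
        exactly; ``None`` (default) picks the penalty by generalized
        cross-validation.
    """
    if isinstance(samples, pd.DataFrame):
        ages = samples["age_ma"].to_numpy(dtype=float)
        vals = samples["value"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, float)
        ages, vals = arr[:, 0], arr[:, 1]
    if ages.size < 4:
        raise ValueError("need at least 4 samples to fit a smoothing spline")
    if np.unique(ages).size != ages.size:
        dup = sorted({a for a in ages.tolist() if ages.tolist().count(a) > 1})
        raise ValueError(f"duplicate ages in samples: {dup}")
    order = np.argsort(ages)
    ages, vals = ages[order], vals[order]
    if smoothing is not None and smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    lam = None if smoothing is None else float(smoothing)
    spline = make_smoothing_spline(ages, vals, lam=lam)
    return EnvCurve(ages=ages, values=vals, spline=spline, smoothing=smoothing, step_myr=step_myr)


def read_curve_csv(path, smoothing: float | None = None, step_myr: float = DEFAULT_STEP_MYR) -> EnvCurve:
    """Read an ``age_ma,value`` CSV and fit the smoothing spline."""
    df = pd.read_csv(path)
    if not {"age_ma", "value"} <= set(df.columns):
        raise ValueError("curve CSV needs columns 'age_ma' and 'value'")
    return fit_smoothing_spline(df[["age_ma", "value"]], smoothing=smoothing, step_myr=step_myr)
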