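"""Sigmoid fitting and tangent-method onset estimation for staining data.

The fraction of tissue area stained for glycosaminoglycans is modelled as a
4-parameter logistic of age,

    f(x) = b + L / (1 + exp(-k (x - x0))),

with baseline b, amplitude L, midpoint x0 (years), and rate k (per year).
Onset and end of accumulation follow the tangent (inoculum) construction
borrowed from growth-curve lag estimation: the tangent at the inflection
point (x0, b + L/2) has slope L k / 4; its intersections with the baseline
y = b and the upper plateau y = b + L give

    onset = x0 - 2 / k,    end = x0 + 2 / k.

The fast-accumulation window is the interval around x0 where the tangent
still overlaps the sigmoid to within a tolerance eps (a fraction of the
amplitude), found by a numeric scan at 0.01-year resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidFit",
    "logistic4",
    "fit_logistic",
    "onset_end_ages",
    "fast_window",
    "analyze_staining",
    "animal_means",
]


def logistic4(x, b, L, x0, k):
    return b + L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


@dataclass
class SigmoidFit:
    baseline: float  # b, fraction
    amplitude: float  # L, fraction
    midpoint: float  # x0, years
    rate: float  # k, per year
    rss: float
    reliable: bool
    onset_age: float | None = None
    end_age: float | None = None
    fast_start: float | None = None
    fast_end: float | None = None
    epsilon: float | None = None  # fraction of amplitude


def _start_grid(x: np.ndarray, y: np.ndarray):
    """Deterministic multi-start grid for the nonlinear fit."""
    b0 = float(np.min(y))
    l0 = max(float(np.ptp(y)), 1e-3)
    x0s = np.quantile(x, [0.25, 0.5, 0.75])
    return [(b0, l0, float(x0), k0) for x0 in x0s for k0 in (0.2, 0.5, 1.0, 2.0)]


def fit_logistic(ages, fractions) -> SigmoidFit:
    """Bounded nonlinear least squares of the 4-parameter logistic.

    Multi-start over a deterministic grid of (midpoint, rate) inits; the
    lowest-RSS converged fit wins. Fits whose amplitude collapses toward
    zero (flat data) or that sit on a bound are flagged unreliable.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 points")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")

    lower = np.array([0.0, 1e-6, x.min() - 5.0, 1e-3])
    upper = np.array([1.0, 1.0, x.max() + 5.0, 10.0])
    best, best_rss, errors = None, np.inf, []
    for p0 in _start_grid(x, y):
        p0 = np.clip(p0, lower, upper)
        try:
            popt, _ = curve_fit(logistic4, x, y, p0=p0, bounds=(lower, upper), maxfev=10000)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            errors.append(str(exc))
            continue
        rss = float(np.sum((y - logistic4(x, *popt)) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise RuntimeError("logistic fit failed from every start: " + "; ".join(errors[:3]))
    b, L, x0, k = (float(v) for v in best)
    resid_rms = np.sqrt(best_rss / x.size)
    on_bound = bool(np.any(np.isclose(best, lower, atol=1e-8) | np.isclose(best, upper, atol=1e-8)))
    reliable = (L >= max(5e-3, 2.0 * resid_rms)) and not on_bound
    return SigmoidFit(baseline=b, amplitude=L, midpoint=x0, rate=k,
                      rss=best_rss, reliable=reliable)


def onset_end_ages(fit: SigmoidFit, method: str = "closed_form") -> tuple[float, float]:
    """Onset and end ages from the inflection-tangent construction.

    ``method="closed_form"`` evaluates x0 -/+ 2/k directly;
    ``method="numeric"`` intersects the tangent line with the two asymptotes
    numerically (the two agree to floating-point precision and the numeric
    route exists as a cross-check).
    """
    if fit.rate <= 0:
        raise ValueError("rate must be positive")
    if method == "closed_form":
        return fit.midpoint - 2.0 / fit.rate, fit.midpoint + 2.0 / fit.rate
    if method == "numeric":
        slope = fit.amplitude * fit.rate / 4.0
        mid_y = fit.baseline + fit.amplitude / 2.0
        # tangent: y = mid_y + slope (x - x0); solve y = b and y = b + L
        a_on = fit.midpoint + (fit.baseline - mid_y) / slope
        a_end = fit.midpoint + (fit.baseline + fit.amplitude - mid_y) / slope
        return float(a_on), float(a_end)
    raise ValueError(f"unknown method {method!r}")


def _tangent(fit: SigmoidFit, x: np.ndarray) -> np.ndarray:
    slope = fit.amplitude * fit.rate / 4.0
    return fit.baseline + fit.amplitude / 2.0 + slope * (x - fit.midpoint)


def fast_window(fit: SigmoidFit, epsilon: float = 0.02,
                resolution: float = 0.01) -> tuple[float, float]:
    """Ages bracketing the fast-accumulation phase.

    The smallest age below the midpoint (and symmetrically the largest age
    above it) at which the tangent deviates from the sigmoid by no more than
    ``epsilon * amplitude``, scanned at ``resolution``-year steps.
    """
    if not 0.0 < epsilon < 0.2:
        raise ValueError("epsilon must lie in (0, 0.2)")
    span = 6.0 / fit.rate
    left = np.arange(fit.midpoint - span, fit.midpoint + resolution / 2, resolution)
    dev_left = np.abs(_tangent(fit, left) - logistic4(left, fit.baseline, fit.amplitude,
                                                      fit.midpoint, fit.rate))
    tol = epsilon * fit.amplitude
    start = float(left[np.argmax(dev_left <= tol)])
    right = np.arange(fit.midpoint + span, fit.midpoint - resolution / 2, -resolution)
    dev_right = np.abs(_tangent(fit, right) - logistic4(right, fit.baseline, fit.amplitude,
                                                        fit.midpoint, fit.rate))
    end = float(right[np.argmax(dev_right <= tol)])
    return start, end


def animal_means(staining: pd.DataFrame) -> pd.DataFrame:
    """Average replicate images to one fraction per animal.

    Expects columns (animal, age, image_id, fraction); fitting animal means
    rather than individual images avoids pseudo-replication.
    """
    return (
        staining.groupby("animal", sort=True)
        .agg(age=("age", "first"), fraction=("fraction", "mean"))
        .reset_index()
    )


def analyze_staining(staining: pd.DataFrame, epsilon: float = 0.02) -> SigmoidFit:
    """Full onset analysis of a per-image staining table."""
    means = animal_means(staining)
    fit = fit_logistic(means["age"].to_numpy(), means["fraction"].to_numpy())
    fit.onset_age, fit.end_age = onset_end_ages(fit)
    fit.fast_start, fit.fast_end = fast_window(fit, epsilon)
    fit.epsilon = epsilon
    return fit
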