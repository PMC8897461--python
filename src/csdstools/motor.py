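"""Motor-learning analysis: rotarod Hill-sigmoid fits and reaching success.

The accelerating-rotarod learning curve over 15 trials is fitted with a
four-parameter sigmoid derived from the Hill equation,

    t(x) = t0 + (tmax - t0) * x^h / (ls50^h + x^h),

with trial index x = 1..15, baseline time t0, asymptotic maximum tmax, Hill
coefficient h and midpoint ls50.  The learning speed LS50 is reported in two
ways: the fitted midpoint parameter, and the literal reading "trials needed to
reach 50 % of the maximum time", solved on the fitted curve (the two coincide
when t0 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillFit",
    "LearningSpeed",
    "hill_curve",
    "fit_learning_curve",
    "learning_speed",
    "max_time",
    "reaching_success_rate",
]

TRIAL_CAP_S = 90.0

# deterministic multi-start grid; fixed order for reproducibility
_H_STARTS = (0.5, 1.0, 2.0, 4.0)
_LS50_STARTS = (2.0, 5.0, 8.0, 12.0)

LS50_BOUNDS = (0.5, 30.0)
H_BOUNDS = (1e-3, 10.0)


def hill_curve(x, t0: float, tmax: float, ls50: float, h: float):
    """Evaluate the Hill sigmoid at trial index ``x`` (monotone for h > 0)."""
    x = np.asarray(x, dtype=float)
    xh = np.power(x, h)
    return t0 + (tmax - t0) * xh / (ls50**h + xh)


@dataclass(frozen=True)
class HillFit:
    t0: float
    tmax: float
    ls50: float
    h: float
    rss: float
    converged: bool
    flat: bool = False
    tmax_at_bound: bool = False

    def predict(self, x):
        if self.flat:
            return np.full_like(np.asarray(x, dtype=float), self.t0)
        return hill_curve(x, self.t0, self.tmax, self.ls50, self.h)


class LearningSpeed(NamedTuple):
    trials: float
    starts_above_half_max: bool


def fit_learning_curve(
    times_s: Sequence[float], cap_s: float = TRIAL_CAP_S
) -> HillFit:
    """Least-squares Hill fit of one animal's trial-time series.

    Bounds: t0, tmax in [0, cap]; ls50 in [0.5, 30]; h in (0, 10].  A
    deterministic multi-start grid over (h, ls50) guards against local
    minima; the best residual sum of squares wins (first in grid order on
    ties).  An all-identical series is returned as a flagged flat fit with
    undefined ls50/h; tmax within 0.5 s of the cap is flagged at-bound.
    """
    y = np.asarray(times_s, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("need at least 5 trial times")
    if not np.isfinite(y).all():
        raise ValueError("trial times must be finite")
    if (y < 0).any() or (y > cap_s + 1e-9).any():
        raise ValueError(f"trial times must lie in [0, {cap_s}] s")
    x = np.arange(1, y.size + 1, dtype=float)

    if np.ptp(y) == 0:
        v = float(y[0])
        return HillFit(v, v, float("nan"), float("nan"), 0.0, True, flat=True)

    lo = np.array([0.0, 0.0, LS50_BOUNDS[0], H_BOUNDS[0]])
    hi = np.array([cap_s, cap_s, LS50_BOUNDS[1], H_BOUNDS[1]])
    t0_start = float(np.clip(y.min(), 0, cap_s))
    tmax_start = float(np.clip(y.max(), 0, cap_s))

    def residuals(p):
        return hill_curve(x, *p) - y

    best = None
    for h0 in _H_STARTS:
        for l0 in _LS50_STARTS:
            p0 = np.clip([t0_start, tmax_start, l0, h0], lo + 1e-9, hi - 1e-9)
            try:
                sol = least_squares(
                    residuals, p0, bounds=(lo, hi),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:
                continue
            rss = float(2 * sol.cost)
            if sol.success and (best is None or rss < best[0] - 1e-12):
                best = (rss, sol.x)
    if best is None:
        return HillFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), False,
        )
    rss, (t0, tmax, ls50, h) = best
    return HillFit(
        float(t0), float(tmax), float(ls50), float(h), rss, True,
        tmax_at_bound=bool(tmax >= cap_s - 0.5),
    )


def learning_speed(fit: HillFit) -> LearningSpeed:
    """Literal LS50: smallest x with predicted t(x) >= 0.5 * tmax.

    Solved in closed form on the fitted curve.  When the baseline t0 already
    sits at or above half-maximum the curve never crosses it from below;
    0 trials is reported with a flag.  Equals the fitted ls50 parameter when
    t0 = 0.
    """
    if fit.flat or not fit.converged:
        raise ValueError("learning speed requires a converged, non-flat fit")
    half = 0.5 * fit.tmax
    if half <= fit.t0:
        return LearningSpeed(0.0, True)
    # t0 + (tmax-t0) * f = half  =>  f = x^h/(ls50^h + x^h)
    f = (half - fit.t0) / (fit.tmax - fit.t0)
    x = fit.ls50 * (f / (1.0 - f)) ** (1.0 / fit.h)
    return LearningSpeed(float(x), False)


def max_time(series_s: Sequence[float] | None = None, fit: HillFit | None = None) -> dict:
    """Maximum time on the rod: fitted asymptote and/or empirical maximum.

    Returns a dict with whichever of ``fitted_tmax_s`` / ``empirical_max_s``
    is computable from the inputs, plus the at-bound flag of the fit.
    """
    if series_s is None and fit is None:
        raise ValueError("need a series or a fit")
    out: dict = {}
    if series_s is not None:
        y = np.asarray(series_s, dtype=float)
        out["empirical_max_s"] = float(np.max(y))
    if fit is not None:
        out["fitted_tmax_s"] = float(fit.tmax)
        out["tmax_at_bound"] = bool(fit.tmax_at_bound)
    return out


def reaching_success_rate(outcomes, n_pellets: int = 48) -> float:
    """Percent of pellets eaten after the first or second correct reach.

    ``outcomes`` is one day's sequence of per-pellet booleans (True =
    success); exactly ``n_pellets`` outcomes are required.
    """
    arr = np.asarray(outcomes)
    if arr.ndim != 1 or arr.size != n_pellets:
        raise ValueError(f"expected exactly {n_pellets} outcomes, got {arr.size}")
    return float(100.0 * np.count_nonzero(arr) / n_pellets)
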