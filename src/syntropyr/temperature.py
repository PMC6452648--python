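"""Temperature-response model discrimination for pyrite-forming activity.

Biologically catalyzed activity is typically unimodal around an optimum
temperature, whereas abiotic low-temperature pyrite formation follows a
sigmoidal (monotone) temperature dependence.  This module fits both
shapes to an activity-vs-temperature profile and classifies the response
by information-criterion comparison:

* unimodal: the cardinal temperature model with inflexion (Rosso form),
  parameters (T_min, T_opt, T_max, peak), zero outside [T_min, T_max];
* sigmoidal: a 3-parameter logistic in temperature
  (asymptote, midpoint, steepness).

Model selection uses AIC with the small-sample correction (AICc) when the
point count allows it, falling back to plain AIC for the very short
profiles (5-7 temperatures) typical of incubation series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: |delta AIC| below which neither shape is preferred.
AIC_INDETERMINATE = 2.0
#: Floor on the per-point residual variance so a perfect fit has finite AIC.
_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class TemperatureProfile:
    """Activity (pyrite fraction or CH4) measured over a temperature series."""

    temperatures_C: tuple[float, ...]
    activity: tuple[float, ...]
    replicate_sd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures_C) < 4:
            raise ValueError("need at least 4 temperature points")
        if len(self.temperatures_C) != len(self.activity):
            raise ValueError("temperatures and activities differ in length")


@dataclass(frozen=True)
class ResponseFit:
    model: str  # "unimodal" | "sigmoidal"
    params: dict[str, float]
    rss: float
    aic: float
    ok: bool


def cardinal_model(t: np.ndarray, t_min: float, t_opt: float, t_max: float, peak: float) -> np.ndarray:
    """Rosso cardinal-temperature model, scaled to ``peak`` at T_opt."""
    t = np.asarray(t, dtype=float)
    num = (t - t_max) * (t - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (t - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2 * t)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = peak * np.where(np.abs(den) > 1e-12, num / np.where(den == 0, 1, den), 0.0)
    out = np.where((t <= t_min) | (t >= t_max), 0.0, out)
    return np.clip(out, 0.0, None)


def logistic_model(t: np.ndarray, asymptote: float, midpoint: float, steepness: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return asymptote / (1.0 + np.exp(-steepness * (t - midpoint)))


def _aic(rss: float, n: int, k: int) -> float:
    """AIC from a least-squares fit; AICc when n > k + 2."""
    rss = max(rss, _RSS_FLOOR * n)
    aic = n * math.log(rss / n) + 2 * k
    if n > k + 2:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _multi_start_fit(residuals, starts, bounds) -> tuple[np.ndarray | None, float]:
    best_x, best_cost = None, math.inf
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
    return best_x, 2.0 * best_cost


def fit_unimodal(profile: TemperatureProfile) -> ResponseFit:
    """Least-squares cardinal-temperature fit; deterministic multi-start."""
    t = np.asarray(profile.temperatures_C, dtype=float)
    y = np.asarray(profile.activity, dtype=float)
    if np.count_nonzero(y) < 2:
        return ResponseFit("unimodal", {}, float(np.sum(y**2)), math.inf, ok=False)

    span = float(t.max() - t.min())
    peak0 = float(y.max())
    topt0 = float(t[np.argmax(y)])
    starts = [
        np.array([t.min() - f_lo * span, topt0 + d, t.max() + f_hi * span, peak0])
        for f_lo, f_hi, d in [(0.05, 0.05, 0.0), (0.3, 0.3, 0.0), (0.05, 0.3, 3.0), (0.3, 0.05, -3.0)]
    ]
    if t.min() < topt0 < t.max():
        # support-edge start: cardinal temperatures at the observed range
        starts.insert(0, np.array([t.min(), topt0, t.max(), peak0]))
    lo = [t.min() - 2 * span, t.min(), t.min(), 0.0]
    hi = [t.max(), t.max(), t.max() + 2 * span, 10 * max(peak0, 1e-9)]

    def residuals(p):
        t_min, t_opt, t_max, peak = p
        if not (t_min < t_opt < t_max):
            return np.full_like(y, 1e3)
        return cardinal_model(t, t_min, t_opt, t_max, peak) - y

    x, rss = _multi_start_fit(residuals, starts, (lo, hi))
    if x is None:
        return ResponseFit("unimodal", {}, math.inf, math.inf, ok=False)
    params = dict(zip(("T_min", "T_opt", "T_max", "peak"), map(float, x)))
    return ResponseFit("unimodal", params, rss, _aic(rss, y.size, 4), ok=True)


def fit_sigmoidal(profile: TemperatureProfile) -> ResponseFit:
    """Least-squares 3-parameter logistic fit in temperature."""
    t = np.asarray(profile.temperatures_C, dtype=float)
    y = np.asarray(profile.activity, dtype=float)
    if np.count_nonzero(y) < 2:
        return ResponseFit("sigmoidal", {}, float(np.sum(y**2)), math.inf, ok=False)

    span = float(t.max() - t.min())
    a0 = float(y.max())
    starts = [
        np.array([a0, float(np.median(t)), s]) for s in (0.05, 0.2, 1.0, -0.2)
    ]
    lo = [0.0, t.min() - span, -10.0]
    hi = [10 * max(a0, 1e-9), t.max() + span, 10.0]

    def residuals(p):
        return logistic_model(t, *p) - y

    x, rss = _multi_start_fit(residuals, starts, (lo, hi))
    if x is None:
        return ResponseFit("sigmoidal", {}, math.inf, math.inf, ok=False)
    params = dict(zip(("asymptote", "midpoint", "steepness"), map(float, x)))
    return ResponseFit("sigmoidal", params, rss, _aic(rss, y.size, 3), ok=True)


def classify_response(profile: TemperatureProfile) -> dict:
    """Classify a profile as biotic-like (unimodal) or abiotic-like (sigmoid).

    The lower-AIC model wins; |delta AIC| < 2 or two failed fits yield
    ``indeterminate``.  The classification is invariant to uniform
    rescaling of the activity axis (both models have a free amplitude).
    """
    uni = fit_unimodal(profile)
    sig = fit_sigmoidal(profile)
    if not uni.ok and not sig.ok:
        return {"classification": "indeterminate", "delta_aic": 0.0, "unimodal": uni, "sigmoidal": sig}
    delta = sig.aic - uni.aic  # positive favors unimodal
    if not uni.ok:
        label = "abiotic-like"
    elif not sig.ok:
        label = "biotic-like"
    elif abs(delta) < AIC_INDETERMINATE:
        label = "indeterminate"
    else:
        label = "biotic-like" if delta > 0 else "abiotic-like"
    return {"classification": label, "delta_aic": float(delta), "unimodal": uni, "sigmoidal": sig}
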