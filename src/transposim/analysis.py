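"""Fitting and regime-classification routines for trajectories and datasets.

Power laws are fitted by least squares on the log-log scale, which is
variance-stabilising under the multiplicative noise of gel and colony-count
measurements; a natural-scale nonlinear fit is available as an option.
Exponential decays are fitted on the log scale through the origin (the
bound fraction is 1 at time zero by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitResult",
    "fit_power_law",
    "fit_exp_decay",
    "fit_log_curve",
    "classify_regime",
]


@dataclass(frozen=True)
class FitResult:
    model: str  # power_law | exp_decay | log_curve | linear
    estimates: dict  # name -> (value, standard error)
    r_squared: float
    residuals: np.ndarray  # on the fitted scale
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (value, se) in self.estimates.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite estimate for {name}")


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_power_law(doses, responses, natural_scale: bool = False) -> FitResult:
    """Fit ``y = a x^b``; also fit the occlusion-constrained ``b = -1`` model.

    The default is ordinary least squares of ``ln y`` on ``ln x``.  The
    result carries the free-exponent estimates; the constrained model's
    scale, goodness of fit and a residual-trend flag (correlation of the
    constrained residuals with ``ln x``, which exposes saturating,
    non-power-law inhibition) are reported in ``flags``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dose/response pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("doses and responses must be positive (log scale)")
    lx, ly = np.log(x), np.log(y)
    (b, lna), cov = np.polyfit(lx, ly, 1, cov=True)
    resid = ly - (b * lx + lna)
    b_se, lna_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    a = math.exp(lna)
    if natural_scale:
        from scipy.optimize import curve_fit

        popt, pcov = curve_fit(
            lambda xx, aa, bb: aa * xx**bb, x, y, p0=(a, b), maxfev=10000
        )
        a, b = popt
        a_se, b_se = np.sqrt(np.diag(pcov))
        resid = y - a * x**b
        r2 = _r2(y, resid)
        estimates = {"a": (float(a), float(a_se)), "b": (float(b), float(b_se))}
        return FitResult("power_law", estimates, r2, resid, {"scale": "natural"})
    # constrained b = -1 model: ln y + ln x = ln a
    lna_c = float(np.mean(ly + lx))
    resid_c = ly - (lna_c - lx)
    trend = 0.0
    # correlation is meaningless on numerically-zero residuals
    if np.std(resid_c) > 1e-9 and np.std(lx) > 0:
        trend = float(np.corrcoef(resid_c, lx)[0, 1])
    flags = {
        "scale": "log-log",
        "constrained_a": math.exp(lna_c),
        "constrained_r_squared": _r2(ly, resid_c),
        "constrained_residual_trend": trend,
        "misspecified_constrained": abs(trend) > 0.6,
    }
    return FitResult(
        "power_law",
        {"a": (a, a * lna_se), "b": (float(b), float(b_se))},
        _r2(ly, resid),
        resid,
        flags,
    )


def fit_exp_decay(times, fractions) -> FitResult:
    """Fit ``f = exp(-k t)`` through the origin on the log scale.

    Returns the rate constant ``k`` and the corresponding half-life.
    Fractions must lie in (0, 1]; at least two distinct positive times are
    required for the slope to be identified.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if np.any(f <= 0) or np.any(f > 1.0 + 1e-9):
        raise ValueError("fractions must lie in (0, 1]")
    pos = t > 0
    if np.unique(t[pos]).size < 1 or t.size < 2:
        raise ValueError("insufficient data: need observations at positive times")
    lf = np.log(f)
    stt = float(np.sum(t * t))
    if stt == 0:
        raise ValueError("insufficient data: all observations at time zero")
    k = -float(np.sum(t * lf)) / stt
    resid = lf + k * t
    dof = max(t.size - 1, 1)
    k_se = math.sqrt(float(np.sum(resid**2)) / dof / stt)
    estimates = {
        "k": (k, k_se),
        "half_life": (math.log(2.0) / k if k > 0 else math.inf, math.nan),
    }
    return FitResult("exp_decay", estimates, _r2(lf, resid), resid)


def fit_log_curve(x, y) -> FitResult:
    """Least-squares fit of ``y = c ln(x)`` (no intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    lx = np.log(x)
    denom = float(np.sum(lx * lx))
    if denom == 0:
        raise ValueError("degenerate design: all x equal 1")
    c = float(np.sum(y * lx)) / denom
    resid = y - c * lx
    dof = max(x.size - 1, 1)
    c_se = math.sqrt(float(np.sum(resid**2)) / dof / denom)
    return FitResult("log_curve", {"c": (c, c_se)}, _r2(y, resid), resid)


def classify_regime(
    traj,
    baseline_time_to_10: float | None = None,
    lag_factor: float = 10.0,
    window: float = 0.5,
) -> str:
    """Classify an invasion trajectory.

    Returns one of ``exponential`` (copy number still compounding),
    ``linear_steady`` (occlusion-buffered constant rate), ``lagged``
    (time to 10 copies exceeds ``lag_factor`` times the supplied baseline)
    or ``negative`` (net copy loss at the end).

    The exponential/linear call compares, over the trailing window, the
    relative variation of ``dN/dt`` (constant when growth is linear) with
    that of ``d lnN / dt`` (constant when growth is exponential); both
    statistics are invariant to uniform rescaling of time and of copy
    number.  Trajectories spanning fewer than three doublings are flagged
    by raising ``ValueError``.
    """
    t, N = np.asarray(traj.times, float), np.asarray(traj.N, float)
    if N[-1] < N[0]:
        return "negative"
    if baseline_time_to_10 is not None:
        above = np.where(N >= 10.0 * N[0])[0]
        t10 = t[above[0]] if above.size else math.inf
        if t10 > lag_factor * baseline_time_to_10:
            return "lagged"
    if N[-1] < 8.0 * N[0]:
        raise ValueError(
            "trajectory spans fewer than three doublings; regime is not identified"
        )
    sel = t >= (1.0 - window) * t[-1]
    if sel.sum() < 5:
        sel = np.zeros_like(sel, dtype=bool)
        sel[-5:] = True
    tw, Nw = t[sel], N[sel]
    dN = np.gradient(Nw, tw)
    dlnN = dN / Nw
    cv_lin = float(np.std(dN) / np.mean(dN)) if np.mean(dN) > 0 else math.inf
    cv_exp = float(np.std(dlnN) / np.mean(dlnN)) if np.mean(dlnN) > 0 else math.inf
    return "exponential" if cv_exp < cv_lin else "linear_steady"
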