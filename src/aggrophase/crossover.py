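"""Two-regime crossover fits for in-vitro polymerization kinetics.

At constant concentration the weighted polymer mass grows as ``t**2`` at
short times (activation plus dimerization) and as ``t**beta`` with
``beta ~ 0.5`` at long times (polymer-polymer aggregation).  The interpolation

    m_w(t) - 1 = A * t**2 / (1 + (t / tau)**(2 - beta))

reproduces both limits and defines a crossover time ``tau`` that scales with
the dimensionless monomer density as ``tau ~ rho**-gamma``.  Rescaling
``t -> t * rho**gamma`` collapses curves at different densities onto a single
master curve.  The crossover form is a pluggable strategy: any callable
``model(t, A, tau, beta)`` returning ``m_w - 1`` can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateFitError, FitError, SupportError

__all__ = [
    "GrowthCurve",
    "CrossoverFit",
    "crossover_model",
    "fit_crossover",
    "fit_gamma",
    "master_collapse",
    "mask_plateau",
]


@dataclass
class GrowthCurve:
    """Averaged weighted-mass kinetics at one density."""

    rho: float
    times: np.ndarray
    m_w: np.ndarray
    n_replicas: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.m_w = np.asarray(self.m_w, dtype=float)
        if self.times.size != self.m_w.size:
            raise ValueError("times and m_w must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.m_w < 1.0 - 1e-9):
            raise ValueError("m_w must be >= 1")


@dataclass
class CrossoverFit:
    """Fitted crossover parameters: amplitude, crossover time, late exponent."""

    A: float
    tau: float
    beta: float
    early_exponent: float = 2.0
    stderr: dict = field(default_factory=dict)
    gof: float = float("nan")  # mean squared log-residual
    covariance: Optional[np.ndarray] = None


def crossover_model(t: np.ndarray, A: float, tau: float, beta: float) -> np.ndarray:
    """Default crossover form: t**2 early, t**beta late, switching at tau."""
    t = np.asarray(t, dtype=float)
    return A * t ** 2 / (1.0 + (t / tau) ** (2.0 - beta))


def fit_crossover(
    curve: GrowthCurve,
    model: Callable = crossover_model,
    beta0: float = 0.5,
    mask: Optional[np.ndarray] = None,
) -> CrossoverFit:
    """Weighted least squares of ``log (m_w - 1)`` against the crossover form.

    Requires data on both sides of the inflection (about a decade each);
    single-regime data raise :class:`DegenerateFitError` naming the missing
    regime.
    """
    t = curve.times
    y = curve.m_w - 1.0
    sel = (y > 0) & (t > 0)
    if mask is not None:
        sel &= mask
    t, y = t[sel], y[sel]
    if t.size < 10:
        raise FitError("need >= 10 positive samples to fit the crossover")
    logy = np.log(y)

    # quick regime check from local slopes at the two ends
    k = max(4, t.size // 5)
    s_early = stats.linregress(np.log(t[:k]), logy[:k]).slope
    s_late = stats.linregress(np.log(t[-k:]), logy[-k:]).slope
    if s_late > 1.5:
        raise DegenerateFitError(
            "data show only the early t^2 regime; the late t^beta regime is "
            "missing (tau unbounded)"
        )
    if s_early < 1.0:
        raise DegenerateFitError(
            "data show only the late t^beta regime; the early t^2 regime is "
            "missing"
        )

    tau0 = float(np.sqrt(t[0] * t[-1]))
    A0 = float(np.exp(logy[0] - 2 * np.log(t[0])))

    def resid(theta):
        logA, logtau, beta = theta
        m = model(t, np.exp(logA), np.exp(logtau), beta)
        return np.log(np.clip(m, 1e-300, None)) - logy

    res = optimize.least_squares(
        resid,
        x0=[np.log(A0), np.log(tau0), beta0],
        bounds=([-50, np.log(t[0] / 10), 1e-3], [50, np.log(t[-1] * 10), 1.999]),
    )
    if not res.success:
        raise FitError(f"crossover fit failed: {res.message}")
    logA, logtau, beta = res.x
    # covariance from the Jacobian at the optimum
    J = res.jac
    dof = max(t.size - 3, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov, se = None, np.full(3, np.nan)
    A, tau = float(np.exp(logA)), float(np.exp(logtau))
    if tau >= t[-1] * 5 or tau <= t[0] / 5:
        raise DegenerateFitError(
            "fitted crossover time lies outside the sampled range; the "
            f"{'late' if tau >= t[-1] else 'early'} regime is missing"
        )
    return CrossoverFit(
        A=A, tau=tau, beta=float(beta),
        stderr={"A": A * se[0], "tau": tau * se[1], "beta": se[2]},
        gof=float(np.mean(res.fun ** 2)),
        covariance=cov,
    )


def mask_plateau(curve: GrowthCurve, window: int = 7, slope_tol: float = 0.3,
                 recovery_tol: float = 2.5) -> np.ndarray:
    """Boolean mask excluding a latentization plateau (and its recovery).

    A plateau is a run of near-zero local log-log slope flanked by growth;
    detected by a centred rolling regression of log(m_w - 1) on log t.  The
    steep catch-up segment after the plateau (local slope above
    ``recovery_tol``, i.e. faster than the early t^2 law) is masked as well.
    Growth before and after is kept.
    """
    t, y = curve.times, curve.m_w - 1.0
    sel = (y > 0) & (t > 0)
    mask = np.array(sel)
    idx = np.where(sel)[0]
    lt, ly = np.log(t[sel]), np.log(y[sel])
    if lt.size < 2 * window + 1:
        return mask
    slopes = np.full(lt.size, np.nan)
    for i in range(window, lt.size - window):
        s = stats.linregress(lt[i - window : i + window + 1],
                             ly[i - window : i + window + 1]).slope
        slopes[i] = s
    flat = (slopes < slope_tol) | (slopes > recovery_tol)
    # only interior anomalies count (both record ends must be regular growth)
    interior = np.zeros_like(flat)
    lo, hi = window, lt.size - window - 1
    interior[lo : hi + 1] = flat[lo : hi + 1]
    mask[idx[interior]] = False
    return mask


def fit_gamma(pairs: Sequence[tuple]) -> "stats._stats_mstats_common.LinregressResult":
    """Log-log regression of crossover time on density: tau ~ rho**-gamma.

    ``pairs`` is a sequence of (rho, tau).  Returns an object with fields
    ``gamma`` and ``stderr`` (wrapped linregress).
    """
    if len(pairs) < 3:
        raise FitError("need >= 3 (rho, tau) points to fit gamma")
    rho = np.array([p[0] for p in pairs], dtype=float)
    tau = np.array([p[1] for p in pairs], dtype=float)
    span = rho.max() / rho.min()
    if span < 10.0:
        raise FitError(f"densities span a factor {span:.2f}; need >= one decade")
    reg = stats.linregress(np.log(rho), np.log(tau))

    class GammaFit:
        gamma = -float(reg.slope)
        stderr = float(reg.stderr)
        r_squared = float(reg.rvalue ** 2)
        intercept = float(reg.intercept)

    return GammaFit()


def master_collapse(
    curves: Sequence[GrowthCurve],
    gamma: float,
    n_grid: int = 100,
) -> tuple:
    """Rescale ``t -> t * rho**gamma`` and score the collapse.

    Quality is the mean squared log-distance between rescaled curves,
    evaluated on the common (overlapping) support in rescaled time.  Returns
    ``(quality, rescaled)`` where ``rescaled`` is a list of (t_rescaled, m_w)
    pairs.  Disjoint supports raise :class:`SupportError`.
    """
    if len(curves) < 2:
        raise FitError("need >= 2 curves to collapse")
    rescaled = []
    los, his = [], []
    for c in curves:
        ts = c.times * c.rho ** gamma
        sel = (c.m_w > 1.0) & (ts > 0)
        rescaled.append((ts, c.m_w))
        los.append(ts[sel][0] if sel.any() else np.inf)
        his.append(ts[sel][-1] if sel.any() else -np.inf)
    lo, hi = max(los), min(his)
    if not (hi > lo):
        raise SupportError("rescaled curves have no common support")
    grid = np.geomspace(lo, hi, n_grid)
    logs = []
    for ts, mw in rescaled:
        sel = mw > 1.0
        logs.append(np.interp(np.log(grid), np.log(ts[sel]),
                              np.log(mw[sel] - 1.0)))
    logs = np.array(logs)
    quality = float(np.mean(np.var(logs, axis=0, ddof=0)))
    return quality, rescaled
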