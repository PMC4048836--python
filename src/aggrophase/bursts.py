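"""Burst (avalanche) statistics of polymer-length signals near criticality.

Close to the growing/stationary transition the mean polymer length exhibits
intermittent, crackling-noise-like pulses.  This module extracts pulses from
a time series (threshold above a running-median baseline), histograms their
durations ``T`` and sizes ``s`` (area under the pulse), and fits all
subcritical distributions simultaneously with the scaling form

    P(T) = A * T**(-alpha) * exp(-T / T0),     T0 = t0 * (k_out - k_out*)**(-delta)

whose cutoff diverges at the transition (for sizes: exponent ``kappa`` and
cutoff exponent ``1/sigma``).  Exponents are estimated by unbinned maximum
likelihood; histograms are for display.  An optional stretched-exponential
cutoff ``exp(-(T/T0)**p)`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import BinningError, FitError, WindowError

__all__ = [
    "Burst",
    "ScalingFit",
    "extract_bursts",
    "burst_distribution",
    "joint_scaling_fit",
    "scaling_collapse",
    "sample_truncated_power_law",
]


@dataclass(frozen=True)
class Burst:
    """A single pulse: start time, duration T, size s (area above baseline)."""

    start: float
    duration: float
    size: float

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.size <= 0:
            raise ValueError("burst duration and size must be > 0")


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with edge shrinkage (odd effective window)."""
    n = x.size
    half = max(window // 2, 1)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def extract_bursts(
    times: np.ndarray,
    signal: np.ndarray,
    baseline_window_frac: float = 0.01,
    eps_mad: float = 1.0,
    window: Optional[tuple] = None,
) -> list:
    """Extract pulses where the signal exceeds baseline + eps.

    Baseline is a running median over ``baseline_window_frac`` of the record
    length; eps is ``eps_mad`` times the median absolute deviation of the
    detrended signal.  A burst spans a maximal interval with
    ``signal > baseline + eps``; its size is the trapezoidal integral of the
    excess over that interval.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times, signal = times[sel], signal[sel]
    if times.size < 3:
        raise WindowError("stationary window holds fewer than 3 samples")
    w = max(3, int(round(baseline_window_frac * times.size)))
    baseline = _running_median(signal, w)
    detrended = signal - baseline
    mad = np.median(np.abs(detrended - np.median(detrended)))
    eps = eps_mad * mad
    above = detrended > eps
    bursts: list = []
    i = 0
    n = times.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j > i:  # need at least two samples for a duration
            T = times[j] - times[i]
            s = float(np.trapezoid(detrended[i : j + 1] - eps * 0.0,
                                   times[i : j + 1]))
            if T > 0 and s > 0:
                bursts.append(Burst(start=float(times[i]), duration=float(T),
                                    size=s))
        i = j + 1
    return bursts


def burst_distribution(
    values: Sequence[float],
    n_bins: int = 20,
    min_count: int = 100,
) -> tuple:
    """Logarithmically binned probability density with Poisson errors.

    Returns ``(centres, density, density_err)``.  Raises
    :class:`BinningError` when fewer than ``min_count`` values are supplied.
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size < min_count:
        raise BinningError(
            f"{values.size} bursts provided; >= {min_count} required for "
            f"default binning"
        )
    edges = np.geomspace(values.min(), values.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    widths = np.diff(edges)
    total = values.size
    density = counts / (total * widths)
    err = np.sqrt(counts) / (total * widths)
    centres = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    return centres[keep], density[keep], err[keep]


# ---------------------------------------------------------------------------
# joint maximum-likelihood scaling fit
# ---------------------------------------------------------------------------

def _log_norm(alpha: float, T0: float, tmin: float, stretch: float = 1.0) -> float:
    """log of int_tmin^inf T^-alpha exp(-(T/T0)^stretch) dT (numeric)."""
    # substitute T = tmin * e^u to tame the power law
    def integrand(u):
        T = tmin * np.exp(u)
        decay = np.minimum((T / T0) ** stretch, 700.0)
        return np.exp((1 - alpha) * u - decay)

    val, _ = integrate.quad(integrand, 0, np.log(max(50 * T0 / tmin, 1e3)),
                            limit=200)
    return float(np.log(max(val * tmin ** (1 - alpha), 1e-300)))


@dataclass
class ScalingFit:
    """Joint scaling-fit result for burst durations or sizes."""

    which: str  # "durations" or "sizes"
    exponent: float  # alpha (durations) or kappa (sizes)
    cutoff_exponent: float  # delta or 1/sigma
    k_star: float
    t0: float
    stderr: Dict[str, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    n_events: int = 0
    excluded_k: list = field(default_factory=list)
    stretch: float = 1.0


def joint_scaling_fit(
    samples_by_k: Dict[float, np.ndarray],
    which: str = "durations",
    k_star_hint: Optional[float] = None,
    k_star_known: Optional[float] = None,
    stretch: float = 1.0,
    profile_points: int = 11,
) -> ScalingFit:
    """Simultaneous MLE of the truncated-power-law family across k_out values.

    ``samples_by_k`` maps each (subcritical) ``k_out`` to its burst durations
    or sizes.  Distributions at or below ``k_star`` (supercritical side,
    marked by system-spanning events) must be excluded by the caller or via
    ``k_star_known``; any group with ``k_out <= k_star`` is dropped with a
    record in ``excluded_k``.

    Model: P(x) ∝ x**(-a) * exp(-(x/T0(k))**stretch),
           T0(k) = t0 * (k - k_star)**(-d).
    Profile-likelihood standard errors are reported for a and d.
    """
    ks = sorted(samples_by_k)
    if len(ks) < 3:
        raise FitError("need >= 3 subcritical k_out values")
    excluded = []
    if k_star_known is not None:
        for k in list(ks):
            if k <= k_star_known:
                excluded.append(k)
                ks.remove(k)
        if len(ks) < 3:
            raise FitError("fewer than 3 groups remain above k_star")
    data = {k: np.asarray(samples_by_k[k], dtype=float) for k in ks}
    for k, v in data.items():
        if np.any(v <= 0):
            raise FitError(f"non-positive samples at k_out={k}")
    tmin = {k: float(v.min()) for k, v in data.items()}
    n_tot = sum(v.size for v in data.values())
    kmin = min(ks)

    k_gap_floor = 1e-3 * max(kmin, 1e-12)

    def nll(theta):
        a, d, logt0, ks_off = theta
        gap = np.exp(ks_off)
        k_star = kmin - gap  # k_star strictly below smallest group
        if not (0.5 < a < 4.0 and 0.05 < d < 8.0) or gap < k_gap_floor:
            return 1e12
        t0 = np.exp(logt0)
        total = 0.0
        for k in ks:
            T0 = t0 * (k - k_star) ** (-d)
            x = data[k]
            ll = (-a * np.log(x) - (x / T0) ** stretch).sum()
            ll -= x.size * _log_norm(a, T0, tmin[k], stretch)
            total -= ll
        return total / n_tot

    a0 = 1.9 if which == "durations" else 1.6
    d0 = 2.0
    spans = [float(np.percentile(v, 90)) for v in data.values()]
    logt00 = float(np.log(np.median(spans) * (max(ks) - kmin + 1e-9) ** d0 + 1e-12))
    ks_off0 = np.log(max(kmin * 0.2, 1e-4)) if k_star_hint is None else np.log(
        max(kmin - k_star_hint, 1e-8)
    )
    best = None
    for d_try in (d0, 1.0, 3.0):
        res = optimize.minimize(
            nll, x0=[a0, d_try, logt00, ks_off0], method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, d, logt0, ks_off = best.x
    k_star = kmin - np.exp(ks_off)

    # profile-likelihood errors (Delta lnL = 1/2 in natural units)
    def profile_err(index, value, width):
        grid = np.linspace(value - width, value + width, profile_points)
        lls = []
        for g in grid:
            def nll_fixed(theta):
                full = list(theta)
                full.insert(index, g)
                return nll(full)
            x0 = [v for i, v in enumerate(best.x) if i != index]
            r = optimize.minimize(nll_fixed, x0=x0, method="Nelder-Mead",
                                  options={"xatol": 1e-4, "maxiter": 1500})
            lls.append(r.fun * n_tot)
        lls = np.array(lls) - best.fun * n_tot
        # quadratic approximation around the minimum
        coef = np.polyfit(grid, lls, 2)
        if coef[0] <= 0:
            return float("nan")
        return float(1.0 / np.sqrt(2 * coef[0]))

    se_a = profile_err(0, a, max(0.1, 0.05 * a))
    se_d = profile_err(1, d, max(0.3, 0.2 * d))

    return ScalingFit(
        which=which,
        exponent=float(a),
        cutoff_exponent=float(d),
        k_star=float(k_star),
        t0=float(np.exp(logt0)),
        stderr={"exponent": se_a, "cutoff_exponent": se_d},
        log_likelihood=float(-best.fun * n_tot),
        n_events=n_tot,
        excluded_k=excluded,
        stretch=stretch,
    )


def scaling_collapse(
    samples_by_k: Dict[float, np.ndarray],
    fit: ScalingFit,
    n_bins: int = 15,
    min_count: int = 30,
) -> tuple:
    """Rescale per-k distributions onto the universal curve and score it.

    Coordinates: ``x = T * (k - k_star)**delta``, ``y = P(T) * T**alpha``.
    Quality is the mean squared log-distance between rescaled curves on the
    common support (0 for a perfect collapse).
    """
    rescaled = {}
    for k, v in samples_by_k.items():
        if k <= fit.k_star:
            continue
        c, dens, err = burst_distribution(v, n_bins=n_bins, min_count=min_count)
        x = c * (k - fit.k_star) ** fit.cutoff_exponent
        y = dens * c ** fit.exponent
        keep = y > 0
        rescaled[k] = (x[keep], y[keep])
    if len(rescaled) < 2:
        raise FitError("need >= 2 rescalable groups")
    lo = max(x[0] for x, _ in rescaled.values())
    hi = min(x[-1] for x, _ in rescaled.values())
    if not hi > lo:
        return float("inf"), rescaled
    grid = np.geomspace(lo, hi, 40)
    logs = [np.interp(np.log(grid), np.log(x), np.log(y))
            for x, y in rescaled.values()]
    quality = float(np.mean(np.var(np.array(logs), axis=0)))
    return quality, rescaled


def sample_truncated_power_law(
    rng: np.random.Generator,
    n: int,
    alpha: float,
    T0: float,
    tmin: float = 1.0,
    stretch: float = 1.0,
) -> np.ndarray:
    """Draw samples from P(x) ∝ x**-alpha exp(-(x/T0)**stretch), x >= tmin.

    Rejection sampling with a pure power-law proposal (exact)."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 for a normalizable proposal")
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 1000)
        u = rng.random(m)
        x = tmin * (1 - u) ** (-1.0 / (alpha - 1.0))
        acc = rng.random(m) < np.exp(-((x / T0) ** stretch))
        good = x[acc]
        take = min(good.size, n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out
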