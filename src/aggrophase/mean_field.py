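"""Mean-field aggregation-fragmentation kinetics with synthesis and degradation.

The model extends the Blatz-Tobolsky linear-polymerization equations with
monomer production (rate ``k_in``) and size-dependent degradation
(rate ``k_out * f(i)`` with ``f(i) = i**-3`` for ``i <= c``, else 0).
Populations ``n_i`` of polymers of size ``i`` obey, with a constant
(size-independent) end-joining kernel,

    dn_i/dt = (k_p/2) * sum_{j=1}^{i-1} n_j n_{i-j}  -  k_p n_i M0
              - k_f (i-1) n_i  +  2 k_f sum_{j>i} n_j
              + k_in delta_{i,1}  -  k_out f(i) n_i

where ``M0 = sum_i n_i``.  This factor convention is the one under which the
``c = 1`` steady state satisfies

    (k_in k_p) / (2 k_out k_f) + (k_in / k_out) / M0 = 1

exactly, which serves as the module's self-consistency check.

Two control-parameter regimes exist: for ``k_out`` below a critical value
``k_out*`` the mean polymer length grows without bound as ``m_p ~ C t**0.5``;
above it the system reaches a finite stationary state.  The prefactor
vanishes at the transition as ``C ~ (k_out* - k_out)**theta`` with
``theta = 1/2``.

An optional activation/latentization layer splits free monomers into
inactive, active and latent sub-species.  Only *active* monomers participate
in bond formation (inactive and latent monomers are inert); polymers of size
``i >= 2`` aggregate freely among themselves.  This reproduces the early
``m_w - 1 ~ t**3`` regime of the activation model (dimer flux proportional
to the square of the active-monomer population) followed by the late linear
regime of constant-kernel aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import fftconvolve
from scipy import stats

from .errors import (
    BracketingError,
    FitError,
    IntegrationError,
    InvalidStateError,
    PreconditionError,
    TruncationLeakWarning,
)

__all__ = [
    "MeanFieldParams",
    "SizeDistribution",
    "MeanFieldTrajectory",
    "PhasePoint",
    "FitResult",
    "mf_rhs",
    "integrate_mf",
    "mean_polymer_length",
    "weighted_mass",
    "classify_phase",
    "fit_growth_prefactor",
    "find_critical_kout",
    "fit_prefactor_exponent",
    "phase_diagram_scan",
    "steady_state_relation_residual",
    "degradation_weights",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanFieldParams:
    """Kinetic rates of the mean-field model.

    Parameters
    ----------
    k_in : float
        Monomer production rate (concentration / time).
    k_out : float
        Degradation rate scale (1 / time); acts as ``k_out * i**-3`` on
        sizes ``i <= c``.
    k_p : float
        Aggregation (end-joining) rate (1 / (concentration * time)).
    k_f : float
        Fragmentation rate per internal bond (1 / time).
    k_A : float
        Monomer activation rate (1 / time); 0 disables the activation layer.
    k_L : float
        Latentization rate of active monomers (1 / time); 0 disables.
    c : int
        Degradation size cutoff; ``f(i) = i**-3`` for ``i <= c``, 0 beyond.
    i_max : int
        Truncation size for direct integration.
    """

    k_in: float = 0.0
    k_out: float = 0.0
    k_p: float = 1.0
    k_f: float = 0.0
    k_A: float = 0.0
    k_L: float = 0.0
    c: int = 5
    i_max: int = 512

    def __post_init__(self) -> None:
        for name in ("k_in", "k_out", "k_p", "k_f", "k_A", "k_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.i_max < 2 or self.i_max < self.c:
            raise ValueError("i_max must be >= 2 and >= c")

    @property
    def has_subspecies(self) -> bool:
        return self.k_A > 0 or self.k_L > 0


def degradation_weights(params: MeanFieldParams) -> np.ndarray:
    """Vector f(i) = i**-3 for i <= c else 0, indexed i = 1..i_max."""
    i = np.arange(1, params.i_max + 1, dtype=float)
    f = np.where(i <= params.c, i ** -3.0, 0.0)
    return f


@dataclass
class SizeDistribution:
    """Populations ``n_i`` for ``i = 1..i_max`` plus optional monomer sub-species.

    ``n[0]`` is the total monomer population.  When the activation layer is
    active, ``inactive + active + latent`` must equal ``n[0]``.
    """

    n: np.ndarray
    inactive: Optional[float] = None
    active: Optional[float] = None
    latent: Optional[float] = None
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 1 or self.n.size < 2:
            raise InvalidStateError("n must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.n)):
            raise InvalidStateError("non-finite populations in size distribution")
        if np.any(self.n < -1e-12 * max(1.0, float(np.max(np.abs(self.n))))):
            raise InvalidStateError("negative populations in size distribution")
        subs = [self.inactive, self.active, self.latent]
        if any(s is not None for s in subs):
            tot = sum(0.0 if s is None else float(s) for s in subs)
            if abs(tot - self.n[0]) > 1e-9 * max(1.0, abs(self.n[0])):
                raise InvalidStateError(
                    "monomer sub-species do not sum to the monomer population"
                )

    # --- moments ---------------------------------------------------------
    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.n.size + 1, dtype=float)

    @property
    def M0(self) -> float:
        return float(self.n.sum())

    @property
    def M1(self) -> float:
        return float(np.dot(self.sizes, self.n))

    @property
    def M2(self) -> float:
        return float(np.dot(self.sizes ** 2, self.n))

    @classmethod
    def empty(cls, i_max: int, t: float = 0.0) -> "SizeDistribution":
        return cls(n=np.zeros(i_max), t=t)

    @classmethod
    def monomers(
        cls,
        amount: float,
        i_max: int,
        species: Literal["plain", "inactive", "active"] = "plain",
        t: float = 0.0,
    ) -> "SizeDistribution":
        n = np.zeros(i_max)
        n[0] = amount
        if species == "plain":
            return cls(n=n, t=t)
        if species == "inactive":
            return cls(n=n, inactive=amount, active=0.0, latent=0.0, t=t)
        return cls(n=n, inactive=0.0, active=amount, latent=0.0, t=t)


def weighted_mass(state: SizeDistribution) -> float:
    """Weighted polymer mass ``m_w = M2 / M1`` (light-scattering mean size).

    Returns NaN (undefined-observable signal) when ``M1 = 0``.
    """
    m1 = state.M1
    if m1 <= 0:
        return float("nan")
    return state.M2 / m1


def mean_polymer_length(state: SizeDistribution) -> float:
    """Mean length of polymers of size >= 2, ``m_p = (M1 - n1)/(M0 - n1)``.

    Monomers are excluded.  Returns NaN (undefined-observable signal) when
    there are no polymers of size >= 2.
    """
    n1 = float(state.n[0])
    denom = state.M0 - n1
    if denom <= 0:
        return float("nan")
    return (state.M1 - n1) / denom


@dataclass
class MeanFieldTrajectory:
    """Sampled summaries of an integration: moments and observables."""

    times: np.ndarray
    M0: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    n1: np.ndarray
    m_w: np.ndarray
    m_p: np.ndarray
    params: MeanFieldParams
    final_state: SizeDistribution
    leak_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise InvalidStateError("trajectory times must be strictly increasing")


@dataclass
class FitResult:
    """Fitted parameters with standard errors and diagnostics."""

    params: dict
    stderr: dict
    r_squared: float
    n_points: int
    extra: dict = field(default_factory=dict)


@dataclass
class PhasePoint:
    """Phase classification at one parameter point."""

    params: MeanFieldParams
    phase: Literal["growing", "stationary", "undecided"]
    C: Optional[float] = None
    beta: Optional[float] = None
    steady_m_p: Optional[float] = None
    note: str = ""


# ---------------------------------------------------------------------------
# right-hand side and Jacobian
# ---------------------------------------------------------------------------

def _agg_partner_sum(n: np.ndarray) -> np.ndarray:
    """S(i_max - i) = sum_{j <= i_max - i} n_j, the mass-conserving
    (reflecting) truncation: aggregation events whose product would exceed
    i_max are simply not allowed, so no mass leaves through the boundary."""
    cs = np.cumsum(n)  # cs[m-1] = S(m)
    out = np.zeros_like(n)
    imax = n.size
    # partner sum for y-index a (size a+1): S(imax - (a+1)) = cs[imax-a-2]
    out[: imax - 1] = cs[imax - 2 :: -1][: imax - 1]
    return out


def _rhs_plain(n: np.ndarray, p: MeanFieldParams, fvec: np.ndarray) -> np.ndarray:
    imax = n.size
    dy = np.zeros_like(n)
    if p.k_p > 0:
        conv = fftconvolve(n, n)[: imax]
        # conv[k] = sum_{a+b=k} n[a] n[b]; size i gain uses pairs j+(i-j)=i,
        # y-index i-1 <- conv index i-2.
        dy[1:] += 0.5 * p.k_p * conv[: imax - 1]
        dy -= p.k_p * _agg_partner_sum(n) * n
    if p.k_f > 0:
        bonds = np.arange(0, imax, dtype=float)  # i-1 internal bonds
        dy -= p.k_f * bonds * n
        suffix = np.cumsum(n[::-1])[::-1]  # sum_{j>=i}
        dy += 2.0 * p.k_f * (suffix - n)
    dy[0] += p.k_in
    if p.k_out > 0:
        dy -= p.k_out * fvec * n
    return dy


def _jac_plain(n: np.ndarray, p: MeanFieldParams, fvec: np.ndarray) -> np.ndarray:
    imax = n.size
    J = np.zeros((imax, imax))
    if p.k_p > 0:
        # d(gain_i)/d n_k = k_p * n_{i-k} (y-indices: J[i,k] = k_p*n[i-k-1], i>k)
        col = np.concatenate(([0.0], n[: imax - 1]))
        idx = np.arange(imax)
        diff = idx[:, None] - idx[None, :]
        J += p.k_p * np.where(diff >= 1, col[np.clip(diff, 0, imax - 1)], 0.0)
        # loss_a = k_p n_a S(imax - a - 1 classes); d/dn_b = k_p (delta S + n_a [a+b <= imax-2])
        S = _agg_partner_sum(n)
        mask = (idx[:, None] + idx[None, :]) <= (imax - 2)
        J -= p.k_p * (np.diag(S) + np.outer(n, np.ones(imax)) * mask)
    if p.k_f > 0:
        bonds = np.arange(0, imax, dtype=float)
        J -= p.k_f * np.diag(bonds)
        J += 2.0 * p.k_f * np.triu(np.ones((imax, imax)), k=1)
    if p.k_out > 0:
        J -= p.k_out * np.diag(fvec)
    return J


def _rhs_sub(y: np.ndarray, p: MeanFieldParams, fvec: np.ndarray) -> np.ndarray:
    """RHS with monomer sub-species: y = [aI, aA, aL, n_2 .. n_imax].

    Only active monomers form bonds; polymers (i >= 2) aggregate freely.
    Size-1 fragmentation products re-enter the active pool (they carry the
    activated conformation that let them bond).
    """
    imax = p.i_max
    aI, aA, aL = y[0], y[1], y[2]
    npoly = y[3:]
    # effective aggregating vector v[0] = active monomers, v[i-1] = n_i
    v = np.empty(imax)
    v[0] = aA
    v[1:] = npoly
    dv = np.zeros(imax)
    if p.k_p > 0:
        conv = fftconvolve(v, v)[: imax]
        dv[1:] += 0.5 * p.k_p * conv[: imax - 1]
        dv -= p.k_p * _agg_partner_sum(v) * v
    if p.k_f > 0:
        bonds = np.arange(0, imax, dtype=float)
        dv -= p.k_f * bonds * v
        suffix = np.cumsum(v[::-1])[::-1]
        dv += 2.0 * p.k_f * (suffix - v)
        # fragmentation never produces inactive/latent monomers; gains to
        # index 0 stay in the active pool, consistent with v[0] = aA.
    if p.k_out > 0:
        dv -= p.k_out * fvec * v
        # degrade inactive and latent monomers at the same f(1) rate
    dy = np.zeros_like(y)
    dy[0] = -p.k_A * aI - (p.k_out * fvec[0] * aI if p.k_out > 0 else 0.0)
    dy[1] = p.k_A * aI - p.k_L * aA + dv[0]
    dy[2] = p.k_L * aA - (p.k_out * fvec[0] * aL if p.k_out > 0 else 0.0)
    dy[3:] = dv[1:]
    dy[0] += p.k_in  # produced monomers are inactive when activation is on
    return dy


def mf_rhs(state: SizeDistribution, params: MeanFieldParams) -> SizeDistribution:
    """Time derivative of a size distribution under the mean-field equations.

    Returns a ``SizeDistribution`` whose fields hold derivatives (they may be
    negative; invariant checks are bypassed).
    """
    if state.n.size != params.i_max:
        raise InvalidStateError(
            f"state truncated at {state.n.size}, params.i_max = {params.i_max}"
        )
    fvec = degradation_weights(params)
    if params.has_subspecies:
        aI = state.inactive if state.inactive is not None else 0.0
        aA = state.active if state.active is not None else state.n[0]
        aL = state.latent if state.latent is not None else 0.0
        y = np.concatenate(([aI, aA, aL], state.n[1:]))
        dy = _rhs_sub(y, params, fvec)
        dn = np.concatenate(([dy[0] + dy[1] + dy[2]], dy[3:]))
        out = SizeDistribution.__new__(SizeDistribution)
        out.n, out.inactive, out.active, out.latent, out.t = (
            dn, dy[0], dy[1], dy[2], state.t,
        )
        return out
    dn = _rhs_plain(state.n, params, fvec)
    out = SizeDistribution.__new__(SizeDistribution)
    out.n, out.inactive, out.active, out.latent, out.t = dn, None, None, None, state.t
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_mf(
    params: MeanFieldParams,
    init: SizeDistribution,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    leak_threshold: float = 1e-3,
    leak_tail: Optional[int] = None,
) -> MeanFieldTrajectory:
    """Integrate the mean-field equations and sample moments on ``t_grid``.

    Uses a stiff-capable adaptive solver with an analytic Jacobian (plain
    model).  Truncation is mass-conserving (aggregation past ``i_max`` is
    forbidden); the monitor tracks the mass residing in the top ``leak_tail``
    size classes (default: top 10% of classes) and warns when it exceeds
    ``leak_threshold`` of M1, signalling that the ceiling is distorting the
    distribution and a larger ``i_max`` is needed.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise PreconditionError("t_grid must be increasing with >= 2 points")
    if leak_tail is None:
        leak_tail = max(5, params.i_max // 10)
    fvec = degradation_weights(params)

    if params.has_subspecies:
        aI = init.inactive if init.inactive is not None else (
            init.n[0] if params.k_A > 0 else 0.0
        )
        aA = init.active if init.active is not None else (
            0.0 if params.k_A > 0 else init.n[0]
        )
        aL = init.latent if init.latent is not None else 0.0
        y0 = np.concatenate(([aI, aA, aL], init.n[1:]))
        rhs = lambda t, y: _rhs_sub(y, params, fvec)
        jac = None
    else:
        y0 = init.n.copy()
        rhs = lambda t, y: _rhs_plain(y, params, fvec)
        jac = lambda t, y: _jac_plain(y, params, fvec)

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    kwargs = dict(method=method, t_eval=t_grid, rtol=rtol, atol=atol)
    if jac is not None and method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = jac
    sol = solve_ivp(rhs, (t0, t1), y0, **kwargs)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    sizes = np.arange(1, params.i_max + 1, dtype=float)
    if params.has_subspecies:
        mono = sol.y[0] + sol.y[1] + sol.y[2]
        npoly = sol.y[3:]
        M0 = mono + npoly.sum(axis=0)
        M1 = mono + sizes[1:] @ npoly
        M2 = mono + (sizes[1:] ** 2) @ npoly
        n1 = mono
        tail_mass = (sizes[-leak_tail:] @ npoly[-leak_tail:]) if leak_tail else 0.0
        yF = sol.y[:, -1]
        nF = np.concatenate(([yF[0] + yF[1] + yF[2]], yF[3:]))
        final = SizeDistribution(
            n=np.clip(nF, 0.0, None),
            inactive=max(yF[0], 0.0), active=max(yF[1], 0.0),
            latent=max(yF[2], 0.0), t=t1,
        )
    else:
        n = sol.y
        M0 = n.sum(axis=0)
        M1 = sizes @ n
        M2 = (sizes ** 2) @ n
        n1 = n[0]
        tail_mass = sizes[-leak_tail:] @ n[-leak_tail:]
        final = SizeDistribution(n=np.clip(n[:, -1], 0.0, None), t=t1)

    with np.errstate(divide="ignore", invalid="ignore"):
        m_w = np.where(M1 > 0, M2 / np.where(M1 > 0, M1, 1.0), np.nan)
        denom = M0 - n1
        m_p = np.where(denom > 0, (M1 - n1) / np.where(denom > 0, denom, 1.0), np.nan)

    leak = float(np.max(np.where(M1 > 0, np.atleast_1d(tail_mass) / np.where(M1 > 0, M1, 1.0), 0.0)))
    if leak > leak_threshold:
        warnings.warn(
            f"truncation leak {leak:.2%} of M1 exceeds {leak_threshold:.2%}; "
            f"consider i_max >= {2 * params.i_max}",
            TruncationLeakWarning,
        )
    return MeanFieldTrajectory(
        times=t_grid, M0=M0, M1=M1, M2=M2, n1=n1, m_w=m_w, m_p=m_p,
        params=params, final_state=final, leak_fraction=leak,
    )


def log_time_grid(t0: float, t1: float, n: int = 200) -> np.ndarray:
    """Logarithmic sampling grid starting at t=0 with log-spaced interior."""
    g = np.geomspace(t0, t1, n)
    return np.concatenate(([0.0], g)) if t0 > 0 else g


# ---------------------------------------------------------------------------
# phase analysis
# ---------------------------------------------------------------------------

def _final_decade(traj: MeanFieldTrajectory):
    t = traj.times
    mask = t >= t[-1] / 10.0
    mask &= t > 0
    return t[mask], traj.m_p[mask]


def classify_phase(
    traj: MeanFieldTrajectory,
    tol: float = 0.05,
    slope_stationary: float = 0.1,
    slope_growing: tuple = (0.25, 0.75),
) -> PhasePoint:
    """Classify a trajectory as growing, stationary or undecided.

    Stationary: relative change of ``m_p`` over the final decade of time is
    below ``tol`` and the local log-log slope is below ``slope_stationary``
    (a t**0.5 growth changes by a factor 10**0.5 per decade, so the regimes
    are well separated).  Growing: the final-decade log-log slope lies in
    ``slope_growing`` and ``m_p`` is still increasing; a slope above the
    window with more than a tenfold rise over the decade is also growing
    (pre-asymptotic escape), flagged in the note.  Anything else is
    explicitly undecided — never silently coerced.
    """
    t, mp = _final_decade(traj)
    valid = np.isfinite(mp) & (mp > 0)
    t, mp = t[valid], mp[valid]
    if t.size < 10:
        raise PreconditionError("final decade must contain >= 10 samples")
    rel_change = abs(mp[-1] - mp[0]) / max(abs(mp[-1]), 1e-300)
    fit = stats.linregress(np.log(t), np.log(mp))
    slope = fit.slope
    if rel_change < tol and abs(slope) < slope_stationary:
        return PhasePoint(params=traj.params, phase="stationary",
                          steady_m_p=float(mp[-1]))
    if mp[-1] > mp[0]:
        C = float(np.exp(fit.intercept))
        if slope_growing[0] <= slope <= slope_growing[1]:
            return PhasePoint(params=traj.params, phase="growing",
                              C=C, beta=float(slope))
        if slope > slope_growing[1] and mp[-1] / mp[0] > 10.0:
            return PhasePoint(params=traj.params, phase="growing",
                              C=C, beta=float(slope),
                              note="pre-asymptotic escape (steep slope)")
    return PhasePoint(
        params=traj.params, phase="undecided",
        note=f"slope={slope:.3f}, rel_change={rel_change:.3g}; extend the run",
    )


def fit_growth_prefactor(
    traj: MeanFieldTrajectory,
    window: tuple,
    fix_beta: Optional[float] = None,
) -> FitResult:
    """Least-squares fit of ``log m_p = log C + beta log t`` over ``window``.

    With ``fix_beta`` the amplitude alone is fitted at the imposed exponent
    (used for the prefactor-scaling analysis where beta = 0.5 is imposed).
    """
    t = traj.times
    mask = (t >= window[0]) & (t <= window[1]) & np.isfinite(traj.m_p) & (traj.m_p > 0) & (t > 0)
    if mask.sum() < 10:
        raise FitError(f"fit window contains {int(mask.sum())} points, need >= 10")
    lt, lm = np.log(t[mask]), np.log(traj.m_p[mask])
    n = lt.size
    if fix_beta is not None:
        resid = lm - fix_beta * lt
        logC = float(np.mean(resid))
        se = float(np.std(resid, ddof=1) / np.sqrt(n))
        ss_res = float(np.sum((resid - logC) ** 2))
        ss_tot = float(np.sum((lm - lm.mean()) ** 2))
        return FitResult(
            params={"C": float(np.exp(logC)), "beta": fix_beta},
            stderr={"C": float(np.exp(logC)) * se, "beta": 0.0},
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            n_points=n,
        )
    fit = stats.linregress(lt, lm)
    C = float(np.exp(fit.intercept))
    return FitResult(
        params={"C": C, "beta": float(fit.slope)},
        stderr={"C": C * float(fit.intercept_stderr), "beta": float(fit.stderr)},
        r_squared=float(fit.rvalue ** 2),
        n_points=n,
    )


def _run_and_classify(params: MeanFieldParams, t_max: float, n_samples: int = 120,
                      tol: float = 0.05) -> PhasePoint:
    init = SizeDistribution.empty(params.i_max)
    t0 = min(1.0, t_max / 1e4)
    traj = integrate_mf(params, init, log_time_grid(t0, t_max, n_samples),
                        leak_threshold=np.inf)
    return classify_phase(traj, tol=tol)


def find_critical_kout(
    params: MeanFieldParams,
    bracket: tuple,
    t_max: float,
    rel_width: float = 0.01,
    t_cap_factor: int = 8,
) -> tuple:
    """Bisect ``k_out`` between a growing and a stationary endpoint.

    Returns ``(k_star, uncertainty)``.  Undecided midpoints trigger doubling
    of the integration horizon up to ``t_cap_factor * t_max``; if still
    undecided the bracket is not narrowed at that midpoint and the reported
    uncertainty reflects the residual interval.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if params.k_in == 0:
        return 0.0, 0.0

    def classify_with_doubling(k):
        tm = t_max
        point = _run_and_classify(replace(params, k_out=k), tm)
        while point.phase == "undecided" and tm < t_cap_factor * t_max:
            tm *= 2
            point = _run_and_classify(replace(params, k_out=k), tm)
        return point.phase

    ph_lo = classify_with_doubling(lo)
    ph_hi = classify_with_doubling(hi)
    if ph_lo == ph_hi or "undecided" in (ph_lo, ph_hi):
        raise BracketingError(
            f"bracket endpoints classify as {ph_lo}/{ph_hi}"
        )
    if ph_lo != "growing":
        lo, hi = hi, lo  # ensure lo growing, hi stationary

    while abs(hi - lo) > rel_width * abs(hi + lo) / 2:
        mid = 0.5 * (lo + hi)
        phase = classify_with_doubling(mid)
        if phase == "growing":
            lo = mid
        elif phase == "stationary":
            hi = mid
        else:
            # undecidable at the cap: the point sits in the near-critical
            # zone.  Narrow from both sides and report the zone half-width
            # as the uncertainty.
            glo, ghi = lo, mid
            while abs(ghi - glo) > rel_width * abs(ghi + glo) / 2:
                m = 0.5 * (glo + ghi)
                if classify_with_doubling(m) == "growing":
                    glo = m
                else:
                    ghi = m
            slo, shi = mid, hi
            while abs(shi - slo) > rel_width * abs(shi + slo) / 2:
                m = 0.5 * (slo + shi)
                if classify_with_doubling(m) == "stationary":
                    shi = m
                else:
                    slo = m
            return 0.5 * (glo + shi), 0.5 * abs(shi - glo)
    k_star = 0.5 * (lo + hi)
    return k_star, 0.5 * abs(hi - lo)


def fit_prefactor_exponent(
    params: MeanFieldParams,
    k_star: float,
    k_out_values: Sequence[float],
    t_max: float,
    beta: float = 0.5,
    n_samples: int = 150,
) -> FitResult:
    """Fit ``C ~ (k_out* - k_out)**theta`` from subcritical growth runs.

    For each subcritical ``k_out``, integrates from empty, fits the growth
    prefactor at imposed ``beta`` over the final decade, then regresses
    ``log C`` on ``log (k_star - k_out)``.
    """
    Cs, dks = [], []
    for ko in k_out_values:
        if ko >= k_star:
            continue
        p = replace(params, k_out=float(ko))
        init = SizeDistribution.empty(p.i_max)
        traj = integrate_mf(p, init, log_time_grid(min(1.0, t_max / 1e4), t_max,
                                                   n_samples),
                            leak_threshold=np.inf)
        fit = fit_growth_prefactor(traj, (t_max / 10, t_max), fix_beta=beta)
        Cs.append(fit.params["C"])
        dks.append(k_star - ko)
    if len(Cs) < 3:
        raise FitError("need >= 3 subcritical k_out values")
    reg = stats.linregress(np.log(dks), np.log(Cs))
    return FitResult(
        params={"theta": float(reg.slope), "C_values": Cs, "dk_values": dks},
        stderr={"theta": float(reg.stderr)},
        r_squared=float(reg.rvalue ** 2),
        n_points=len(Cs),
    )


def phase_diagram_scan(
    grid: Sequence[MeanFieldParams],
    t_max: float,
    tol: float = 0.05,
) -> list:
    """Classify each parameter point of a finite grid; one PhasePoint each."""
    return [_run_and_classify(p, t_max, tol=tol) for p in grid]


def steady_state_relation_residual(
    params: MeanFieldParams,
    steady: SizeDistribution,
    drift: Optional[float] = None,
    drift_tol: float = 1e-6,
) -> float:
    """LHS of the c=1 steady-state identity; equals 1 at a true steady state.

    LHS = (k_in k_p)/(2 k_out k_f) + (k_in/k_out)/M0.  Raises on c != 1, on
    an empty state (k_in = 0), or when a drift estimate above tolerance is
    supplied.
    """
    if params.c != 1:
        raise PreconditionError("identity applies only for c = 1")
    if drift is not None and drift > drift_tol:
        raise PreconditionError(f"state drifting at {drift:.3g} per unit time")
    M0 = steady.M0
    if M0 <= 0 or params.k_in == 0:
        raise PreconditionError("relation inapplicable: empty steady state")
    if params.k_out == 0 or params.k_f == 0:
        raise PreconditionError("relation requires k_out > 0 and k_f > 0")
    return (params.k_in * params.k_p) / (2 * params.k_out * params.k_f) + (
        params.k_in / params.k_out
    ) / M0


def run_to_steady_mf(
    params: MeanFieldParams,
    duration: float,
    init: Optional[SizeDistribution] = None,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> tuple:
    """Integrate to (near) steady state; returns (state, drift_per_time).

    Drift is the max relative rate of change of (M0, M1) at the final time.
    """
    if init is None:
        init = SizeDistribution.empty(params.i_max)
    grid = np.array([0.0, duration / 2, duration])
    traj = integrate_mf(params, init, grid, rtol=rtol, atol=atol,
                        leak_threshold=np.inf)
    state = traj.final_state
    d = mf_rhs(state, params)
    sizes = state.sizes
    dM0 = abs(float(d.n.sum()))
    dM1 = abs(float(np.dot(sizes, d.n)))
    drift = max(dM0 / max(state.M0, 1e-300), dM1 / max(state.M1, 1e-300))
    return state, drift
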