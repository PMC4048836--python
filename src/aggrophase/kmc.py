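"""High-level lattice KMC runs: trajectories, replicas, effective rates.

Wraps the production engine (:mod:`aggrophase.engine`) behind trajectory
objects, seeds replicas deterministically, and implements the
effective-parameter estimators used to map the 3D model onto mean-field
language: the effective degradation rate (efflux mass flux per unit resident
mass, which is boundary-limited and therefore falls with slab width H) and
the effective polymerization rate (joining-event flux converted to the
constant-kernel rate that would produce it in mean field, which peaks at the
phase transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import OBS_COLS, FastKmc
from .errors import PreconditionError
from .lattice import (
    INACTIVE,
    KmcParams,
    LatticeGeometry,
    LatticeState,
    init_random_monomers,
)

__all__ = [
    "KmcTrajectory",
    "run_kmc",
    "run_invitro_replicas",
    "average_m_w",
    "effective_degradation_rate",
    "effective_polymerization_rate",
]


@dataclass
class KmcTrajectory:
    """Sampled observables of one lattice KMC run."""

    times: np.ndarray
    m_w: np.ndarray
    m_p: np.ndarray
    n_objects: np.ndarray
    n_polymers: np.ndarray
    mass: np.ndarray
    cum_influx: np.ndarray
    cum_efflux: np.ndarray
    cum_joins: np.ndarray
    params: KmcParams
    geometry: LatticeGeometry
    seed: int

    @classmethod
    def from_obs(cls, obs: np.ndarray, params: KmcParams,
                 geometry: LatticeGeometry, seed: int) -> "KmcTrajectory":
        cols = {name: obs[:, i] for i, name in enumerate(OBS_COLS)}
        return cls(times=cols["t"], m_w=cols["m_w"], m_p=cols["m_p"],
                   n_objects=cols["n_objects"], n_polymers=cols["n_polymers"],
                   mass=cols["mass"], cum_influx=cols["cum_influx"],
                   cum_efflux=cols["cum_efflux"], cum_joins=cols["cum_joins"],
                   params=params, geometry=geometry, seed=seed)


def run_kmc(
    state: LatticeState,
    params: KmcParams,
    t_max: float,
    sample_times: Sequence[float],
    seed: int = 0,
    return_engine: bool = False,
):
    """Run the production engine from ``state`` and sample observables.

    ``sample_times`` must lie within [0, t_max].  In fully periodic mode with
    ``k_in = k_out = 0`` the total mass is exactly conserved; in slab mode
    the balance resident = initial + influx - efflux holds exactly.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size and (sample_times[0] < 0 or sample_times[-1] > t_max):
        raise PreconditionError("sample_times must lie within [0, t_max]")
    eng = FastKmc.from_state(state, params)
    obs = eng.run(t_max, sample_times, seed=seed)
    traj = KmcTrajectory.from_obs(obs, params, state.geometry, seed)
    if return_engine:
        return traj, eng
    return traj


def run_invitro_replicas(
    L: int,
    rho: float,
    params: KmcParams,
    t_max: float,
    sample_times: Sequence[float],
    n_replicas: int,
    seed: int = 0,
) -> list:
    """Replica runs from statistically identical random initial conditions.

    Replica seeds are derived deterministically from ``seed``; placements and
    event sequences differ between replicas, the protocol does not.
    """
    geom = LatticeGeometry(L, L, L, "periodic")
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicas)
    for i, child in enumerate(children):
        s1, s2 = child.generate_state(2) % (2 ** 31 - 1)
        st = init_random_monomers(geom, rho=rho, seed=int(s1), state=INACTIVE)
        out.append(run_kmc(st, params, t_max, sample_times, seed=int(s2)))
    return out


def average_m_w(trajs: Sequence[KmcTrajectory]) -> tuple:
    """Replica-averaged weighted mass on the common sampling grid."""
    times = trajs[0].times
    mw = np.nanmean(np.stack([tr.m_w for tr in trajs]), axis=0)
    return times, mw


def _steady_window(traj: KmcTrajectory, window: Optional[tuple]):
    t = traj.times
    if window is None:
        window = (t[-1] / 2, t[-1])
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 2:
        raise PreconditionError("measurement window holds fewer than 2 samples")
    return sel


def effective_degradation_rate(
    traj: KmcTrajectory,
    window: Optional[tuple] = None,
    drift_tol: float = 0.2,
) -> float:
    """Efflux mass flux per unit resident mass over a steady window (1/time).

    Requires the resident mass to be statistically stationary over the
    window (relative drift below ``drift_tol``); growing-phase trajectories
    raise :class:`PreconditionError`.
    """
    sel = _steady_window(traj, window)
    t = traj.times[sel]
    mass = traj.mass[sel]
    mean_mass = float(mass.mean())
    if mean_mass <= 0:
        raise PreconditionError("window contains no resident mass")
    drift = abs(mass[-1] - mass[0]) / max(mean_mass, 1e-300)
    if drift > drift_tol:
        raise PreconditionError(
            f"resident mass drifts by {drift:.2f} over the window; "
            "not a statistical steady state"
        )
    efflux = traj.cum_efflux[sel]
    rate = (efflux[-1] - efflux[0]) / (t[-1] - t[0])
    return float(rate / mean_mass)


def effective_polymerization_rate(
    traj: KmcTrajectory,
    window: Optional[tuple] = None,
) -> float:
    """Constant-kernel aggregation rate reproducing the joining-event flux.

    ``k_p_eff = (joins per unit time) * V / <N>**2`` with N the number of
    aggregating objects; returns NaN (undefined signal) when the window
    contains no objects.
    """
    sel = _steady_window(traj, window)
    t = traj.times[sel]
    joins = traj.cum_joins[sel]
    n_obj = traj.n_objects[sel]
    mean_n = float(n_obj.mean())
    if mean_n <= 0:
        return float("nan")
    V = traj.geometry.n_sites
    rate = (joins[-1] - joins[0]) / (t[-1] - t[0])
    return float(rate * V / mean_n ** 2)
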