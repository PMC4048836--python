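"""Production engine vs reference implementation and exact CTMC oracle."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2 as chi2_dist

from aggrophase.engine import FastKmc
from aggrophase.kmc import run_kmc
from aggrophase.lattice import (
    ACTIVE,
    INACTIVE,
    LATENT,
    KmcParams,
    LatticeGeometry,
    LatticeState,
    Polymer,
    init_random_monomers,
    invitro_params,
)


def two_monomer_state(sites, states=(ACTIVE, ACTIVE), L=3):
    st = LatticeState(geometry=LatticeGeometry(L, L, L, "periodic"))
    for s, a in zip(sites, states):
        st.add_polymer(Polymer(sites=[s], states=[a]))
    return st


# --------------------------------------------------------------- exact CTMC
def _sites3():
    return list(itertools.product(range(3), repeat=3))


def _adjacent(a, b):
    d = [(a[k] - b[k]) % 3 for k in range(3)]
    d = [min(x, 3 - x) for x in d]
    return sorted(d) == [0, 0, 1]


def _neighbours(s):
    out = []
    for k in range(3):
        for step in (1, -1):
            t = list(s)
            t[k] = (t[k] + step) % 3
            out.append(tuple(t))
    return out


def test_engine_matches_matrix_exponential_ctmc():
    """Two active monomers, diffusion + joining on a 3x3x3 torus: the
    engine's dimerization probability at a fixed horizon matches the exact
    matrix-exponential solution of the full 432-state CTMC."""
    kD, kH, T = 1.0, 1.0, 0.8
    sites = _sites3()
    idx = {}
    states = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            idx[frozenset((a, b))] = len(states)
            states.append(("free", frozenset((a, b))))
    n_free = len(states)
    bonded_start = n_free
    bonded = [fs for fs in
              (frozenset((a, b)) for i, a in enumerate(sites)
               for b in sites[i + 1 :]) if _adjacent(*tuple(fs))]
    bidx = {fs: bonded_start + i for i, fs in enumerate(bonded)}
    N = n_free + len(bonded)
    Q = np.zeros((N, N))
    for fs, i in idx.items():
        a, b = tuple(fs)
        for mono, other in ((a, b), (b, a)):
            for t in _neighbours(mono):
                if t == other:
                    continue
                j = idx[frozenset((t, other))]
                Q[i, j] += kD
        if _adjacent(a, b):
            Q[i, bidx[fs]] += kH
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    start = ((0, 0, 0), (1, 1, 1))
    p0 = np.zeros(N)
    p0[idx[frozenset(start)]] = 1.0
    pT = p0 @ expm(Q * T)
    p_dimer_exact = pT[bonded_start:].sum()

    params = KmcParams(k_D=kD, k_H=kH, k_A=0.0, k_E=0, k_R=0, k_K=0)
    n_rep = 10_000
    n_dimer = 0
    ss = np.random.SeedSequence(321)
    for child in ss.spawn(n_rep):
        st = two_monomer_state(list(start))
        eng = FastKmc.from_state(st, params)
        obs = eng.run(T, np.array([T]), seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        n_dimer += int(obs[0, 3] == 1)  # one object left -> dimerized
    p_hat = n_dimer / n_rep
    se = np.sqrt(p_dimer_exact * (1 - p_dimer_exact) / n_rep)
    assert abs(p_hat - p_dimer_exact) < 4 * se


# --------------------------------------------------------- engine/reference
def test_engine_activation_marginal_is_exact():
    """P(lone monomer activated by T) = 1 - exp(-k_A T), independent of the
    concurrent diffusion events."""
    kD, kA, T = 1.0, 0.4, 0.5
    trials = 4000
    n_act = 0
    for k in range(trials):
        st = two_monomer_state([(1, 1, 1)], states=(INACTIVE,), L=5)
        eng = FastKmc.from_state(st, KmcParams(k_D=kD, k_H=0, k_A=kA,
                                               k_E=0, k_R=0, k_K=0))
        eng.run(T, np.array([T]), seed=k + 1)
        n_act += int(eng.counts[4] == 0)  # inactive set emptied
    p_exact = 1 - np.exp(-kA * T)
    se = np.sqrt(p_exact * (1 - p_exact) / trials)
    assert abs(n_act / trials - p_exact) < 4 * se


def test_engine_and_reference_agree_in_distribution(rng):
    """Object-count distribution at a fixed horizon agrees between the
    null-event engine and the full-enumeration reference (chi-square)."""
    geom = LatticeGeometry(4, 4, 4)
    params = KmcParams(k_D=1, k_H=1, k_A=1, k_E=1, k_R=1, k_K=1)
    T = 3.0
    nrep = 250

    def sample_reference(seed):
        st = init_random_monomers(geom, N_m=8, seed=123)
        r = np.random.default_rng(seed)
        from aggrophase.lattice import gillespie_step
        from aggrophase.errors import FrozenStateError
        while st.t < T:
            try:
                gillespie_step(st, params, r)
            except FrozenStateError:
                break
        return len(st.polymers)

    def sample_engine(seed):
        st = init_random_monomers(geom, N_m=8, seed=123)
        eng = FastKmc.from_state(st, params)
        obs = eng.run(T, np.array([T]), seed=seed)
        return int(obs[0, 3])

    ref = np.array([sample_reference(1000 + i) for i in range(nrep)])
    fast = np.array([sample_engine(5000 + i) for i in range(nrep)])
    cats = np.arange(1, 9)
    ref_c = np.array([(ref == c).sum() for c in cats], dtype=float)
    fast_c = np.array([(fast == c).sum() for c in cats], dtype=float)
    keep = (ref_c + fast_c) >= 8
    ref_c, fast_c = ref_c[keep], fast_c[keep]
    # two-sample chi-square
    tot = ref_c + fast_c
    exp_ref = tot * ref_c.sum() / (ref_c.sum() + fast_c.sum())
    exp_fast = tot * fast_c.sum() / (ref_c.sum() + fast_c.sum())
    chi2 = float((((ref_c - exp_ref) ** 2) / exp_ref).sum()
                 + (((fast_c - exp_fast) ** 2) / exp_fast).sum())
    assert chi2_dist.sf(chi2, df=max(keep.sum() - 1, 1)) > 0.01


# --------------------------------------------------------------- invariants
def test_engine_mass_conservation_periodic():
    st = init_random_monomers(LatticeGeometry(8, 8, 8), N_m=60, seed=4)
    eng = FastKmc.from_state(st, invitro_params(k_f=0.2, k_L=0.1))
    obs = eng.run(200.0, np.linspace(1, 200, 50), seed=11)
    assert np.all(obs[:, 5] == 60)
    out = eng.to_state()
    out.validate()
    assert out.total_mass == 60


def test_engine_slab_mass_balance():
    geom = LatticeGeometry(6, 6, 6, "slab")
    st = LatticeState(geometry=geom)
    params = KmcParams(k_D=1, k_H=1, k_A=1, k_E=1, k_R=1, k_K=1,
                       k_f=0.01, k_in=0.5, k_out=3.0)
    eng = FastKmc.from_state(st, params)
    obs = eng.run(300.0, np.linspace(5, 300, 40), seed=3)
    mass, influx, efflux = obs[:, 5], obs[:, 6], obs[:, 7]
    assert np.all(mass == influx - efflux)
    eng.to_state().validate()


def test_latent_monomers_never_join():
    geom = LatticeGeometry(5, 5, 5)
    st = LatticeState(geometry=geom)
    for i, site in enumerate([(0, 0, 0), (1, 0, 0), (2, 2, 2), (3, 2, 2)]):
        st.add_polymer(Polymer(sites=[site], states=[LATENT]))
    eng = FastKmc.from_state(st, KmcParams(k_D=1, k_H=5, k_A=0, k_E=0,
                                           k_R=0, k_K=0))
    obs = eng.run(200.0, np.array([200.0]), seed=1)
    assert obs[0, 3] == 4  # still four objects: latency is absorbing
    assert eng.ev_counts[1] == 0  # no join events


def test_engine_determinism():
    def run(seed):
        st = init_random_monomers(LatticeGeometry(6, 6, 6), N_m=30, seed=2)
        eng = FastKmc.from_state(st, invitro_params(k_f=0.05))
        return eng.run(50.0, np.linspace(1, 50, 20), seed=seed)

    a, b, c = run(9), run(9), run(10)
    assert np.array_equal(a, b, equal_nan=True)
    assert not np.array_equal(a, c, equal_nan=True)


def test_single_boundary_monomer_efflux_rate():
    """A lone immobile monomer on a boundary plane leaves at rate k_out."""
    geom = LatticeGeometry(3, 3, 4, "slab")
    r = 2.0
    times = []
    for k in range(2000):
        st = LatticeState(geometry=geom)
        st.add_polymer(Polymer(sites=[(1, 1, 0)], states=[INACTIVE]))
        eng = FastKmc.from_state(st, KmcParams(k_D=0, k_H=0, k_A=0, k_E=0,
                                               k_R=0, k_K=0, k_out=r))
        eng.run(50.0, np.array([]), seed=k + 1)
        times.append(eng.clock[0])
    mean = np.mean(times)
    se = np.std(times) / np.sqrt(len(times))
    assert abs(mean - 1 / r) < 4 * se


def test_run_kmc_frozen_truncates_sampling():
    """A frozen state ends the run early; remaining samples carry the
    frozen values."""
    st = two_monomer_state([(0, 0, 0)], states=(LATENT,), L=5)
    traj = run_kmc(st, KmcParams(k_D=0, k_H=0, k_A=0, k_E=0, k_R=0, k_K=0),
                   10.0, np.linspace(1, 10, 5), seed=1)
    assert np.all(traj.n_objects == 1)
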