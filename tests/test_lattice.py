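"""Reference lattice model: exact event catalogue and move semantics."""

from collections import Counter

import numpy as np
import pytest

from aggrophase.errors import CapacityError, FrozenStateError
from aggrophase.lattice import (
    ACTIVE,
    INACTIVE,
    LATENT,
    KmcParams,
    LatticeGeometry,
    LatticeState,
    Polymer,
    enumerate_events,
    gillespie_step,
    init_random_monomers,
    invitro_params,
)


def make_state(chains, L=7, mode="periodic"):
    st = LatticeState(geometry=LatticeGeometry(L, L, L, mode))
    for sites, states in chains:
        st.add_polymer(Polymer(sites=list(sites), states=list(states)))
    return st


# ------------------------------------------------------------ initialization
def test_init_empty_and_full():
    geom = LatticeGeometry(4, 4, 4)
    empty = init_random_monomers(geom, N_m=0, seed=1)
    assert len(empty.polymers) == 0
    assert np.isnan(empty.observables()["m_w"])
    full = init_random_monomers(geom, rho=1.0, seed=1)
    assert len(full.polymers) == 64
    with pytest.raises(CapacityError):
        init_random_monomers(geom, N_m=65, seed=1)


def test_init_seeds_differ_but_density_matches():
    geom = LatticeGeometry(8, 8, 8)
    a = init_random_monomers(geom, N_m=40, seed=1)
    b = init_random_monomers(geom, N_m=40, seed=2)
    assert len(a.polymers) == len(b.polymers) == 40
    assert set(a.occupancy) != set(b.occupancy)


# ------------------------------------------------------------ catalogue
def test_single_monomer_catalogue():
    st = make_state([([(3, 3, 3)], [INACTIVE])])
    evs = enumerate_events(st, KmcParams(k_D=1.0, k_A=0.5, k_H=1.0))
    kinds = Counter(e.kind for e in evs)
    assert kinds == {"diffuse": 6, "activate": 1}


def test_straight_trimer_catalogue():
    st = make_state([([(1, 1, 1), (2, 1, 1), (3, 1, 1)], [ACTIVE] * 3)])
    p = KmcParams(k_D=1, k_H=1, k_R=1, k_E=1, k_K=1, k_A=1, k_f=0.25)
    evs = enumerate_events(st, p)
    kinds = Counter(e.kind for e in evs)
    # two reptation events at k_R / 9
    reps = [e for e in evs if e.kind == "reptate"]
    assert len(reps) == 2 and all(e.rate == pytest.approx(1 / 9) for e in reps)
    # fragmentation: 2 internal bonds
    assert kinds["fragment"] == 2
    assert sum(e.rate for e in evs if e.kind == "fragment") == pytest.approx(0.5)
    # end rotations: 4 empty neighbours of each adjacent monomer
    assert kinds["end_rotate"] == 8
    # straight chain has no kink moves, no diffusion (length > 1)
    assert "kink" not in kinds and "diffuse" not in kinds


def test_corner_trimer_has_one_kink():
    st = make_state([([(1, 1, 1), (2, 1, 1), (2, 2, 1)], [ACTIVE] * 3)])
    evs = enumerate_events(st, KmcParams(k_K=1.0, k_D=0, k_H=0, k_A=0))
    kinks = [e for e in evs if e.kind == "kink"]
    assert len(kinks) == 1
    assert kinks[0].data[2] == (1, 2, 1)  # the opposite corner


def test_join_eligibility_rules():
    # active + inactive adjacent -> one join event at k_H
    st = make_state([([(1, 1, 1)], [ACTIVE]), ([(2, 1, 1)], [INACTIVE])])
    p = KmcParams(k_D=1, k_A=0, k_H=2.5)
    joins = [e for e in evs_of(st, p, "join")]
    assert len(joins) == 1 and joins[0].rate == 2.5
    # two inactive monomers -> no join
    st2 = make_state([([(1, 1, 1)], [INACTIVE]), ([(2, 1, 1)], [INACTIVE])])
    assert not evs_of(st2, p, "join")
    # latent partner blocks joining even against an active one
    st3 = make_state([([(1, 1, 1)], [ACTIVE]), ([(2, 1, 1)], [LATENT])])
    assert not evs_of(st3, p, "join")
    # interior monomers never re-bond: monomer adjacent to chain middle
    st4 = make_state([
        ([(1, 1, 1), (2, 1, 1), (3, 1, 1)], [ACTIVE] * 3),
        ([(2, 2, 1)], [ACTIVE]),
    ])
    joins4 = evs_of(st4, p, "join")
    assert len(joins4) == 0  # (2,2,1) touches only the interior site (2,1,1)


def evs_of(state, params, kind):
    return [e for e in enumerate_events(state, params) if e.kind == kind]


def test_slab_influx_and_efflux_catalogue():
    geom = LatticeGeometry(4, 4, 5, "slab")
    st = LatticeState(geometry=geom)
    st.add_polymer(Polymer(sites=[(0, 0, 0)], states=[ACTIVE]))     # on boundary
    st.add_polymer(Polymer(sites=[(2, 2, 2)], states=[ACTIVE]))     # in bulk
    p = KmcParams(k_D=0, k_A=0, k_H=0, k_in=0.5, k_out=2.0)
    evs = enumerate_events(st, p)
    influx = [e for e in evs if e.kind == "influx"]
    assert len(influx) == 2 * 16 - 1  # both z-planes, one site occupied
    efflux = [e for e in evs if e.kind == "efflux"]
    assert len(efflux) == 1 and efflux[0].rate == 2.0  # only the boundary one


def test_efflux_rate_scales_with_length():
    geom = LatticeGeometry(4, 4, 5, "slab")
    st = LatticeState(geometry=geom)
    st.add_polymer(Polymer(sites=[(0, 0, 0), (1, 0, 0), (1, 1, 0)],
                           states=[ACTIVE] * 3))
    evs = enumerate_events(st, KmcParams(k_D=0, k_A=0, k_H=0, k_out=2.0))
    efflux = [e for e in evs if e.kind == "efflux"]
    assert len(efflux) == 1
    assert efflux[0].rate == pytest.approx(2.0 / 27)


# ------------------------------------------------------------ stepping
def test_frozen_state_signal():
    st = make_state([([(1, 1, 1)], [LATENT])])
    with pytest.raises(FrozenStateError):
        gillespie_step(st, KmcParams(k_D=0, k_A=0, k_H=0),
                       np.random.default_rng(0))


def test_single_event_waiting_time(rng):
    """With one event of rate r the mean waiting time is 1/r."""
    r = 0.35
    dts = []
    for _ in range(4000):
        st = make_state([([(1, 1, 1)], [INACTIVE])])
        dts.append(gillespie_step(st, KmcParams(k_D=0, k_H=0, k_A=r), rng))
        assert st.polymers[0].states[0] == ACTIVE
    mean = np.mean(dts)
    se = np.std(dts) / np.sqrt(len(dts))
    assert abs(mean - 1 / r) < 3 * se


def test_event_frequencies_match_rates(rng):
    """First executed event from a fixed state follows rate proportions."""
    kD, kA = 1.0, 0.4
    n_act = 0
    trials = 3000
    for _ in range(trials):
        st = make_state([([(3, 3, 3)], [INACTIVE])])
        gillespie_step(st, KmcParams(k_D=kD, k_H=0, k_A=kA), rng)
        if st.polymers[0].states[0] == ACTIVE:
            n_act += 1
    p_expected = kA / (kA + 6 * kD)
    res = np.array([n_act, trials - n_act])
    exp = np.array([p_expected, 1 - p_expected]) * trials
    chi2 = float(((res - exp) ** 2 / exp).sum())
    from scipy.stats import chi2 as chi2_dist
    assert chi2_dist.sf(chi2, df=1) > 0.01


def test_mass_conservation_and_invariants_under_all_moves(rng):
    st = init_random_monomers(LatticeGeometry(5, 5, 5), N_m=25, seed=9)
    p = invitro_params(k_f=0.1, k_L=0.05)
    mass0 = st.total_mass
    for _ in range(800):
        gillespie_step(st, p, rng)
    st.validate()  # self-avoidance, connectivity, occupancy consistency
    assert st.total_mass == mass0


def test_reptation_preserves_connectivity(rng):
    st = make_state([([(1, 1, 1), (2, 1, 1), (2, 2, 1), (2, 2, 2)],
                      [ACTIVE] * 4)])
    p = KmcParams(k_D=0, k_H=0, k_A=0, k_R=1.0, k_E=0, k_K=0)
    for _ in range(200):
        gillespie_step(st, p, rng)
        st.validate()
    assert st.polymers and next(iter(st.polymers.values())).length == 4
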