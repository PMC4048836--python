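"""Event-driven production engine for the 3D lattice model (numba).

Simulates the same continuous-time Markov chain as the reference
implementation in :mod:`aggrophase.lattice`, using a null-event scheme:
each event class carries a constant per-object envelope rate; an attempt
that turns out inadmissible (blocked site, wrong monomer state, thinning of
a length-dependent rate) is a self-loop of the chain and only advances the
clock.  Self-loop transitions leave the law of a CTMC unchanged, so the
scheme is exact, not approximate; it is cross-validated against the
full-enumeration reference and a matrix-exponential oracle in the tests.

Envelope rates per Gillespie draw (counts maintained incrementally):

==================  =============================================
diffusion           n_free * 6 k_D
join (free end)     n_free * 6 (k_H/2)
join (chain end)    n_poly * 12 (k_H/2)
activation          n_inactive * k_A
latentization       n_active * k_L
reptation           n_poly * 2 (k_R/4)      thinned by (2/i)^2
end rotation        n_poly * 12 k_E
kink                n_monomers * k_K        (internal corners only)
fragmentation       n_monomers * k_f        (one bond per non-head monomer)
influx (slab)       2 Lx Ly k_in            (empty boundary sites only)
efflux (slab)       n_objects * k_out       thinned by i^-exponent
==================  =============================================

The directed-attempt rate k_H/2 makes every admissible endpoint pair meet at
total rate k_H (each side of the pair attempts toward the other).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lattice import (
    ACTIVE,
    INACTIVE,
    LATENT,
    KmcParams,
    LatticeGeometry,
    LatticeState,
    Polymer,
)

__all__ = ["FastKmc"]

# observable columns written at each sample
OBS_COLS = [
    "t", "m_w", "m_p", "n_objects", "n_polymers", "mass",
    "cum_influx", "cum_efflux", "cum_joins",
]

# event-counter indices
E_DIFF, E_JOIN, E_ACT, E_LAT, E_REP, E_ROT, E_KINK, E_FRAG, E_IN, E_OUT, E_NULL = range(11)


@njit(cache=True, inline="always")
def _neighbor(site, d, Lx, Ly, Lz, slab):
    z = site % Lz
    r = site // Lz
    y = r % Ly
    x = r // Ly
    if d == 0:
        x = (x + 1) % Lx
    elif d == 1:
        x = (x - 1) % Lx
    elif d == 2:
        y = (y + 1) % Ly
    elif d == 3:
        y = (y - 1) % Ly
    elif d == 4:
        z = z + 1
        if z >= Lz:
            if slab:
                return -1
            z = 0
    else:
        z = z - 1
        if z < 0:
            if slab:
                return -1
            z = Lz - 1
    return (x * Ly + y) * Lz + z


@njit(cache=True, inline="always")
def _sadd(arr, pos, size, x):
    arr[size] = x
    pos[x] = size
    return size + 1


@njit(cache=True, inline="always")
def _srem(arr, pos, size, x):
    i = pos[x]
    last = arr[size - 1]
    arr[i] = last
    pos[last] = i
    pos[x] = -1
    return size - 1


@njit(cache=True)
def _reverse(P, phead, ptail, mnext, mprev):
    cur = phead[P]
    while cur != -1:
        nxt = mnext[cur]
        mnext[cur] = mprev[cur]
        mprev[cur] = nxt
        cur = nxt
    h = phead[P]
    phead[P] = ptail[P]
    ptail[P] = h


@njit(cache=True)
def _run_kmc(
    # geometry / params
    Lx, Ly, Lz, slab,
    k_D, k_H, k_R, k_E, k_K, k_A, k_L, k_f, k_in, k_out, efflux_exp,
    # state arrays
    occ, mpos, mstate, mnext, mprev, mpoly,
    phead, ptail, plen,
    mfree_stack, pfree_stack,
    set_free_arr, set_free_pos,
    set_poly_arr, set_poly_pos,
    set_inact_arr, set_inact_pos,
    set_act_arr, set_act_pos,
    set_all_arr, set_all_pos,
    # scalars packed in arrays for mutation
    counts,      # [n_mfree, n_pfree, n_free, n_poly, n_inact, n_act, n_all,
                 #  mass, sum_len_sq, cum_influx, cum_efflux]
    ev_counts,   # 11 event counters
    clock,       # [t]
    # run control
    t_end, sample_times, out,
    seed,
):
    np.random.seed(seed)
    t = clock[0]
    sidx = 0
    nsamp = sample_times.shape[0]
    boundary_sites = 2 * Lx * Ly

    while True:
        n_free = counts[2]
        n_poly = counts[3]
        n_inact = counts[4]
        n_act = counts[5]
        n_all = counts[6]
        n_obj = n_free + n_poly

        r_diff = n_free * 6.0 * k_D
        r_hookF = n_free * 3.0 * k_H          # 6 dirs * k_H/2
        r_hookE = n_poly * 6.0 * k_H          # 2 ends * 6 dirs * k_H/2
        r_act = n_inact * k_A
        r_lat = n_act * k_L
        r_rep = n_poly * 0.5 * k_R            # 2 ends * k_R/4
        r_rot = n_poly * 12.0 * k_E
        r_kink = n_all * k_K
        r_frag = n_all * k_f
        r_in = boundary_sites * k_in if slab else 0.0
        r_out = n_obj * k_out if slab else 0.0
        R = (r_diff + r_hookF + r_hookE + r_act + r_lat + r_rep + r_rot
             + r_kink + r_frag + r_in + r_out)

        if R <= 0.0:
            # frozen: emit remaining samples at the frozen values
            while sidx < nsamp:
                _record(out, sidx, sample_times[sidx], counts, ev_counts)
                sidx += 1
            break

        dt = -np.log(np.random.random()) / R
        # emit samples crossed by this waiting interval (state is constant)
        while sidx < nsamp and t + dt >= sample_times[sidx]:
            _record(out, sidx, sample_times[sidx], counts, ev_counts)
            sidx += 1
        t += dt
        if t >= t_end and sidx >= nsamp:
            break

        u = np.random.random() * R

        # ------------------------------------------------ diffusion
        if u < r_diff:
            F = set_free_arr[np.random.randint(0, n_free)]
            m = phead[F]
            d = np.random.randint(0, 6)
            tgt = _neighbor(mpos[m], d, Lx, Ly, Lz, slab)
            if tgt >= 0 and occ[tgt] == -1:
                occ[mpos[m]] = -1
                occ[tgt] = m
                mpos[m] = tgt
                ev_counts[E_DIFF] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_diff

        # ------------------------------------------------ join attempts
        if u < r_hookF + r_hookE:
            if u < r_hookF:
                P = set_free_arr[np.random.randint(0, n_free)]
                mu = phead[P]
            else:
                P = set_poly_arr[np.random.randint(0, n_poly)]
                mu = phead[P] if np.random.random() < 0.5 else ptail[P]
            d = np.random.randint(0, 6)
            tgt = _neighbor(mpos[mu], d, Lx, Ly, Lz, slab)
            ok = False
            if tgt >= 0 and occ[tgt] != -1:
                mw_ = occ[tgt]
                Q = mpoly[mw_]
                if Q != P and (mprev[mw_] == -1 or mnext[mw_] == -1):
                    sa = mstate[mu]
                    sb = mstate[mw_]
                    if sa != LATENT and sb != LATENT and (sa == ACTIVE or sb == ACTIVE):
                        ok = True
            if ok:
                mw_ = occ[tgt]
                Q = mpoly[mw_]
                # orient: mu must be tail of P, mw_ must be head of Q
                if plen[P] > 1 and mu != ptail[P]:
                    _reverse(P, phead, ptail, mnext, mprev)
                if plen[Q] > 1 and mw_ != phead[Q]:
                    _reverse(Q, phead, ptail, mnext, mprev)
                a = plen[P]
                b = plen[Q]
                # remove both from membership sets
                if a == 1:
                    counts[2] = _srem(set_free_arr, set_free_pos, counts[2], P)
                else:
                    counts[3] = _srem(set_poly_arr, set_poly_pos, counts[3], P)
                if b == 1:
                    counts[2] = _srem(set_free_arr, set_free_pos, counts[2], Q)
                else:
                    counts[3] = _srem(set_poly_arr, set_poly_pos, counts[3], Q)
                mnext[ptail[P]] = phead[Q]
                mprev[phead[Q]] = ptail[P]
                if b <= a:
                    cur = phead[Q]
                    while cur != -1:
                        mpoly[cur] = P
                        cur = mnext[cur]
                    ptail[P] = ptail[Q]
                    plen[P] = a + b
                    pfree_stack[counts[1]] = Q
                    counts[1] += 1
                    keep = P
                else:
                    cur = ptail[P]
                    while cur != -1:
                        mpoly[cur] = Q
                        cur = mprev[cur]
                    phead[Q] = phead[P]
                    plen[Q] = a + b
                    pfree_stack[counts[1]] = P
                    counts[1] += 1
                    keep = Q
                counts[3] = _sadd(set_poly_arr, set_poly_pos, counts[3], keep)
                counts[8] += (a + b) * (a + b) - a * a - b * b
                ev_counts[E_JOIN] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_hookF + r_hookE

        # ------------------------------------------------ activation
        if u < r_act:
            m = set_inact_arr[np.random.randint(0, n_inact)]
            mstate[m] = ACTIVE
            counts[4] = _srem(set_inact_arr, set_inact_pos, counts[4], m)
            counts[5] = _sadd(set_act_arr, set_act_pos, counts[5], m)
            ev_counts[E_ACT] += 1
            continue
        u -= r_act

        # ------------------------------------------------ latentization
        if u < r_lat:
            m = set_act_arr[np.random.randint(0, n_act)]
            mstate[m] = LATENT
            counts[5] = _srem(set_act_arr, set_act_pos, counts[5], m)
            ev_counts[E_LAT] += 1
            continue
        u -= r_lat

        # ------------------------------------------------ reptation
        if u < r_rep:
            P = set_poly_arr[np.random.randint(0, n_poly)]
            L = plen[P]
            if np.random.random() < 4.0 / (L * L):
                from_head = np.random.random() < 0.5
                lead = phead[P] if from_head else ptail[P]
                nemp = 0
                emp0 = -1
                emp1 = -1
                emp2 = -1
                emp3 = -1
                emp4 = -1
                emp5 = -1
                for d in range(6):
                    tgt = _neighbor(mpos[lead], d, Lx, Ly, Lz, slab)
                    if tgt >= 0 and occ[tgt] == -1:
                        if nemp == 0:
                            emp0 = tgt
                        elif nemp == 1:
                            emp1 = tgt
                        elif nemp == 2:
                            emp2 = tgt
                        elif nemp == 3:
                            emp3 = tgt
                        elif nemp == 4:
                            emp4 = tgt
                        else:
                            emp5 = tgt
                        nemp += 1
                if nemp > 0:
                    j = np.random.randint(0, nemp)
                    if j == 0:
                        tgt = emp0
                    elif j == 1:
                        tgt = emp1
                    elif j == 2:
                        tgt = emp2
                    elif j == 3:
                        tgt = emp3
                    elif j == 4:
                        tgt = emp4
                    else:
                        tgt = emp5
                    # slide every monomer one position toward the lead
                    cur = lead
                    newsite = tgt
                    while cur != -1:
                        old = mpos[cur]
                        occ[newsite] = cur
                        mpos[cur] = newsite
                        newsite = old
                        cur = mnext[cur] if from_head else mprev[cur]
                    occ[newsite] = -1  # vacated trailing site
                    ev_counts[E_REP] += 1
                else:
                    ev_counts[E_NULL] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_rep

        # ------------------------------------------------ end rotation
        if u < r_rot:
            P = set_poly_arr[np.random.randint(0, n_poly)]
            if np.random.random() < 0.5:
                end = phead[P]
                adj = mnext[end]
            else:
                end = ptail[P]
                adj = mprev[end]
            d = np.random.randint(0, 6)
            tgt = _neighbor(mpos[adj], d, Lx, Ly, Lz, slab)
            if tgt >= 0 and occ[tgt] == -1:
                occ[mpos[end]] = -1
                occ[tgt] = end
                mpos[end] = tgt
                ev_counts[E_ROT] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_rot

        # ------------------------------------------------ kink move
        if u < r_kink:
            m = set_all_arr[np.random.randint(0, n_all)]
            a = mprev[m]
            c = mnext[m]
            if a != -1 and c != -1:
                tgt = _kink_target(mpos[a], mpos[m], mpos[c], Lx, Ly, Lz, slab)
                if tgt >= 0 and occ[tgt] == -1:
                    occ[mpos[m]] = -1
                    occ[tgt] = m
                    mpos[m] = tgt
                    ev_counts[E_KINK] += 1
                else:
                    ev_counts[E_NULL] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_kink

        # ------------------------------------------------ fragmentation
        if u < r_frag:
            m = set_all_arr[np.random.randint(0, n_all)]
            if mprev[m] != -1:
                O = mpoly[m]
                L = plen[O]
                # count right side with a cap of L/2 to find the shorter side
                lenR = 0
                cur = m
                cap = L // 2 + 1
                while cur != -1 and lenR <= cap:
                    lenR += 1
                    cur = mnext[cur]
                p_ = mprev[m]
                mnext[p_] = -1
                mprev[m] = -1
                B = pfree_stack[counts[1] - 1]
                counts[1] -= 1
                counts[3] = _srem(set_poly_arr, set_poly_pos, counts[3], O)
                if lenR <= cap and lenR <= L - lenR:
                    # right side is the shorter: relabel it as B
                    cur = m
                    while cur != -1:
                        mpoly[cur] = B
                        cur = mnext[cur]
                    phead[B] = m
                    ptail[B] = ptail[O]
                    ptail[O] = p_
                    plen[B] = lenR
                    plen[O] = L - lenR
                else:
                    # left side shorter (or equal): relabel head..p_ as B
                    lenL = 0
                    cur = p_
                    while cur != -1:
                        mpoly[cur] = B
                        lenL += 1
                        cur = mprev[cur]
                    phead[B] = phead[O]
                    ptail[B] = p_
                    phead[O] = m
                    plen[B] = lenL
                    plen[O] = L - lenL
                for X in (O, B):
                    if plen[X] == 1:
                        counts[2] = _sadd(set_free_arr, set_free_pos, counts[2], X)
                    else:
                        counts[3] = _sadd(set_poly_arr, set_poly_pos, counts[3], X)
                a_ = plen[O]
                b_ = plen[B]
                counts[8] += a_ * a_ + b_ * b_ - L * L
                ev_counts[E_FRAG] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        u -= r_frag

        # ------------------------------------------------ influx
        if slab and u < r_in:
            j = np.random.randint(0, boundary_sites)
            half = Lx * Ly
            if j < half:
                x = j // Ly
                y = j % Ly
                z = 0
            else:
                jj = j - half
                x = jj // Ly
                y = jj % Ly
                z = Lz - 1
            site = (x * Ly + y) * Lz + z
            if occ[site] == -1:
                m = mfree_stack[counts[0] - 1]
                counts[0] -= 1
                B = pfree_stack[counts[1] - 1]
                counts[1] -= 1
                mpos[m] = site
                mstate[m] = INACTIVE
                mnext[m] = -1
                mprev[m] = -1
                mpoly[m] = B
                occ[site] = m
                phead[B] = m
                ptail[B] = m
                plen[B] = 1
                counts[2] = _sadd(set_free_arr, set_free_pos, counts[2], B)
                counts[4] = _sadd(set_inact_arr, set_inact_pos, counts[4], m)
                counts[6] = _sadd(set_all_arr, set_all_pos, counts[6], m)
                counts[7] += 1
                counts[8] += 1
                counts[9] += 1
                ev_counts[E_IN] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        if slab:
            u -= r_in

        # ------------------------------------------------ efflux
        if slab and k_out > 0.0:
            j = np.random.randint(0, n_obj)
            if j < n_free:
                O = set_free_arr[j]
            else:
                O = set_poly_arr[j - n_free]
            L = plen[O]
            accept = True
            if L > 1:
                accept = np.random.random() < L ** (-efflux_exp)
            if accept:
                touches = False
                cur = phead[O]
                while cur != -1:
                    z = mpos[cur] % Lz
                    if z == 0 or z == Lz - 1:
                        touches = True
                        break
                    cur = mnext[cur]
                if touches:
                    cur = phead[O]
                    while cur != -1:
                        nxt = mnext[cur]
                        occ[mpos[cur]] = -1
                        if mstate[cur] == INACTIVE:
                            counts[4] = _srem(set_inact_arr, set_inact_pos,
                                              counts[4], cur)
                        elif mstate[cur] == ACTIVE:
                            counts[5] = _srem(set_act_arr, set_act_pos,
                                              counts[5], cur)
                        counts[6] = _srem(set_all_arr, set_all_pos, counts[6], cur)
                        mfree_stack[counts[0]] = cur
                        counts[0] += 1
                        cur = nxt
                    if L == 1:
                        counts[2] = _srem(set_free_arr, set_free_pos, counts[2], O)
                    else:
                        counts[3] = _srem(set_poly_arr, set_poly_pos, counts[3], O)
                    pfree_stack[counts[1]] = O
                    counts[1] += 1
                    counts[7] -= L
                    counts[8] -= L * L
                    counts[10] += L
                    ev_counts[E_OUT] += 1
                else:
                    ev_counts[E_NULL] += 1
            else:
                ev_counts[E_NULL] += 1
            continue
        ev_counts[E_NULL] += 1

    clock[0] = t
    return sidx


@njit(cache=True, inline="always")
def _wrapdiff(d, L, periodic):
    if periodic:
        if d == L - 1:
            return -1
        if d == -(L - 1):
            return 1
    return d


@njit(cache=True)
def _kink_target(sa, sb, sc, Lx, Ly, Lz, slab):
    za = sa % Lz; ra = sa // Lz; ya = ra % Ly; xa = ra // Ly
    zb = sb % Lz; rb = sb // Lz; yb = rb % Ly; xb = rb // Ly
    zc = sc % Lz; rc = sc // Lz; yc = rc % Ly; xc = rc // Ly
    dax = _wrapdiff(xa - xb, Lx, True)
    day = _wrapdiff(ya - yb, Ly, True)
    daz = _wrapdiff(za - zb, Lz, not slab)
    dcx = _wrapdiff(xc - xb, Lx, True)
    dcy = _wrapdiff(yc - yb, Ly, True)
    dcz = _wrapdiff(zc - zb, Lz, not slab)
    # corner requires orthogonal displacements (collinear -> sum is zero)
    if dax + dcx == 0 and day + dcy == 0 and daz + dcz == 0:
        return -1
    x = (xb + dax + dcx) % Lx
    y = (yb + day + dcy) % Ly
    z = zb + daz + dcz
    if slab:
        if z < 0 or z >= Lz:
            return -1
    else:
        z %= Lz
    return (x * Ly + y) * Lz + z


@njit(cache=True, inline="always")
def _record(out, sidx, ts, counts, ev_counts):
    mass = counts[7]
    n_free = counts[2]
    n_poly = counts[3]
    out[sidx, 0] = ts
    out[sidx, 1] = counts[8] / mass if mass > 0 else np.nan
    poly_mass = mass - n_free
    out[sidx, 2] = poly_mass / n_poly if n_poly > 0 else np.nan
    out[sidx, 3] = n_free + n_poly
    out[sidx, 4] = n_poly
    out[sidx, 5] = mass
    out[sidx, 6] = counts[9]
    out[sidx, 7] = counts[10]
    out[sidx, 8] = ev_counts[E_JOIN]


class FastKmc:
    """Array-backed lattice state with a numba Gillespie driver."""

    def __init__(self, geometry: LatticeGeometry, params: KmcParams,
                 capacity: int | None = None):
        self.geometry = geometry
        self.params = params
        n = geometry.n_sites if capacity is None else capacity
        self.capacity = n
        self.occ = np.full(geometry.n_sites, -1, dtype=np.int64)
        self.mpos = np.zeros(n, dtype=np.int64)
        self.mstate = np.zeros(n, dtype=np.int8)
        self.mnext = np.full(n, -1, dtype=np.int64)
        self.mprev = np.full(n, -1, dtype=np.int64)
        self.mpoly = np.full(n, -1, dtype=np.int64)
        self.phead = np.full(n, -1, dtype=np.int64)
        self.ptail = np.full(n, -1, dtype=np.int64)
        self.plen = np.zeros(n, dtype=np.int64)
        self.mfree = np.arange(n - 1, -1, -1, dtype=np.int64).copy()
        self.pfree = np.arange(n - 1, -1, -1, dtype=np.int64).copy()
        self.set_free = (np.zeros(n, dtype=np.int64), np.full(n, -1, np.int64))
        self.set_poly = (np.zeros(n, dtype=np.int64), np.full(n, -1, np.int64))
        self.set_inact = (np.zeros(n, dtype=np.int64), np.full(n, -1, np.int64))
        self.set_act = (np.zeros(n, dtype=np.int64), np.full(n, -1, np.int64))
        self.set_all = (np.zeros(n, dtype=np.int64), np.full(n, -1, np.int64))
        # [n_mfree, n_pfree, n_free, n_poly, n_inact, n_act, n_all,
        #  mass, sum_len_sq, cum_influx, cum_efflux]
        self.counts = np.zeros(11, dtype=np.int64)
        self.counts[0] = n
        self.counts[1] = n
        self.ev_counts = np.zeros(11, dtype=np.int64)
        self.clock = np.zeros(1, dtype=np.float64)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_state(cls, state: LatticeState, params: KmcParams,
                   capacity: int | None = None) -> "FastKmc":
        geom = state.geometry
        eng = cls(geom, params, capacity=capacity)
        for poly in state.polymers.values():
            eng._add_chain(
                [eng._flat(s) for s in poly.sites], list(poly.states)
            )
        eng.clock[0] = state.t
        eng.counts[9] = state.mass_influx
        eng.counts[10] = state.mass_efflux
        return eng

    def _flat(self, site) -> int:
        x, y, z = site
        g = self.geometry
        return (x * g.Ly + y) * g.Lz + z

    def _unflat(self, s: int):
        g = self.geometry
        z = s % g.Lz
        r = s // g.Lz
        return (r // g.Ly, r % g.Ly, z)

    def _add_chain(self, flat_sites, states) -> int:
        c = self.counts
        mids = []
        for s, stt in zip(flat_sites, states):
            m = self.mfree[c[0] - 1]
            c[0] -= 1
            if self.occ[s] != -1:
                raise ValueError("site doubly occupied")
            self.occ[s] = m
            self.mpos[m] = s
            self.mstate[m] = stt
            self.mnext[m] = -1
            self.mprev[m] = -1
            mids.append(m)
        for a, b in zip(mids, mids[1:]):
            self.mnext[a] = b
            self.mprev[b] = a
        P = self.pfree[c[1] - 1]
        c[1] -= 1
        self.phead[P] = mids[0]
        self.ptail[P] = mids[-1]
        self.plen[P] = len(mids)
        for m in mids:
            self.mpoly[m] = P
        for m, stt in zip(mids, states):
            if stt == INACTIVE:
                c[4] = _py_sadd(self.set_inact, c[4], m)
            elif stt == ACTIVE:
                c[5] = _py_sadd(self.set_act, c[5], m)
            c[6] = _py_sadd(self.set_all, c[6], m)
        if len(mids) == 1:
            c[2] = _py_sadd(self.set_free, c[2], P)
        else:
            c[3] = _py_sadd(self.set_poly, c[3], P)
        c[7] += len(mids)
        c[8] += len(mids) ** 2
        return P

    # -- running -----------------------------------------------------------
    def run(self, t_end: float, sample_times: np.ndarray, seed: int) -> np.ndarray:
        """Advance to ``t_end``, recording OBS_COLS at ``sample_times``.

        Returns the (n_samples, 9) observable array; the state is left at
        the final simulated time and can be run further.
        """
        sample_times = np.asarray(sample_times, dtype=np.float64)
        out = np.full((sample_times.size, len(OBS_COLS)), np.nan)
        p, g = self.params, self.geometry
        _run_kmc(
            g.Lx, g.Ly, g.Lz, g.boundary_mode == "slab",
            p.k_D, p.k_H, p.k_R, p.k_E, p.k_K, p.k_A, p.k_L, p.k_f,
            p.k_in, p.k_out, p.efflux_exponent,
            self.occ, self.mpos, self.mstate, self.mnext, self.mprev,
            self.mpoly, self.phead, self.ptail, self.plen,
            self.mfree, self.pfree,
            self.set_free[0], self.set_free[1],
            self.set_poly[0], self.set_poly[1],
            self.set_inact[0], self.set_inact[1],
            self.set_act[0], self.set_act[1],
            self.set_all[0], self.set_all[1],
            self.counts, self.ev_counts, self.clock,
            float(t_end), sample_times, out,
            int(seed) % (2 ** 31 - 1),
        )
        return out

    # -- export ------------------------------------------------------------
    def to_state(self) -> LatticeState:
        """Export to the dict-based reference representation (for checks)."""
        st = LatticeState(geometry=self.geometry, t=float(self.clock[0]))
        c = self.counts
        for arr, size in ((self.set_free[0], c[2]), (self.set_poly[0], c[3])):
            for i in range(size):
                P = int(arr[i])
                sites, states = [], []
                cur = int(self.phead[P])
                while cur != -1:
                    sites.append(self._unflat(int(self.mpos[cur])))
                    states.append(int(self.mstate[cur]))
                    cur = int(self.mnext[cur])
                st.add_polymer(Polymer(sites=sites, states=states))
        st.mass_influx = int(c[9])
        st.mass_efflux = int(c[10])
        return st


def _py_sadd(set_pair, size, x):
    arr, pos = set_pair
    arr[size] = x
    pos[x] = size
    return size + 1
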