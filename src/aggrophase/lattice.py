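"""Reference 3D lattice model of linear-polymer aggregation (exact catalogue).

Linear polymers live on a cubic lattice with single occupancy.  Free
monomers diffuse (rate ``k_D`` per empty neighbour site); chains move by
reptation (one forward and one backward event per chain at ``k_R / i**2``),
end rotations (``k_E`` per admissible terminal placement), and kink moves
(``k_K`` per admissible internal corner flip).  Chain ends and free monomers
join at ``k_H`` per admissible adjacent pair — eligible when neither meeting
monomer is latent and at least one is active — and internal bonds break at
``k_f`` per bond.  Monomers activate at ``k_A`` and active monomers become
latent at ``k_L`` (latency blocks further joining but keeps existing bonds).
In slab mode (periodic x,y; closed z) monomers are injected at ``k_in`` per
empty boundary-plane site and whole objects touching a boundary plane leave
at ``k_out / i**efflux_exponent``.

This module is the *reference* implementation: it enumerates the complete
event catalogue each step, so it is exact but slow.  The production engine
(:mod:`aggrophase.engine`) simulates the identical continuous-time Markov
chain with a null-event scheme and is validated against this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import CapacityError, FrozenStateError, InvalidStateError

__all__ = [
    "LatticeGeometry",
    "KmcParams",
    "Polymer",
    "LatticeState",
    "Event",
    "init_random_monomers",
    "enumerate_events",
    "gillespie_step",
    "invitro_params",
    "er_params",
]

INACTIVE, ACTIVE, LATENT = 0, 1, 2
_DIRS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass(frozen=True)
class LatticeGeometry:
    """Slab or fully periodic cubic lattice of Lx * Ly * Lz sites."""

    Lx: int
    Ly: int
    Lz: int
    boundary_mode: Literal["periodic", "slab"] = "periodic"

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) < 3:
            raise ValueError("all lattice dimensions must be >= 3")

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly * self.Lz

    def neighbours(self, site: Tuple[int, int, int]):
        x, y, z = site
        for dx, dy, dz in _DIRS:
            nx, ny = (x + dx) % self.Lx, (y + dy) % self.Ly
            nz = z + dz
            if self.boundary_mode == "periodic":
                nz %= self.Lz
            elif nz < 0 or nz >= self.Lz:
                continue
            yield (nx, ny, nz)

    def is_boundary(self, site: Tuple[int, int, int]) -> bool:
        return self.boundary_mode == "slab" and site[2] in (0, self.Lz - 1)

    def boundary_sites(self):
        if self.boundary_mode != "slab":
            return
        for z in (0, self.Lz - 1):
            for x in range(self.Lx):
                for y in range(self.Ly):
                    yield (x, y, z)


@dataclass(frozen=True)
class KmcParams:
    """Kinetic rates of the lattice model (all 1/time)."""

    k_D: float = 1.0
    k_H: float = 1.0
    k_R: float = 1.0
    k_E: float = 1.0
    k_K: float = 1.0
    k_A: float = 1.0
    k_L: float = 0.0
    k_f: float = 0.0
    k_in: float = 0.0
    k_out: float = 0.0
    efflux_exponent: float = 3.0

    def __post_init__(self) -> None:
        for name in ("k_D", "k_H", "k_R", "k_E", "k_K", "k_A", "k_L", "k_f",
                     "k_in", "k_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def invitro_params(k_D: float = 1.0, k_f: float = 0.0, k_L: float = 0.0) -> KmcParams:
    """In-vitro convention: time in 1/k_D, all motion/bonding rates = k_D."""
    return KmcParams(k_D=k_D, k_H=k_D, k_E=k_D, k_R=k_D, k_K=k_D, k_A=k_D,
                     k_L=k_L, k_f=k_f, k_in=0.0, k_out=0.0)


def er_params(k_in: float = 1.0, k_out: float = 0.0) -> KmcParams:
    """ER (slab) convention: time in 1/k_in; k_D = 100, k_f = 1e-3 * k_in."""
    return KmcParams(k_D=100.0 * k_in, k_H=k_in, k_E=k_in, k_R=k_in,
                     k_K=k_in, k_A=k_in, k_L=0.0, k_f=1e-3 * k_in,
                     k_in=k_in, k_out=k_out)


@dataclass
class Polymer:
    """Ordered self-avoiding nearest-neighbour chain with per-monomer state."""

    sites: List[Tuple[int, int, int]]
    states: List[int]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.states) or not self.sites:
            raise InvalidStateError("sites/states mismatch or empty polymer")

    @property
    def length(self) -> int:
        return len(self.sites)

    def validate(self, geom: LatticeGeometry) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise InvalidStateError("polymer revisits a site")
        for a, b in zip(self.sites, self.sites[1:]):
            if b not in set(geom.neighbours(a)):
                raise InvalidStateError("polymer path not nearest-neighbour")


@dataclass
class LatticeState:
    """Occupancy map + polymer registry + clock + event bookkeeping."""

    geometry: LatticeGeometry
    polymers: Dict[int, Polymer] = field(default_factory=dict)
    t: float = 0.0
    next_id: int = 0
    event_counts: Dict[str, int] = field(default_factory=dict)
    mass_influx: int = 0
    mass_efflux: int = 0
    occupancy: Dict[Tuple[int, int, int], Tuple[int, int]] = field(
        default_factory=dict
    )  # site -> (polymer id, index along chain)

    def rebuild_occupancy(self) -> None:
        self.occupancy = {}
        for pid, poly in self.polymers.items():
            for idx, s in enumerate(poly.sites):
                if s in self.occupancy:
                    raise InvalidStateError(f"site {s} doubly occupied")
                self.occupancy[s] = (pid, idx)

    def add_polymer(self, poly: Polymer) -> int:
        pid = self.next_id
        self.next_id += 1
        self.polymers[pid] = poly
        for idx, s in enumerate(poly.sites):
            if s in self.occupancy:
                raise InvalidStateError(f"site {s} doubly occupied")
            self.occupancy[s] = (pid, idx)
        return pid

    def remove_polymer(self, pid: int) -> Polymer:
        poly = self.polymers.pop(pid)
        for s in poly.sites:
            del self.occupancy[s]
        return poly

    @property
    def total_mass(self) -> int:
        return sum(p.length for p in self.polymers.values())

    def observables(self) -> dict:
        lengths = np.array([p.length for p in self.polymers.values()])
        mass = lengths.sum() if lengths.size else 0
        m_w = float((lengths ** 2).sum() / mass) if mass else float("nan")
        polys = lengths[lengths >= 2]
        m_p = float(polys.sum() / polys.size) if polys.size else float("nan")
        return {
            "t": self.t, "m_w": m_w, "m_p": m_p,
            "n_objects": int(lengths.size), "n_polymers": int(polys.size),
            "mass": int(mass),
        }

    def validate(self) -> None:
        for poly in self.polymers.values():
            poly.validate(self.geometry)
        occ = {}
        for pid, poly in self.polymers.items():
            for idx, s in enumerate(poly.sites):
                if s in occ:
                    raise InvalidStateError(f"site {s} doubly occupied")
                occ[s] = (pid, idx)
        if occ != self.occupancy:
            raise InvalidStateError("occupancy map inconsistent with registry")


def init_random_monomers(
    geometry: LatticeGeometry,
    N_m: Optional[int] = None,
    rho: Optional[float] = None,
    seed: int = 0,
    state: int = INACTIVE,
) -> LatticeState:
    """Uniformly place ``N_m`` (or ``rho * n_sites``) monomers on empty sites."""
    if (N_m is None) == (rho is None):
        raise ValueError("specify exactly one of N_m or rho")
    if N_m is None:
        N_m = int(round(rho * geometry.n_sites))
    if N_m > geometry.n_sites:
        raise CapacityError(f"{N_m} monomers exceed {geometry.n_sites} sites")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(geometry.n_sites, size=N_m, replace=False)
    st = LatticeState(geometry=geometry)
    for flat in chosen:
        x, r = divmod(int(flat), geometry.Ly * geometry.Lz)
        y, z = divmod(r, geometry.Lz)
        st.add_polymer(Polymer(sites=[(x, y, z)], states=[state]))
    return st


# ---------------------------------------------------------------------------
# event catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    kind: str
    rate: float
    data: tuple = ()


def _bond_eligible(sa: int, sb: int) -> bool:
    """Neither meeting monomer latent; at least one active."""
    return LATENT not in (sa, sb) and ACTIVE in (sa, sb)


def _is_corner(a, b, c) -> bool:
    """True when b is a 90-degree corner between its neighbours a and c."""
    return a != c and not (
        a[0] == b[0] == c[0] and a[1] == b[1] == c[1]
    ) and not (
        a[0] == b[0] == c[0] and a[2] == b[2] == c[2]
    ) and not (
        a[1] == b[1] == c[1] and a[2] == b[2] == c[2]
    )


def _wrap(geom: LatticeGeometry, x: int, y: int, z: int):
    x %= geom.Lx
    y %= geom.Ly
    if geom.boundary_mode == "periodic":
        z %= geom.Lz
    elif z < 0 or z >= geom.Lz:
        return None
    return (x, y, z)


def _corner_target(geom: LatticeGeometry, a, b, c):
    """Opposite corner site a + c - b, with periodic wrapping (minimal image)."""
    def short(d, L, periodic):
        if periodic:
            if d > L // 2:
                d -= L
            elif d < -(L // 2):
                d += L
        return d

    per_z = geom.boundary_mode == "periodic"
    dx = short(a[0] - b[0], geom.Lx, True) + short(c[0] - b[0], geom.Lx, True)
    dy = short(a[1] - b[1], geom.Ly, True) + short(c[1] - b[1], geom.Ly, True)
    dz = short(a[2] - b[2], geom.Lz, per_z) + short(c[2] - b[2], geom.Lz, per_z)
    return _wrap(geom, b[0] + dx, b[1] + dy, b[2] + dz)


def enumerate_events(state: LatticeState, params: KmcParams) -> List[Event]:
    """Complete catalogue of (event, rate) pairs for the current state."""
    geom = state.geometry
    occ = state.occupancy
    events: List[Event] = []
    seen_pairs = set()

    for pid, poly in state.polymers.items():
        L = poly.length
        # monomer motion
        if L == 1 and params.k_D > 0:
            for tgt in geom.neighbours(poly.sites[0]):
                if tgt not in occ:
                    events.append(Event("diffuse", params.k_D, (pid, tgt)))
        # activation / latentization (per monomer, also inside polymers)
        for idx, s in enumerate(poly.states):
            if s == INACTIVE and params.k_A > 0:
                events.append(Event("activate", params.k_A, (pid, idx)))
            if s == ACTIVE and params.k_L > 0:
                events.append(Event("latentize", params.k_L, (pid, idx)))
        if L >= 2:
            # reptation: one forward + one backward event at k_R / L^2,
            # admissible when the leading end has an empty neighbour
            if params.k_R > 0:
                for endidx in (0, L - 1):
                    head = poly.sites[endidx]
                    if any(t not in occ for t in geom.neighbours(head)):
                        events.append(
                            Event("reptate", params.k_R / L ** 2, (pid, endidx))
                        )
            # end rotations: terminal monomer to any empty neighbour of the
            # adjacent chain monomer
            if params.k_E > 0:
                for endidx, adj in ((0, 1), (L - 1, L - 2)):
                    for tgt in geom.neighbours(poly.sites[adj]):
                        if tgt not in occ:
                            events.append(
                                Event("end_rotate", params.k_E, (pid, endidx, tgt))
                            )
            # kink moves: internal corner flips to the empty opposite corner
            if params.k_K > 0:
                for idx in range(1, L - 1):
                    a, b, c = poly.sites[idx - 1], poly.sites[idx], poly.sites[idx + 1]
                    if _is_corner(a, b, c):
                        tgt = _corner_target(geom, a, b, c)
                        if tgt is not None and tgt not in occ:
                            events.append(Event("kink", params.k_K, (pid, idx, tgt)))
            # fragmentation: every internal bond
            if params.k_f > 0:
                for bond in range(L - 1):
                    events.append(Event("fragment", params.k_f, (pid, bond)))
        # joining: admissible endpoint pairs (each unordered pair once)
        if params.k_H > 0:
            ends = [(0, poly.sites[0])] if L == 1 else [
                (0, poly.sites[0]), (L - 1, poly.sites[-1])
            ]
            for endidx, site in ends:
                for tgt in geom.neighbours(site):
                    if tgt not in occ:
                        continue
                    qid, qidx = occ[tgt]
                    if qid == pid:
                        continue
                    q = state.polymers[qid]
                    if q.length > 1 and qidx not in (0, q.length - 1):
                        continue  # interior monomers never re-bond
                    key = tuple(sorted([(pid, endidx), (qid, qidx)]))
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    if _bond_eligible(poly.states[endidx], q.states[qidx]):
                        events.append(Event("join", params.k_H,
                                            (pid, endidx, qid, qidx)))
        # efflux: whole object touching a boundary plane
        if params.k_out > 0 and geom.boundary_mode == "slab":
            if any(geom.is_boundary(s) for s in poly.sites):
                events.append(
                    Event("efflux", params.k_out / L ** params.efflux_exponent,
                          (pid,))
                )
    # influx on empty boundary-plane sites
    if params.k_in > 0 and geom.boundary_mode == "slab":
        for site in geom.boundary_sites():
            if site not in occ:
                events.append(Event("influx", params.k_in, (site,)))
    return events


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------

def _apply(state: LatticeState, params: KmcParams, ev: Event,
           rng: np.random.Generator) -> None:
    geom = state.geometry
    polymers = state.polymers
    if ev.kind == "diffuse":
        pid, tgt = ev.data
        poly = polymers[pid]
        del state.occupancy[poly.sites[0]]
        poly.sites[0] = tgt
        state.occupancy[tgt] = (pid, 0)
    elif ev.kind == "activate":
        pid, idx = ev.data
        polymers[pid].states[idx] = ACTIVE
    elif ev.kind == "latentize":
        pid, idx = ev.data
        polymers[pid].states[idx] = LATENT
    elif ev.kind == "reptate":
        pid, endidx = ev.data
        poly = polymers[pid]
        head = poly.sites[endidx]
        empties = [t for t in geom.neighbours(head)
                   if t not in state.occupancy]
        tgt = empties[rng.integers(len(empties))]
        if endidx != 0:
            poly.sites.reverse()
            poly.states.reverse()
        # head advances to tgt; everyone shifts toward the head
        del state.occupancy[poly.sites[-1]]
        poly.sites[1:] = poly.sites[:-1]
        poly.sites[0] = tgt
        for i, s in enumerate(poly.sites):
            state.occupancy[s] = (pid, i)
    elif ev.kind == "end_rotate":
        pid, endidx, tgt = ev.data
        poly = polymers[pid]
        del state.occupancy[poly.sites[endidx]]
        poly.sites[endidx] = tgt
        state.occupancy[tgt] = (pid, endidx)
    elif ev.kind == "kink":
        pid, idx, tgt = ev.data
        poly = polymers[pid]
        del state.occupancy[poly.sites[idx]]
        poly.sites[idx] = tgt
        state.occupancy[tgt] = (pid, idx)
    elif ev.kind == "fragment":
        pid, bond = ev.data
        poly = state.remove_polymer(pid)
        left = Polymer(sites=poly.sites[: bond + 1], states=poly.states[: bond + 1])
        right = Polymer(sites=poly.sites[bond + 1 :], states=poly.states[bond + 1 :])
        state.add_polymer(left)
        state.add_polymer(right)
    elif ev.kind == "join":
        pid, endidx, qid, qidx = ev.data
        p = state.remove_polymer(pid)
        q = state.remove_polymer(qid)
        if endidx == 0:
            p.sites.reverse(); p.states.reverse()
        if qidx != 0:
            q.sites.reverse(); q.states.reverse()
        state.add_polymer(Polymer(sites=p.sites + q.sites,
                                  states=p.states + q.states))
    elif ev.kind == "efflux":
        (pid,) = ev.data
        poly = state.remove_polymer(pid)
        state.mass_efflux += poly.length
    elif ev.kind == "influx":
        (site,) = ev.data
        state.add_polymer(Polymer(sites=[site], states=[INACTIVE]))
        state.mass_influx += 1
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {ev.kind}")


def gillespie_step(
    state: LatticeState,
    params: KmcParams,
    rng: np.random.Generator,
    events: Optional[List[Event]] = None,
) -> float:
    """One exact Gillespie step: Exp waiting time, rate-proportional choice.

    Mutates ``state`` in place and returns the time increment.  Raises
    :class:`FrozenStateError` when no event has positive rate.
    """
    if events is None:
        events = enumerate_events(state, params)
    rates = np.array([e.rate for e in events])
    R = rates.sum()
    if R <= 0:
        raise FrozenStateError("no events available; state is frozen")
    dt = rng.exponential(1.0 / R)
    choice = rng.choice(len(events), p=rates / R)
    ev = events[choice]
    _apply(state, params, ev, rng)
    state.t += dt
    state.event_counts[ev.kind] = state.event_counts.get(ev.kind, 0) + 1
    return dt
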