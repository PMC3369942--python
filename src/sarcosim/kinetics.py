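"""Stochastic events of the bundle model.

Events are driven by per-entity exponential clocks (a common-random-numbers
scheme): every myosin binding site, filament and crosslink candidate pair
owns its own RNG stream, keyed deterministically by (seed, subsystem,
entity ids). A clock fires when the integrated hazard since its last event
first exceeds an Exp(1) threshold drawn from the entity's stream. For a
constant hazard this reproduces the exact exponential waiting time; for
state-dependent hazards (crosslinking, severing) it is the exact
first-passage construction of an inhomogeneous Poisson process. Because no
draw depends on the time step, refining dt shifts event times by O(dt)
instead of resampling the whole realization — seeded runs converge under dt
refinement, and identical (params, seed) reproduce the event log exactly.

Plus-end crosslinking is sampled between mobile units rather than between
individual filament pairs: all members of a cluster share one plus-end
coordinate, so the ``n_a * n_b`` independent candidate pairs between two
units collapse exactly into a single merge event with total hazard
``n_a * n_b * k(d)``. This is equivalent in distribution to per-pair
sampling and avoids scanning quadratically many coincident pairs inside
large clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    SITE_SIGMA,
    BundleState,
    Cluster,
    Params,
    _wrap_unchecked,
    min_image,
    wrap,
)

__all__ = [
    "EventLog",
    "EventClocks",
    "crosslink_rate",
    "sample_crosslink_events",
    "merge_clusters",
    "apply_links",
    "dissociate_filament",
    "myosin_attach_detach",
    "myosin_detach",
    "myosin_attach",
    "turnover",
    "sever",
    "init_bundle",
    "draw_lengths",
    "sample_severing_lengths",
    "make_streams",
]

CROSSLINK_CUTOFF = 4.0  # eligibility radius in units of delta; k(4 delta) < 2e-7 k0

# subsystem codes for entity-stream seeding
_DOM_SITE, _DOM_TURN, _DOM_SEVER, _DOM_DISS, _DOM_XLINK = 1, 2, 3, 4, 5


@dataclass
class EventLog:
    """Append-only per-step event records: (time, kind, participant ids, aux)."""

    records: list = field(default_factory=list)

    def add(self, time: float, kind: str, ids: tuple, aux: float = 0.0) -> None:
        self.records.append((time, kind, ids, aux))

    def __len__(self) -> int:
        return len(self.records)


def _entity_rng(seed: int, domain: int, *ids: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, domain, *ids)))


class EventClocks:
    """Per-entity event clocks; lazily initialized per subsystem."""

    def __init__(self, params: Params):
        self.params = params
        self.seed = params.seed
        self.site_rng = None
        self.site_next = None  # next attach (unbound) / detach (bound) time
        self.was_bound = None
        self.cat_rng = None
        self.next_cat = None
        self.sever_rng = None
        self.sever_H = None
        self.sever_thresh = None
        self.diss_rng = None
        self.diss_H = None
        self.diss_thresh = None
        self.xl: dict = {}  # (rep_a, rep_b) -> [gen, hazard integral, threshold]

    def ensure_myosin(self, t: float) -> None:
        if self.site_rng is not None:
            return
        m = self.params.N_myosin
        k_on = self.params.k_on
        self.site_rng = [
            [_entity_rng(self.seed, _DOM_SITE, j, s) for s in (0, 1)]
            for j in range(m)
        ]
        self.site_next = np.full((m, 2), np.inf)
        if k_on > 0:
            for j in range(m):
                for s in (0, 1):
                    self.site_next[j, s] = t + self.site_rng[j][s].exponential(
                        1.0 / k_on
                    )
        self.was_bound = np.zeros((m, 2), dtype=bool)

    def ensure_turnover(self, t: float, n: int) -> None:
        if self.cat_rng is not None:
            return
        k = self.params.k_turnover
        self.cat_rng = [_entity_rng(self.seed, _DOM_TURN, i) for i in range(n)]
        self.next_cat = np.array(
            [t + r.exponential(1.0 / k) for r in self.cat_rng]
        )

    def ensure_sever(self, n: int) -> None:
        if self.sever_rng is not None:
            return
        self.sever_rng = [_entity_rng(self.seed, _DOM_SEVER, i) for i in range(n)]
        self.sever_H = np.zeros(n)
        self.sever_thresh = np.array([r.exponential() for r in self.sever_rng])

    def ensure_diss(self, n: int) -> None:
        if self.diss_rng is not None:
            return
        self.diss_rng = [_entity_rng(self.seed, _DOM_DISS, i) for i in range(n)]
        self.diss_H = np.zeros(n)
        self.diss_thresh = np.array([r.exponential() for r in self.diss_rng])


def clocks(state: BundleState) -> EventClocks:
    ck = getattr(state, "event_clocks", None)
    if ck is None:
        ck = EventClocks(state.params)
        state.event_clocks = ck
    return ck


def crosslink_rate(d, k0, delta):
    """Gaussian plus-end crosslinking rate kernel k0 * exp(-(d/delta)^2)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    return k0 * np.exp(-np.square(np.asarray(d, dtype=float) / delta))


def _unit_table(state: BundleState):
    """Plus-end coordinate, weight and lowest member id of every mobile unit."""
    free = np.nonzero(state.cluster_of < 0)[0]
    cids = sorted(state.clusters)
    zs = np.concatenate(
        [
            np.array([state.clusters[c].z_pos for c in cids]),
            state.plus_pos[free],
        ]
    )
    ns = np.concatenate(
        [
            np.array([len(state.clusters[c].members) for c in cids], dtype=float),
            np.ones(free.size),
        ]
    )
    rep = np.concatenate(
        [
            np.array([min(state.clusters[c].members) for c in cids], dtype=np.int64),
            free.astype(np.int64),
        ]
    )
    return zs, ns, rep


def sample_crosslink_events(state: BundleState, dt: float):
    """Advance the crosslink clocks of all unit pairs within the capture
    cutoff and return the pairs that fire this step, as (lowest member id,
    lowest member id) tuples; each implies a merge. Pairs within one cluster
    are never eligible."""
    p = state.params
    if p.k0 <= 0:
        return []
    if p.k0 * dt >= 0.1:
        warnings.warn("per-pair crosslink hazard per step exceeds 0.1; reduce dt")
    zs, ns, rep = _unit_table(state)
    K = zs.size
    if K < 2:
        return []
    cutoff = CROSSLINK_CUTOFF * p.delta
    order = np.argsort(zs, kind="stable")
    zs_s, ns_s, rep_s = zs[order], ns[order], rep[order]
    # sorted sweep with ring wrap: compare each unit to successors within cutoff
    zs_ext = np.concatenate([zs_s, zs_s + p.L_sys])
    hi = np.searchsorted(zs_ext, zs_s + cutoff, side="right")
    counts = np.minimum(hi - np.arange(K) - 1, K - 1)
    tot = int(counts.sum())
    if tot == 0:
        return []
    i = np.repeat(np.arange(K), counts)
    step_in_run = np.arange(tot) - np.repeat(np.cumsum(counts) - counts, counts)
    b = i + 1 + step_in_run
    j = b % K
    d = zs_ext[b] - zs_s[i]
    # de-duplicate pairs seen from both sides of the wrap
    key = np.minimum(rep_s[i], rep_s[j]) * (state.sigma.size + 1) + np.maximum(
        rep_s[i], rep_s[j]
    )
    _, keep = np.unique(key, return_index=True)
    i, j, d = i[keep], j[keep], d[keep]
    hazard = ns_s[i] * ns_s[j] * crosslink_rate(d, p.k0, p.delta) * dt
    ck = clocks(state)
    out = []
    for a, bb, h in zip(rep_s[i], rep_s[j], hazard):
        pair = (int(min(a, bb)), int(max(a, bb)))
        slot = ck.xl.get(pair)
        if slot is None:
            gen = _entity_rng(ck.seed, _DOM_XLINK, *pair)
            slot = [gen, 0.0, gen.exponential()]
            ck.xl[pair] = slot
        slot[1] += h
        if slot[1] >= slot[2]:
            slot[1] = 0.0
            slot[2] = slot[0].exponential()
            out.append(pair)
    out.sort()
    return out


def merge_clusters(a: Cluster, b: Cluster, L_sys: float) -> Cluster:
    """Merge two clusters; the new Z-band coordinate is the filament-number
    weighted circular average of the two, members are the union."""
    if a is b or a.id == b.id:
        raise ValueError("cannot merge a cluster with itself")
    na, nb = len(a.members), len(b.members)
    z_new = wrap(a.z_pos + nb / (na + nb) * min_image(b.z_pos - a.z_pos, L_sys), L_sys)
    return Cluster(id=min(a.id, b.id), z_pos=z_new, members=a.members | b.members)


def _ensure_cluster(state: BundleState, fid: int) -> int:
    cid = int(state.cluster_of[fid])
    if cid >= 0:
        return cid
    return state.new_cluster(float(state.plus_pos[fid]), {int(fid)})


def apply_links(state: BundleState, pairs, log: EventLog | None = None) -> None:
    """Apply sampled crosslink events as iterated pairwise cluster merges in
    ascending (id, id) order; simultaneous multi-way merges are associative
    up to floating-point roundoff."""
    L = state.params.L_sys
    for fa, fb in sorted(pairs):
        ca = _ensure_cluster(state, fa)
        cb = _ensure_cluster(state, fb)
        if ca == cb:
            continue
        a, b = state.clusters[ca], state.clusters[cb]
        merged = merge_clusters(a, b, L)
        dead = cb if merged.id == ca else ca
        state.clusters.pop(dead)
        state.clusters[merged.id] = merged
        members = np.fromiter(merged.members, dtype=np.int64)
        state.cluster_of[members] = merged.id
        state.plus_pos[members] = merged.z_pos
        state.touch_topology()
        if log is not None:
            log.add(state.time, "merge", (fa, fb), merged.z_pos)


def dissociate_filament(state: BundleState, dt: float,
                        log: EventLog | None = None) -> None:
    """Clustered filaments spontaneously leave their cluster (rate k_diss),
    becoming free units at unchanged position."""
    k = state.params.k_diss
    if k <= 0:
        return
    ck = clocks(state)
    ck.ensure_diss(state.sigma.size)
    clustered = state.cluster_of >= 0
    ck.diss_H[clustered] += k * dt
    for fid in np.nonzero(clustered & (ck.diss_H >= ck.diss_thresh))[0]:
        fid = int(fid)
        ck.diss_H[fid] = 0.0
        ck.diss_thresh[fid] = ck.diss_rng[fid].exponential()
        cid = int(state.cluster_of[fid])
        cl = state.clusters[cid]
        cl.members.discard(fid)
        state.cluster_of[fid] = -1
        if not cl.members:
            state.clusters.pop(cid)
        state.touch_topology()
        if log is not None:
            log.add(state.time, "dissociate", (fid,), cid)


def _sync_external_unbinds(state: BundleState, ck: EventClocks) -> None:
    """Sites unbound outside the attach/detach clocks (end drop-off, severing,
    turnover) need a fresh attach clock."""
    bound = state.my_bound >= 0
    newly = ck.was_bound & ~bound
    if np.any(newly):
        k_on = state.params.k_on
        for j, s in zip(*np.nonzero(newly)):
            ck.site_next[j, s] = (
                state.time + ck.site_rng[j][s].exponential(1.0 / k_on)
                if k_on > 0
                else np.inf
            )
    ck.was_bound = bound.copy()


def myosin_detach(state: BundleState, dt: float,
                  log: EventLog | None = None) -> None:
    """Bound sites unbind as Poisson processes with rate k_off (per-site
    clocks drawn at binding time)."""
    p = state.params
    if state.my_center.size == 0:
        return
    ck = clocks(state)
    ck.ensure_myosin(state.time)
    _sync_external_unbinds(state, ck)
    if p.k_off <= 0:
        return
    fire = (state.my_bound >= 0) & (ck.site_next <= state.time + dt)
    if not np.any(fire):
        return
    k_on = p.k_on
    for j, s in zip(*np.nonzero(fire)):
        state.my_bound[j, s] = -1
        state.my_offset[j, s] = 0.0
        ck.was_bound[j, s] = False
        ck.site_next[j, s] = (
            state.time + ck.site_rng[j][s].exponential(1.0 / k_on)
            if k_on > 0
            else np.inf
        )
        if log is not None:
            log.add(state.time, "my_detach", (int(j), int(s)), 0.0)


def myosin_attach(state: BundleState, dt: float,
                  log: EventLog | None = None) -> None:
    """Unbound sites attempt attachment at rate k_on; a firing site binds a
    uniformly chosen eligible filament (matching polarity — left site
    sigma=-1, right site sigma=+1 — whose body covers the site's lab
    position), or redraws its clock if none is eligible."""
    p = state.params
    if state.my_center.size == 0 or p.k_on <= 0:
        return
    ck = clocks(state)
    ck.ensure_myosin(state.time)
    _sync_external_unbinds(state, ck)
    fire = (state.my_bound < 0) & (ck.site_next <= state.time + dt)
    if not np.any(fire):
        return
    xsites = state.site_positions()
    L = p.L_sys
    for j, s in zip(*np.nonzero(fire)):
        rng = ck.site_rng[j][s]
        x = xsites[j, s]
        offs = _wrap_unchecked(state.sigma * (state.plus_pos - x), L)
        elig = np.nonzero((state.sigma == SITE_SIGMA[s]) & (offs <= state.length))[0]
        if elig.size:
            pick = int(elig[rng.integers(elig.size)])
            state.my_bound[j, s] = pick
            state.my_offset[j, s] = offs[pick]
            ck.was_bound[j, s] = True
            ck.site_next[j, s] = (
                state.time + rng.exponential(1.0 / p.k_off)
                if p.k_off > 0
                else np.inf
            )
            if log is not None:
                log.add(state.time, "my_attach", (int(j), int(s), pick), offs[pick])
        else:
            ck.site_next[j, s] = state.time + rng.exponential(1.0 / p.k_on)


def myosin_attach_detach(state: BundleState, dt: float,
                         log: EventLog | None = None) -> None:
    """Detachments then attachments, matching the per-step event ordering."""
    myosin_detach(state, dt, log)
    myosin_attach(state, dt, log)


def draw_lengths(params: Params, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample filament lengths for the configured length_mode."""
    m = params.ell_mean
    mode = params.length_mode
    if mode in ("monodisperse", "severing"):
        return np.full(n, m)
    if mode == "lognormal":
        s = params.sigma_ell * m
        if s == 0:
            return np.full(n, m)
        mu = np.log(m * m / np.sqrt(m * m + s * s))
        slog = np.sqrt(np.log(1.0 + (s * s) / (m * m)))
        return rng.lognormal(mean=mu, sigma=slog, size=n)
    if mode == "exponential":
        return rng.exponential(scale=m, size=n)
    raise ValueError(f"unknown length_mode {mode!r}")


def turnover(state: BundleState, dt: float, log: EventLog | None = None) -> None:
    """Filament catastrophes: complete depolymerization at rate k_turnover,
    balanced by de novo nucleation of a free replacement filament at a
    uniform random position, so the filament count is conserved."""
    p = state.params
    if p.k_turnover <= 0:
        return
    if p.length_mode == "severing":
        raise ValueError("turnover is not defined in severing mode")
    n = state.sigma.size
    ck = clocks(state)
    ck.ensure_turnover(state.time, n)
    for fid in np.nonzero(ck.next_cat <= state.time + dt)[0]:
        fid = int(fid)
        rng = ck.cat_rng[fid]
        ck.next_cat[fid] = state.time + rng.exponential(1.0 / p.k_turnover)
        on_fil = state.my_bound == fid
        state.my_bound[on_fil] = -1
        state.my_offset[on_fil] = 0.0
        cid = int(state.cluster_of[fid])
        if cid >= 0:
            cl = state.clusters[cid]
            cl.members.discard(fid)
            if not cl.members:
                state.clusters.pop(cid)
            state.cluster_of[fid] = -1
        state.touch_topology()
        state.plus_pos[fid] = rng.uniform(0.0, p.L_sys)
        state.sigma[fid] = 1 if rng.random() < 0.5 else -1
        state.length[fid] = draw_lengths(p, rng, 1)[0]
        if log is not None:
            log.add(state.time, "turnover", (fid,), state.plus_pos[fid])


def sever(state: BundleState, dt: float, log: EventLog | None = None) -> None:
    """Length-proportional severing: a filament of length l is cut with rate
    r_sever * l at a uniform position; the minus-end fragment depolymerizes,
    so the new length is the (uniform) distance from the cut to the plus end.
    Sites stranded beyond the cut detach; cluster membership is unchanged."""
    p = state.params
    if p.r_sever <= 0:
        raise ValueError("sever requires r_sever > 0")
    ck = clocks(state)
    ck.ensure_sever(state.sigma.size)
    ck.sever_H += p.r_sever * state.length * dt
    fired = np.nonzero(ck.sever_H >= ck.sever_thresh)[0]
    for fid in fired:
        fid = int(fid)
        rng = ck.sever_rng[fid]
        ck.sever_H[fid] = 0.0
        ck.sever_thresh[fid] = rng.exponential()
        # uniform cut; (1 - U) keeps the surviving length strictly positive
        new_len = state.length[fid] * (1.0 - rng.random())
        state.length[fid] = new_len
        stranded = (state.my_bound == fid) & (state.my_offset > new_len)
        state.my_bound[stranded] = -1
        state.my_offset[stranded] = 0.0
        if log is not None:
            log.add(state.time, "sever", (fid,), new_len)


def sample_severing_lengths(
    v_tread: float,
    r_sever: float,
    n: int,
    rng: np.random.Generator,
    t_relax: float | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Stationary filament lengths from the severing process run standalone.

    n filaments grow at v_tread and are cut by the length-proportional
    severing kinetics until the ensemble relaxes (default ~20 mean
    lifetimes); returns the final length sample. ``rng`` seeds the ensemble.
    """
    if v_tread <= 0 or r_sever <= 0:
        raise ValueError("v_tread and r_sever must be > 0")
    lam = np.sqrt(v_tread / r_sever)
    if t_relax is None:
        t_relax = 20.0 / np.sqrt(v_tread * r_sever)
    if dt is None:
        dt = 0.02 / (r_sever * 5.0 * lam)  # keeps per-step cut hazard small
    params = Params(
        N_actin=n,
        N_myosin=0,
        v_tread=v_tread,
        length_mode="severing",
        r_sever=r_sever,
        ell_mean=lam,
        L_sys=max(20.0, 3.0 * lam),
        dt=dt,
        seed=int(rng.integers(2**31 - 1)),
    )
    state = BundleState(params)
    state.length[:] = lam
    for _ in range(int(round(t_relax / dt))):
        state.length += v_tread * dt
        sever(state, dt)
        state.time += dt
    return state.length.copy()


def make_streams(seed: int) -> dict[str, np.random.Generator]:
    """Initial-condition RNG stream, spawned deterministically from the seed
    (event randomness lives in per-entity clocks, see EventClocks)."""
    (child,) = np.random.SeedSequence(seed).spawn(1)
    return {"init": np.random.default_rng(child)}


def init_bundle(params: Params, rng: np.random.Generator | None = None) -> BundleState:
    """Initial condition: filaments at uniform random positions with fair-coin
    orientations, each its own singleton cluster; lengths per length_mode;
    myosins at uniform random positions, unbound."""
    streams = make_streams(params.seed)
    if rng is None:
        rng = streams["init"]
    state = BundleState(params, rng=rng)
    state.streams = streams
    n = params.N_actin
    state.plus_pos[:] = rng.uniform(0.0, params.L_sys, size=n)
    state.sigma[:] = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    state.length[:] = draw_lengths(params, rng, n)
    for i in range(n):
        state.new_cluster(float(state.plus_pos[i]), {i})
    if params.N_myosin:
        state.my_center[:] = rng.uniform(0.0, params.L_sys, size=params.N_myosin)
    return state
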