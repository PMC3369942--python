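"""Periodic-ring geometry and the core state containers of the bundle model.

The model lives on a one-dimensional ring of circumference ``L_sys`` with
periodic boundary conditions. All coordinates are continuous reals kept in
the half-open interval ``[0, L_sys)``. Simulation units: lengths in units of
the mean actin filament length ``ell_mean``, time in units of
``ell_mean / v_tread`` (filament length over treadmilling speed), forces in
units of ``gamma * ell_mean * v_tread``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "wrap",
    "min_image",
    "overlap",
    "pairwise_overlap",
    "Params",
    "Filament",
    "Cluster",
    "Myosin",
    "MyosinSite",
    "BundleState",
    "LENGTH_MODES",
]

LENGTH_MODES = ("monodisperse", "lognormal", "exponential", "severing")


def wrap(x, L_sys):
    """Map a coordinate (scalar or array) onto the ring ``[0, L_sys)``.

    The boundary convention is half-open: ``wrap(L_sys, L_sys) == 0``.
    """
    if L_sys <= 0:
        raise ValueError("L_sys must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinate")
    return _wrap_unchecked(x, L_sys)


def _wrap_unchecked(x, L_sys):
    """wrap() without the input validation, for hot inner loops."""
    x = np.asarray(x, dtype=float)
    r = x - np.floor(x / L_sys) * L_sys
    # floating point can land exactly on L_sys (e.g. tiny negative x)
    r = np.where(r >= L_sys, r - L_sys, r)
    return float(r) if r.ndim == 0 else r


def _wrapf(x: float, L_sys: float) -> float:
    """Scalar fast path of wrap()."""
    r = x % L_sys
    return r if r < L_sys else 0.0


def min_image(dx, L_sys):
    """Signed minimum-image displacement in ``[-L_sys/2, L_sys/2)``.

    The tie at exactly ``L_sys/2`` is broken toward the negative image so
    the convention is deterministic.
    """
    if L_sys <= 0:
        raise ValueError("L_sys must be positive")
    return wrap(np.asarray(dx, dtype=float) + 0.5 * L_sys, L_sys) - 0.5 * L_sys


def _span(plus_pos: float, sigma: int, length: float) -> tuple[float, float]:
    """Unwrapped interval (lo, hi) occupied by a filament.

    A filament's body extends from its plus end opposite to its orientation:
    sigma=+1 spans [plus_pos - length, plus_pos], sigma=-1 spans
    [plus_pos, plus_pos + length].
    """
    if sigma == 1:
        return plus_pos - length, plus_pos
    return plus_pos, plus_pos + length


def overlap(f1: "Filament", f2: "Filament", L_sys: float) -> float:
    """Mutual projection overlap length of two filaments on the ring.

    Computed by enumerating periodic images of the second span and summing
    interval intersections; images are disjoint for lengths < L_sys, so the
    sum is the exact arc-intersection measure. Symmetric and invariant under
    joint translation across the boundary.
    """
    lo1, hi1 = _span(f1.plus_pos, f1.sigma, f1.length)
    lo2, hi2 = _span(f2.plus_pos, f2.sigma, f2.length)
    base = lo2 + np.floor((lo1 - lo2) / L_sys) * L_sys
    total = 0.0
    for k in (-1.0, 0.0, 1.0, 2.0):
        lo = base + k * L_sys
        total += max(0.0, min(hi1, lo + (hi2 - lo2)) - max(lo1, lo))
    return total


def pairwise_overlap(lo: np.ndarray, hi: np.ndarray, L_sys: float) -> np.ndarray:
    """Symmetric matrix of ring-overlap lengths for N unwrapped spans."""
    base = lo[None, :] + np.floor((lo[:, None] - lo[None, :]) / L_sys) * L_sys
    ln = hi - lo
    total = np.zeros((lo.size, lo.size))
    for k in (-1.0, 0.0, 1.0, 2.0):
        s = base + k * L_sys
        total += np.clip(
            np.minimum(hi[:, None], s + ln[None, :]) - np.maximum(lo[:, None], s),
            0.0,
            None,
        )
    np.fill_diagonal(total, 0.0)
    return total


@dataclass(frozen=True)
class Params:
    """All model constants, in simulation units (ℓ, ℓ/v_tread, γℓv_tread).

    Parameters
    ----------
    v_tread : treadmilling (net plus-end polymerization) speed; sets the
        time unit.
    gamma : cytosolic drag coefficient per unit filament length.
    zeta : inter-filament sliding friction per unit overlap length
        (0 disables the pairwise friction force).
    k0, delta : plus-end crosslinking rate amplitude and capture range of
        the Gaussian rate kernel k(d) = k0 exp(-(d/delta)^2).
    F_stall : active myosin force, equal to the stall force.
    v_my0 : unloaded myosin walking speed (used when my_mobility is None).
    my_mobility : optional motor mobility mu; when set, the unloaded walking
        speed is derived as mu * F_stall, tying walking speed to active
        force as for a motor whose duty cycle sets both.
    k_on, k_off : myosin binding-site attach/detach Poisson rates.
    L_my : bipolar myosin filament length (distance between its two sites).
    ell_mean : mean actin filament length (the length unit).
    sigma_ell : relative standard deviation of the filament length
        distribution (lognormal mode).
    k_turnover : per-filament catastrophe (complete depolymerization +
        renewal) rate.
    r_sever : severing-agent binding rate per unit filament length.
    k_diss : optional single-filament dissociation rate from a cluster
        (0 = irreversible crosslinking).
    L_sys : ring circumference. N_actin, N_myosin : filament counts.
    dt : time step. seed : RNG seed. length_mode : one of
    {monodisperse, lognormal, exponential, severing}.
    """

    v_tread: float = 1.0
    gamma: float = 1.0
    zeta: float = 0.0
    k0: float = 10.0
    delta: float = 0.1
    F_stall: float = 0.0
    v_my0: float = 0.5
    my_mobility: Optional[float] = None
    k_on: float = 10.0
    k_off: float = 10.0
    L_my: float = 0.5
    ell_mean: float = 1.0
    sigma_ell: float = 0.0
    k_turnover: float = 0.0
    r_sever: float = 0.0
    k_diss: float = 0.0
    L_sys: float = 20.0
    N_actin: int = 100
    N_myosin: int = 50
    dt: float = 1e-3
    seed: int = 0
    length_mode: str = "monodisperse"

    def __post_init__(self):
        nonneg = (
            "v_tread gamma zeta k0 F_stall v_my0 k_on k_off L_my ell_mean "
            "sigma_ell k_turnover r_sever k_diss N_actin N_myosin"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.L_sys <= 2 * self.ell_mean:
            raise ValueError("L_sys must exceed 2 * ell_mean")
        if self.length_mode not in LENGTH_MODES:
            raise ValueError(f"length_mode must be one of {LENGTH_MODES}")
        if self.length_mode == "severing":
            if self.r_sever <= 0:
                raise ValueError("length_mode='severing' requires r_sever > 0")
            if self.k_turnover != 0:
                raise ValueError("length_mode='severing' requires k_turnover = 0")
        if self.my_mobility is not None and self.my_mobility < 0:
            raise ValueError("my_mobility must be >= 0")

    @property
    def v_my_unloaded(self) -> float:
        """Effective unloaded walking speed (mu*F_stall if mobility is set)."""
        if self.my_mobility is not None:
            return self.my_mobility * self.F_stall
        return self.v_my0

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Filament:
    """A rigid polar rod; its body is derived from (plus_pos, sigma, length)."""

    id: int
    sigma: int  # +1: plus end faces +x, -1: faces -x
    length: float
    plus_pos: float
    cluster_id: Optional[int] = None

    def span(self) -> tuple[float, float]:
        return _span(self.plus_pos, self.sigma, self.length)


@dataclass
class Cluster:
    """A Z-band: a crosslinking band pinning the plus ends of its members."""

    id: int
    z_pos: float
    members: set = field(default_factory=set)


@dataclass
class MyosinSite:
    bound_filament: Optional[int] = None
    offset: float = 0.0  # distance from the bound filament's plus end


@dataclass
class Myosin:
    """Bipolar myosin filament: a rigid connector with two polarity-specific
    binding sites, the left one (center - L_my/2) binding only sigma=-1
    filaments and the right one (center + L_my/2) binding only sigma=+1."""

    id: int
    center: float
    sites: tuple = (None, None)


# site index conventions: site 0 = left (binds sigma=-1), site 1 = right
SITE_SIGMA = np.array([-1, 1], dtype=np.int8)
SITE_SIDE = np.array([-0.5, 0.5])  # lab position = center + SITE_SIDE * L_my


class BundleState:
    """Full system snapshot with array-backed storage.

    Filament arrays are indexed by filament id (ids are stable; turnover
    reuses the slot of the removed filament). Clusters are kept in a dict
    keyed by cluster id; ``cluster_of[i] == -1`` marks a free filament.
    Myosin site arrays have shape (N_myosin, 2), site 0 binding sigma=-1
    and site 1 binding sigma=+1 filaments; ``bound_fil == -1`` is unbound.
    """

    def __init__(self, params: Params, rng: np.random.Generator | None = None):
        self.params = params
        self.time = 0.0
        n = params.N_actin
        m = params.N_myosin
        self.sigma = np.ones(n, dtype=np.int8)
        self.length = np.full(n, params.ell_mean)
        self.plus_pos = np.zeros(n)
        self.cluster_of = np.full(n, -1, dtype=np.int64)
        self.clusters: dict[int, Cluster] = {}
        self._next_cluster_id = 0
        self.my_center = np.zeros(m)
        self.my_bound = np.full((m, 2), -1, dtype=np.int64)
        self.my_offset = np.zeros((m, 2))
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        # bumped on every cluster-membership change; lets the mechanics cache
        # its mobile-unit partition between steps
        self.topo_version = 0

    def touch_topology(self) -> None:
        self.topo_version += 1

    # -- construction helpers -------------------------------------------------

    def new_cluster(self, z_pos: float, members: set) -> int:
        cid = self._next_cluster_id
        self._next_cluster_id += 1
        self.clusters[cid] = Cluster(cid, wrap(z_pos, self.params.L_sys), set(members))
        for i in self.clusters[cid].members:
            self.cluster_of[i] = cid
            self.plus_pos[i] = self.clusters[cid].z_pos
        self.touch_topology()
        return cid

    # -- views ----------------------------------------------------------------

    def filament(self, i: int) -> Filament:
        cid = int(self.cluster_of[i])
        return Filament(
            id=i,
            sigma=int(self.sigma[i]),
            length=float(self.length[i]),
            plus_pos=float(self.plus_pos[i]),
            cluster_id=None if cid < 0 else cid,
        )

    def myosin(self, j: int) -> Myosin:
        sites = tuple(
            MyosinSite(
                bound_filament=None if self.my_bound[j, s] < 0 else int(self.my_bound[j, s]),
                offset=float(self.my_offset[j, s]),
            )
            for s in (0, 1)
        )
        return Myosin(id=j, center=float(self.my_center[j]), sites=sites)

    def spans(self) -> tuple[np.ndarray, np.ndarray]:
        """Unwrapped (lo, hi) arrays for every filament body."""
        lo = np.where(self.sigma == 1, self.plus_pos - self.length, self.plus_pos)
        hi = lo + self.length
        return lo, hi

    def site_positions(self) -> np.ndarray:
        """(M, 2) lab positions of all myosin binding sites, wrapped."""
        L = self.params.L_sys
        return _wrap_unchecked(
            self.my_center[:, None] + SITE_SIDE[None, :] * self.params.L_my, L
        )

    def n_free(self) -> int:
        return int(np.sum(self.cluster_of < 0))

    # -- invariant checks ------------------------------------------------------

    def validate(self) -> None:
        """Raise AssertionError on any violated structural invariant."""
        p = self.params
        L = p.L_sys
        assert np.all((self.plus_pos >= 0) & (self.plus_pos < L)), "plus_pos out of ring"
        assert np.all(self.length > 0), "non-positive filament length"
        assert np.all(np.isin(self.sigma, (-1, 1))), "bad orientation"
        seen: set[int] = set()
        for cid, cl in self.clusters.items():
            assert len(cl.members) >= 1, "empty cluster"
            assert 0 <= cl.z_pos < L, "cluster z_pos out of ring"
            assert not (cl.members & seen), "filament in two clusters"
            seen |= cl.members
            for i in cl.members:
                assert self.cluster_of[i] == cid, "cluster_of mismatch"
                assert self.plus_pos[i] == cl.z_pos, "member plus_pos not at z_pos"
        for i in np.nonzero(self.cluster_of >= 0)[0]:
            assert int(self.cluster_of[i]) in self.clusters, "dangling cluster_id"
        if self.my_center.size:
            assert np.all((self.my_center >= 0) & (self.my_center < L)), "myosin out of ring"
            bound = self.my_bound >= 0
            assert np.all(self.my_offset[bound] >= 0), "negative offset"
            fil = self.my_bound[bound]
            assert np.all(self.my_offset[bound] <= self.length[fil] + 1e-12), (
                "offset beyond filament length"
            )
            # polarity-specific binding
            for s in (0, 1):
                b = self.my_bound[:, s]
                ok = b < 0
                assert np.all(self.sigma[b[~ok]] == SITE_SIGMA[s]), "polarity violation"
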