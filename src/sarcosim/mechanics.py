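"""Deterministic per-step mechanics of the bundle.

Inertia is negligible at these scales, so every time step solves an exact,
quasi-static force balance that is linear in the unknown velocities of all
mobile units (crosslinked clusters and free filaments). Force terms:

* cytosolic drag ``-gamma * l_m * u_m`` on each filament's monomers, where
  ``u_m = V_unit - sigma_m * v_tread`` is the monomer velocity (the plus end
  leads the monomers by the treadmilling speed);
* optional inter-filament sliding friction ``-zeta * O_mn * (u_m - u_n)``
  proportional to the mutual span overlap ``O_mn``;
* myosin pair forces from a linear force-velocity relation, eliminated
  analytically into a symmetric velocity coupling plus a constant bias.

The resulting system ``A V = b`` is symmetric positive definite and solved
directly; the only discretization error is explicit-Euler advection of
positions and event timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BundleState, _wrap_unchecked, _wrapf, pairwise_overlap

__all__ = [
    "MobileUnit",
    "ForceSystem",
    "monomer_velocity",
    "single_cluster_velocity",
    "myosin_pair_force",
    "assemble_force_system",
    "solve_velocities",
    "advance",
]


@dataclass
class MobileUnit:
    unit_id: int
    kind: str  # "cluster" | "free_filament"
    ref: int  # cluster id or filament id
    members: np.ndarray  # filament ids


@dataclass
class ForceSystem:
    """Linear force balance ``A V = b`` over mobile-unit velocities.

    ``A`` has units of force per speed, ``b`` of force; ``unit_of[m]`` maps
    filament ``m`` to its row/column.
    """

    A: np.ndarray
    b: np.ndarray
    units: list
    unit_of: np.ndarray


def monomer_velocity(unit_velocity, sigma, v_tread):
    """Monomer (material) velocity of a filament whose plus end moves with
    its mobile unit: the plus end leads the monomers by sigma * v_tread."""
    return unit_velocity - sigma * v_tread


def single_cluster_velocity(lengths_plus, lengths_minus, v_tread):
    """Closed-form Z-band velocity of an isolated cluster.

    Local force balance of the cytosolic drag on all member filaments,
    ``sum gamma * l_m * (V - sigma_m * v) = 0``, gives
    ``V = v * (sum l_+ - sum l_-) / (sum l_+ + sum l_-)``.
    """
    lp = np.asarray(lengths_plus, dtype=float)
    lm = np.asarray(lengths_minus, dtype=float)
    tot = lp.sum() + lm.sum()
    if tot <= 0:
        raise ValueError("cluster must contain at least one filament")
    return v_tread * (lp.sum() - lm.sum()) / tot


def myosin_pair_force(sigma_a, sigma_b, u_a, u_b, F_stall, v_my0):
    """Solve the massless bipolar-myosin subsystem for one doubly-bound motor.

    Unknowns: internal loads F_a, F_b on the two heads, walking speeds
    w_a, w_b (relative to the filament monomers, toward the plus end) and
    the connector velocity V_m. Equations: head force balance
    ``sigma_a F_a + sigma_b F_b = 0``; rigid-connector kinematics
    ``V_m = u_a + sigma_a w_a = u_b + sigma_b w_b``; linear force-velocity
    ``w_i = v_my0 (1 - F_i / F_stall)`` (linearly extrapolated past stall,
    so strong opposing loads drive back-slipping).

    Returns ``(force on filament a, force on filament b, w_a, w_b, V_m)``.
    The filament forces are the reactions ``-sigma_i F_i`` and are exactly
    equal and opposite.
    """
    if F_stall == 0 or v_my0 == 0:
        w = v_my0
        vm = 0.5 * (u_a + sigma_a * w + u_b + sigma_b * w)
        return 0.0, 0.0, w, w, vm
    F_a = F_stall * sigma_a * ((u_a - u_b) + v_my0 * (sigma_a - sigma_b)) / (2.0 * v_my0)
    F_b = -sigma_a * sigma_b * F_a
    w_a = v_my0 * (1.0 - F_a / F_stall)
    w_b = v_my0 * (1.0 - F_b / F_stall)
    V_m = u_a + sigma_a * w_a
    return -sigma_a * F_a, -(-sigma_a * F_a), w_a, w_b, V_m


def build_units(state: BundleState) -> tuple[list, np.ndarray]:
    """Partition filaments into mobile units: clusters (ascending id), then
    free filaments (ascending id). Cached on the state's topology version."""
    cache = getattr(state, "_unit_cache", None)
    if cache is not None and cache[0] == state.topo_version:
        return cache[1], cache[2]
    units: list[MobileUnit] = []
    unit_of = np.empty(state.sigma.size, dtype=np.int64)
    for cid in sorted(state.clusters):
        members = np.fromiter(state.clusters[cid].members, dtype=np.int64)
        members.sort()
        unit_of[members] = len(units)
        units.append(MobileUnit(len(units), "cluster", cid, members))
    for fid in np.nonzero(state.cluster_of < 0)[0]:
        unit_of[fid] = len(units)
        units.append(MobileUnit(len(units), "free_filament", int(fid), np.array([fid])))
    state._unit_cache = (state.topo_version, units, unit_of)
    return units, unit_of


def assemble_force_system(state: BundleState) -> ForceSystem:
    """Assemble the symmetric linear force balance for the current topology."""
    p = state.params
    units, unit_of = build_units(state)
    K = len(units)
    v = p.v_tread
    A = np.zeros((K, K))
    b = np.zeros(K)

    gl = p.gamma * state.length
    np.add.at(A, (np.arange(K), np.arange(K)), np.bincount(unit_of, weights=gl, minlength=K))
    b += np.bincount(unit_of, weights=gl * state.sigma * v, minlength=K)

    if p.zeta > 0:
        lo, hi = state.spans()
        O = pairwise_overlap(lo, hi, p.L_sys)
        cross = unit_of[:, None] != unit_of[None, :]
        Zo = p.zeta * O * cross
        M = np.zeros((state.sigma.size, K))
        M[np.arange(state.sigma.size), unit_of] = 1.0
        A += np.diag(np.bincount(unit_of, weights=Zo.sum(axis=1), minlength=K))
        A -= M.T @ Zo @ M
        dsig = state.sigma[:, None] - state.sigma[None, :]
        b += v * np.bincount(unit_of, weights=(Zo * dsig).sum(axis=1), minlength=K)

    F = p.F_stall
    v0 = p.v_my_unloaded
    if F > 0 and v0 > 0 and state.my_center.size:
        both = (state.my_bound[:, 0] >= 0) & (state.my_bound[:, 1] >= 0)
        if np.any(both):
            c = F / (2.0 * v0)
            f0 = state.my_bound[both, 0]  # sigma = -1 heads
            f1 = state.my_bound[both, 1]  # sigma = +1 heads
            i = unit_of[f0]
            j = unit_of[f1]
            ext = i != j  # motors internal to one unit exert zero net force
            i, j = i[ext], j[ext]
            np.add.at(A, (i, i), c)
            np.add.at(A, (j, j), c)
            np.add.at(A, (i, j), -c)
            np.add.at(A, (j, i), -c)
            # constant bias (sigma_m - sigma_n)(c v - F/2) with sigma_m = -1
            bias = -2.0 * (c * v - 0.5 * F)
            np.add.at(b, i, bias)
            np.add.at(b, j, -bias)

    return ForceSystem(A=A, b=b, units=units, unit_of=unit_of)


def solve_velocities(fsys: ForceSystem) -> np.ndarray:
    """Exact direct solve of ``A V = b``; residual must be < 1e-9."""
    try:
        V = np.linalg.solve(fsys.A, fsys.b)
    except np.linalg.LinAlgError as exc:
        diag = np.abs(np.diag(fsys.A))
        worst = fsys.units[int(np.argmin(diag))]
        raise np.linalg.LinAlgError(
            f"singular force system at unit {worst.kind}:{worst.ref}"
        ) from exc
    return V


def residual(fsys: ForceSystem, V: np.ndarray) -> float:
    if V.size == 0:
        return 0.0
    return float(np.max(np.abs(fsys.A @ V - fsys.b)))


def advance(state: BundleState, V: np.ndarray, fsys: ForceSystem) -> BundleState:
    """Advance positions, myosin centers/offsets and (in severing mode)
    filament lengths by one explicit-Euler step of size dt. Mutates and
    returns the state; bound sites whose offset leaves the filament detach."""
    p = state.params
    dt = p.dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    L = p.L_sys
    v = p.v_tread

    V_fil = V[fsys.unit_of]
    u = V_fil - state.sigma * v

    for unit, vel in zip(fsys.units, V):
        if unit.kind == "cluster":
            cl = state.clusters[unit.ref]
            cl.z_pos = _wrapf(cl.z_pos + vel * dt, L)
            state.plus_pos[unit.members] = cl.z_pos
        else:
            state.plus_pos[unit.ref] = _wrapf(state.plus_pos[unit.ref] + vel * dt, L)

    if state.my_center.size:
        v0 = p.v_my_unloaded
        F = p.F_stall
        b0 = state.my_bound[:, 0]
        b1 = state.my_bound[:, 1]
        both = (b0 >= 0) & (b1 >= 0)
        only0 = (b0 >= 0) & ~both
        only1 = (b1 >= 0) & ~both

        if np.any(both):
            u_a = u[b0[both]]  # sigma_a = -1
            u_b = u[b1[both]]  # sigma_b = +1
            if F == 0 or v0 == 0:
                w_a = np.full(u_a.shape, v0)
                w_b = np.full(u_b.shape, v0)
                vm = 0.5 * ((u_a - w_a) + (u_b + w_b))
            else:
                F_a = F * (-1.0) * ((u_a - u_b) + v0 * (-2.0)) / (2.0 * v0)
                F_b = F_a
                w_a = v0 * (1.0 - F_a / F)
                w_b = v0 * (1.0 - F_b / F)
                vm = u_a - w_a
            state.my_center[both] = _wrap_unchecked(state.my_center[both] + vm * dt, L)
            state.my_offset[both, 0] += (v - w_a) * dt
            state.my_offset[both, 1] += (v - w_b) * dt
        for sidx, mask in ((0, only0), (1, only1)):
            if np.any(mask):
                fil = state.my_bound[mask, sidx]
                sig = float(-1 if sidx == 0 else 1)
                vm = u[fil] + sig * v0
                state.my_center[mask] = _wrap_unchecked(
                    state.my_center[mask] + vm * dt, L
                )
                state.my_offset[mask, sidx] += (v - v0) * dt

    if p.length_mode == "severing":
        state.length += v * dt

    # drop-off: sites carried past either filament end detach
    if state.my_center.size:
        for sidx in (0, 1):
            bnd = state.my_bound[:, sidx] >= 0
            if np.any(bnd):
                fil = state.my_bound[bnd, sidx]
                off = state.my_offset[bnd, sidx]
                out = (off < 0) | (off > state.length[fil])
                if np.any(out):
                    rows = np.nonzero(bnd)[0][out]
                    state.my_bound[rows, sidx] = -1
                    state.my_offset[rows, sidx] = 0.0

    state.time += dt
    return state
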