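"""Order metrics and model-level statistics.

Sarcomeric order is quantified by the structure factor of the cluster
positions: with cluster plus-end coordinates ``X_a`` and weights ``N_a``
(filament numbers),

    S(q) = | sum_a N_a exp(i q X_a) |^2 / (sum_a N_a)^2,

evaluated at ring-commensurate wave vectors ``q_m = 2 pi m / L_sys`` so the
periodic boundary is exact. The height of the principal Bragg peak inside a
wavelength window around the expected sarcomere spacing defines the
sarcomeric order parameter ``S*``; an analogous order parameter on myosin
centers (unit weights) quantifies A-band order.

The severing length-control model (growth at ``v`` at the plus end, total
cut hazard ``r * l``, surviving plus-end fragment uniform on the precut
length) has the stationary density solving

    v p'(l) = r (1 - P(l)) - r l p(l),      P' = p,  p(0) = 0,

which is integrated numerically as a first-order system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "StructureFactorCurve",
    "OrderTimeSeries",
    "structure_factor",
    "order_parameter",
    "sarcomeric_order_parameter",
    "myosin_order_parameter",
    "cluster_count",
    "cluster_table",
    "spacing",
    "fit_saturation",
    "myosin_localization",
    "severing_steady_pdf",
    "order_from_table",
    "DEFAULT_WINDOW",
]

# principal-peak search window in units of ell_mean; excludes the trivial
# long-wavelength modes (a fully coalesced two-blob state is not "ordered")
DEFAULT_WINDOW = (1.0, 4.0)


@dataclass
class StructureFactorCurve:
    m: np.ndarray  # mode indices, 1..m_max
    q: np.ndarray  # wave vectors 2 pi m / L_sys
    S: np.ndarray  # values in [0, 1]
    L_sys: float


@dataclass
class OrderTimeSeries:
    times: np.ndarray
    S_star: np.ndarray
    S_my: np.ndarray
    cluster_count: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        n = self.times.size
        for name in ("S_star", "S_my", "cluster_count", "spacing"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} not aligned with times")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def structure_factor(positions, weights, L_sys, m_max) -> StructureFactorCurve:
    """Weighted structure factor at the first m_max ring-commensurate modes."""
    x = np.asarray(positions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("empty position list")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    m = np.arange(1, int(m_max) + 1)
    q = 2.0 * np.pi * m / L_sys
    amp = (w[None, :] * np.exp(1j * q[:, None] * x[None, :])).sum(axis=1)
    S = np.abs(amp) ** 2 / wsum**2
    return StructureFactorCurve(m=m, q=q, S=S, L_sys=float(L_sys))


def order_parameter(curve: StructureFactorCurve, wavelength_window=DEFAULT_WINDOW):
    """Principal-Bragg-peak order parameter.

    Returns (S*, lambda*): the maximum of S(q_m) over modes whose wavelength
    L_sys/m lies in the window, and the argmax wavelength (smallest mode
    index on ties).
    """
    lam_min, lam_max = wavelength_window
    L = curve.L_sys
    m_lo = max(1, math.ceil(L / lam_max - 1e-12))
    m_hi = math.floor(L / lam_min + 1e-12)
    sel = (curve.m >= m_lo) & (curve.m <= m_hi)
    if not np.any(sel):
        raise ValueError("wavelength window excludes all ring-commensurate modes")
    ms = curve.m[sel]
    Ss = curve.S[sel]
    best = int(np.nonzero(Ss == Ss.max())[0][0])  # smallest mode index on ties
    return float(Ss[best]), float(L / ms[best])


def _unit_positions_weights(state):
    """Cluster plus-end coordinates and filament-number weights; free
    filaments count as weight-1 clusters."""
    free = np.nonzero(state.cluster_of < 0)[0]
    cids = sorted(state.clusters)
    pos = np.concatenate(
        [np.array([state.clusters[c].z_pos for c in cids]), state.plus_pos[free]]
    )
    w = np.concatenate(
        [
            np.array([len(state.clusters[c].members) for c in cids], dtype=float),
            np.ones(free.size),
        ]
    )
    return pos, w


def _window_scaled(state, wavelength_window):
    if wavelength_window is not None:
        return wavelength_window
    ell = state.params.ell_mean
    return (DEFAULT_WINDOW[0] * ell, DEFAULT_WINDOW[1] * ell)


def _m_max(L_sys, window):
    return max(1, math.floor(L_sys / window[0] + 1e-12))


def sarcomeric_order_parameter(state, wavelength_window=None):
    """(S*, lambda*) of the actin cluster configuration."""
    window = _window_scaled(state, wavelength_window)
    pos, w = _unit_positions_weights(state)
    curve = structure_factor(pos, w, state.params.L_sys, _m_max(state.params.L_sys, window))
    return order_parameter(curve, window)


def myosin_order_parameter(state, wavelength_window=None):
    """S* of the myosin center positions with unit weights."""
    if state.my_center.size == 0:
        raise ValueError("state contains no myosin")
    window = _window_scaled(state, wavelength_window)
    curve = structure_factor(
        state.my_center,
        np.ones(state.my_center.size),
        state.params.L_sys,
        _m_max(state.params.L_sys, window),
    )
    return order_parameter(curve, window)[0]


def cluster_count(state) -> int:
    """Number of clusters; free single filaments count as one cluster each."""
    return len(state.clusters) + state.n_free()


def cluster_table(state) -> pd.DataFrame:
    """Tabular snapshot of cluster positions and weights (free filaments
    included as weight-1 entries)."""
    pos, w = _unit_positions_weights(state)
    return pd.DataFrame(
        {"time": state.time, "position": pos, "weight": w.astype(int)}
    )


def spacing(state, wavelength_window=None):
    """(lambda*, nn_mean): Bragg wavelength plus the mean ring gap between
    circularly sorted cluster positions. On a ring the latter is exactly
    L_sys / n_clusters, so lambda* is the informative spacing estimate."""
    window = _window_scaled(state, wavelength_window)
    _, lam = sarcomeric_order_parameter(state, window)
    pos, _ = _unit_positions_weights(state)
    if pos.size < 2:
        raise ValueError("nn_mean undefined for fewer than 2 clusters")
    nn_mean = state.params.L_sys / pos.size
    return lam, nn_mean


def fit_saturation(times, S_values):
    """Least-squares fit of the exponential saturation curve
    S(t) = S_sat (1 - exp(-t / tau)).

    Deterministic initialization: S_sat0 = max(S), tau0 = time at half-max.
    Returns (S_sat, tau, rms_residual); all-zero data gives (0, nan, 0) and
    a constant positive signal collapses to the degenerate tau -> 0 limit,
    reported as tau = 0.0 with a warning.
    """
    t = np.asarray(times, dtype=float)
    S = np.asarray(S_values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.all(S == 0):
        warnings.warn("all-zero signal: saturation time undefined")
        return 0.0, float("nan"), 0.0
    s0 = float(S.max())
    above = np.nonzero(S >= 0.5 * s0)[0]
    tau0 = float(t[above[0]]) if above.size else float(t[-1]) / 2.0
    tau0 = max(tau0, 1e-6 * max(t[-1], 1.0))

    def model(tt, s_sat, tau):
        return s_sat * (1.0 - np.exp(-tt / tau))

    popt, _ = curve_fit(
        model,
        t,
        S,
        p0=(s0, tau0),
        bounds=((0.0, 1e-12), (np.inf, np.inf)),
        maxfev=20000,
    )
    s_sat, tau = float(popt[0]), float(popt[1])
    rms = float(np.sqrt(np.mean((model(t, *popt) - S) ** 2)))
    if tau <= 1e-6 * max(t[-1], 1.0):
        warnings.warn("degenerate fit: tau at its lower limit (step-like data)")
        tau = 0.0
    return s_sat, tau, rms


def myosin_localization(state):
    """Mean relative offset of bound myosin sites along their filaments.

    0 = sites at plus ends (Z-band, wrong sorting), 1 = at minus ends
    (A-band, correct sorting). Returns nan if no site is bound.
    """
    bound = state.my_bound >= 0
    if not np.any(bound):
        warnings.warn("no bound myosin site: localization undefined")
        return float("nan")
    fil = state.my_bound[bound]
    return float(np.mean(state.my_offset[bound] / state.length[fil]))


def severing_steady_pdf(v_tread, r_sever, l_grid) -> np.ndarray:
    """Stationary filament-length density of the severing model.

    Integrates the closed first-order system (p, P) of the stationary
    balance from l = 0 with p(0) = 0, P(0) = 0 (hence p'(0) = r/v), on a
    fine internal grid extending to at least 8 sqrt(v/r), normalizes, and
    evaluates on l_grid.
    """
    if v_tread <= 0 or r_sever <= 0:
        raise ValueError("v_tread and r_sever must be > 0")
    l_grid = np.asarray(l_grid, dtype=float)
    lam = math.sqrt(v_tread / r_sever)
    l_max = max(8.0 * lam, float(l_grid.max()) if l_grid.size else 0.0)
    k = r_sever / v_tread

    def rhs(l, y):
        p, P = y
        return [k * (1.0 - P) - k * l * p, p]

    t_eval = np.linspace(0.0, l_max, 4001)
    sol = solve_ivp(
        rhs, (0.0, l_max), [0.0, 0.0], t_eval=t_eval, rtol=1e-10, atol=1e-12,
        method="RK45",
    )
    p_fine = np.clip(sol.y[0], 0.0, None)
    norm = np.trapezoid(p_fine, t_eval)
    return np.interp(l_grid, t_eval, p_fine / norm)


def order_from_table(table, L_sys, wavelength_window=DEFAULT_WINDOW) -> pd.DataFrame:
    """Post-process a cluster trajectory table (columns: time, position,
    weight) into per-time order metrics, independently of the simulator.

    ``table`` may be a DataFrame or a path to a delimited text file.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    out = []
    m_max = _m_max(L_sys, wavelength_window)
    for t, grp in table.groupby("time", sort=True):
        curve = structure_factor(
            grp["position"].to_numpy(), grp["weight"].to_numpy(), L_sys, m_max
        )
        s_star, lam = order_parameter(curve, wavelength_window)
        out.append(
            {
                "time": t,
                "S_star": s_star,
                "lambda_star": lam,
                "cluster_count": len(grp),
            }
        )
    return pd.DataFrame(out)
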