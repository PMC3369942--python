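"""Scenario presets and the main simulation loop.

Per-step event ordering is fixed: (1) myosin detach, (2) myosin attach,
(3) crosslinking and cluster merging, (4) optional filament dissociation,
(5) turnover or severing, (6) force-balance solve, (7) kinematic advance.
Forces are therefore always computed on the post-event topology.

Presets mirror the canonical study conditions: cluster coalescence with and
without inter-filament friction, sarcomeric ordering with myosin, the myosin
force scan, length polydispersity, actin turnover, and severing-based length
control. Preset parameter values are package decisions, recorded here and in
the methods note; every run logs its fully resolved parameter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics, mechanics
from .analysis import (
    StructureFactorCurve,
    cluster_count,
    cluster_table,
    fit_saturation,
    myosin_localization,
    myosin_order_parameter,
    order_parameter,
    sarcomeric_order_parameter,
    spacing,
    structure_factor,
)
from .analysis import _m_max, _unit_positions_weights, _window_scaled
from .geometry import BundleState, Params
from .kinetics import EventLog

__all__ = ["Scenario", "RunResult", "SCENARIOS", "step", "run", "scan", "get_scenario"]


@dataclass(frozen=True)
class Scenario:
    """A named, frozen simulation preset."""

    name: str
    overrides: dict = field(default_factory=dict)
    T_end: float = 100.0
    sample_interval: float = 0.5
    replicates: int = 5
    scan_param: Optional[str] = None
    scan_values: tuple = ()

    def params(self, seed: int = 0, **extra) -> Params:
        kw = dict(self.overrides)
        kw.update(extra)
        kw["seed"] = seed
        return Params(**kw)


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario(
            "fig2_no_friction",
            overrides=dict(N_actin=60, N_myosin=0, zeta=0.0, F_stall=0.0),
            T_end=50.0,
        ),
        Scenario(
            "fig2_friction",
            overrides=dict(N_actin=60, N_myosin=0, zeta=1.0, F_stall=0.0),
            T_end=50.0,
        ),
        # Myosin regime: motor mobility mu = 0.25 puts the critical force at
        # F_c = v/mu = 4 gamma*ell*v; the default F_stall = 0.5 sits deep in
        # the ordering regime (treadmilling outpaces walking, bridging motors
        # repel neighboring clusters with ~v/mu - F per bridge).
        Scenario(
            "fig3_myosin",
            overrides=dict(F_stall=0.5, my_mobility=0.25, N_myosin=100),
            T_end=60.0,
        ),
        Scenario(
            "fig3_force_scan",
            overrides=dict(F_stall=0.5, my_mobility=0.25, N_myosin=100),
            T_end=60.0,
            scan_param="F_stall",
            scan_values=(1.0, 2.5, 5.0),
        ),
        Scenario(
            "fig4_polydisperse",
            overrides=dict(
                F_stall=0.5, my_mobility=0.25, N_myosin=100,
                length_mode="lognormal", sigma_ell=0.25,
            ),
            T_end=60.0,
            scan_param="sigma_ell",
            scan_values=(0.0, 0.2, 0.4),
        ),
        Scenario(
            "fig5_turnover",
            overrides=dict(F_stall=0.5, my_mobility=0.25, N_myosin=100, k_turnover=0.2),
            T_end=60.0,
            scan_param="k_turnover",
            scan_values=(0.02, 0.05, 0.2),
        ),
        Scenario(
            "fig6_severing",
            overrides=dict(
                F_stall=0.5,
                my_mobility=0.25,
                N_myosin=100,
                length_mode="severing",
                r_sever=float(np.pi / 2.0),  # stationary mean length = ell_mean
            ),
            T_end=60.0,
        ),
    )
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def step(state: BundleState, log: EventLog | None = None) -> float:
    """Advance the state by one time step; returns the force-balance residual."""
    p = state.params
    dt = p.dt
    if state.my_center.size:
        kinetics.myosin_detach(state, dt, log)
        kinetics.myosin_attach(state, dt, log)
    links = kinetics.sample_crosslink_events(state, dt)
    if links:
        kinetics.apply_links(state, links, log)
    if p.k_diss > 0:
        kinetics.dissociate_filament(state, dt, log)
    if p.length_mode == "severing":
        kinetics.sever(state, dt, log)
    elif p.k_turnover > 0:
        kinetics.turnover(state, dt, log)
    fsys = mechanics.assemble_force_system(state)
    V = mechanics.solve_velocities(fsys)
    res = mechanics.residual(fsys, V)
    mechanics.advance(state, V, fsys)
    return res


@dataclass
class RunResult:
    scenario: str
    seed: int
    params: Params
    series: pd.DataFrame  # per-sample scalar observables
    traj: pd.DataFrame  # long cluster/myosin table
    summary: dict
    max_residual: float
    log: EventLog
    state: BundleState


def _sample(state: BundleState, rows_scalar: list, rows_traj: list,
            collect_traj: bool, curves: list | None = None):
    s_star, lam = sarcomeric_order_parameter(state)
    if curves is not None:
        window = _window_scaled(state, None)
        m_max = _m_max(state.params.L_sys, window)
        pos, w = _unit_positions_weights(state)
        S_act = structure_factor(pos, w, state.params.L_sys, m_max).S
        if state.my_center.size:
            S_my = structure_factor(
                state.my_center, np.ones(state.my_center.size),
                state.params.L_sys, m_max,
            ).S
        else:
            S_my = np.full(m_max, np.nan)
        curves.append((S_act, S_my))
    try:
        _, nn = spacing(state)
    except ValueError:
        nn = float("nan")
    s_my = (
        myosin_order_parameter(state) if state.my_center.size else float("nan")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loc = myosin_localization(state) if state.my_center.size else float("nan")
    rows_scalar.append(
        dict(
            time=state.time,
            S_star=s_star,
            lambda_star=lam,
            S_my=s_my,
            cluster_count=cluster_count(state),
            nn_mean=nn,
            localization=loc,
        )
    )
    if collect_traj:
        ct = cluster_table(state)
        for pos, w in zip(ct["position"], ct["weight"]):
            rows_traj.append((state.time, "cluster", -1, pos, int(w), 0.0))
        for j in range(state.my_center.size):
            nb = int((state.my_bound[j] >= 0).sum())
            mean_off = (
                float(state.my_offset[j][state.my_bound[j] >= 0].mean()) if nb else 0.0
            )
            rows_traj.append(
                (state.time, "myosin", j, float(state.my_center[j]), nb, mean_off)
            )


def run(
    scenario: Scenario | str,
    seed: int,
    T_end: float | None = None,
    collect_traj: bool = True,
    validate_every: float = 5.0,
    **overrides,
) -> RunResult:
    """Execute a scenario end to end and compute summary observables.

    Terminal scalar observables are reported as means over the final 10% of
    samples (one snapshot would alias steady-state fluctuations); the fitted
    saturation time tau comes from the full S*(t) series.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    params = scenario.params(seed=seed, **overrides)
    t_end = scenario.T_end if T_end is None else T_end
    state = kinetics.init_bundle(params)
    log = EventLog()
    n_steps = int(round(t_end / params.dt))
    sample_every = max(1, int(round(scenario.sample_interval / params.dt)))
    check_every = max(1, int(round(validate_every / params.dt)))
    rows_scalar: list = []
    rows_traj: list = []
    curves: list = []
    _sample(state, rows_scalar, rows_traj, collect_traj, curves)
    max_res = 0.0
    for k in range(1, n_steps + 1):
        res = step(state, log)
        if res > max_res:
            max_res = res
        if k % sample_every == 0 or k == n_steps:
            _sample(state, rows_scalar, rows_traj, collect_traj, curves)
        if k % check_every == 0:
            try:
                state.validate()
            except AssertionError as exc:
                raise RuntimeError(
                    f"invariant violation at t={state.time:.6f}: {exc}; "
                    f"state: {len(state.clusters)} clusters, "
                    f"{state.n_free()} free filaments"
                ) from exc
    series = pd.DataFrame(rows_scalar)
    traj = pd.DataFrame(
        rows_traj, columns=["time", "kind", "id", "position", "weight", "extra"]
    )
    # terminal order metrics from the time-averaged structure factor over the
    # final 10% of samples: averaging S(q) before the peak search suppresses
    # fluctuation-induced flips between the fundamental and its harmonics
    tail = max(1, len(series) // 10)
    window = _window_scaled(state, None)
    m_max = _m_max(params.L_sys, window)
    modes = np.arange(1, m_max + 1)
    q = 2.0 * np.pi * modes / params.L_sys
    S_act_avg = np.mean([c[0] for c in curves[-tail:]], axis=0)
    curve_avg = StructureFactorCurve(m=modes, q=q, S=S_act_avg, L_sys=params.L_sys)
    term_S, term_lam = order_parameter(curve_avg, window)
    if state.my_center.size:
        S_my_avg = np.mean([c[1] for c in curves[-tail:]], axis=0)
        term_S_my = order_parameter(
            StructureFactorCurve(m=modes, q=q, S=S_my_avg, L_sys=params.L_sys),
            window,
        )[0]
    else:
        term_S_my = float("nan")
    summary = {
        "scenario": scenario.name,
        "seed": seed,
        "T_end": t_end,
        "terminal_S_star": float(term_S),
        "terminal_S_my": float(term_S_my),
        "terminal_lambda_star": float(term_lam),
        "terminal_cluster_count": int(series["cluster_count"].iloc[-1]),
        "terminal_nn_mean": float(series["nn_mean"].tail(tail).mean()),
        "terminal_localization": float(series["localization"].tail(tail).mean()),
        "max_residual": max_res,
    }
    good = series["S_star"].notna()
    if good.sum() >= 5 and series.loc[good, "S_star"].max() > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_sat, tau, rms = fit_saturation(
                series.loc[good, "time"].to_numpy(),
                series.loc[good, "S_star"].to_numpy(),
            )
        summary.update(fit_S_sat=s_sat, fit_tau=tau, fit_rms=rms)
    return RunResult(
        scenario=scenario.name,
        seed=seed,
        params=params,
        series=series,
        traj=traj,
        summary=summary,
        max_residual=max_res,
        log=log,
        state=state,
    )


def scan(
    scenario: Scenario | str,
    param_name: str | None = None,
    values=None,
    seeds=None,
    T_end: float | None = None,
) -> pd.DataFrame:
    """Replicate runs across a parameter sweep.

    Returns a tidy table with one row per (value, seed) plus aggregated
    mean and standard-error columns merged in per value.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    param_name = param_name or scenario.scan_param
    values = values if values is not None else scenario.scan_values
    if param_name is None or not len(values):
        raise ValueError("scan requires a parameter name and a non-empty value list")
    if param_name not in Params.__dataclass_fields__:
        raise ValueError(f"unknown parameter {param_name!r}")
    seeds = list(seeds) if seeds is not None else list(range(scenario.replicates))
    rows = []
    for val in values:
        for seed in seeds:
            res = run(
                scenario, seed=seed, T_end=T_end, collect_traj=False,
                **{param_name: val},
            )
            row = {"value": val, "seed": seed}
            row.update(
                {k: v for k, v in res.summary.items() if isinstance(v, (int, float))}
            )
            rows.append(row)
    tidy = pd.DataFrame(rows)
    agg = tidy.groupby("value").agg(["mean", "sem"])
    agg.columns = ["_".join(c) for c in agg.columns]
    agg = agg.drop(columns=[c for c in agg.columns if c.startswith("seed_")])
    return tidy.merge(agg.reset_index(), on="value", how="left")
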