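"""Configuration and file I/O.

Configs are flat YAML/JSON key-value documents mixing Params fields with a
few run keys (scenario, T_end, sample_interval); unknown keys are rejected
by name. Outputs are delimited text: a long trajectory table
(time, kind, id, position, weight, extra), a per-sample scalar series, a
one-row summary, and a JSON run manifest with the fully resolved parameters
so any run can be reproduced byte-identically from its manifest.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import pandas as pd
import yaml

from .geometry import Params

__all__ = [
    "load_config",
    "write_outputs",
    "write_manifest",
    "export_kymograph",
    "RUN_KEYS",
]

RUN_KEYS = ("scenario", "T_end", "sample_interval", "replicates", "out")


def load_config(path) -> dict:
    """Load a flat config document; returns {'params': Params, run keys...}.

    Unknown keys raise ValueError naming the offending key path.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a flat key-value mapping")
    param_fields = set(Params.__dataclass_fields__)
    pkw, run = {}, {}
    for key, val in doc.items():
        if key in param_fields:
            pkw[key] = val
        elif key in RUN_KEYS:
            run[key] = val
        else:
            raise ValueError(f"unknown config key: {key!r}")
    run["params"] = Params(**pkw)
    return run


def write_manifest(path, params: Params, seed: int, scenario: str | None = None,
                   extra: dict | None = None) -> None:
    from . import __version__

    doc = {
        "code_version": __version__,
        "scenario": scenario,
        "seed": seed,
        "params": params.to_dict(),
        "written_at": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")


def write_outputs(result, outdir) -> dict[str, Path]:
    """Write trajectory, scalar series, summary and manifest for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / "trajectory.csv",
        "series": outdir / "series.csv",
        "summary": outdir / "summary.csv",
        "manifest": outdir / "manifest.json",
    }
    result.traj.to_csv(paths["trajectory"], index=False)
    result.series.to_csv(paths["series"], index=False)
    pd.DataFrame([result.summary]).to_csv(paths["summary"], index=False)
    write_manifest(
        paths["manifest"], result.params, result.seed, scenario=result.scenario
    )
    return paths


def export_kymograph(traj: pd.DataFrame, path, L_sys: float | None = None) -> None:
    """Static kymograph of cluster trajectories (position vs time, point size
    and color encoding cluster filament number), myosins overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    cl = traj[traj["kind"] == "cluster"]
    sc = ax.scatter(
        cl["time"], cl["position"], c=cl["weight"], s=2 + 1.2 * cl["weight"],
        cmap="viridis", lw=0,
    )
    my = traj[traj["kind"] == "myosin"]
    if len(my):
        ax.scatter(my["time"], my["position"], s=1.5, c="magenta", alpha=0.4, lw=0)
    fig.colorbar(sc, ax=ax, label="filaments per cluster")
    ax.set_xlabel("time  [ℓ / v]")
    ax.set_ylabel("position  [ℓ]")
    if L_sys:
        ax.set_ylim(0, L_sys)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
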