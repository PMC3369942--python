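"""Actin cluster formation and coalescence, with and without sliding friction.

Treadmilling filaments whose plus ends meet are irreversibly crosslinked
into clusters (nascent Z-bodies). Without inter-filament friction the
clusters keep fusing into a few giant ones; with friction, counter-sliding
monomers of neighboring clusters rub against each other and coalescence
arrests at a finite cluster number — a kinetically stabilized pattern.
"""

from sarcosim import run

for name in ("fig2_no_friction", "fig2_friction"):
    res = run(name, seed=0, collect_traj=False)
    series = res.series
    print(f"{name}:")
    print(f"  clusters: {series['cluster_count'].iloc[0]} initially -> "
          f"{series['cluster_count'].iloc[-1]} at t = {series['time'].iloc[-1]:g}")
    tail = series[series['time'] >= series['time'].iloc[-1] - 10]
    print(f"  cluster count over the last 10 time units: "
          f"{tail['cluster_count'].min()}..{tail['cluster_count'].max()}")

print(
    "\nWithout friction the bundle collapses into a handful of giant"
    " clusters; with friction (zeta = gamma) the count plateaus at a finite"
    " value and stays constant - the coalescence is kinetically arrested."
)
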