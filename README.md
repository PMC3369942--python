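# sarcosim

Agent-based one-dimensional model of **sarcomeric pattern formation** in
actomyosin bundles: how an initially unstriated bundle of treadmilling
actin filaments self-organizes into the periodic Z-band / A-band
architecture of premyofibrils and striated stress fibers.

The package is for biophysicists studying cytoskeletal self-organization:
it provides the simulation engine, scenario presets, order-parameter
analysis, and a severing-based filament length-control model, as an
importable library with a thin CLI.

## Model in brief

`N` rigid polar filaments live on a periodic ring of size `L`. Each
treadmills at speed `v`: its plus end leads the monomers by `σv`
(orientation `σ = ±1`). Three couplings drive pattern formation:

- **Plus-end crosslinking** — plus ends a distance `d` apart link at rate
  `k₀ exp(−(d/δ)²)`, condensing filaments into clusters (nascent Z-bodies)
  whose pinned filaments polymerize against the crosslinker and undergo
  local retrograde flow. An isolated cluster moves at the closed-form
  velocity `V = v(Σl₊ − Σl₋)/Σl` from the balance of cytosolic drag `γ`
  per unit length.
- **Sliding friction** (optional) — `ζ` per unit overlap between
  counter-sliding monomers; it arrests cluster coalescence kinetically.
- **Bipolar myosin** — connectors of length `L_my` with two
  polarity-specific binding sites, Poisson attach/detach, and a linear
  force–velocity relation `w = v₀(1 − F/F_stall)` with `v₀ = μ F_stall`.
  When treadmilling beats walking (`F_stall < F_c = v/μ`) the actin
  conveyor belt transports myosin to the minus ends (the A-band) and
  bridging myosins repel neighboring clusters, locking in a periodic
  pattern; above `F_c` the bundle collapses into giant clusters.

Mechanics are overdamped: every step solves the exact linear force balance
`A·V = b` over all mobile units. Order is quantified by the structure
factor `S(q) = |Σ_a N_a e^{iqX_a}|²/(ΣN_a)²` over cluster positions; the
principal Bragg peak height in a wavelength window around the sarcomere
spacing is the order parameter `S*`.

Units: lengths in mean filament lengths `ℓ`, time in `ℓ/v`, force in `γℓv`.

## Worked example

```python
from sarcosim import run

res = run("fig3_myosin", seed=1)
for k in ("terminal_S_star", "terminal_S_my", "terminal_lambda_star",
          "terminal_localization", "terminal_cluster_count", "fit_tau"):
    print(k, round(res.summary[k], 2))
```

prints (seed 1):

```
terminal_S_star 0.89
terminal_S_my 0.87
terminal_lambda_star 2.5
terminal_localization 0.97
terminal_cluster_count 8
fit_tau 4.08
```

meaning: by `t = 60 ℓ/v` the 100-filament bundle has condensed into 8
clusters on a 20ℓ ring at a regular spacing of 2.5ℓ (`S* = 0.89`, a sharp
Bragg peak), myosin is ordered the same way (`S*_my = 0.87`) and sits at
97% of the way to the filament minus ends — the correct A-band
localization — and the order parameter saturated with time scale
`τ ≈ 4 ℓ/v`.

More narrative walk-throughs live in `examples/` (coalescence vs kinetic
arrest, sarcomeric ordering, the myosin force scan, severing length
control). The same machinery is scriptable from the shell:

```sh
sarcosim simulate --scenario fig3_myosin --seed 1 --out run_out --kymograph
sarcosim scan --scenario fig3_force_scan --t-end 50 --out scan.csv
sarcosim analyze run_out/trajectory.csv --l-sys 20
sarcosim scenarios
```

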