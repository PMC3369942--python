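# Methods

## Model

`sarcosim` simulates a one-dimensional bundle of `N_actin` rigid, polar
actin filaments on a periodic ring of circumference `L_sys`. Each filament
is described by its plus-end coordinate, orientation σ ∈ {+1, −1} (+1 means
the plus end faces +x, with the body extending to −x) and length ℓ_i.
Filaments treadmill: the plus end polymerizes and the minus end
depolymerizes at the same net speed v, so the plus end leads the material
monomers by σ·v. Transverse structure is averaged out: any two filaments
interact whenever their axial projections overlap.

Simulation units: lengths in units of the mean filament length ℓ, time in
ℓ/v, force in γℓv, with γ the cytosolic drag coefficient per unit filament
length. Defaults v = γ = ℓ = 1.

Three active ingredients drive pattern formation:

1. **Processive plus-end crosslinking.** Two filaments whose plus ends are
   a distance d apart link irreversibly at rate k(d) = k₀·exp(−(d/δ)²)
   (defaults k₀ = 10/T, δ = 0.1ℓ). Linked plus ends form a *cluster* (a
   nascent Z-body) that pins all member plus ends at one coordinate while
   still letting them polymerize — each filament therefore undergoes local
   retrograde flow away from the cluster. Cluster fusion places the merged
   Z-band at the filament-number-weighted circular mean of the two
   positions. An optional dissociation rate `k_diss` makes crosslinking
   reversible (off by default).

2. **Overdamped mechanics.** Every time step solves the quasi-static force
   balance for all mobile units (clusters and free filaments). Forces:
   cytosolic drag −γℓ_i·u_i on each filament's monomers
   (u_i = V_unit − σ_i v); optional sliding friction −ζ·O_ij·(u_i − u_j)
   proportional to the pairwise span overlap O_ij; and myosin pair forces
   (below). All terms are linear in the unit velocities, so each step is an
   exact direct solve of a symmetric positive-definite system A·V = b
   (residual < 1e-9 is asserted in tests). An isolated cluster obeys the
   closed form V = v·(Σℓ₊ − Σℓ₋)/Σℓ.

3. **Bipolar myosin.** A myosin filament is a rigid, massless connector of
   length `L_my` with two polarity-specific binding sites (the left site
   binds σ = −1 filaments, the right site σ = +1). Sites attach/detach as
   Poisson processes (rates `k_on`, `k_off`); attachment picks uniformly
   among filaments of matching polarity covering the site. A bound head
   walks toward the plus end with the linear force–velocity relation
   w = v₀(1 − F_load/F_stall), extrapolated past stall so strong opposing
   loads drive back-slipping. For a doubly bound myosin the internal loads,
   walking speeds and connector velocity follow from head force balance and
   rigid-connector kinematics; elimination gives a symmetric velocity
   coupling F_stall/(2v₀) plus a constant polarity-dependent bias, which is
   folded into A·V = b. Site offsets from the plus end evolve as
   d(offset)/dt = v − w (the conveyor-belt identity); a site carried past
   either filament end detaches.

### Walking speed and the critical force

The unloaded walking speed is tied to the active force through a motor
mobility μ: v₀ = μ·F_stall (preset μ = 0.25). This makes the myosin force
genuinely antagonistic to ordering, as a single bridging myosin between two
stalled neighboring clusters exerts a repulsive force v/μ − F_stall: weak
motors act as near-rigid active crosslinks that polymerization pushes
against (strong repulsion, fast ordering), while beyond the critical force
F_c = v/μ walking outruns the retrograde conveyor, bridges become
attractive, myosin sorts to the plus ends (Z-bands) and the bundle
collapses into a few giant clusters instead of a periodic pattern. A fixed,
force-independent v₀ < v would make larger forces strictly more repulsive
and could never reproduce this antagonism; `v_my0` is retained as an
independent parameter for configurations that want it (set `my_mobility`
to None).

### Stochastic events and determinism

Per step, events execute in a fixed order: myosin detach, myosin attach,
crosslink + merge, optional dissociation, turnover or severing, force
solve, kinematic advance. Events are driven by per-entity exponential
clocks: every binding site, filament and crosslink candidate pair owns an
RNG stream keyed by (seed, subsystem, entity ids), and an event fires when
the integrated hazard since the last event first exceeds an Exp(1)
threshold from that stream — the exact first-passage construction of an
(inhomogeneous) Poisson process. Constant-rate events (attach, detach,
catastrophe) thus get exact exponential waiting times, and because no draw
depends on the step size, refining dt shifts event times by O(dt) instead
of resampling the realization: seeded runs converge under dt refinement,
enabling one mechanism does not perturb another's event sequence, and
identical configuration + seed reproduce output files byte for byte.

Crosslinking is sampled between mobile units rather than filament pairs:
members of a cluster share one plus-end coordinate, so the n_a·n_b
candidate pairs between two units collapse exactly into one merge event
with probability 1 − exp(−n_a·n_b·k(d)·dt). Simultaneous multi-way merges
are applied as iterated pairwise merges in ascending id order (associative
to round-off). Pair search beyond 4δ is skipped (rate < 2·10⁻⁷ k₀).

### Turnover and severing

*Turnover* removes a filament wholesale at rate `k_turnover` (catastrophe),
detaching its myosin and vacating its cluster, and nucleates a free
replacement at a uniform random position with a fresh orientation and
length — the filament count is conserved. *Severing* (its own
`length_mode`) lets filaments grow at v while a severing agent lands at
rate `r_sever` per unit length and cuts at a uniform position; the
minus-end fragment depolymerizes instantly, so the surviving length is
uniform on the precut length. The stationary density solves
v·p′ = r·(1 − P) − r·l·p, integrated numerically as a first-order system
from p(0) = 0 (hence p′(0) = r/v) and normalized; its scale is √(v/r).
The severing preset uses r = π/2 so the stationary mean length equals ℓ,
which fixes the mechanism's intrinsic polydispersity at σ_ℓ ≈ 0.52.

## Order metrics

Sarcomeric order is the height S* of the principal Bragg peak of the
structure factor S(q) = |Σ_a N_a e^{iqX_a}|²/(ΣN_a)² over cluster positions
X_a weighted by filament numbers N_a (free filaments count as weight-1
clusters), evaluated at ring-commensurate q_m = 2πm/L_sys and maximized
over wavelengths λ = L_sys/m in a window [1, 4]·ℓ around the expected
sarcomere spacing. The window excludes trivial long-wavelength modes, but
with only a handful of clusters the windowed maximum of a few phasors is
O(1) regardless of order — S* discriminates ordered from disordered states
only while enough clusters exist (the giant-cluster collapse above F_c is
instead diagnosed by the cluster count and the myosin localization).
An analogous S*_my uses myosin centers with unit weights. Myosin
localization is the mean bound-site offset divided by filament length
(1 = minus ends/A-band, correct sorting; 0 = plus ends/Z-band, wrong).
The ordering time scale τ comes from a deterministic least-squares fit of
S(t) = S_sat(1 − e^{−t/τ}).

Terminal order metrics reported by `run()` are read off the structure
factor time-averaged over the final 10% of samples: averaging S(q) before
the peak search suppresses fluctuation-induced flips of the argmax between
the fundamental spacing and its harmonics that make per-snapshot λ*
bimodal (the counterpart of ensemble-averaging structure factors across
replicates). Other terminal scalars are tail means; the trajectory and the
per-sample series are written in full.

## Synthetic initial conditions

`init_bundle` places filaments uniformly at random with fair-coin
orientations, each its own singleton cluster, and unbound myosins uniformly
at random. Lengths are monodisperse, log-normal (moment-matched to mean ℓ
and relative s.d. σ_ℓ), exponential, or initialized at ℓ under severing
dynamics. This emulates an unstriated, pre-formed bundle; it does not model
bundle assembly itself, transverse structure, filament flexibility,
excluded volume, substrate anchorage or force-dependent polymerization, so
passing tests demonstrate the self-organization mechanism under these
idealizations, not quantitative agreement with any particular cell type.

## Scenario presets and problem sizes

| preset | what it exercises | key overrides |
|---|---|---|
| fig2_no_friction | coalescence into giant clusters | N=60, no myosin, ζ=0, T=50 |
| fig2_friction | kinetic arrest | ζ=γ |
| fig3_myosin | sarcomeric ordering | N=100, 100 myosins, F=0.5, μ=0.25, T=60 |
| fig3_force_scan | critical force | F ∈ {1, 2.5, 5}, F_c = 4 |
| fig4_polydisperse | length variability | log-normal, σ_ℓ ∈ {0, 0.2, 0.4} |
| fig5_turnover | order vs turnover | k_turnover ∈ {0.02, 0.05, 0.2} |
| fig6_severing | length control in situ | severing mode, r = π/2 |

Defaults L_sys = 20ℓ, dt = 10⁻³, k_on = k_off = 10/T, L_my = 0.5ℓ,
5 replicates per scan point. The myosin count (100) and mobility (0.25)
were calibrated once so the ordering regime sits comfortably inside the
preset window: ~8 clusters at spacing ≈ 2.5ℓ arrest on a 20ℓ ring. All
presets resolve to a fully logged parameter set; tests and the acceptance
script run them at these sizes (T_end 50–60) so a full pass stays within
ordinary workstation budgets.

## Numerical choices and limitations

- Explicit Euler with fixed dt; forces are linear in velocities, so the
  only discretization error is event timing and position advection (the
  conveyor identity is exact per step; its global error is O(dt)).
- The tie at exactly L_sys/2 in the minimum-image convention breaks toward
  the negative image; coordinates live in the half-open [0, L_sys).
- Myosins doubly bound within one cluster are retained (they exert zero net
  force); whether heads detach or stall at filament ends is not observable
  at this coarse-graining — drop-off was chosen.
- A filament dissociating from a cluster keeps its position; replacement
  filaments after catastrophe are free, not pre-clustered.
- F_stall = 0 (or v₀ = 0) makes motors force-free; singly bound myosins
  advect with their filament plus free walking.
- Known limitations: no filament buckling or titin-like elasticity, no
  static (clamped) boundary mode, no transverse structure, no
  force-dependent polymerization; S* loses discriminating power below ~10
  clusters (see Order metrics).
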