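# Methods

## The individual-based model

`schooldyn` simulates N identical fish as self-propelled particles in
unbounded 3D space. Each fish i carries a position r_i (body lengths,
BL) and a unit heading p_i, swims at constant speed U, and at every
time step reorients according to prioritized zonal rules evaluated over
concentric shells:

* **avoidance** (top priority) — if any neighbour sits within the
  closed ball d ≤ z_r, the desired heading is the normalized negative
  mean of the unit vectors toward those neighbours; nothing else is
  considered;
* **alignment** — neighbours in the shell z_r < d ≤ z_r + z_l
  contribute their headings;
* **attraction** — neighbours in z_r + z_l < d ≤ z_r + z_l + z_a
  contribute the unit vectors toward themselves.

z_l and z_a are therefore shell *widths* stacked outside the avoidance
radius; the outermost interaction radius is z_r + z_l + z_a. Alignment
and attraction are restricted to a forward vision cone of full angle
α (blind cone of 360° − α behind the fish); avoidance is deliberately
not vision-censored by default (near-field collision avoidance), with
`blind_cone_repulsion` available to censor it too.

When the avoidance set is empty the two social responses are combined
by **count weighting** (`term_weighting="count"`, the default): the raw
sums of unit vectors are added, so a shell's influence scales with how
many neighbours populate it. A crowded attraction shell can then outvote
a sparse alignment shell, which is what sustains milling at small z_l.
The alternative `"normalized"` mode gives each response a unit direction
and equal weight regardless of counts; alignment is then effectively
much stronger and the milling–schooling transition moves from z_l ≈ 3
down to z_l ≈ 2 (we keep this mode available because it corresponds to
the equal-attention reading of the update rule, but it does not
reproduce the phase behaviour this package targets). With
`align_self=True` (default) the focal fish's own heading joins the
alignment sum, adding directional persistence.

If a response sum is degenerate (norm < 1e-12) that term is dropped;
with no perceived neighbours, or a fully cancelling response, the fish
keeps its current heading.

**Noise.** After the deterministic desired heading is formed, an
independent N(0, σ) draw is added to each Cartesian component and the
vector is renormalized — a spherically wrapped Gaussian about the
desired direction. For small σ the angular deviation θ between input
and output satisfies E[θ²] = 2σ², i.e. a per-component angular std of
σ√(2/3). Note that the std of the *positive* angle itself is
σ√(2 − π/2) ≈ 0.66σ; the √(2/3) relation refers to the per-component
(isotropic 3D) deviation, and that is the statistic our tests measure.

**Turning constraint.** The realized turn from p_i(t) to the
(post-noise) target is capped. Two conventions are shipped: `"rate"`
(default) treats the printed maximum turning angle θ_max as an angular
speed, capping a step at θ_max·dt; `"per_step"` caps every discrete
update at θ_max outright. Per-step capping turns out to destroy milling
entirely at any tested dt (fish reorient so fast that the group either
polarizes or stays a swarm), so the rate convention is the physically
meaningful one here. When the target is exactly antiparallel the turn
plane is undefined; we rotate toward a fixed perpendicular (the
coordinate axis least aligned with the current heading, projected
orthogonal) so runs are bit-reproducible.

**Update order.** Synchronous: all desired headings are computed from
the time-t state; noise, then the turn cap, are applied; finally
positions advance along the *new* headings, r_i(t+dt) = r_i(t) +
U·p_i(t+dt)·dt. One seeded `numpy` Generator drives a run; ensemble run
k uses seed base_seed + k, and every result file's manifest records the
seeds, so any table can be regenerated bit-identically.

### Default parameters

| quantity | symbol | default | units |
|---|---|---|---|
| group size | N | 100 | — |
| avoidance radius | z_r | 1 | BL |
| alignment shell width | z_l | 4 (phase variable) | BL |
| attraction shell width | z_a | 10 | BL |
| field of vision | α | 270 | deg |
| max turning rate | θ_max | 40 | deg/s |
| swim speed | U | 3 | BL per time unit |
| heading noise (per component) | σ | 0.01 | — |
| time step | dt | 0.25 | time units |
| run length | T | 500 (300 in scaled studies) | time units |

Initial conditions are positions uniform in the unit cube and headings
uniform on the sphere, a deliberately dense, disordered start.

### Choice of dt (and what it entails)

dt is a genuine model parameter here, not only an integration knob: the
noise σ is injected per update, and the outcome of the milling–schooling
competition from dense random initial conditions depends measurably on
step coarseness. We calibrated dt against the behaviour the package is
built to exhibit — with z_a = 10, σ = 0.01, N = 100: ~100% of runs
milling at z_l = 2.8, ~100% schooling at z_l = 3.4, and a 50% crossing
near z_l ≈ 3.0–3.1. Measured over 30-run ensembles, dt = 0.25 gives
93%/100% on the two plateaus with the crossing at ≈ 3.05; dt = 0.2
gives 85%/96%; dt = 0.3 overshoots (100%/87%, with coarse-step
artifacts at the schooling side). dt = 0.25 is the default. Two honest
consequences:

* the milling basin at z_l = 2.8 is ≈ 0.93 per run, not exactly 1, so
  a 10-run ensemble occasionally reports 90% there; likewise ~5% of
  runs at z_l = 3.4 fall into a mill that outlives a T = 300 run;
* at this dt the per-step noise kick (≈ σ√(2/3) rad) stays below the
  per-step turn cap (10° at dt = 0.25) for every σ ≤ 0.1, so strong
  individual noise does **not** eliminate the milling state — it delays
  the forward escape and widens the hysteresis loop instead. A
  noise-destroyed milling regime would require the kick to exceed the
  cap (σ ≳ 0.2 at dt = 0.1), which conflicts with the step size that
  reproduces the plateau percentages. We document this as a known
  limitation of the shipped convention rather than tuning around it.

## Order parameters and phase labels

Polarization P(t) is the norm of the mean heading. Milling order M(t)
is the norm of the mean unit angular-momentum direction
(r_i − r_c) × p_i about the centroid r_c; degenerate terms (fish at the
centroid or heading parallel to its radius) contribute zero, keeping M
continuous. Both are isometry-invariant and bounded in [0, 1]. Cohesion
is summarized by the mean and std of the nearest-neighbour distance
(NND, via a k-d tree).

Steady states are trailing-window averages (default 50 time units) and
are labelled: *fragmented* if mean NND exceeds the outermost interaction
radius or σ_NND > 2 BL; else *schooling* if P̄ ≥ 0.6 and M̄ ≤ 0.4;
*milling* if M̄ ≥ 0.6 and P̄ ≤ 0.4; else *swarming*. The 0.6/0.4 cutoffs
split strongly bimodal distributions (steady-state P and M cluster near
0 and 1 around the transition), so labels are insensitive to ±0.1
threshold shifts; all four cutoffs are configurable. The milling
residence time T_milling accumulates samples whose smoothed (1-time-unit
moving average) M and P fall in the milling region; τ = T_milling/T.

## Ensemble experiments

* **Phase diagram** — independent ensembles over a (z_l, z_a) grid.
* **Bifurcation sweep** — ensembles along z_l; the transition location
  z_l* is the first grid point where ≥ 50% of runs school, plus a
  linear interpolation between the bracketing points.
* **Escape rates** — because runs started above the transition mostly
  polarize directly (never milling), residence statistics are collected
  by the release protocol: equilibrate each run into a mill at
  z_l = 2.0 for 150 time units, switch z_l to the target, and measure
  T_milling of the remainder. Runs still milling at the end enter the
  mean as censored lower bounds and are counted. κ = 1/⟨T_milling⟩.
  The random-start variant (`escape_rate_curve`) is kept for
  completeness and flags never-milled runs.
* **Kramers fit** — κ(r) = A·r·exp(−r/(3σ_eff²)) with r = z_l − z_l*,
  fitted on log κ (linear in log A and 1/(3σ_eff²); the exact linear
  solution seeds `curve_fit`). On our measured range the fitted σ_eff
  is large: the data sit on the rising, drift-dominated flank of the
  law, where κ ≈ A·r.
* **Hysteresis ramps** — z_l stepped up 1 → 5 and back, each value held
  (default 400, scaled studies 60 time units) with the school state
  carried across holds; independent chains are averaged.

## The polarization SDE

The group-level reduction dP = rP(1−P)dt + σdW descends from the
single-well effective potential U(P) = −r(P²/2 − P³/3): equilibria at
P = 0 and P = 1 for every r, exchanging stability at r = 0 (a
transcritical bifurcation), with curvatures U'' = ∓r at the two
equilibria and barrier ΔU = r/6 between them. (Evaluating the potential
literally gives U(1) − U(0) = −r/6; the escape law uses the barrier
magnitude r/6, and `effective_potential` returns that by convention.)
Escape from the marginal milling state follows Kramers' form
κ = A·r·e^(−r/(3σ²)), which rises with r up to r = 3σ² and decays
beyond; only the rising flank describes first-passage behaviour, and
consistency tests compare there.

Integration is Euler–Maruyama with dt = 1e-3, adequate for the T ≤ 10
horizons used (strong order-1 convergence is verified against the
logistic solution). Boundaries at P ∈ {0, 1} reflect by default (P stays
a valid polarization exactly); clipping is available. The finite-time
bifurcation cloud draws initial conditions uniform on [0, 1]; the SDE
hysteresis ramps r over [−1, 1] in steps of 0.1, 10-time-unit holds,
50 chains.

## What the synthetic fixtures do and do not show

Ring mills (exact M = 1), aligned lattices (exact P = 1) and two-state
order series (exact residence fraction) give every observable and every
estimator a closed-form ground truth without running the simulator;
they validate the measurement pipeline, not the dynamics. Passing them
says nothing about real fish: the model has no hydrodynamics, no body
shape, no boundaries, no individual variability, and its noise is an
isotropic heading perturbation rather than a behavioural model.

## Numerical and degenerate-case choices

Zone boundaries are closed on the right (d = z_r is avoidance,
d = z_r + z_l is alignment). Visibility compares cos(angle) ≥ cos(α/2)
directly. All unit-normalizations treat norms < 1e-12 as degenerate and
fall back (drop the term / keep the heading / deterministic
perpendicular). Headings are renormalized after every step, keeping
norms at 1 to 1e-9 over 10⁴-step runs. The neighbour classification is
dense O(N²) vectorized (N = 100 makes a spatial index pointless) and is
tested for exact agreement against an independent double-loop oracle.

## Scales used by the shipped studies

The analysis drivers and acceptance checks run deliberately reduced
ensembles chosen to keep a full desk reproduction under half an hour:
sweeps use 10 runs × T = 300 per point (the headline phase structure at
those sizes matches 30-run checks to within binomial error), escape
curves 8 release runs per point, fish hysteresis 2 chains × 60-unit
holds, SDE ensembles 50 paths. Percentages estimated from 10 runs carry
±10-point granularity; tolerances in the tests reflect that.
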