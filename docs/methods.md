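# Methods

## The model

`swarmsim` simulates swarms of flying insects (midges, fruit flies, locusts,
moths — and bats, which swarm similarly) as unit-mass self-propelled agents
in three dimensions.  Each insect `i` carries a position `r_i`, an actual
velocity `v_i` and a preferred velocity `v_i,pref`.  The preferred velocity
is driven by a force balance

    dv_i,pref/dt = F_int + F_fric + F_res + F_xi

with four ingredients:

- **Zonal interaction force** `F_int`.  Neighbors (within `r_att`) act on
  the insect according to which concentric shell they occupy: repulsion
  inside `[0, r_rep)`, velocity alignment in `[r_rep, r_ali)`, attraction in
  `[r_ali, r_att]` (half-open inner bounds, closed outer bound).  Each
  shell's contribution is the shell *average* of
  `g·r̂_ji + (1-|g|)·v̂_ji` scaled by the shell weight `chi_k`, where `g`
  is the zone indicator (−1/0/+1), `r̂_ji` the unit separation and `v̂_ji`
  the unit relative velocity.  Empty shells contribute nothing.
- **Friction** `F_fric = −γ‖v‖v`.  The printed form of the drag law is a
  scalar–vector product, read here as quadratic (speed-proportional) drag;
  `drag_form="linear"` switches to Stokes drag `−γv`.  Either way the
  dissipated power `F·v` is non-positive.
- **Stimulus response** `F_res`.  Gated by the visual range `r_res`
  (Heaviside).  Pursuit (`kind=0`): a unit force toward the stimulus, scaled
  `chi_res`.  Escape (`kind=1`): the away-from-threat direction rotated
  about the world up axis `n=(0,1,0)` by `θ ~ U[−π/2, 0]`, so the force
  always lies 90–180° away from the threat — escape with maximal
  unpredictability.  An insect responds to at most one stimulus per step
  (the nearest active one; predators and targets never superpose).
- **Inherent noise** `F_xi`.  Four generators: per-step white noise
  (uniform on `[−1,1]³`, scaled by `gain`), Gaussian white noise (the sine
  branch of Box–Muller, `λ·sqrt(−2 ln W1)·sin(2π W2)`; note this branch is
  *exactly* standard normal, so its variance is `λ²`, not `λ²/2`), and two
  position-correlated fields: a three-channel gradient (Perlin) noise
  `P(r/scale)·gain` and its curl `C = ∇×P`.  The three Perlin channels are
  one seeded noise instance sampled at large fixed coordinate offsets.  The
  curl uses the exact analytic derivatives of the gradient noise (a
  finite-difference path with step `1e-4·scale` exists for cross-checks),
  so `C` is divergence-free up to floating error — swirling, never
  compressing.  Curl noise is the default: it reproduces the smooth but
  erratic flight of real insects, where white noise gives jittery,
  physically implausible jerk.

Per time step (explicit Euler, exactly in this order): classify neighbors
by `r_att`; accumulate the four forces; `v_pref ← v + F·Δt`; pass all
preferred velocities through the reciprocal collision-avoidance operator
`f_R` to get actual velocities; `r ← r + v·Δt`; apply the boundary rule.
No higher-order integrator is used — the model is defined at the level of
this update rule.

## Collision avoidance (f_R)

`f_R` is an ORCA-style reciprocal velocity-obstacle operator in 3D.  Each
neighbor within reach (`2·radius + 2·max_speed·τ`) induces a half-space
constraint on the agent's velocity, derived from the truncated collision
cone over the horizon `τ`; both agents take half of the required
correction, so the constraint set is reciprocal.  Within the intersection
of all half-spaces and the `max_speed` sphere, each agent adopts the
velocity closest in 2-norm to its preferred one, found by an incremental
linear program (line/plane/sphere sub-programs).  Agents already
overlapping get a push-apart constraint that resolves the overlap within
one time step.

When the constraint set is empty (an agent boxed in by near-contact
neighbors), the operator returns the *least-penetrating* velocity — the
exact minimizer of the maximum constraint violation, solved as a small
linear program — so a crowded agent still backs away as hard as it can.
The configured `infeasible_policy` (`zero_velocity`, the default, or
`halve_step`) applies only in the last resort when even that program fails.
Two degenerate geometries get exact special cases: a relative velocity
lying exactly on the collision-cone axis escapes along the cone's surface
normal (sideways plus a slight braking — an axis-perpendicular push would
undercut the clearance by the cone-angle factor), and near-axis courses
within a relative tolerance of 1e-6 use the same branch so the escape
direction never comes from rounding noise.

Static obstacles (the lamp in the phototaxis scene) are spheres handled as
non-reciprocal constraints: the agent takes the full correction.

Defaults and why: `agent_radius = 0.05` box units (the hard core must sit
inside the zonal repulsion shell — the midge parameter set has
`r_rep = 0.17`, so a body-length-derived radius of 0.1 would force
permanent hard-sphere contact; fitted RVO radii for the same data are
≈ 0.07); `time_horizon = 0.25 s` (longer horizons over-constrain dense
clusters, shorter ones let agents blunder into near-contact before
reacting — both raise infeasibility); `max_speed = 5` units/s;
`max_neighbors = 10` constraint pairs per agent for speed, with the
exception that any pair able to reach contact within one step is always
constrained (the capacity cap must never drop an imminent collision), and
pair inclusion is symmetric (reciprocity assumes both agents constrain
against each other).

## Scenarios

`build_scenario` returns ready configs for the published collective
behaviors: `midge_box` (100 insects, 20×20×20 glass box), `aggregation`
(500), `fruitfly_box`, `mate_competition` (pursuit of a female),
`escape` (a predator crossing the box mid-run; the swarm disperses and
re-aggregates), `bats` (a circling echolocation cue), `migration` (2,000
locusts in a 24×5×0.5 m open corridor pursuing a crop-like target),
`phase_transition` and `phototaxis` (lamp = pursuit target + sphere
obstacle).  The parameter table distinguishes scenarios by the eleven model
parameters; radii are stored internally as absolute values, while configs
and the table use the compact shell-width convention
(`ratt* = r_att − r_ali`, `rali* = r_ali − r_rep`) behind an explicit flag.

The source parameter table is only partially legible per scenario for the
rows γ/scale/gain/chi_rep/r_rep/chi_att/ratt* (six printed values for nine
scenario columns).  The reconstruction here assigns the six values in order
to midge, aggregation, fruitfly, mating, escape and bats, and reuses the
escape base for migration, the mating base for the phase transition, and
the bats base for phototaxis — the behaviorally closest columns.  The
four fully-printed rows (chi_ali, rali*, chi_res, r_res) are mapped
one-to-one.

The phase transition is driven by a schedule: the noise gain ramps linearly
to zero while the alignment weight ramps from zero to its table value over
the run.  The polarization order parameter `‖Σ v̂_i‖/N` then rises from the
disordered (< 0.3) to the ordered (> 0.7) regime.  The measured density is
logged per run and the frame at which it crosses the configured critical
value (default 50 per unit volume) is recorded as the critical event.

A temperature extension maps environment temperature to a reference
airborne-insect density via the published quadratic
`N(T) = −0.1073 T² + 4.7643 T − 33.4556` (peak near 22.2 °C).  It is an
annotation only — the model is agent-based and cannot steer its realized
density toward a target, so no closed-loop control is attempted.  Negative
values (below ≈ 8.7 °C) are clamped to zero with a warning.

Other conventions: `Δt = 1/60 s` (a typical motion-capture frame rate; the
source never prints its step), reflecting walls for box scenarios,
open boundaries for migration, initial positions uniform in the box with
zero velocities.  Densities follow the fixed-reference-volume convention —
insect count divided by a configured reference volume — under which 500
midges at 9,469.7 /m³ and 3,000 midges at 56,818.2 /m³ are the same volume
at 6× the count.  (The locust figures print a 100× count change alongside
a 10× density change "in the same space"; those two numbers are mutually
inconsistent, and only the fixed-volume convention is supported.)

## Evaluation framework

Two swarms are compared through distributions, not positions: seven
per-insect, per-frame kinematic metrics — speed `v`, acceleration magnitude
`a`, angular velocity `ω = arccos(v̂₁·v̂₂)/Δt`, angular acceleration
`α = Δω/Δt`, Cartesian jerk `μ = ‖Δv₁ − Δv₂‖/Δt²` (trajectory roughness),
nearest-neighbor distance `d` (a density proxy) and the distance-weighted
nearest-neighbor speed difference `η = (v_nei − v)/d` (separates
weakly-aligned swarms from flocks).  All are computed from positions by
finite differences; samples with a zero-magnitude velocity are skipped in
the angular metrics and the arccos argument is clamped to [−1, 1].  `η` is
kept signed (a config switch provides `|η|`).

Each sample set is z-scored (population SD; each dataset with its own
mean/SD, since real and simulated data live on different scales — pooled
standardization is available), binned into `M = 50` equal bins over the
pooled min/max interval of both z-scored sets, and turned into a discrete
probability density `Q_i = S_i·M/(S·(u₂−u₁))` that integrates to one.  The
energy of a metric is the L1 distance between the two densities (a switch
computes it over per-bin probability masses instead, which differs by the
constant bin width), optionally normalized as
`E_φ = (raw − p₁)/p₂`; the evaluation score is
`E = 1 − Σ w_φ E_φ`.  Comparing a dataset with itself gives exactly
`E = 1`.

When `m ≥ 2` models are compared, the weights come from the entropy of
each energy column: min-max normalize the column (the normalizers `p₁` =
column min and `p₂` = column range are reused in the score), flip to
`r = 1 − x`, form the distribution `g` over models, compute the normalized
Shannon entropy `e_j`, and set `w_j ∝ 1 − e_j`.  A term on which all
models agree carries zero weight; if *every* term is non-discriminating
the comparison is refused.  The comparison loop alternates per-model
re-fitting (Par-Est under the current weights) with re-weighting until the
weights move less than `tol = 1e-3` (max-norm) or `max_iter = 10` is
reached.

## Parameter estimation (Par-Est)

A real-coded elitist GA maximizes the evaluation score of a simulated
swarm against a reference trajectory: tournament selection (size 3),
uniform crossover (rate 0.8), per-gene Gaussian mutation (σ = 10 % of the
gene's range, rate 0.1), one elite, default population 30 × 40
generations.  Seven parameters are estimable from trajectory data (γ,
chi_rep, r_rep, chi_att, r_att, scale, gain); alignment and response
parameters are not (recorded swarms show no strong alignment tendency and
contain no controlled stimulus) and stay at their configured base values.
Candidate radii are repaired rather than rejected (`r_rep` capped at
`r_att`, `r_ali` clipped between them), so every candidate is a valid
model.  Search boxes default to `[0, 4×base]` per parameter.

Fitness evaluations share a fixed simulation seed and run length, so the
only variation between candidates is the parameters themselves —
deliberately trading an unbiased fitness estimate for a much less noisy
one.  Fitness simulations and the swarm-like fixture both discard a
burn-in (default 300 frames): motion-capture datasets record established
swarms, whereas uniform-random initialization spends hundreds of frames
nucleating, and without the burn-in that transient dominates every metric
distribution.

## The synthetic fixture generator

`generate_fixture` stands in for the motion-capture datasets:

- `swarmlike` — the full dynamics + Curl model with the midge parameter
  column (100-insect glass-box setting, run at the requested size), burn-in
  discarded.  It reproduces the *structure* of such data — bounded, noisy,
  weakly aligned trajectories of an established swarm at a fixed frame
  rate — but not the biology of any particular species: its parameters are
  the published fits, not re-estimated from real insects, so passing
  recovery/ablation tests shows the machinery discriminates and calibrates
  on model-generated data, not that the model matches *Chironomus riparius*.
- `lattice`, `straightline`, `two_body` — analytic trajectories with
  closed-form metric values (zero rotation/jerk; constant nearest-neighbor
  distance with `η = ±(Δspeed)/d` from two insects co-rotating on
  concentric circles), used as unit-test oracles.

## Scaled experiment sizes

The calibration and ablation experiments are run at desk scale as the
package's own defaults: parameter recovery uses a 50-insect, 300-frame
reference, a GA of 8 × 3 generations over (chi_att, r_att, gain), and five
GA seeds; the ablation comparison (full model vs dynamics-only `gain→0` vs
noise-only `chi→0, γ=0`) uses 40-insect references, a 6 × 2 GA per model
and one entropy-weighting round, over five reference seeds.  Success is
counted as a majority (≥ 4/5) of seeds, since the GA is stochastic by
nature.  Recovery is judged by score — the GA must reach (within 10 %) the
score of the generating parameters under the identical fitness pipeline —
not by parameter values, which are not identifiable from short references
(several parameter combinations yield statistically indistinguishable
swarms; the GA may even legitimately *exceed* the generating parameters'
score, because the fitness compares one finite realization against
another).

## Numerical choices and edge cases

- Coincident agents (`r_ji < 1e-9`): the repulsion direction is a random
  unit vector from the seeded stream (symmetry breaking, never NaN).
- Identical velocities in the alignment shell: the alignment unit vector is
  undefined and that contribution is dropped.
- A non-finite force aborts the step with the offending term named.
- Everything is deterministic in `(config, seed)`: one `numpy` Generator
  drives initialization, noise draws and any symmetry breaking; the
  position-correlated fields are pure functions of `(position, seed)`.
- Trajectory files are columnar text (`frame  insect  x  y  z`) at full
  float precision via shortest round-trip repr; parsing errors name the
  offending line.

## Known limitations

- Adult flying insects only — no walking, swimming or eusocial behavior,
  no wing aerodynamics or morphology.
- Under forced over-compression (boxes much smaller than the swarm's
  natural packing) the avoidance constraint set can be genuinely empty for
  sustained periods; the least-penetration completion then bounds pairwise
  penetration to about 2 % of the body diameter rather than preventing it.
- Cross-seed evaluation scores of even the *same* model vary noticeably at
  desk scale (tens of insects, hundreds of frames) because the metric
  histograms are built from strongly autocorrelated samples; comparative
  statements (ablation ordering, recovery) are robust, absolute scores are
  not.
- The density–temperature relation is an annotation; realized density is
  an emergent property and is not controlled.
- The GA is probabilistic and may return sub-optimal parameters; all
  experiments therefore use majority-of-seeds criteria.
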