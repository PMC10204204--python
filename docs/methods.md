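# Methods

`setasim` is an agent-based mechanical model of suspension feeding by
crustacean mouthpart setae.  Two mirrored pairs of seta rows — short inner
setae (7 segments, maxilla-2-like) and long outer setae (15 segments,
maxilla-1-like) — are driven back and forth above a ground plane and
interact with a dilute cloud of food particles.  A particle that enters a
small box on the ground plane (the mouth) is counted as eaten and replaced
upstream.  The model asks how segment stiffness gradients, tip adhesion and
sweep amplitude shape feeding efficiency.

## Model

### Seta chains

Each seta is a chain of `n_segments` segments of rest length `dR = 1` (the
length unit) joined at nodes.  Node 0 is clamped at the base; node 1 is
kinematically driven (the "base segment"); nodes ≥ 2 follow overdamped
first-order dynamics `γ_s dr/dt = F_elastic` — setae carry no inertia, only
the particles do.

Elastic forces derive from two energy terms per chain:

* **Longitudinal** (per segment, stiffness `K∥`): a quartic double-well
  `U(ℓ) = K∥/(8 dR²) (ℓ² − dR²)²` whose force is linear with slope `K∥`
  for small extension and stiffens cubically for large extension.
* **Transverse** (per interior node, stiffness `K⊥ = K∥`): midpoint
  restoration `U = K⊥/2 |(r_{j−1}+r_{j+1})/2 − r_j|²`, which keeps
  neighbouring segments close to parallel.  The force is the *full*
  gradient of this energy: the centre node feels `K⊥ (midpoint − r)` and
  each neighbour the −1/2 reaction.  The reactions matter: without them a
  straight chain pointing in *any* direction from node 1 is an equilibrium,
  so a rotation imposed on the base segment would never propagate along
  the chain, and momentum would not be conserved.  With them, the unique
  energy minimum for a clamped base is the straight continuation of the
  driven base segment, and the chain follows its drive with a
  stiffness-dependent lag.

The relaxation time of the slowest bending mode scales as `γ_s n⁴ / K`:
long chains are intrinsically far slower to follow their drive than short
ones, and soft chains slower than hard ones.  This single scaling produces
the model's central material distinction: hard short chains track the
drive almost rigidly, soft ones lag and under-sweep.

Material presets (`K_hard = 100`, `K_soft = 25`, ratio 4): `soft` (all
segments soft), `hard` (all hard), `hard_soft_tips` (hard shaft, distal 2
segments soft).  The ratio was chosen so that soft 7-segment chains still
reach, with reduced amplitude, the working region near the mouth — much
softer chains simply freeze near their initial orientation and the model
degenerates.

### Actuation

The base segment sweeps in the (y, z) plane between `φ_min` (toward the
mouth midplane, negative) and `φ_max`, mirrored on the two sides of the
mouth.  The waveform is a smoothed trapezoid

    φ(t) = mid + amp · tanh(q sin(ω t + φ₀)) / tanh(q)

with dwell sharpness `q` (default 4; q → 0 recovers a sinusoid).  The
dwells at the extremes model the stopping points where the rotation
reverses, and they are load-bearing for the science: during the dwell a
lagging chain catches up toward the sweep extreme, so delivery grades
continuously with stiffness instead of switching off for any chain that
lags.  Per-seta heterogeneity: each seta draws its frequency uniformly
from `[0.9, 1.1] · ω₀ ·` (row factor) and a random initial phase — rows
beat incoherently, as real setae do.  Defaults: `ω₀ = 0.5`, short rows at
factor 1 sweeping `[−0.4π, −0.1π]` (a small working arc at the mouth),
long rows at factor 0.3 with dwell 6 sweeping `[−0.4π, 0.3π]` (slow, wide
gathering strokes).

### Chain integration

The chain update is a backward-Euler step solved by fixed-point iteration
(4 iterations) preconditioned with the constant matrix
`M = I + (dt/γ_s)(A_⊥ + A_∥⁰)`, where `A_⊥` is the (exactly linear)
transverse operator and `A_∥⁰` a zero-rest-length spring Laplacian with
the longitudinal stiffnesses.  `M⁻¹` is prefactored once per seta; the
scheme is unconditionally stable, so no substepping is needed even at
stiffness-to-friction ratios of `K/γ_s = 2500` (hard chains, `γ_s = 0.04`)
where an explicit step at `dt = 0.01` would diverge.  An explicit-Euler
relaxation step is retained in the API (`relax_chain`) and the two
integrators are cross-checked in the tests at small steps.  Chain nodes
reflect at the ground plane z = 0.

### Particles and coupling

`N_p = 50` point particles of mass 1 move in the box
`[0, L_x] × [−L_y, L_y] × [0, L_z] = [0, 40] × [−15, 15] × [0, 20]`.
No particle–particle interactions and no back-reaction on the setae.
Hydrodynamics is replaced by a velocity-equilibration surrogate: each
particle feels

* `γ_seta (v_node − v_p) e^(−r/r_f)` summed over chain nodes
  (`γ_seta = 1`, `r_f = 0.75`) — node velocities are finite differences
  over the step, so a moving chain drags nearby particles;
* `γ_ext (v_ext − v_p)` with ambient flow `v_ext = (1.2, 0, 0)`
  (`γ_ext = 0.5`);
* a Morse adhesion force from adhesive nodes,
  `U = u0 (1 − e^(−a (r − r_vdw)))²` with `a = 2`, `r_vdw = 0.5`.

The coupling range `r_f = 0.75` (about one segment length) keeps the
surrogate local.  This matters: with a multi-segment range, a *parked*
chain freezes the water around it over several segment lengths — an
artifact of coupling to velocity rather than solving a flow — and rows of
dwelling long setae then blanket and stall the whole feeding zone.

Adhesion sits on the distal nodes of the last 2 segments.  Named levels:
`none = 0`, `low = 0.3`, `intermediate = 1.0`, `strong = 5.0`.  `low` is
the baseline van der Waals contact that every cuticle surface has; the
scenario variants "without high adhesion" use it.  Baseline contact is the
delivery channel for non-specialised setae: with literal zero adhesion a
seta can stir particles but cannot carry them, and no variant would beat
the bare-flow reference.

Particles integrate by semi-implicit Euler at `dt = 0.01`.  Pairs beyond
the cutoff `r_cut = −r_f ln(10⁻⁵)` are skipped (neglected kernel weight
< 10⁻⁵, aggregate error < 10⁻³ relative).

### Boundaries, mouth, capture

A particle leaving the domain is re-injected at a uniform random position
on the upstream inflow slab `x ∈ [0, 0.05 L_x]` with velocity `v_ext`
(reinjection is also applied to eaten particles, modelling the permanent
particle supply; a periodic-x alternative is available in config).  The
mouth is a half-open box centred at `(L_x/2, 0, 0)`:
`3 × [−1.5, 1.5] × [0, 2.6)`.  Its height, 2.6, lies between the lowest
swept-tip height of a hard short seta at `φ_min = −0.4π` (z ≈ 2.2) and at
`−0.375π` (z ≈ 2.7), so the feeding collapse at too-shallow sweep angles
emerges from geometry rather than from a programmed threshold.  Captures
in a step are processed in particle-index order.

### Geometry

Short rows at `y = ±6.5`: a 7-segment seta at `φ = −0.4π` then places its
tip just above the mouth centre (`6.5 ≈ 7 sin 0.4π`).  Long rows at
`y = ±10` gather over the outer half of the domain and park their tips,
after dwell catch-up, near the short-seta arc on the opposite side —
particles they carry inward are handed over to the strongly adhesive short
tips.  Rows span `x ∈ [L_x/2 − 7, L_x/2 + 7]` with 14 setae each side.

## Observables

* `N_eaten(t)` staircase sampled every 0.1 time units.
* Event log (capture time, particle index); avalanches are maximal
  clusters of events with inter-event gaps ≤ 0.5 (≈ 1/25 of the short
  sweep period), summarised by start time and size.
* Particle density accumulated per step on a 120 × 80 (y, z) grid after a
  burn-in of t = 25, with its y-marginal histogram; normalised to the
  maximum at export.

## Performance

`run()` executes in a single numba-compiled kernel (single-threaded,
`cache=True`); a full default run (t_end = 250, 25 000 steps, up to 672
chain nodes, 50 particles) takes seconds.  The op-by-op Python path
(`initialize` / `step`) implements identical update rules and the test
suite asserts the two produce bit-identical capture logs and occupancy
grids on a shared window.

## What the model does and does not show

The generator *is* the experiment: all inputs are synthetic, and the
defaults above define the study conditions.  Emergent results reproduced
under them: the ordering of short-seta material variants (strongly
adhesive soft tips on hard shafts far ahead; all seta-bearing variants
ahead of the bare-flow reference), screening collapse below a threshold
sweep angle near −0.375π with performance *below* the reference, benefit
of adding hard long setae to the short-seta optimum, an interior optimum
in long-tip adhesion, a handicap for long rows sweeping flat to the
ground, and quasi-periodic capture avalanches locked to the sweep cycle.

Known limitations.  The friction surrogate conserves no fluid momentum
and has no long-range hydrodynamics; there are no particle–particle or
seta–seta interactions, no back-reaction of particles on setae, and
particle size, shape and surface roughness are absorbed into the Morse
parameters.  Because setae feel no external load, material softness acts
*only* through dynamic lag of the driven chain; consequently variants that
differ only in the stiffness of a short distal tip region (e.g. hard long
setae vs. hard long setae with soft tips, both non-adhesive) are nearly
indistinguishable here, and the small penalty such tips show in the
original system is not resolved by this surrogate.  Counts of setae,
segments and particles are stylised, not morphometric; absolute capture
counts are model units, and only orderings and shapes of the curves are
meaningful.
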