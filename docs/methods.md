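# Model and methods

`tumorinit` simulates the earliest stage of solid-tumor formation in a small
patch of epithelial tissue, at the resolution of individual cells.  Cells
are discs (2D) or spheres (3D) on a bounded circular/spherical domain with a
few blood-vessel points on its boundary.  Three phenotypes interact:
epithelial cells (the host tissue), tumor cells (arising by mutation at
mitosis, or pre-seeded), and T-cells (entering from the vessels and
removing tumor cells on contact).  The model is semi-stochastic: migration
and growth follow stochastic differential equations, cycle progression and
death are per-step Bernoulli events, and the chemokine field is a
deterministic functional of the (random) tumor-cell trajectories.

## Chemokine transport without a mesh

Each living tumor cell secretes chemokine at constant rate γ from its
centre.  On an effectively unbounded matrix with constant diffusivity D the
concentration is the superposition of free-space heat kernels convolved
along every source trajectory (Duhamel's principle):

    c(t, x) = Σ_j ∫ γ (4πD(t−s))^(−d/2) exp(−‖x − x_j(s)‖² / 4D(t−s)) ds,

with the integral running over each cell's lifetime [τ_B, min(τ_D, t)].
Traces of dead cells are retained — their chemokine is still dispersing —
and only dropped from evaluation once t − τ_D ≥ t̃ (default 80 s), where the
contribution has decayed monotonically to a negligible level.  The gradient
used for T-cell chemotaxis is the analytic spatial derivative of the same
quadrature.

Numerics: trajectories are sampled at cadence `dt_quad` (default 5 s) and
integrated by the trapezoidal rule; the last node is placed one quadrature
step before "now" (the integrand vanishes there for any r > 0, and the
kernel is singular at r = 0, τ = 0).  Evaluations closer than `eps_r`
(0.1 µm) to a source are clamped and logged.  The portion of a trace older
than t − t* (default 80 s) is replaced by a closed-form tail in which the
spatial factor of the kernel is dropped — valid once r²/(4Dt*) is small
(≤ 0.05 for r up to the domain radius at the defaults).  In 2D this tail,
(γ/4πD)·log((t−τ_B)/t*), is the exact integral of the r = 0 kernel.  The 3D
form used here, (γ/2πD)(1/√t* − 1/√(t−τ_B)), follows the same published
closed form this model family uses, but it exceeds the exact time-integral
of the r = 0 3D kernel by a factor √(4πD); treat 3D concentrations beyond
the tail switch as upper bounds, or push `t_star` beyond the horizon to
integrate everything by quadrature (the steady-state validation tests do
exactly that).  Concentrations are only ever needed at T-cell positions and
vessel points; vessel-point values are refreshed at the `dt_quad` cadence
rather than every motion step.

## Mechanics: haptotaxis and contact repulsion

A cell pulling the matrix with traction force F induces a strain energy
density M⁰ = F²/(2π²E_s R⁴) at its centre (E_s the matrix modulus), sensed
by other cells attenuated as exp(−λ‖x−x_j‖/R_j) and cut off beyond L =
30 µm.  Overlapping cells store Hertzian contact energy,
(16/25 or 2/5)·E_c/(√2π)·(h/R)^{5/2} in 2D/3D, where h is half the centre
overlap.  The drift direction of a cell sums unit vectors to its neighbours
weighted by these energies — long-range terms attract (mechanotaxis up the
strain-energy field), contact terms repel — and the drift magnitude is
α·M_total with mobility α = (F/F̂)²βR³/f (zero for dead cells; M-phase
cells respond to contacts only).  The outer boundary acts as a mirror-image
contact cell; vessel points act as contact spheres of radius R_b.  The sum
of a cell's contact energies (cell–cell, wall, vessel) is the pressure
proxy p that modulates cycling and death, and the total sensed energy
M(x_i) is the quantity compared against the intravasation threshold M_b*.

A note on λ: no published value exists for the attenuation rate.  The
default λ = 10 per cell radius makes remote strain signals decay within a
fraction of a cell diameter, so under defaults the motion is dominated by
contact repulsion, random walk and (for T-cells) chemotaxis; users studying
long-range mechanotaxis should lower λ to O(0.3), at which the signal
decays to e⁻³ across the sensing cutoff.

## Cell cycle, division, mutation, death

G1 (growth), S, G2 (growth) and M (mitosis ≈ 1 s) phases.  G1/G2/M have
fixed mean durations; S exits each step with probability (Δt/T_S)·F(p),
i.e. a geometric residence with mean T_S/F(p), where F(p) =
c₁/(1 + c₂ e^{c₃p}) (defaults 11, 9, 1; F(0) = 1.1) shuts proliferation
down under pressure.  The radius grows linearly at κ = (R_max−R₀)/(T_G1+T_G2)
during G1/G2 with optional noise σ_g, and R_max = 2^{1/3}R₀ so two
daughters of radius R₀ conserve the mother's M-phase volume in 3D.  At
division, mother and daughter (both radius R₀) are displaced to x ± R₀u
along a uniform random direction, touching at the former centre; an
epithelial daughter mutates to the tumor phenotype with probability P_M
(0.25), which opens a chemokine trace.

Death is sampled every step with P_D(Δt) = 1 − 2^{(1/T₂ − 1/T_C)·Δt·G(p)},
with G(p) = c₄/(1 + e^{−c₅p}) (defaults 9, 10).  At G ≡ 1 this is exact
calibration: a colony dividing every T_C doubles in the observed time T₂
for any step size (survival consistency holds identically in the exponent).
Phase boundaries carry their overshoot and tolerate float round-off; this
matters because the tumor calibration (T_C = 21 s, T₂ = 4000 s) sits on a
knife edge — the offspring mean per cycle is 2·2^{T_C/T₂−1} ≈ 1.004, and a
systematic stretch of the realized cycle by even one step per cycle would
flip the population subcritical.

A consequence worth stating plainly: with the printed constants the
zero-pressure death multiplier is G(0) = c₄/2 = 4.5, which multiplies the
calibrated death exponent 4.5-fold for every cell at all times.  Under the
full pressure-modulated model every lineage is therefore strongly
subcritical (tumor offspring mean ≈ 0.09 per cycle) and any tissue decays
within a few cycle times.  The modulation is implemented exactly as stated
and enabled by default (`engine.pressure_modulation`); scenarios that need
a viable tissue — including the immune-comparison experiment below — switch
it off and run on the bare doubling-time calibration.

## Immune response and vessel traffic

T-cells enter at vessel points with per-interval probability
P_T(Δt) = 1 − (1 − A c²/(B + c²))^{Δt}; the saturation level A and scale B
default to 0.05 and 200 ('bad'), or 0.5 and 100 for the 'good' immune
setting.  A new T-cell (radius 4.5 µm, non-cycling, death calibrated like
an epithelial cell) is placed just inside the boundary; in a confluent
tissue some overlap with residents is unavoidable, so placement accepts the
least-overlapping of 16 jittered candidates up to a penetration tolerance
(default 3 µm — transmigration squeezes between resident cells and contact
repulsion resolves the residual within a few steps), otherwise the entry is
skipped.  T-cells drift up the chemokine gradient with sensitivity
µ = µ_factor·α (Table default µ_factor = 10⁴, 'good' 5·10⁴) and engulf
every tumor cell they touch, instantaneously, closing its trace.  Tumor
cells in geometric contact with a vessel sphere whose sensed energy exceeds
M_b* = 0.1 kPa intravasate: they leave through the bloodstream, increment
the cumulative intravasation counter, and with probability P_S = 0.01 are
tagged as seeding events (no downstream dynamics).

## Time integration

Deterministic drift is integrated with classical RK4 (the chemotactic
gradient and the Wiener increment are held frozen across substeps; the
noise enters Maruyama-style as σ√Δt·N(0, I)).  The step adapts so that no
cell displaces more than a quarter of its diameter, including a 3σ noise
allowance; a step that still violates the cap is redone at Δt/2 down to a
floor `dt_min` (default 0.1 s), below which the realized displacement is
clamped to exactly R/2.  The floor exists because the chemotactic drift
µ∇c is numerically enormous at the default parameter scales (µ·α ~ 10⁷–10⁸
while ∇c ~ 10⁻⁴–10⁻²): a literal quarter-diameter rule would drive Δt to
microseconds and the run would never finish.  The clamp preserves the cap
invariant exactly; its practical meaning is that T-cells move at the
maximum resolvable speed (R/2 per floor step, ≈ 11–22 µm/s) whenever any
chemokine gradient is present.  Subprocess order within a step: trace
refresh → mechanics → chemokine → motion → cycle events → extravasation and
engulfment → intravasation → boundary projection, all evaluated on the
pre-move configuration.  Execution is single-threaded and the iteration
order is fixed, so a run is bit-reproducible from (config, seed), and a
checkpointed run resumes bit-identically.

## Initial condition

A disc/ball of radius 40 µm (default) is filled with epithelial cells of
radius R₀ = 3 µm at a target packing fraction (0.7 in 2D → ~124 cells; 0.5
in 3D), placed by random draws and relaxed by contact sweeps until the
largest pair penetration is below 10⁻³R₀.  Pure random sequential
adsorption jams near ~97 cells on this geometry, which is why placement
allows initial overlap and relaxes it.  Cells start in G1 with ages uniform
on [0, T_G1] (set `synchronized_start` for in-phase waves).  Four vessel
points sit equally spaced on the 2D boundary, six octahedrally in 3D.
Optionally all cells within `tumor_seed_radius` of the centre start as
tumor cells with traces open at t = 0 — a pre-initiated microtumor.

## The immune-comparison experiment

The qualitative claim under test: a strong immune response ('good':
A = 0.5, B = 100, µ = 5·10⁴α) suppresses an initiating tumor that a weak
one (the defaults) does not.  Reproducing this from mutation-driven
initiation on the full domain is not feasible at the printed parameter
scales: with γ = 2 the vessel-point concentration reaches only c² ~ 0.1–0.3
against B = 100–200 after tens of sources have secreted for hundreds of
seconds, so T-cell arrivals are rare and late.  The packaged experiment
(`immune_compare`) therefore runs a scaled-down, paired design chosen on
those arithmetic grounds: a 30-µm disc whose central 26 µm starts as tumor
(~50 source cells — the vessel-point signal is nearly unchanged by the
shrink, because the vessels are also closer), pressure modulation off (see
above), and both arms of each replicate sharing a seed and
differing only in (A, B, µ_factor).  The seeded microtumor carries a
secretion history (`tumor_seed_age` = 1000 s, traces opened in the past):
a ~50-cell clone has necessarily been secreting throughout its growth, and
without that history the vessels only sense it hundreds of seconds into
the run, after the near-critical clone may have outgrown what the first
T-cell can clear.  The horizon is t_end = 1000 s; engulfment in
this model is noticeably slowed by chemical memory — the gradient keeps
pointing at traces of cells killed up to t̃ = 80 s earlier, so T-cells
linger in cleared zones — so suppression frequently leaves straggler
cells at the horizon rather than completing extinction.  Reported
outputs: per-replicate final tumor fractions, the one-sided paired t-test
p-value for mean('good') < mean('bad') (the contrast is stated on the
mean; per-pair differences are bimodal — near zero when neither arm
diverges, large and negative when T-cells clear the tumor), and the
'good'-arm extinction rate.  Individual trajectories remain noisy: the
tumor phenotype is an essentially critical branching process (offspring
mean 2·2^{T_C/T₂−1} ≈ 1.004 per cycle), so single runs can crash or treble
on their own, which is exactly why the experiment is paired.

## What the synthetic scenarios do and do not show

All inputs are generated by the package itself; there is no external data.
The cycle times are dimensionless model values (the tumor cycle is
deliberately exaggerated relative to the epithelial one), so absolute times
must not be read as biological hours.  The initializer emulates a confluent
monolayer/patch but not tissue architecture (no polarity, no basement
membrane, no heterogeneous stiffness — the matrix is homogeneous and
isotropic by assumption, durotaxis excluded).  Passing tests demonstrate
internal consistency with the model's closed forms and calibrations, and
qualitative behaviors (tumor takeover, immune suppression, intravasation
counting) — not quantitative agreement with any real tissue.

## Numerical choices and degenerate inputs

* Quadrature: trapezoid over recorded trace samples; refinement is
  second-order on closed traces; on live traces the moving endpoint adds a
  first-order term that is negligible whenever the evaluation point is more
  than a few µm from the source.
* Heat kernel at τ → 0: defined as 0 for r > 0; r = 0, τ = 0 raises.
* Direction degeneracy: a drift direction with ‖z‖ < 10⁻¹² is treated as
  no deterministic drift this step (symmetric configurations).
* T_S = 0 (tumor default) skips the S phase entirely; T₂ = T_C is rejected
  at validation (the death calibration would make the phenotype immortal).
* Doubling-time utility (`branching_doubling_time`): a non-spatial colony
  with death at the bare calibration and division at fixed cycle age,
  started from the stable age profile f(a) ∝ 2^{−a/T_C}; with 2,000 cells
  the first-passage estimate of the doubling time is noisy (per-replicate
  SD ≈ 35%) and carries a finite-population bias of a few percent, which is
  why the acceptance computation averages many replicates.
* Packing failure (too-high `packing_fraction`) raises with a suggestion
  rather than returning a jammed, overlapping state.

## Known limitations

* The printed 3D long-time tail overestimates old-source contributions
  (factor √(4πD)); 2D is exact.
* The pressure modulation G(p) as printed makes all lineages subcritical
  even at p = 0; it is reproduced faithfully, not repaired.
* The chemotactic sensitivity scale makes T-cell speed saturate at the
  numerical cap rather than vary with gradient magnitude.
* Engulfment has no handling time; intravasation requires vessel contact
  in addition to the energy criterion (the criterion alone has no locality
  and would let interior cells leave the domain).
* No nutrient or oxygen fields; pressure stands in for crowding stress.
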