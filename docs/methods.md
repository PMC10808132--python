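# Methods

## Scope and data model

The package analyses steered-pulling trajectories of wireframe DNA
tetrahedra ("mechanocapsules") and implements the arithmetic of the
surface-fluorescence assays used to characterise them.  Trajectories are
exchanged in the oxDNA *classic* formats: a topology file (`N_nt N_strands`
header, then `strand base 3'-neighbour 5'-neighbour` rows) and a
configuration/trajectory file (`t = / b = / E =` headers, then 9- or
15-column per-nucleotide rows).  The newer v2 dialects are out of scope.
Nucleotides are indexed 0-based in file order; coordinates are treated as
unwrapped because the structures (~10 nm) are small relative to their boxes
(an optional minimum-image utility exists but is off by default).

Unit conversions: 1 simulation length unit = 0.8518 nm, 1 time unit =
3.03 × 10⁻¹² s, and 1 force unit = 48.63 pN (the standard oxDNA
energy/length convention).  The force constant is not independently
printed in the source literature for this system; we keep it because it
reproduces the one stiffness printed in SI units — 0.2 simulation stiffness
units × (48.63/0.8518) = 11.418 pN/nm ≈ 11.42 pN/nm — to within 0.05 %.

## Force reconstruction

A pulling protocol is two harmonic traps: one fixed at the anchor
nucleotide, one translated at constant velocity along a unit axis û.  The
series stiffness is 1/k_eff = 1/k₁ + 1/k₂.  Per frame the transmitted force
is k_eff times the *summed stretch of both springs* projected on û:

    F = k_eff · [(x_a − a) + (b(t) − x_b)] · û

with a the fixed trap position, b(t) = b₀ + v·t, and x_a, x_b the
attachment-nucleotide positions.  Counting each stretch positively in the
pulling direction makes the expression reduce, for springs in true
mechanical series, to the common tension; it is zero when both nucleotides
sit on their traps and invariant under rigid translation of the whole
system with its traps.  Extension defaults to the projected separation of
the two attachment nucleotides minus its first-frame value (this convention
shows the rupture jump); a trap-separation convention is selectable.
Against trap separation the slope of a quasi-static pull is the full series
stiffness of traps plus structure; against nucleotide separation it is the
structure alone — both are verified against an analytic three-spring chain
in the tests.

The raw force is smoothed with an exponential moving average.  The
smoothing constant is not specified by the source analysis; we default to
α = 2/(W+1) with window W = 1 % of the frame count, which is scale-free in
trajectory length, and expose it.  Rupture detection reports the global
maximum of the smoothed force, accepted only if the force falls below
(1 − d)·peak within the following w fraction of frames (defaults d = 0.5,
w = 0.1, both configurable).  The validity heuristic is ours: the source
analysis only marks the peak, and an unfinished (still-loading) ramp should
not report a rupture force.  Rupture forces are reported as positive
tensile values; mean ± SEM with explicit n is the convention for
replicates.

## Structural metrics

Base pairing is judged geometrically because re-implementing a
nucleotide-level hydrogen-bond energy is out of scope: each nucleotide
carries a bonding site at position + 0.4 length units along its base
vector, and a designed pair is bound while the sites are within 0.4 length
units (≈0.34 nm, configurable) and the base vectors are anti-aligned
(dot < 0, optional).  The denatured fraction of a frame is 1 − bound/designed
over a reference pair list; because it is ambiguous whether a single
quoted percentage counts only the force-bearing strand's pairs or the whole
structure, the pipeline reports both (`fraction` and `fraction_fb`).

Pore geometry treats each face as the triangle of its three hinge
nucleotides (user-specified; the builder labels them automatically for the
synthetic structure — there is no automatic vertex detection for arbitrary
structures).  The incircle radius is 2·area/perimeter, zero for triangles
flatter than 10⁻⁹ nm².  Per frame the four radii are aggregated as max and
mean (the plotting convention is: line at the max, shading between max and
mean).  Leakage is strict: a frame is leaky only when the max radius
*exceeds* the cargo radius.

## The synthetic trajectory generator

`cg_sim` exists so the whole pipeline can be exercised without an external
GPU engine.  It is a bead-per-nucleotide overdamped Langevin model:

- **Geometry.**  Four face strands each run the perimeter of one face of a
  regular tetrahedron, so each of the six duplex edges carries two
  antiparallel strands; beads sit on straight edge axes at the 0.34 nm
  helical rise (no explicit helix), and the two strands of an edge are
  offset ±0.34 nm perpendicular to it so paired bonding sites coincide at
  rest.  One face strand is truncated and the last `fb_bp` pairs of its
  final edge are carried by a separate force-bearing (FB) strand whose
  outer terminus (at a vertex) is the ligand/pull point — releasing it is
  rupture.  Five strands total, mirroring the 5–6-oligonucleotide designs.
  Sequences follow a fixed repeating pattern with exact Watson–Crick
  complementarity across every designed pair.
- **Forces.**  Harmonic backbone springs between strand neighbours (rest
  lengths from the built geometry, so the initial frame is force-free;
  default stiffness 400 pN/nm), harmonic base-pair springs (300 pN/nm),
  the two traps, optional soft excluded volume (off by default, for
  speed; the structures under study do not self-collide in these runs).
- **Breaking.**  A pair bond breaks irreversibly the first time its
  extension exceeds x* (default 0.8 nm); every break is logged as
  (step, i, j).  Threshold breaking is deterministic given the seed, which
  is what makes the event log usable as a test oracle; a Bell-model
  stochastic off-rate (rate k₀·e^{f·x_b/kT}) is available behind a flag.
- **Integration.**  First-order (no inertia): Δx = (Δt/γ)F + √(2kT Δt/γ)ξ,
  with T = 310 K, friction γ = 10⁻⁶ pN·s/nm and Δt = 10⁻¹⁰ s by default.
  Only quasi-static pulling behaviour matters for testing the analysis, so
  inertia would add nothing.  A step that moves any bead farther than the
  largest rest length aborts with a diagnostic.  The integer seed fixes the
  entire noise stream: identical configurations give bit-identical
  trajectories and event logs.

**Choice of the breaking threshold.**  At 310 K the pair-extension
fluctuation of the bead-ladder duplex is σ ≈ 0.11 nm (the soft mode is
shear between the two strands of an edge, which a plain distance spring
does not restrain).  An irreversible threshold must sit far above the
thermal first-passage range or bonds break at zero force; x* = 0.8 nm
(≈7σ) produces no spontaneous breaks in 3 × 3·10⁵-step equilibrium runs
while remaining reachable under load.  The consequence is that per-bond
rupture forces are k·x* ≈ 10²  pN — an order of magnitude above the tens of
piconewtons of real nucleotide-level models, in which breaking is thermally
activated well below the mechanical limit.  This is a known, accepted
limitation: the generator reproduces *orderings and trends* (rupture force
monotone in bond strength and in FB pair count; denaturation growing with
anchor-to-pull separation; pore radii bounded below rupture), not absolute
forces, and the tests assert exactly those properties.

**Loading rate.**  The reference pulling rate is 1.4 × 10⁴ nm/s
(5 × 10⁻⁸ length/time units).  At the default timestep that rate needs ~10⁷
steps to cover a full pull, so `make_pull_protocol` accepts a target pull
distance and, when the configured step budget cannot cover it, raises the
rate to fit and logs the rescaling — the pull is scaled down in duration,
never silently truncated.  Desk-scale runs in the tests and the acceptance
script use 3 × 10⁵–4 × 10⁵ steps (pull rates ~10⁶ nm/s); the drag force this
adds (γv ≈ 1 pN) is negligible against the forces of interest, and the pull
duration remains long against the slowest relaxation of the structure.

**What the generator does not emulate.**  Sequence-dependent stacking and
salt dependence, helical geometry, hydrodynamics, and realistic absolute
kinetics.  Passing tests therefore demonstrate that the *analysis* is
correct and that the qualitative mechanics are as designed; they do not
validate quantitative predictions for laboratory structures.

## Assay arithmetic

Quenching efficiency is (1 − I_q/I_uq) × 100 — the multiplication applies
to the whole bracket, the only reading consistent with reported
efficiencies near 87 % — clipped to [0, 100] with a warning.  Fold
dequenching is 1/(1 − Q.E./100), so Q.E. and fold are mutually consistent:
fold(Q.E.(a, b)) = b/a.  The F-factor is the ratio of intensity-vs-
concentration slopes of labelled DNA and reference lipid dye.  Bilayer
calibration converts fluorophore mole fraction to density as
fraction × leaflet_factor × 10⁶/footprint per µm² (footprint 0.72 nm²;
leaflet factor 2 by default — the dye is assumed present in both leaflets,
a documented assumption since the convention is not stated in the source —
both configurable) and regresses intensity on density by OLS with an
intercept, reporting R².  Probe intensity converts to density through that
curve divided by the F-factor; intensities below the intercept return 0
with a warning.  Mean inter-probe spacing uses the square-lattice
convention ρ^(−1/2): 2890 µm⁻² ↦ 18.6 nm (a hexagonal convention would
give 20 nm and was rejected because the square convention matches the
reported ~18 nm).  Decay half-life comes from a least-squares fit of
A·e^(−λt) (offset term optional and off by default, since the fit form
is unstated), t½ = ln 2/λ; non-decaying data yield an invalid fit rather
than an exception.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at desk scale: 8–14 bp
edges (96–168 beads) for property sweeps and 17–20 bp edges (204–240
beads) for the pore-bound runs, 1–4 × 10⁵ steps per run, a few seconds each
on one CPU with the numba-compiled integrator.  The sub-rupture runs stop
at half the single-bond threshold force (0.5·k·x*) and verify that the
event log is empty.  Monotonicity checks use 5 planted levels × 10 seeds
and compare level means by Spearman rank correlation; the position sweep
averages 3 seeds per position and allows a 0.02 tolerance between
neighbouring means.  Ties and degenerate inputs: EMA requires α ∈ (0, 1];
effective stiffness requires positive stiffnesses; degenerate triangles
return radius 0; leakage is strict at the boundary; a pore radius exactly
equal to the cargo radius does not leak.

## Known limitations

- Absolute rupture forces and absolute denatured percentages of
  nucleotide-level models are outside the generator's reach (see above);
  reproducing those requires a full oxDNA2 run on the real sequences.
- The geometric hydrogen-bond criterion can transiently misclassify a
  strongly sheared but intact pair; end-of-run fractions on the synthetic
  generator are accurate to ~1 pair in 50 at equilibrium.
- The builder constructs one specific 5-strand layout; arbitrary wireframe
  designs must supply their own pair lists and pore faces.
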