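# Methods

`epitube` implements four quantitative components of a single scientific
argument about why embryonic lung and kidney tubes elongate with a ~2-fold
bias (they lengthen about twice as much as they widen): a continuum model of
tube-cross-section collapse, an estimator of luminal wall shear stress, a
cell-based (vertex) model of the apical epithelium under a longitudinally
biased force, and a branch-morphometrics pipeline for 2D explant time
series. Synthetic generators provide every input with exact ground truth, so
the whole chain is testable without imaging data.

## Tube collapse (`epitube.tube_collapse`)

**Model.** The tube cross-section is a closed elastic ring of midline nodes
(default n = 100 segments) carrying stretching and bending energy

U = (E\* t / 2) ∮ ε² ds + (E\* t³ / 24) ∮ κ² ds,

with plane-strain modulus E\* = E/(1 − ν²), hoop Cauchy strain
ε = (ℓ − ℓ₀)/ℓ₀ per segment, and discrete curvature κ = turning angle
divided by the mean adjacent rest length per node. The tissue is
intrinsically flat (zero rest curvature): a stress-free configuration would
be a straight strip, so even the initial circle carries bending pre-stress
at its surfaces while its midline is strain-free. The ring is a
geometrically nonlinear stretch+bend (Euler–Bernoulli) discretization;
transverse shear is neglected, so ν enters only through E\*. Defaults:
E = 1 (the energy scale), ν = 0.49, ρ = 1, τ = 1, t/R = 0.5.

**Dynamics.** Newton's second law M ẍ + D ẋ = f with lumped mass
(m_i = ρ t s̄_i) and mass-proportional damping D = M/τ is integrated with
an explicit Newmark scheme (γ = 1/2, β = 0) in predictor–corrector form.
The step is sized from the stiffest discrete mode — axial stretch, contact
penalty, and the nodal zigzag bending mode whose stiffness grows as
E\*t³/ℓ³ and dominates at fine discretizations — and is shortened
adaptively during fast snap-through so no node crosses more than a tenth
of the thickness per step (the contact layer stays resolved).
Elastic forces are the analytic gradient of U (verified against finite
differences to ~1e-9 relative). Contact — wall-to-wall and wall-to-clamp —
is a penalty on midline separations below one thickness (half-thickness
offsets on both sides), restricted to node pairs whose wall normals oppose
(facing surfaces): pairs that are close only because they lie along the
same curved wall segment, e.g. across a lobe cap, are not opposing
surfaces and must not be pushed apart. The shipped stiffness keeps
interpenetration of facing walls below 5% of t.

**Scenarios.** (1) *Pressure*: a follower pressure (force along the current
inward normal, potential ΔP·A) ramped linearly at 1.5e-4 E/τ. A
deterministic mode-2 radial perturbation of amplitude 1e-4 R seeds the
buckling, and the onset is measured by a linear-stability probe riding the
ramp: at every check the mode-2 Fourier amplitude is renormalized back to
the seed floor and its per-check growth rate recorded; the growth rate is
a clean, nearly linear function of the pressure, and the pressure at which
its running mean turns positive is reported as the buckling pressure.  On
a thin ring (t/R = 0.1) this lands within ~1% of the classical threshold
3E\*I/R³ (I = t³/12).  At the study's thick wall (t/R = 0.5) the measured
onset is genuinely ~15–25% above the thin-ring formula: the pre-buckling
hoop compression (ε ≈ −P R/(E\*t) ≈ −6% at threshold) shrinks the ring
before it buckles, and the formula neglects that finite-thickness effect —
so the classical law is validated in its own asymptotic regime and the
thick-ring deviation is reported as physics, not error. (2) *Clamps*:
rigid horizontal walls approach at 2e-3 R/τ until their gap is 2.5 t, then
hold; the equilibrium is the expected stadium shape (strain-free flat
walls, two lobes at the gap radius). (3) *Volume*: the enclosed area is
drained linearly toward 20% of its initial value through a stiff quadratic
penalty whose equivalent pressure is capped at twice the ring buckling
pressure (a Huber penalty): while the target is reachable the volume error
stays below 0.5%, and once wall contact resists, the capped drive keeps
the collapse quasi-static instead of crushing the contact — the drained
equilibrium stalls at the contact-limited volume (≈46% of the initial
area for t/R = 0.5). Runs end at static equilibrium (max nodal speed
< 1e-7 R/τ by default); after the ramp stops, the total mechanical energy
(elastic + kinetic + load potential + contact penalty) is monotonically
dissipated, which the tests assert sample by sample.

**Stress read-outs.** `hoop_stress` is the midline membrane stress E\*ε
(zero on the undeformed circle). `surface_stress` is the extreme-fiber
magnitude E\*(|ε| + t|κ|/2), which includes bending; this is the quantity
that localizes at the two high-curvature lobes of a collapsed cross-section
(peak ≥ 5× median in the clamp equilibrium and ≥ 4× in the drained-volume
equilibrium at its quasi-static drive) while the membrane part stays
comparatively uniform. Profiles are arc-length parameterized from node 0.

## Wall shear stress (`epitube.shear_stress`)

**Closed form.** For fully developed laminar flow in an elliptical duct the
exact solution u(y,z) = u_max(1 − y²/a² − z²/b²), u_max = 2ū,
Q = πabū gives the wall profile τ(θ) = 2μu_max √(cos²θ/a² + sin²θ/b²):
maximal on the flat minor-axis co-vertices, minimal at the strongly curved
major-axis tips. The arc-length-weighted boundary mean is computed by
adaptive quadrature. Defaults are the measured values for embryonic lung:
μ = 0.016 Pa·s and ū = 0.364 µm/s; a flow-rate driver (e.g. the
literature estimate 420 µm³/s) may be given instead and is converted
exactly through ū = Q/(πab).

**Arbitrary sections.** For simple polygons, the fully developed axial-flow
problem −∇²u = G/μ, u = 0 on the wall, is solved by finite differences on
a regular grid (default 400 cells across the major axis) with
Shortley–Weller leg shortening at the boundary; by linearity the solution
is rescaled exactly to the requested mean velocity or flow rate. Wall shear
comes from the one-sided normal derivative through u = 0 at the wall
(quadratic extrapolation through samples at 2h and 4h along the inward
normal), evaluated at equally spaced boundary points. On ellipses with
aspect ratios 1–10 the boundary-mean shear agrees with the closed form to
well under 2% at the default resolution. The solver refuses sections whose
narrowest interior opening (longest run per scanline, central 80% of the
span, so end-taper is ignored) is resolved by fewer than 20 cells.

**Bead velocimetry.** The per-track speed is the maximum consecutive-frame
displacement over the frame interval (the maximum-track-speed convention of
spot-tracking software); the fastest track is a lower bound on the true
peak velocity because beads rarely sit on the tube axis, and
ū = u_max/2 follows from the parabolic profile. An optional 3-point moving
average handles noisy tracks.

## Vertex model (`epitube.vertex_model`)

**Energy and dynamics.** Cells are shared-vertex polygons with
U = Σ_k λ(A_k − A0_k)² + Σ_k β(C_k − C0_k)² + Σ_e γ_e ℓ_e; λ = 100,
β = 10, γ = 1 for cell–cell edges and 10 for tissue-boundary edges, in
arbitrary units with unit target cell area — the common vertex-model
operating point. Vertices move by overdamped dynamics
drag·ẋ = −∇U + f_ext (drag = 10). The analytic forces match finite
differences of U to 1e-6 relative (asserted in tests). The time step
adapts so that the 98th-percentile vertex displacement stays below half the
T1 threshold; the few vertices above that percentile (transients around a
fresh division or a pending rearrangement) are clipped to the cap, which
keeps every displacement below the T1 threshold and preserves the per-vertex
descent direction. Energy descent during unforced relaxation is asserted
step by step in the tests.

**Rearrangements.** Interior edges shorter than 1% of the mean edge length
undergo a T1 swap (new edge perpendicular, 1.5× threshold); boundary edges
shorter than the threshold are collapsed to a single vertex — boundary
tension shrinks them and they have no T1 partner, so without collapse they
become stuck force singularities. A swap/collapse cooldown of 50 steps per
vertex pair prevents contested edges from flip-flopping under a biased
force field. Triangular cells below 1% of the mean area are removed (T2)
onto their centroid.

**Growth and division.** Each cell grows from its birth size toward its own
sampled division area: the target area ramps linearly (doubling over the
sampled cycle duration, continuing beyond it) and saturates at 1.1× the
sampled division area so the realised area — a few percent below target in
a crowded tissue — reliably crosses the threshold. Division requires age ≥
cycle duration *and* area ≥ division area. The division plane passes
through the centroid along the shortest principal axis of the polygon's
second-moment tensor (Hertwig's rule: perpendicular to the longest axis);
exact ties are broken by a seeded uniform random angle, and a cut that
grazes a vertex is retried with ±5° jitter. Daughters take half the
mother's grown target (size continuity), age 0, and freshly sampled cycle
duration and division area; the recorded division angle is the angle of
the daughter-centroid axis to the longitudinal (force) axis, folded to
[0°, 90°]. The differentiated top/bottom rows never divide and are not
size-regulated by the division machinery; their targets grow to the global
cap (5× A0). An optional aspect-ratio gate (random axis below a configured
cell elongation) exists but is off by default.

**Calibration.** The cycle duration N(20, 10) a.u., division area
N(1.8, 1.1) A0 (both resampled-truncated positive) and the growth cap of
5 A0 were fixed by a parameter sweep so that the *unforced* 100-cell tissue
after 48 a.u. reproduces an apical area CV of ~0.6 and ~30% six-neighbour
cells (measured 0.586 and 31.6% as 5-seed means, with seed-to-seed spreads
of ±0.03 and ±1.5 points), at ~300 cells. The boundary force unit is
anchored the same way: `force_scale = 4.0` native force units per "1 a.u."
of boundary force makes f = 1 a.u. produce the 2-fold elongation bias
(measured 2.05 ± 0.03 over 5 seeds). Elongation bias is
(L_f/L_0)/(W_f/W_0) with extents from the bounding box of cell centroids
(less sensitive to single protruding cells than vertex extents), L along
the force axis. A quiescent lead-in of 5 a.u. (initial ages sampled so no
cell divides during the first few time units) lets the freshly built
lattice relax mechanically before mitoses are oriented by cell shape;
without it the first division wave carries the lattice anisotropy and the
unforced division-angle distribution is measurably non-uniform.

**Tissue statistics.** Area CV uses the population standard deviation over
all cells (boundary cells included). The neighbour count of a cell is the
number of cells sharing at least one edge with it; the hexagon fraction is
the fraction of cells with exactly six such neighbours, again over all
cells. Both the neighbour-count histogram and the per-cell aspect-ratio
distribution are emitted; the neighbour-count histogram is the calibrated
quantity. Displacement profiles track founder cells through divisions via
the mean centroid of their descendants, normalized by the maximum absolute
axial displacement.

## Branch morphometrics (`epitube.morphometrics`)

Grayscale frames are segmented by CLAHE local-contrast enhancement,
rolling-ball background subtraction, Otsu thresholding and Gaussian
boundary smoothing with re-thresholding at 0.5; only the largest foreground
component is kept (discards are logged). The preprocessing parameters
(clip limit 0.01, ball radius 50 px, σ = 2 px) are package defaults, all
exposed.

Skeletons come from topology-preserving thinning, followed by two cleanups:
endpoint spurs shorter than the local tube width (2× the distance transform
at their junction) are pruned, and endpoint tails that run into rounded
caps — recognizable because the distance transform still rises walking
inward — are trimmed back to the cap centre, where the medial axis of a
round-capped tube actually ends. Junction pixels (≥3 skeleton neighbours)
are clustered into single nodes at their centroid; endpoints have exactly
one neighbour. Branch length is a corner-cut polygonal estimate (chords
through every second path pixel): it coincides exactly with the classic
axial/diagonal step metric on straight paths but removes the up-to-8%
staircase overestimate on oblique ones, keeping lengths of gently curved
tubes within ~2% of truth. Branch width is the local thickness — twice the
Euclidean distance transform sampled along the branch — averaged over
pixels farther than one local radius from any junction (a fully excluded
branch falls back to its midpoint value and is flagged).

Branches are tracked across frames by maximal overlap of the new branch's
skeleton with the previous branches' footprints (skeletons dilated by half
their measured width); ties break by larger overlap, then smaller centroid
distance. The largest-overlap successor continues a lineage; additional
matches to the same predecessor start child lineages (a bifurcation), and
unmatched branches start fresh lineages. Relative length/width series are
normalized to each lineage's first appearance (branches appear at different
times), and the 2D elongation bias of a track is relative length divided by
relative width at its last frame. Coordinates are 0-based (row, col),
y-down; all public outputs are in µm.

## Synthetic data (`epitube.synthetic`)

All generators are deterministic under a fixed seed and return exact ground
truth. `make_honeycomb` builds rows of unit-area pointy-top hexagons; rows may
differ by one cell, so any cell count is reachable with regular,
*unstrained* hexagons, and the row count is chosen to bring the bounding
box closest to the requested aspect (100 cells at aspect 1 become eleven
rows, ten of 9 cells and one of 10, at bounding-box aspect 0.98).  Only
when no regular layout comes within 10% of the requested aspect is the
lattice rescaled anisotropically — residual lattice strain would otherwise
bias the first division orientations.  The top and bottom rows are flagged
differentiated, and the per-cell cycle/threshold state is sampled.
`make_lumen_polygon` produces elliptical lumens (e.g. a = 20, b = 1 µm:
the ~2 µm collapsed luminal width) and dumbbells with a central waist of
relative half-width √w between two lobes. `make_bead_tracks` advects beads
placed uniformly in an elliptical section with the Poiseuille speed
profile (default peak 0.73 µm/s) and emits image-plane tracks (y axial,
x transverse) with optional Gaussian position noise — so the fastest-track
read-out is a lower bound by construction. `make_tube_image_series` renders
a gently curved centerline (arc-length exact; default relative sine
amplitude 0.08, mild enough that skeleton lengths stay within the 3%
contract) with round caps: a pixel is foreground iff its centre lies within
width/2 of the centerline, making mask widths unbiased to < 0.5 px.
Lengths/widths interpolate geometrically between the first and last frame;
an optional side branch appears at a configurable frame.

What these generators do *not* emulate: real fluorescence texture, uneven
illumination, segmentation ambiguity at branch points, 3D projection
artifacts, out-of-plane tube motion, or mesenchymal background. Passing
tests therefore demonstrate correctness of the measurement chain on clean
geometry at realistic scales, not robustness to raw-microscopy artifacts.

## Problem sizes and seeds

The shipped study conditions are those of the modeled system: 100-cell
tissues run for 48 a.u. (five seeds for every reported mean), rings of 100
elements (200 for the refinement check), 400-cell flow grids, and 5-frame
image series. The property tests that sweep the force or tension axes use
a reduced tissue (64 cells, 24 a.u., five seeds per point), which is
sufficient for the monotone trends they assert. Every stochastic component
consumes a `numpy` `Generator` seeded from the run configuration; identical
configuration and seed reproduce results bit for bit.

## Known limitations

- The ring model omits transverse shear; at t/R = 0.5 the thin-ring
  buckling formula itself is only accurate to a few percent, which the 10%
  acceptance band absorbs.
- The flow solver assumes fully developed unidirectional flow on a planar
  section — no secondary flows, no fluid–structure coupling.
- The vertex model applies the shear-stress cue as an abstract boundary
  force in arbitrary units; force levels are deliberately not mapped to
  physical shear-stress magnitudes.
- Branch tracking is overlap-based and assumes explants drift little
  between frames relative to the branch width.
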