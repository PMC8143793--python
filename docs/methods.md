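# Methods

## Scope and model

`fibrosim` implements an in-silico pipeline for assessing whether a fibrotic
left-atrial (LA) substrate can sustain reentrant drivers (RDs, "rotors"):
cell-scale human atrial membrane kinetics with AFib and fibrotic remodeling,
a monodomain tissue solver on triangulated (optionally bilayer) surfaces, a
clinical rapid-pacing induction protocol, phase-based rotor detection and
region-wise scoring, fibrosis spatial-pattern metrics with the published
pro-RD classification polynomial, and a virtual-cohort driver that runs the
whole chain over synthetic substrates and computes the associated
statistics.  Patient LGE-MRI-derived geometries are not publicly available;
all experiments here run on synthetic surrogates whose role is to emulate
the *features the analysis consumes* (burden, texture, regions, pacing
sites), not any individual anatomy.

## Membrane model

The cell model is the standard 21-variable human atrial action-potential
model (voltage, 12 voltage-dependent gates, Ca-dependent `f_Ca`, the
SR-release gates `u`, `v`, `w`, intracellular Na+/K+/Ca2+ and two SR
compartments).  Two remodeled parameterizations are built by scaling maximal
conductances:

* **afib** (chronic AFib): I_Kur x0.5, I_to x0.5, I_CaL x0.3;
* **fibrotic** (TGF-beta1 / fibrosis-associated): the AFib scalings composed
  with I_CaL x0.5 (net x0.15 of baseline), I_Na x0.6, I_K1 x0.5.

The fibrotic changes are defined *relative to the AFib model*, hence the
multiplicative composition.

### Integration

Production integration is Rush-Larsen for all gates (exact exponential
update toward the voltage-dependent steady state) with forward-Euler voltage
and concentration updates.  The default cell-scale step is dt = 5 us; at
that step the integrator agrees with an independent classical 4th-order
Runge-Kutta reference at dt = 2 us to within 0.3 ms in APD90 and 0.5% in
max dV/dt (test-enforced bounds: 0.5 ms and 5%).  Tissue kernels use
dt-locked lookup tables for the 12 voltage-gated Rush-Larsen coefficients
and the voltage-only current factors, sampled nearest-neighbor on a 0.02 mV
grid (steady-state perturbation < 1e-3); a fused numba kernel advances all
nodes.  Nernst potentials are cached and refreshed every 1 ms (intracellular
concentrations drift by well under 0.1% per ms).  The SR-release sigmoid
arguments are saturated at |45| (the sigmoids are numerically 0/1 beyond
that) to keep `exp` on its fast path.

### Cell pacing protocol

Each variant is first equilibrated for 10 s without stimulation — this is
what exposes the fibrotic variant's depolarized diastole (about -75 mV, a
direct consequence of halved I_K1, and consistent with the quiescent-tissue
abnormal-depolarization threshold near -75 mV).  Limit-cycle pacing then
applies a fixed 2 ms, 30 pA/pF stimulus at the chosen basic cycle length
until the successive-beat APD90 difference falls below 0.1 ms (cap 200
beats).

The stimulus amplitude deserves a note.  A per-variant "2x diastolic
threshold" convention turned out to be unstable for the fibrotic variant: at
~2x its own threshold the fibrotic cell shows intermittent capture at BCL
500 ms, never satisfies the APD tolerance, and the model family's well-known
slow intracellular-concentration drift then carries it to a -68 mV diastole
and badly prolonged APD.  A fixed 30 pA/pF (about 2.7x the non-fibrotic
threshold) is the smallest round amplitude that gives robust 1:1 capture and
limit-cycle convergence for every variant, and is therefore the default.

APD is measured at 90% repolarization from the maximum-upstroke instant,
with the stimulus current's direct contribution subtracted from dV/dt so
`dvdt_max` is the intrinsic ionic upstroke rate, not a stimulus artifact.

Under this protocol the fibrotic-vs-AFib comparison yields a +15.4% APD90
prolongation and a -46.4% max-upstroke change.  The upstroke reduction is
about 3 points smaller than the -49.6% the parameterization is cited to
produce: steady-state Na-availability arithmetic (h_inf*j_inf at each
variant's diastole times the 0.6 g_Na scaling) predicts -50%, but
integrating the full dynamics gives the depolarized fibrotic diastole a
m-gate head start (m_inf is ~2.6x higher at -74.6 than at -80.6 mV) that
recovers part of the upstroke; the result is insensitive (±0.3 points) to
every stable stimulus convention we tested.

## Tissue model

The monodomain equation beta*C_m dV/dt = div(sigma grad V) - beta(I_ion -
I_stim) is divided through by beta*C_m, turning conductivities into
diffusivities D = sigma/(beta C_m).  Linear-triangle FEM stiffness assembly
uses the per-element tensor D = D_T I + (D_L - D_T) f f^T with f the unit
fiber vector projected into the element plane; the mass matrix is lumped.
Elements labeled fibrotic use the fibrotic conductivity pair.  Interlayer
links of bilayer meshes contribute a pairwise exchange D_link * A_node /
offset^2 (a 1D conductor with the node's lumped-area cross-section).
Time stepping is operator-split: reaction first, then explicit diffusion
with sub-steps chosen from a Gershgorin bound on the assembled operator so
the update is unconditionally stable in practice (the stiff interlayer links
raise the bound; sub-steps absorb it).  Everything is deterministic —
identical inputs give bit-identical results.

Conductivities (S/m): healthy sigma_L = 0.409, sigma_T = 0.0820 (5:1);
fibrotic sigma_L = 0.177, sigma_T = 0.0221 (8:1); interlayer 0.8.  C_m = 1
uF/cm^2.  The surface-to-volume ratio beta = 0.198 /um is a *calibrated*
quantity, not a measured constant: it is the single knob that maps
conductivity to diffusivity, and it is set so that a planar wave in healthy
tissue on a 200 um strip conducts at the effective longitudinal CV of
71.49 cm/s.

### A note on the effective-CV pair

The effective CV pair (71.49, 37.14) cm/s has ratio 1.925, below the
continuum bound sqrt(sigma_L/sigma_T) = sqrt(5) = 2.236 that any monodomain
implementation must produce with these conductivities (discretization slows
the thin transverse front further, raising the ratio to ~2.5 at 200 um).
beta*C_m scales both CVs together, so no calibration can reach both numbers:
with beta calibrated to the longitudinal target, the transverse CV comes out
near 29.5 cm/s (about 21% below 37.14).  We calibrate to the longitudinal
value and report the transverse number as it falls; the corresponding
acceptance check is expected to fail and is left failing.  (The published
pair presumably reflects measurement in curved patient meshes with dispersed
atlas-mapped fibers, which a clean strip cannot reproduce.)

Activation is the upstroke crossing of -10 mV; CV is measured between the
25% and 75% stations of a strip; a station that never activates yields a
NaN "propagation failure" result rather than an exception, since decremental
conduction is a legitimate outcome.

## Synthetic substrates

Sheets are regular triangulated grids.  The LA surrogate is an ellipsoidal
shell (radii 30/25/28 mm, surface area ~97 cm^2) spanning colatitudes 0-150
deg, with the open bottom edge as the mitral rim, four PV ostium holes, an
appendage bulge with an open tip (six boundary loops total), and rule-based
fibers (circumferential flow re-oriented to circulate around each ostium).
Fibrosis patterns are thresholded graph-smoothed random fields: per-element
white noise diffused on the element-adjacency graph (iteration count set by
the correlation length), optionally remixed with a fraction of fine-scale
noise ("patchiness"), then cut at the area-weighted quantile that achieves
the target burden exactly (mean achieved burden over 50 seeds is within
0.1% of target).  Correlation length is the fibrosis-entropy control knob:
longer correlation means fewer, smoother interfaces and lower FE at fixed
burden (test-enforced).  All outputs are pure functions of (spec, seed).

The five-region partition grows the left and right PV regions geodesically
from the ostia rims until each holds 15% (+-1%) of total surface area, then
splits the remainder into floor / posterior / anterior(+LAA) by surrogate
coordinates.  Fifteen pacing sites are placed at canonical surrogate
positions: anterior and posterior aspects of each PV ostium (8), LAA base,
mitral annulus, posterior wall, and four additional distributed wall sites
to reach the stated count of 15; each site is the node set within 1 mm of
its anchor, and the LPV region contains exactly the four left-PV sites.

## Induction protocol and classification

The standard train delivers 12 stimuli: two pulses at a 300 ms coupling
interval, then intervals ramping down by 20 ms to 200 ms, with the remaining
intervals held at 200 ms until the train totals 12 pulses (intervals 300,
280, 260, 240, 220, 200 x6; last onset at 2500 ms).  This padding is the
unique completion consistent with a 12-stimulus train that starts at 300 ms,
ends at 200 ms and ramps in 20 ms steps.  Tissue is pre-initialized from the
variants' BCL-500 limit cycles and allowed a stimulus-free settling period.
The tissue stimulus is 2 ms at twice the tissue capture threshold (bisected
once per substrate); the reduced-scale cohort uses a fixed 60 pA/pF, which
is about twice the threshold measured on its sheets.

Activity is *extinguished* when no node crosses the activation threshold for
a full quiet window (500 ms at full scale); it is *sustained* when it is
still alive inside the final quiet window of the post-pacing observation
period (5000 ms at full scale; reduced-scale runs shorten it, see below).
Sustained episodes are classified from the post-pacing voltage movie:

* **RD** — at least one persistent free-wall phase singularity;
* **macroscopic reentry** — nonzero phase winding around a boundary loop
  (mitral rim, PV ostium) with no free-wall singularity; excluded from
  driver statistics downstream.

If both signatures are present the driver takes precedence and the record is
flagged ambiguous; sustained activity with neither signature is recorded as
macroscopic reentry with the ambiguity flag (no organizing driver found).

Phase is the angle of the analytic signal (Hilbert transform) of the
sliding-mean-removed voltage (500 ms window); quiescent nodes (peak-to-peak
< 5 mV) are masked.  Per frame, elements whose boundary phase winds by
+-2pi are singular; singular points link frame-to-frame by nearest neighbor
within 2 mm per frame gap, and trajectories shorter than ~one rotation
(100 ms at the reentrant cycle lengths seen here) are discarded.  Unique
morphologies are single-linkage clusters of trajectory mean positions with a
10 mm merge radius (about half a region's linear scale).  The region-wise
inducibility score IdS divides the RD inductions from a region's pacing
sites (summed across models) by the region's site count; both the raw
numerator and the normalized score are available.

## Reduced-scale virtual cohort

A complete patient-scale induction (0.6-1.4M nodes, 7.5+ s of activity) is
far outside a desk budget, so the cohort runs on a reduced scale chosen once
and documented here.  Substrates are 20 x 20 mm sheets at 400 um with
conductivities divided by (s_l^2, s_t^2) = (9, 2.25) — an *anisotropic
rescaling* of the monodomain equation: dividing sigma_d by s_d^2 is exactly
equivalent to stretching the d-coordinate by s_d = (3, 1.5), so the sheet
represents a 60 x 30 mm full-conductivity tissue sampled at (1.2, 0.6) mm.  The scale
pair is constrained by sigma_L >= sigma_T within each tissue class (s_l/s_t
< 5) and was chosen so that healthy tissue stays robustly conducting (its
wavelength exceeds the domain, so fibrosis-free tissue cannot sustain
reentry) while fibrotic tissue becomes a slow, strongly anisotropic
conductor whose clusters can host micro-reentrant circuits.  At this scale
the effective grid coarseness also slows fronts below their continuum
speeds, which is part of the (documented) reduced-scale conditions rather
than a defect: what the cohort must reproduce is the *qualitative*
burden-inducibility relationship, not patient-scale CVs.

Reduced-scale protocol windows: 1200 ms post-pacing observation with a
400 ms quiet window (about six reentrant rotations at the ~200 ms cycle
lengths observed), 600 ms settling, recording every 10 ms.  Each model is
paced from three fixed sites (left edge, right edge, top), the cohort
default being the largest site count that keeps a 20-model cohort inside a
practical test budget.  Burdens sweep 5-25% linearly across models
(cohort-like means are ~14%); model seeds spawn deterministically from the
master seed.

What the generator does *not* emulate: atrial curvature and wall-thickness
variation, atlas fiber dispersion, patient-specific burden/texture joint
statistics, and the O(100 cm^2) surface over which patch statistics
self-average.  Passing cohort tests therefore demonstrate that the pipeline
recovers the direction and significance of the burden-inducibility
relationships on its own synthetic conditions — not that it reproduces the
published patient-cohort fractions, which depend on non-public substrates.

## Fibrosis metrics

FD(e) is the area-weighted fibrotic fraction within a 2.5 mm geodesic
(adjacency-graph) radius of element e; FE(e) is the binary entropy of the
discordant edge-adjacent-pair fraction q in that neighborhood (0*log0 = 0).
The entropy definition is deliberately *not* a function of FD alone — a
solid block and a speckled pattern of equal density differ strongly in FE —
because a proportion-only definition would collapse the published 2D
classifier.  The 2.5 mm radius is roughly twice an imaging voxel.  Elements
are flagged pro-RD when the published polynomial 0.4096 FD^2 + 3.28 FD FE -
0.1036 FE^2 - 0.7112 FD - FE + 0.0429 is positive *and* FD > 0.01: the
positive side is the high-density/high-entropy side (value +1.92 at
FD=FE=1), and the FD guard neutralizes the positive constant term at zero
density.  The quiescent analysis pools equilibrium voltages over all cohort
models after a stimulus-free settling run, takes the 95th percentile
(linear-interpolation convention) as the abnormal-depolarization threshold,
and reports each model's fraction of nodes strictly above it; models still
oscillating at the end of settling are excluded and reported.

## Statistics

Continuous variables compare by Wilcoxon rank-sum (normal approximation;
exact rank enumeration when either group has n < 9) with a Hodges-Lehmann
location-shift 95% CI.  Categorical 2x2 tables use chi-squared with
continuity correction by default — the convention under which the published
inducibility table [[22, 23], [24, 21]] gives p = 0.83 (without correction
it gives p = 0.67); the flag is exposed.  Burden-vs-count relationships
report both the product-moment R with its p-value and a logistic fit of the
dichotomized outcome, since the published methods name logistic regression
while the printed values resemble product-moment correlations.  Quartile
cut-offs use the linear-interpolation percentile convention; degenerate
(tied) cut-offs are flagged.

## Numerical choices and degenerate inputs

* Zero-area elements, zero-length or in-plane-degenerate fibers, and
  non-manifold or inconsistently oriented surfaces are rejected at assembly
  with the offending element named.
* Voltage outside (-120, +80) mV aborts a run with the divergence flag set;
  such induction records are marked invalid and excluded (never counted as
  non-inducible).
* Gate-rate formulas implement the removable singularities of the published
  model (at -47.13, -14.1, +3.3328, +19.9, -10, +7.9 mV) by their limits;
  the h/j branch switch at -40 mV is a genuine, tiny discontinuity of the
  published formulation and is kept as printed.
* The fibrotic/healthy split at nodes: a node is fibrotic if any adjacent
  element is fibrotic.
* Ties in quantile thresholds of the fibrosis field resolve by stable sort
  order, making patterns reproducible bit-exactly.

## Known limitations

* The transverse effective CV cannot match its published value at the
  printed conductivity ratio (see above); the longitudinal CV anchors the
  calibration.
* The fibrotic upstroke reduction integrates to -46.4% against a cited
  -49.6% (see the membrane section for the mechanism).
* Sheet-scale cohorts sample few fibrotic patches per substrate, so
  per-model inducibility is far noisier than in O(100 cm^2) atria;
  cohort-level statistics carry the signal.
* No afterdepolarization-driven (focal) mechanisms: the cell models'
  simplified calcium handling cannot produce EADs/DADs, matching the source
  models; macroscopic (obstacle) reentry is detected only to be excluded.
* No volumetric 3D tissue, no bidomain, no extracellular potentials.
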