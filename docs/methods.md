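# Methods

`lapwsim` builds volumetric electrophysiology models of the left atrial
posterior wall (LAPW) directly from electroanatomical point-cloud data (PCD),
without image segmentation, simulates transmembrane activation with the
monodomain equation and the Courtemanche–Ramirez–Nattel human atrial ionic
model, computes unipolar electrograms (EGMs) at virtual electrodes in the
blood pool, and compares simulated against recorded EGM sets with a battery
of morphology and effect-size statistics. This note records the model, its
assumptions, the tunable parameters, and the numerical and design choices.

## Geometry: point cloud → tetrahedral model

The LAPW is treated as a thin curved sheet. The chain is

1. **Downsampling** — greedy minimum-spacing selection in input order
   (default min spacing 3.5 mm from an ~1 mm cloud). Guarantees a minimum
   pairwise distance, is deterministic and idempotent, and smooths the local
   normal field enough for extrusion, at a spacing comparable to LGE-MRI
   voxels and clinical electrode spacing.
2. **Surface reconstruction** — PCA-align the cloud, project onto the
   principal plane, 2-D Delaunay triangulate, lift back. Assumes the cloud is
   sheet-like (injective projection; checked). This replaces ball-pivoting +
   manual cleanup with a deterministic construction that is always a manifold
   single sheet with consistent winding. Triangle normals are oriented toward
   the +z side of the principal plane where possible.
3. **Cleaning** — vertices whose incident-triangle normals span more than
   `max_normal_angle` (default 60°) are removed one at a time (worst first,
   since one spike corrupts its neighbours' normals) and the sheet is
   re-triangulated until clean. Clinical cases need at most a handful of
   removals; a smooth sheet passes untouched.
4. **Extrusion** — per-vertex area-weighted normals offset by the wall
   thickness (default 2.3 mm, the typical LAPW thickness). Every prism must
   decompose into positively oriented tetrahedra, otherwise the extrusion
   self-intersects (e.g. concave curvature radius below the thickness) and
   the call fails loudly.
5. **Tetrahedralization** — each prism splits into 3 tets with diagonals
   keyed on global vertex indices (Dompierre-style), so neighbouring prisms
   agree on shared quad faces; volume is preserved exactly.
6. **Uniform refinement** — red (1→8) refinement with globally shared edge
   midpoints; the interior octahedron is split along its shortest diagonal
   (index tie-break). Two levels bring a 1 mm sheet mesh to ~250 μm
   elements, the production resolution for converged propagation.

Coordinates are millimetres throughout geometry; the solver converts to cm.

## Fibers and conductivities

Posterior-wall fibers rotate modestly across the wall. The rule-based
template assigns, at transmural depth d ∈ [0, 1] (0 endocardial),
θ(d) = θ_endo + d(θ_epi − θ_endo) in the tangent plane, defaults −60°/+60°.
The actual anatomical template of the original rule-based construction is
not reproducible from public sources; this analytic transmural rotation is
the documented stand-in, and template fields can be mapped to another mesh
by centroid translation + per-axis bounding-box scaling with
nearest-neighbour triad transfer (an atlas-style mapping; rotation is
deliberately not fitted, matching the mapping actually used).

Bidomain conductivities (Henriquez): fiber σ_i = 1.74, σ_e = 6.25 mS/cm;
sheet and sheet-normal σ_i = 0.193, σ_e = 2.36 mS/cm. The monodomain value
per direction is σ_iσ_e/(σ_i+σ_e) (half the harmonic mean): σ_l = 1.3611,
σ_t = 0.17841 mS/cm. Because sheet and sheet-normal values coincide, the
tensor is transversely isotropic: σ = σ_l f⊗f + σ_t(I − f⊗f).

**CV calibration.** All four bidomain values are scaled by a single factor K
until the simulated macroscopic conduction velocity (CV; straight-line
distance between start/end-set centroids over mean-LAT difference) matches a
measured target, iterating K ← K (CV_target/CV_sim)², the inverse of the
cable-theory law CV ∝ √σ. Convergence is judged only on the simulated CV, so
the final K does not depend on the update rule being exact.

## Monodomain solver

χ(C_m ∂V_m/∂t + I_ion + I_stim) = ∇·σ∇V_m on the conductive subdomain with
no-flux boundaries; C_m = 1 μF/cm², χ = 1500 cm⁻¹. Spatial discretization is
P1 tetrahedral FEM with row-sum mass lumping (required for a fully explicit
update; every stiffness row sums to zero, which is the discrete no-flux
property). Time integration is operator-split and explicit: Rush–Larsen
exponential updates for the 15 gates (exact for frozen rates, keeps gates in
[0, 1], and allows dt = 0.01–0.02 ms), forward Euler for V_m and the 5
concentrations, then the explicit diffusion step. dt is configurable down to
0.001 ms; a per-run check refuses dt above 0.9·h²_min·χC_m/(6σ_max).

The ionic model is the standard 21-variable Courtemanche formulation with
published constants and resting initial conditions; at rest the model drifts
< 0.01 mV/s, and a 25 pA/pF × 2.5 ms stimulus produces an AP with a positive
peak and APD90 ≈ 296 ms.

Stimuli are cube regions (all active nodes inside receive 25 pA/pF for
2.5 ms by default). When recorded electrograms are available, stimulus nodes
are chosen as the tissue nodes nearest to the electrodes whose LATs lie
within 2 ms of the earliest activation (plus nodes within one mean edge
length, to guarantee capture).

LAT at a node is the time of the most negative dV/dt, tracked online at
solver resolution. For transmembrane traces this marker lands in phase-1
repolarization, a few ms after the upstroke, but the offset is spatially
constant for a travelling wave, so activation sequences and CV are
unaffected. Two zones break that constancy and must be excluded from CV
measurements: the stimulus region (artificial current shapes the
derivative) and roughly one wavefront width before a no-flux boundary,
where the wavefront collision synchronizes and distorts phase 1; for extracellular traces it is the standard intrinsic-deflection
marker. The same rule is applied to whichever trace is given — the
min-derivative convention is used for both simulated and measured waveforms,
and this deliberate uniformity is the documented resolution of the
transmembrane/extracellular ambiguity.

**Fibrosis as percolation.** Fibrotic elements (subdomain 2) are skipped
entirely during assembly: no state is allocated at nodes touching only
fibrotic elements, and internal no-flux boundaries arise implicitly.
Fibrosis is purely structural — no conduction slowing or ionic remodeling.

## Perlin-noise fibrosis patterns

3-D gradient (Perlin) noise, summed over octaves (amplitude halved and
frequency doubled per octave, octaves seeded independently), sampled at
element centroids scaled by 1/feature_size. For fiber-aligned types the
lookup coordinate is compressed along the local fiber direction by the
anisotropy ratio, elongating features along fibers. Thresholding at the
(1 − density)-quantile (rank-exact) tags the fibrotic set, so the achieved
density is exact to one element for any type and seed.

Type presets (surrogates for the histological archetypes; all configurable):

| type         | octaves | feature size (mm) | fiber anisotropy |
|--------------|---------|-------------------|------------------|
| compact      | 1       | 8                 | 1                |
| diffuse      | 4       | 1                 | 1                |
| interstitial | 3       | 2                 | 6                |
| patchy       | 2       | 4                 | 3                |

On a 20×20×2.3 mm slab at 35% density these presets produce the expected
signature ordering: compact clusters largest, then patchy, then
interstitial/diffuse, with interstitial strands elongated along fibers.

## Unipolar electrograms

φ_e(x, t) = 1/(4πσ_b) Σ_n χ I_m,n(t) V_n / ‖x − x_n‖ over active nodes,
with I_m = (∇·σ∇V_m)/χ taken from the diffusion operator (exactly the
membrane current density C_m dV/dt + I_ion + I_stim of the discrete
scheme) and V_n the lumped nodal volume. Nodal lumping matches the FEM mass
lumping and keeps the single-point-source case closed-form exact. σ_b
defaults to 6.67 mS/cm (≈ 0.667 S/m blood); it is the dominant amplitude
scaler and a first-class config entry. Electrodes must sit ≥ 0.1 mm off
tissue. Post-processing is a zero-phase 2nd-order Butterworth band-pass
(2–220 Hz) followed by polyphase resampling to 1 kHz, the clinical
convention. (Clinical hardware band edges of 2–240 Hz versus the 2–220 Hz
used here are configurable; a non-default band is logged, not silently
reconciled.)

## Features and comparison statistics

Eight characteristic parameters per trace (downstroke, rising and recovery
upstrokes as central-difference derivatives in mV/ms at 1 kHz, signal width,
EGM duration, baseline, peak-to-peak, deflection count) plus LAT. The active
window is the supra-threshold region around the global extremum with
threshold max(5% of peak-to-peak, 3× baseline-segment SD); the baseline is
the mean of the first/last 10 ms unless activity reaches the edges, then the
trace median. Deflections are local extrema with prominence ≥ 10% of
peak-to-peak (the prominence criterion for a "deflection" is not otherwise
defined; 0.10 is the package default).

Between paired recorded/simulated sets the package computes: Cohen's d per
feature with the (n−1)-weighted pooled SD, reported as a magnitude with the
0.2/0.5/0.8 effect bands; absolute percent errors per pair (rec = 0 pairs
excluded and counted); Pearson r on original traces and the maximum
normalized cross-correlation over lags on baseline-removed, unit
peak-to-peak traces; and the morphology pipeline — biorthogonal 4.4 wavelet
detail coefficients (levels 1–4, symmetric extension; the wavelet family is
configurable since only "biorthogonal" is prescribed), PCA fitted on the
recorded set with the smallest component count reaching 90% explained
variance, simulated waveforms projected with the recorded eigenvectors,
seeded k-means (k = 3) in the retained PC space, and distances to the
common vs closest cluster centroid with the percentage of pairs switching
clusters. Distances use all retained components. Isochrone maps assign each
wall surface point the LAT of its nearest electrode (lower index on exact
ties) and bin over the recorded set's LAT range so recorded and simulated
maps share color ranges. One-way ANOVA + Tukey HSD for fibrosis sweeps is
a thin convenience over the standard routines.

## Synthetic data

The generators provide desk-scale stand-ins for clinical inputs: a regular
sheet cloud at 1 mm spacing (optionally cylinder-bent, arc-length preserving,
Gaussian positional noise); an electrode grid snapped above the sheet at a
configurable standoff (electrodes live in the blood pool, so zero standoff
is rejected); and 1 kHz / 140 ms pseudo-recordings with planar-wave LATs
(distance from the low-edge along a fixed axis over cv), normal amplitude
law truncated positive, normal LAT jitter, and optional fractionation
implemented as late single-lobe bumps at 30% amplitude that each add exactly
one countable deflection. The waveform template is a derivative-of-Gaussian
biphasic (RS) deflection whose steepest downslope is exactly at the assigned
LAT. These distributions are chosen for testability — they emulate the
structure the pipeline assumes (planar activation, amplitude variability,
fractionation counts), not the noise statistics of any clinical recording,
so passing tests validate the machinery, not clinical fidelity.

## Problem sizes, determinism, and known limitations

- Test and demo runs use 20×20×2.3 mm slabs at 1 mm element size (2400
  tets), 140 ms at dt = 0.01 ms, with uniform refinement where wavefront
  resolution matters; these sizes are the package's desk-scale choices, and
  all physics checks state theirs explicitly.
- **CV discretization.** Explicit lumped-mass P1 FEM under-resolves the
  ~0.5 mm action-potential upstroke on coarse meshes and underestimates CV:
  on the slab the longitudinal CV at the default conductivities measures
  17.7 / 31.9 / 42.1 cm/s at h = 1 / 0.5 / 0.25 mm (geometric extrapolation
  ≈ 65–70 cm/s, consistent with published Courtemanche tissue velocities).
  Consequently the CV ∝ √σ law — exact only in the continuum — is verified
  on a wavefront-resolving 125 μm strip in the patient-calibrated CV regime;
  at coarser resolution the ×4-conductivity ratio systematically exceeds 2.
  In practice this is why conductivities are calibrated per mesh: K absorbs
  the resolution bias at the operating point.
- One global seed fans out to per-stage seeds via
  `SeedSequence([seed, stage_ordinal])`; fixed seeds give bit-identical
  fixtures, patterns, and feature tables across runs.
- The forward EGM model assumes an infinite homogeneous volume conductor;
  bounded-bath effects, electrode surface averaging, and bipolar synthesis
  are out of scope, as are bidomain formulations and implicit integrators.
- 140-sample traces at decomposition level 4 incur wavelet boundary effects
  across all coefficients (the decomposition is still deterministic and
  shared by both sets, so comparisons remain paired).
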