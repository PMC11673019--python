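# Methods

This note records the models implemented in `voct`, the assumptions they
make, the parameters that matter, and the numerical choices taken where
the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Mechanovibrational spectra

A VOCT measurement is represented as a weighted-displacement spectrum on a
uniform 10 Hz grid: 50–250 Hz for human eyes, 50–300 Hz for porcine.
"Weighted displacement" means the in-phase transverse displacement divided
by the speaker's displacement measured without the sample
(`normalize_by_speaker`), which removes the source's frequency response.
Before clustering, each spectrum is additionally scaled to a unit maximum
(`normalize_unit_max`) so values at one frequency are comparable across
eyes; this normalisation is idempotent and leaves peak locations
untouched.

**Peak detection.** A resonant peak is a strict local maximum over its
3-point neighbourhood on the grid, with a relative height threshold
(default 5% of the spectrum maximum, so detection is invariant under
unit-max rescaling). Ties between equal adjacent samples resolve to the
lower frequency; boundary grid points count when strictly above their
single interior neighbour. Peak frequency resolution is one grid step
(±10 Hz) by construction; no sub-grid interpolation is attempted. Band
assignment windows are 70–90 Hz (cells; widened symmetrically because the
cellular resonance is reported anywhere from 60 to 80 Hz), 110–120,
140–150 and 240–250 Hz, all configurable.

## Synthetic-data generator

No public corneal VOCT dataset exists, so the generator is a first-class
module whose defaults define the study conditions used throughout the
tests.

- **Line shape.** Lorentzian (damped driven resonance), the standard
  shape for a vibrating viscoelastic structure. `width` is the full width
  at half maximum, default **10 Hz** — one grid step. Two consequences
  motivated this width: all four programmed human peaks (80, 110, ~150,
  250 Hz) survive as separate local maxima on the grid, and the
  information carried by one band is not duplicated into its neighbouring
  grid columns, which is what makes single-frequency localization
  well-posed. With substantially broader lines (e.g. 15 Hz FWHM) the
  110 Hz tail swamps the 80 Hz peak and copies the species contrast into
  the 100/120 Hz columns, and a leave-one-frequency-out ablation can then
  no longer isolate the band.
- **Default peak set** (heights are relative weighted displacement):
  cells 80 Hz × 0.5; anterior lamellae + Bowman's layer 110 Hz × 1.0
  (tallest, as in measured healthy human spectra); central stroma at the
  frequency the calibration inverse assigns to the central cornea
  (healthy: E = 3.1 MPa at 550 µm → ≈150 Hz) × 0.7; limbus 250 Hz × 0.6.
- **Keratoconus contrast.** KC spectra move the central-stroma peak to
  the resonance of a softer, thinner central cornea via the calibration
  inverse (E = 2.4 MPa at 450 µm → ≈114 Hz) and reduce its height to
  0.55 — lower resonant positions and heights, not arbitrary shifts.
  The default cohort is 41 control + 22 KC eyes with stages I–IV counted
  2/9/3/8.
- **Species contrast.** Human and porcine profiles are identical except
  the 110 Hz peak height, scaled by 0.3 in porcine eyes (Bowman's layer
  absent). The species cohort is generated on the common 50–250 Hz grid.
- **Variability.** Additive Gaussian noise on displacement, truncated at
  zero, sd = 5% of the tallest peak; per-eye log-normal height jitter
  (log-sd 0.15); Gaussian resonance-centre jitter. The clinical cohort
  uses 3 Hz centre jitter. The species cohort uses 1 Hz: its defining
  structural property is that the species contrast stays confined to the
  110 Hz column, with apparent peak-position variability arising from the
  10 Hz sampling rather than from wandering resonances. The within-group
  variance of real VOCT peak heights is not publicly reported; these
  magnitudes are assumptions, not estimates.
- **Determinism.** Every generating call takes an explicit seed
  (`numpy.random.SeedSequence` spawning per eye); identical inputs give
  byte-identical output. There is no global RNG state.

What the generator does *not* emulate: OCT image formation, speckle,
A-scan physics, intra-eye spatial maps, instrument drift, or any
correlation structure between bands beyond the shared line-shape tails.
Tests passing on this generator therefore demonstrate that the analysis
chain recovers structure that is genuinely present at realistic noise
levels — not that the same accuracies would be obtained on measured eyes.

## Resonance → modulus calibration

The empirical calibration `E·d = a·fn² + b` with a = 0.0651 and b = 233.1
derives from simultaneous in-vitro tensile testing and VOCT on soft
tissues. The right-hand side is treated as MPa·µm (numerically equal to
Pa·m): with d in µm the formula yields E in MPa, the only reading
consistent with corneal moduli of 2–3 MPa at ~500 µm thickness and
110–150 Hz resonances. The source literature prints "d is in m" next to
MPa moduli, which those magnitudes contradict; the package implements d in
µm, flags the unit question in the API docs, and exposes a
`thickness_unit` switch. Thickness itself is a per-eye scalar supplied by
the caller (in vivo it comes from OCT images, outside this package's
scope); whether d should be whole-cornea or per-layer thickness is
likewise a caller decision — at 110 Hz an effective d ≈ 408 µm corresponds
to E = 2.5 MPa.

Uncertainty from the 10 Hz measurement grid propagates by interval
arithmetic: E is evaluated at fn − 10 and fn + 10 Hz (floored at 0 Hz),
giving `[E_low, E_high]`. This matches the stated ±10 Hz accuracy of the
resonance and avoids inventing a Gaussian error model the measurement
process does not justify. The interval narrows as fn decreases, since the
calibration is quadratic in fn.

The mean corneal modulus is the peak-height-weighted average
Σhᵢ·Eᵢ / Σhᵢ — a convex combination, invariant to uniform rescaling of
heights, weighting each component by the light it reflects back.

## Bowman's-layer localization

Human corneas have Bowman's layer; porcine corneas do not. The grid
frequency at which the two species' unit-max spectra are most separable
marks the layer's resonance. Two procedures triangulate it:

1. **Per-frequency mixture scan.** For each frequency, a variational
   Bayesian Gaussian mixture with two components (weak priors, 5 random
   restarts, all seeded) is fitted to the 1-D values of all eyes at that
   frequency. Cluster ids are arbitrary, so accuracy against the species
   labels is maximised over the two cluster↔class permutations — on
   balanced data this is never below 0.5, with a small positive bias
   above it for random assignments (the permutation-max bias; the exact
   chance level is E[max(K, n−K)]/n, K ~ Binomial(n, ½)). Accuracies are
   averaged over seeded refits; a frequency at which all eyes have
   identical values is recorded at 0.5 and flagged. The distinguishing
   frequency is the arg-maximum.
2. **Leave-one-frequency-out ablation.** For each excluded frequency an
   SVC is trained on the remaining 20 columns and scored by stratified
   5-fold cross-validation (each fold an ~80/20 split), repeated with
   refreshed fold assignments; means and sds are reported per exclusion,
   never a maximum over runs. The distinguishing frequency is the
   arg-minimum — the costliest exclusion.

Open choices and how they were resolved: the classifier's kernel is not
dictated by the problem (any maximum-margin formulation works on
well-separated data); the default is RBF with C = 1, both configurable.
The interaction between a single 80/20 split and 5-fold cross-validation
is redundant as usually described; the implementation uses repeated
stratified 5-fold CV on the whole cohort, whose folds *are* 80/20 splits.
The unsupervised and supervised procedures are sometimes jointly labelled
"clustering"; the second is implemented as what it operationally is —
supervised maximum-margin classification against known species labels.
Ties in either curve break toward the lowest frequency and are flagged.
Note one caveat of the argmax rule: when the contrast is strong, many
frequencies saturate near perfect accuracy and the scan's argmax is only
meaningful together with the full curve, which is always returned.

## Corneal finite-element model

**Problem.** Static deformation of the cornea under intraocular pressure:
a meniscus-shaped axisymmetric solid with a spherical anterior surface
(radius of curvature 7.8 mm), axial thickness interpolating quadratically
from the centre to the rim, total diameter 11.5 mm. Healthy geometry:
550 µm centre / 700 µm periphery; keratoconic: 450 / 750 µm (central
thinning, peripheral thickening). These dimensions are typical stand-in
values exposed in config for substitution by subject-specific
measurements. Materials (isotropic, linear): healthy E = 3.1 MPa,
keratoconic E = 2.4 MPa, ν = 0.42, ρ = 1.038 g/cm³. Load: uniform
2000 Pa (≈20 mmHg) normal traction on the posterior surface, applied as a
dead load on the undeformed configuration (consistent with small-strain
linearity). Boundary: all displacement components zero on the peripheral
face ("clamped", modelling attachment to the stiff limbus) and zero
radial displacement on the symmetry axis. Gravity and extraocular muscle
forces are excluded.

**Discretisation.** Geometry, load and boundary conditions are all
axisymmetric, so the problem is solved on the meridian cross-section with
axisymmetric continuum elasticity (strains ε_rr, ε_zz, ε_θθ, γ_rz).
Elements are 9-node biquadratic quadrilaterals with 3×3 Gauss quadrature
on a structured grid (meridian × through-thickness, split to keep element
aspect ratios near one); the default budget is ~1024 elements, within 10%
of the requested count. Biquadratic elements are used because bilinear
quadrilaterals shear-lock in thin bending at this element budget.
Internal units are SI; µm/mm/MPa appear only at the interface.

**Solver.** The reduced symmetric positive-definite system is factorised
(sparse LU) with a few steps of iterative refinement; convergence is
verified on the normwise backward error ‖f − Ku‖/(‖K‖‖u‖ + ‖f‖) < 1e-10
(the thin-shell stiffness is ill-conditioned enough that a residual
scaled by ‖f‖ alone is not a faithful convergence measure). Degenerate
meshes are rejected by a positive-Jacobian check at every quadrature
point before assembly.

**Outputs.** Nodal displacements; the deflection map is the axial
deformation |u_z| (the quantity of clinical interest and the model's
deformation measure — the full vector magnitude differs only by the small
radial sliding component). The central deflection is |u_z| at the
anterior apex node; `deflection_summary` reports both central deflections,
their KC/healthy ratio, and the radial location of each field's maximum.
Fields export to CSV and legacy ASCII VTK.

**Verification.** The oracle is a clamped flat circular disc under
uniform pressure, whose Kirchhoff closed form w = p·a⁴/(64D),
D = E·h³/(12(1−ν²)), is exact in the thin limit. In the thin regime
(h = 150 µm, a = 5 mm, a/h ≈ 33) the FEM error against the closed form
decreases monotonically under refinement to well under 1%. At a
corneal-thickness disc (h = 550 µm, a/h ≈ 9) the converged solid solution
sits a few percent *above* the Kirchhoff value — a physical
transverse-shear effect, first-order captured by the Mindlin correction
p·a²/(4κGh) with κ = 5/6 (available via `include_shear=True`) — so
agreement with the thin-plate formula is checked there at the 5% level
while monotone convergence is asserted in the thin regime where the
formula is the true limit.

**Known limitations.** Homogeneous isotropic linear elasticity (no
fibre-reinforced or hyperelastic constitutive law, no collagen lamellae
anisotropy); dead pressure load rather than a follower load; no contact,
tear film or epithelial layering; thickness measured axially (a
shallow-cap approximation); and the keratoconic geometry is an
axisymmetric idealisation, whereas real cones are typically paracentral
and asymmetric. The reference deformation analyses this model mirrors
were built in a commercial 3-D solid modeller whose formulation and mesh
are not fully specified, so the KC/healthy deflection ratio should be
expected to agree only to within roughly the 15% level, with the
linear-elastic modulus ratio alone (3.1/2.4 ≈ 1.29) as a lower anchor and
the thickness contrast supplying the remainder.

## Pipeline and problem sizes

The pipeline runs simulate → peak detection → calibration → localization
→ FEM from one YAML config with a single top-level seed (stage seeds are
fixed offsets of it), writes every intermediate artifact as CSV, and
aggregates a JSON report; reports are byte-identical across runs with the
same config. Default sizes are the study sizes: 63-eye clinical cohort,
20 + 20 species cohort, ~1024 elements. The repeat counts used by the
test suite's replicated localization check (2 mixture refits and 4 CV
repeats per cohort, 50 cohorts) are the package's choice of desk-scale
defaults; localization rates are driven by the cohort contrast, not by
the number of repeats, which only smooths the accuracy curves.
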