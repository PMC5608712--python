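# Methods

This note records the models, numerical choices, and validation design
behind `vasoelast`, and what the synthetic experiments do and do not
demonstrate about real data.

## Forward model

The vessel cross-section is modelled as a linear, isotropic,
nearly incompressible elastic annulus in **plane strain** — the natural
2D reduction for a long, axially constrained straight vessel imaged in
its transverse plane. The wall is loaded by a uniform luminal pressure
(default 131 mmHg, converted at 0.133322 kPa/mmHg) applied as a
consistent normal traction on the inner boundary; when tracked
displacements are available they are imposed as Dirichlet data on the
outer boundary.

*Element technology.* Pure linear (constant-strain) triangles lock
volumetrically at ν = 0.495 and are excluded from production solves
(one is retained as a textbook reference element in the unit tests).
The solver uses isoparametric **6-node quadratic triangles** with a
6-point degree-4 quadrature; boundary midside nodes are pulled onto the
circular arcs so the pressure load integrates over a curved edge. On
the mouse-carotid annulus (lumen radius 0.19 mm, outer radius 0.30 mm)
the radial displacement at the lumen agrees with the closed-form Lamé
thick-walled-cylinder solution to 0.005% at a 0.01 mm target edge
length, with monotone error decay over refinements 0.04 → 0.02 →
0.01 mm — at ν = 0.495, which is the test that rules out locking.

*Rigid-body constraints.* A pressure load with no Dirichlet data is
self-equilibrated, so the three in-plane rigid modes are removed by
Lagrange-multiplier orthogonality constraints rather than by pinning
nodes. Point pinning would superimpose a rigid motion on the solution
and break direct comparison with the Lamé field (which is itself
orthogonal to the rigid modes); the orthogonality constraints leave the
elastic field untouched. Systems are factorized with a sparse direct
solver (SuperLU) and the factorization is reused across Gauss–Newton
sensitivity columns.

## Inverse problem

The elastogram minimizes `pi(E) = 1/2||U(E) − U_m||² + (α/2)||E||²`
over region-wise moduli. Design choices:

- **Squared norms.** The objective uses squared L2 norms with ½ and α/2
  factors — the standard Tikhonov form whose normal equations are the
  damped Gauss–Newton update implemented here.
- **Update form.** `E^{i+1} = E^i + λ ΔE^i` with
  `ΔE = [JᵀJ + αI]⁻¹ (Jᵀ(U_m − U) − αE)`; the `−αE` term makes the step
  the exact Gauss–Newton direction of `pi`, so backtracking on `pi`
  guarantees a non-increasing objective on accepted iterations. The
  bare normal-equations step (without `−αE`) is available through
  `gauss_newton_step` directly.
- **Sensitivities.** `∂U/∂E_k = −K⁻¹ (K_k/E_k) U` exactly, with `K_k`
  the unit-modulus assembly of region k; columns agree with central
  finite differences to ~1e-7 relative.
- **Parameterization and bounds.** Moduli are updated in physical
  (kPa) space with projection onto [0.1, 1000] kPa after each step;
  with region-wise parameters the projection suffices to keep the
  iteration in the physical regime, and the update then matches the
  printed normal-equations form exactly.
- **Regularization scale.** User-facing α is dimensionless: it is
  multiplied by `trace(JᵀJ)/n_params` at the first iteration. The
  default α = 1e-3 suits noisy data with coarse (1–4 region)
  parameterizations; noise-free validation runs use α = 0, where the
  data fully determine the solution and recovery is exact to solver
  tolerance regardless of the trial value.
- **Misfit support.** When outer-boundary Dirichlet data are imposed,
  the misfit uses interior nodes only (boundary entries carry no
  information); without Dirichlet data all nodes enter. An
  `axial_only` option restricts the misfit to the axial displacement
  component for tracked fields (see *Tracking accuracy* below); the
  RF-route pipeline enables it.
- **Convergence.** Relative objective change < 1e-6, or a relative
  step norm < 1e-9 (which catches the exact-recovery case where the
  misfit keeps shrinking by orders of magnitude), within 50 iterations.
  A step search that fails to descend yields status `stalled` with the
  full trajectory retained.

### Identifiability of layered phantoms

With a known pressure the homogeneous-wall modulus is exactly
identifiable, and the two-layer (intima/media) phantom is exactly
recoverable from noise-free data. Under noise the two-layer problem is
nearly rank-one: `cond(JᵀJ) ≈ 2e6` for the 18/54 kPa concentric phantom
under pressure-only loading, so at a displacement noise SD of 1% of
peak the estimator SD along the weak eigenmode is tens of kPa at any
practical data density, and regularization can only trade that variance
for bias of the same size. The stochastic recovery experiment is
therefore defined on the homogeneous-wall phantom — the configuration
the cohort pipeline actually reconstructs — where the median error at
1% noise is ~0.1%; the two-layer noisy median (~20%) is reported
alongside for transparency.

## RF simulation and echo tracking

Frames are rendered by the standard linear convolution model: each
point scatterer contributes a 40 MHz Gaussian-modulated axial pulse
(σ = 15 µm; two-way carrier period c/2f₀ = 19.25 µm) times a Gaussian
lateral beam profile (σ = 30 µm, the scale of a 40 MHz f/2 aperture at
focus), sampled at 250 MHz axially (3.08 µm depth per sample) and
2.54 µm beam pitch. Scatterer density defaults to 4000/mm² — about ten
scatterers per resolution cell, the usual threshold for fully developed
speckle; reflectivities are standard normal.

Tracking uses zero-mean normalized cross-correlation of 100 µm x
25.4 µm kernels with 80% overlap (station spacing 20 µm x 5.08 µm), an
integer search sized to the expected displacement, and separable
3-point subpixel refinement. Two estimator details matter:

- **Carrier-matched subpixel fit.** The axial correlation oscillates at
  the known RF carrier; a parabolic 3-point fit carries a
  model-mismatch bias (mean 0.20, SD 0.16 samples on a noise-free
  0.25-sample shift), while the cosine fit at the known carrier
  frequency gives mean 0.25, SD < 0.04 samples. The axial default is
  therefore the cosine fit; the lateral correlation has no carrier and
  uses the parabola.
- **Peak-hopping control.** RF correlation has side lobes one carrier
  period away; the search range is kept inside one period when the
  expected displacement allows, and a 3x3 median correction re-anchors
  isolated integer-lag outliers.

*Tracking accuracy.* On noise-free FEM-deformed speckle (3 mmHg
inter-frame pressure increment, peak displacement ≈ 10.6 µm ≈ λ/4),
the axial RMS error at stations whose kernel lies fully inside the wall
is ≈ 0.65 µm, ~6% of peak. The lateral error is an order of magnitude
larger (~6 µm): with a 25.4 µm kernel and a ~30 µm beam the lateral
correlation is an envelope-only ridge with ~42 µm correlation length,
and any decorrelation lets its apex wander by several microns — a
physical property of lateral speckle tracking at this geometry (a rigid
lateral shift with unit correlation is recovered to 0.05 µm). This is
why the modulus inversion from tracked fields uses the axial component,
and why edge kernels (which see a signal-weighted mixture of wall and
anechoic lumen) are excluded from accuracy statistics.

## Synthetic cohorts

The generator emulates the four-group ligation study: sham/ligated x
1/2 weeks, n = 5 (6 in the 2-week ligated arm), left and right carotid.
Per-animal Doppler metrics are drawn `Normal(mean, SEM·√n)` from the
published group tables; the time-averaged mean velocity for the
pulsatility index is derived as `VTI·HR/60`. Ligated-arm LCA wall
moduli are the sham modulus (18 kPa — deliberately distinct from the
20 kPa trial so recovery never starts at truth) times the timepoint's
fold change (2x / 3x), with a mean-preserving 5% lognormal animal
spread. Histology area profiles cover 0–2000 µm at 200 µm stations;
the intima is a missing-value sentinel (never zero) in non-ligated
arteries and a mid-segment bump in ligated LCAs whose size scales with
the animal's stiffness deviation, so modulus–intima correlations carry
signal. Displacement noise is additive i.i.d. Gaussian with SD equal
to a fraction (default 1%) of the clean field's peak magnitude.

What the generator does **not** emulate: Doppler spectra or waveforms
(scalar metrics are drawn, not synthesized from physics), ECG gating,
3D power-Doppler volumes, attenuation/TGC, electronic noise in RF,
out-of-plane motion, and any within-animal correlation between Doppler
metrics (each is drawn independently). Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
statistical structure, not robustness to every artefact of in vivo
acquisition.

## Hemodynamic indices and histology volumes

Flow is `HR·π(d/2)²·VTI/1000` (mL/min) with a circular lumen from a
single diameter (diastolic by default; configurable). Shear stress is
the Poiseuille wall value `4µQ/(πr³)` with µ = 0.035 poise, valid only
for parabolic flow — the assumption is carried as an explicit flag in
the output metadata. Carotid strain follows the printed
systolic-reference formula; since murine diastolic diameters exceed
systolic ones the signed value is negative, and the default output is
the magnitude with the signed value retained alongside. Compartment
volumes use the trapezoidal rule over the 11 stations (exact for the
piecewise-linear reading of serial sections; a rectangle-sum option
exists). The stacked surface model nests equivalent-circle radii
(lumen black, intima yellow, media red, adventitia green).

## Statistics

Means ± SEM (SD/√n); equal-variance Student's t tests (Welch behind a
flag); one-way ANOVA across the four groups with pairwise post hoc t
tests gated on ANOVA p < 0.05; Pearson correlations with exact
t-transform p-values and pairwise exclusion of missing intima values.
No multiple-testing correction by default (a Bonferroni option logs a
note). Scientific computations delegate to `scipy.stats`.

## Validation problem sizes

The acceptance battery (`scripts/acceptance.py`, ~1 minute on one CPU)
uses: Lamé refinements at 0.04/0.02/0.01 mm (up to ~3400 elements);
a four-region phantom at 0.02 mm for the Jacobian check; two-region
recovery at 0.02 mm; 10-seed noisy recovery at 0.025 mm; a 2-week
cohort of n = 5 per arm at 0.025 mm reconstructed through the direct
displacement route; tracking frames of 0.64–0.70 mm square at 250 MHz /
2.54 µm pitch with 2000–2700 scatterers; and two consecutive
determinism runs of a reduced (n = 2) pipeline. These sizes were chosen
as the smallest at which each check is well-resolved (mesh-converged
forward solves, >100 valid tracking stations, Monte-Carlo error well
under the tolerances being tested).

## Known limitations

- Linear elasticity at a finite 131 mmHg load: the computed
  displacements scale linearly with pressure, and absolute moduli are
  conditional on the assumed pressure (no hyperelasticity, anisotropy,
  viscoelasticity, or fluid–structure interaction).
- The two-layer modulus contrast is not identifiable from noisy
  pressure-only data (see above); layered reconstructions need either
  very low noise or stronger priors.
- Lateral tracking error is tracking-geometry-limited; vector
  displacement accuracy is dominated by the lateral component.
- The cohort generator draws Doppler metrics independently per metric,
  so index-level correlations across animals are weaker than in vivo.
- Histology "areas" are inputs: no image segmentation is performed.
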