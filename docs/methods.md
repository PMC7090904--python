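# Methods notes

This note documents the models, numerical choices and limitations behind
`limbssm`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shape model

**Representation.** Bone surfaces in dense correspondence (identical vertex
count and semantics) are stacked as 3k-vectors. After rigid-only generalised
Procrustes alignment (GPA) to the evolving mean — no scaling, converged when
the mean moves < 1e-6 mm RMS — PCA of the sample covariance gives modes and
variances. Scores are stored in SD units (`b_k = raw score / √λ_k`) so the
±3 bound and the Mahalanobis penalty `Σ b_k²` are dimensionless; raw scores
are recoverable via the eigenvalues. Modes with eigenvalue < 1e-12 × the
largest are dropped; at most n−1 modes are kept. Tibia and fibula are carried
as one multi-part shape vector with per-vertex part labels, so their relative
pose is preserved by construction.

**Correspondence.** The dense registration used to build clinical models is
replaced by a two-step scheme with the same structure: (1) a thin-plate-spline
warp driven by the shared named landmarks, densified with pseudo-landmark
pairs (default 50) chosen by farthest-point sampling on the reference and
paired by closest-point search on the target; (2) closest-point projection of
every warped reference vertex onto the target surface. For the synthetic
cohorts correspondence is exact by shared parametrisation and this scheme is
only exercised by its own tests.

**Quality metrics.** Compactness is the cumulative eigenvalue fraction;
generality the mean leave-one-out reconstruction RMS; specificity the mean
RMS distance of random instances (scores ~ standard normal truncated at ±3,
default 1000 seeded samples) to the nearest training shape.

**Subspace recovery.** GPA estimates shape modes in the quotient of shape
space by rigid motions, so recovery of a known generating subspace is
assessed against span(generating directions ⊕ infinitesimal rigid motions at
the template). With n = 30 training shapes, ~800 vertices and 0.1 mm vertex
noise, accumulated high-dimensional noise tilts the weakest estimated mode by
a few degrees even though its eigenvalue sits two orders of magnitude above
the noise floor; the generator's latent loadings (below) are strong enough to
keep that tilt under 5°.

## Landmark-driven reconstruction

Pose is parametrised as a rotation vector (composed with the initial
alignment, about the landmark centroid) plus translation; pose and scores are
optimised *jointly* by L-BFGS-B with box constraints (scores ±3 SD, rotation
±π, translation ±1 m around the initialisation; `ftol` 1e-14, `gtol` 1e-10).
Initialisation: `b = 0`, pose from the closed-form rigid alignment of the
mean-shape landmarks to the targets; optional seeded multi-starts jitter both
pose and scores. Anterior tibial crest points (ATP/ATM/ATD) have no fixed
bony correspondence: they are represented as barycentric points on the model
surface, frozen during each inner optimisation and refreshed by closest-point
search in an outer loop (≤ 10 iterations, stopping when the supporting
triangles and weights stabilise).

The bone-landmark objective is `Σ d_i² + w Σ b_k²`; the skin-landmark
objective is the offset likelihood `Σ [½ log σ_i² + (d_i − d̂_i)²/(2σ_i²)] +
w Σ b_k²` with `d_i` the Euclidean distance from the posed model point to the
measured landmark. The "without correction" variant sets `d̂ ≡ 0, σ ≡ 1 mm`.
`w` defaults to 1.

**Shrinkage, identifiability, and the role of `w`.** The penalty is a
Gaussian prior: at the optimum the scores are shrunk towards zero by a factor
`w/(w + ‖U_k‖²)` per mode, where `U_k` is the landmark-restricted scaled mode
(for the skin objective, additionally weighted by 1/σ²). With a handful of
landmarks and σ of several millimetres this shrinkage is substantial — by
design: it is what keeps sparse, noisy fits anatomically plausible. Exact
self-consistency checks (recovering the generating scores from noise-free
landmarks) are therefore run with `w = 0`, where recovery is exact to
optimiser tolerance. The skin objective constrains only scalar distances, so
with few landmarks several shapes can satisfy all constraints; the prior
selects among them. The femoral fit is well-posed thanks to the derived
head-surface points; the all-offset tibial skin fit relies on the prior.

**Derived head points.** The femoral head centre enters either from a head
sphere fit (bone route) or from the pelvic regression (skin route); points
superior/medial/anterior/posterior of the centre at the scaled head radius
(21.1 mm × length ratio, length = FHC to mid-epicondyle distance) are added
as landmarks mapped to the extreme head vertices of the template, with a
10 mm dispersion in the skin likelihood.

## Soft-tissue offset models

Offsets are scalar radial magnitudes (skin point minus bone point along the
outward normal when synthesised; Euclidean distances when measured). Per
landmark: fit the full linear model on (height, mass, age, gender, BMI); if
adjusted R² ≤ 0.5, fall back to sample mean ± SD; otherwise remove single
terms greedily while the AIC decreases, then drop all terms with marginal
F-test p ≥ 0.05 and refit once. The fitting σ is the residual SD of the final
model. The published table stores printed means/SDs verbatim; for its three
regression rows only the sample SD and full-model R² are printed, so their
fitting σ is the implied residual SD `SD·√(1−R²)` (GT 10.4, LE 3.0, ME
3.7 mm). BMI is definitionally mass/height², hence collinear with mass in any
physically consistent cohort (r ≈ 0.9): selection may legitimately retain BMI
in place of mass, and confidence-interval statements are made per
coefficient. Predicted offsets are clipped at 0 mm.

## Synthetic data generator

The generator emulates the *statistical* structure the method needs, not
anatomy per se:

* **Bones.** Capped elliptical tubes with smoothstep flares: femur with
  condylar flare, proximal lateral flare (GT) and an icosphere head on a neck
  (45° elevation, anteversion rotating the neck about the long axis); tibia
  with plateau/malleolar flares plus a thin lateral fibula, twisted about the
  long axis by the torsion angle (zero at the plateau, full at the ankle).
  Landmarks are template vertices at defined parametric locations; meshes are
  watertight per part, ~800 vertices by default (≥ 500 enforced). Vertex
  positions are affine in (length, shaft radius, condylar width, head radius)
  at fixed angles — deliberately, so a linear latent model over those
  parameters spans an exactly 3-dimensional shape subspace.
* **Population.** Latent 1 is the standardised stature score (height drawn
  truncated-normal 1.74 ± 0.09 m within 1.55–1.93 m; femur length 426 +
  26·z₁ mm), latents 2–3 are truncated standard normals driving shaft radius
  (±1.2 mm/SD) and condylar width (±6 mm femur / 5 mm tibia per SD — within
  reported anatomical variability and strong enough for the subspace-recovery
  contract above). Mass comes from BMI (truncated normal 24.5 ± 3.5 within
  17–34.8) × height², clipped to 45–108 kg; age uniform 23–70; gender
  Bernoulli(13/35). Per-vertex Gaussian noise (default 0.1 mm) is added; all
  randomness streams from one seed via spawned per-subject generators, so
  cohorts are bitwise reproducible and stable under subject-count changes.
* **Digitisation.** Skin landmark = bone vertex + (d̂(covariates) +
  N(0, σ_landmark))·outward normal + isotropic N(0, 1 mm) noise, offset
  clipped at 0. The recorded offset observation is the exact resulting
  skin-bone distance. The hip-centre "estimate" used by the skin route is the
  true centre + isotropic N(0, 8 mm) error, standing in for the pelvic
  regression chain; subject pelvis width is 145·height mm + N(0, 8 mm).

What passing tests on this generator do **not** show: performance on real
anatomy (no cortical detail, no posture-dependent soft-tissue deformation, no
segmentation error), and the published per-cohort error magnitudes, which
depend on a specific MR dataset. The synthetic study reproduces the
*qualitative* ordering of methods, not the printed medians.

## Evaluation

Surface error is one-way: the reconstruction is ICP-aligned to the truth
(exact closest-point-on-triangle correspondences, point-to-point updates,
RMSE-change tolerance 1e-6 mm, ≤ 100 iterations, deterministic
centroid/principal-axes initialisation with third-moment sign fixing), then
the RMS of reconstruction-vertex → truth-surface distances is reported. HJC
error is the distance between centres expressed in the true femoral frame.
Of the anatomical measures, three have fully stated constructions —
femoral anteversion (neck axis vs epicondylar line, projected about the
fitted shaft axis), anatomical–mechanical axis angle, and tibial torsion
(plateau principal axis vs malleolar axis about the long axis); the remaining
published measures rest on conventions defined only in an external reference
and are excluded. The tilted anatomical frame introduces a ~1.5° projection
bias in torsion; tests allow 2.5°. Method comparison: Kruskal-Wallis omnibus,
then pairwise paired Wilcoxon signed-rank (exact for n ≤ 25 without ties,
normal approximation otherwise) with Holm step-down adjustment, α = 0.05.
Quantiles use linear interpolation; IQR = Q3 − Q1.

## Frames and conventions

Femur: origin mid LE/ME, y towards the FHC, x the epicondylar direction
orthogonalised to y, z = x × y. Tibia: origin mid-malleoli, y towards TT,
x malleolar. Pelvis: origin mid-ASIS, z towards the subject's right ASIS,
x anterior, y = z × x. The hip-centre regression components are mapped
(anteroposterior, inferosuperior, mediolateral) with the lateral sign
mirrored for left limbs; the canonical template is right-sided with +z
anterior.

## Study pipeline sizes

The default synthetic study uses 8–20 subjects, one segment, leave-one-out
models rebuilt per subject, and 3 modes (the synthetic population has exactly
3). These sizes were chosen so the full suite and the acceptance script each
run in minutes on a single CPU while leaving every qualitative conclusion
intact; all are config fields (`StudyConfig`) and scale up unchanged.

## Known limitations

* Offsets are scalar magnitudes along outward normals; direction-resolved
  (vector) soft-tissue fields and posture effects (supine imaging vs standing
  digitisation) are out of scope.
* The correspondence scheme assumes reasonably similar shapes; it is a
  dependency-light surrogate, not a diffeomorphic registration.
* The skin-landmark objective uses distances only; with very sparse landmark
  sets the reconstruction is prior-dominated (see shrinkage note above).
* Cartilage thickness is not modelled in hip-centre comparisons.
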