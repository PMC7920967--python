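# Methods

## Geometric substrate

All surfaces are triangle meshes in world millimetres, 0-based indices
throughout. Meshes read from binary NIfTI masks are extracted with
marching cubes at level 0.5 in voxel space, mapped through the volume's
affine, and reduced to their largest connected component. Marching cubes
is a deliberate, standard substitute for restricted Delaunay meshing: the
downstream pipeline only consumes a closed manifold triangulation and is
agnostic to how it was produced. Masks whose foreground touches the grid
boundary are rejected with an instruction to pad, because a clipped
isosurface cannot be closed.

Vertex areas use the barycentric (one-third) rule: each triangle assigns
a third of its area to each corner. This convention is always positive,
exactly partitions the total surface area, and makes two later identities
exact (see *Conservation* below). The Voronoi/mixed-area alternative is
sharper for obtuse-free meshes but can go negative; we do not use it.

## Laplace–Beltrami operator

Discretization is linear-FEM: cotangent stiffness matrix `S` with
barycentric lumped mass `M`. Eigenpairs solve the generalized symmetric
problem `S v = λ M v`; eigenvectors are mass-orthonormal. The sparse path
uses shift-invert ARPACK with `sigma = −1e−8` (robust to the zero
eigenvalue of the constant mode) and a **fixed start vector**: spheres
and near-spheres have degenerate eigenspaces (multiplicity 2l+1), and
without a fixed start the returned basis — and everything downstream,
including parcellation labels — would vary between runs. Small meshes
(< 200 vertices, or k close to n) fall back to a dense solve.
Verification: on icospheres the spectrum matches the spherical-harmonic
law λ_l = l(l+1)/r² within 3% through l = 3.

## Parcellation

Patch count follows the average-area rule `k = round(area / 150 mm²)`
(half-away-from-zero, floored at one). Each vertex is embedded as the
k-vector of its entries in the k lowest non-constant eigenvectors and
clustered by k-means (k-means++, 20 restarts, seeded). The constant
eigenvector is excluded by default — it is identical at every vertex and
carries no geometry; `include_trivial_eig=True` reproduces the literal
"first k" reading. After clustering, disconnected label islands are
dissolved into the neighbouring patch with the longest shared boundary
(summed edge length), iterated to convergence, and labels are put in
canonical order (descending patch area, ties by lowest vertex index) so
that identical inputs give identical, comparable labelings.

## Expansion factors and features

The expansion factor at vertex v is the barycentric vertex-area ratio
subject/template — the simplest discrete measure of local area change.
Patch features are the *unweighted* arithmetic mean of vertex factors in
the patch (area-weighted averaging is available behind an option and
documented as a deviation). Features are analyzed on the raw factor
scale; a log option exists for users who prefer symmetric multiplicative
effects.

Correspondence is assumed, not estimated: subjects must share the
template's vertex topology. The synthetic generator guarantees this by
construction; independently meshed real segmentations do not, and the
pipeline refuses them with an explicit message rather than silently
matching nearest vertices. Template construction is iterative: rigidly
align every subject to the running mean (Kabsch, rotation+translation
only — scale is signal, handled by the ICV covariate), re-average
vertices, stop when the template moves < 1e−4 mm on average or after 20
rounds.

**Conservation.** Two identities hold to machine precision and are
enforced by tests: vertex areas sum to the total surface area, and the
template-vertex-area-weighted mean of any expansion field equals the
total-area ratio of subject to template.

## Statistical model

Per patch, nested ordinary least squares:
null `y ~ 1 + age + sex + ICV`, alternative adds the response indicator.
Covariates enter unstandardized (the statistic is invariant to affine
rescaling of y and of any column paired with the intercept; raw scale
keeps coefficients interpretable in expansion-factor units per year, per
mm³, etc.). Sex is coded female = 1, male = 0; the coding is inert to the
statistic. The test statistic is `s_p = SSE_null / SSE_alt ≥ 1`,
algebraically `1 + F/(n − 5)` with F the partial F statistic of the
response column — an identity cross-checked against an independent OLS
implementation in the tests. An exactly-fit patch (`SSE_alt` at round-off
level relative to ‖y‖²) yields `s_p = +inf` with a warning; the
permutation machinery treats it as always-maximal.

## Permutation inference

Familywise error over a structure's patches is controlled with the
max-statistic procedure: at each of B rearrangements of the feature
vectors among subjects, the maximum `s_p` across patches is recorded;
adjusted p-values are `(1 + #{max ≥ s_p}) / (1 + B)` (the +1 convention
guarantees validity and excludes zero p-values). When the subject count
is so small that n! ≤ B, all permutations are enumerated exhaustively
instead (warned), and sampled results reduce to the exact test.

Significance is declared by exceedance count `b ≤ K`, with K the largest
integer satisfying `(1+K)/(1+B) < 0.05`; the reported critical value is
the (K+1)-th largest permutation maximum. This makes three statements
*exactly* equivalent, ties included: `p_adj < 0.05`, `s_p >` critical
value (strict inequality at the threshold), and the significance flag.
With B = 1000 the critical value is the 50th largest maximum, i.e. the
95th percentile of the permutation distribution.

Two schemes are provided. `shuffle_features` (default) permutes whole
feature vectors against the full design — the procedure's literal form.
It also breaks feature–covariate associations, so when covariates carry
real signal it is only approximately exact; our null calibration (500
cohorts × 1000 permutations, covariate effects on, zero group effect)
measures 5.6% familywise error against the nominal 5%, within Monte-Carlo
error. `freedman_lane` permutes only null-model residuals, preserving
covariate structure (measured 5.0% on the same cohorts); it is offered as
an option, not silently swapped in.

**Percent atrophy** of a flagged patch is reported as
`100·(1 − mean_NR / mean_others)` of the raw patch features. It is
descriptive and unadjusted: group differences in head size leak into it
(the worked example overshoots an injected 15% by ~4 points because the
non-responder group has smaller ICV). The covariate-adjusted effect size
is the GLM's response coefficient.

## Synthetic cohorts

The generator emulates the structure of a small lithium-response imaging
study; defaults are fixed at that study's design and are not tuning
knobs:

- group sizes 21 / 9 / 5 (healthy comparison / responder / non-responder);
- age ~ N(36.3, 13.0²), N(37.7, 15.2²), N(31.0, 9.8²) years by group,
  clipped to the 18–65 enrolment window;
- ICV ~ N(1503, 132²), N(1472, 134²), N(1406, 34²) cm³ by group;
- sex as each group's fixed female count (15/21, 7/9, 5/5), shuffled
  within group. Fixed composition rather than Bernoulli draws keeps
  mixed-sex groups mixed in every realization, so the design matrix of
  the responder/non-responder contrast is always full rank — with
  Bernoulli draws an all-female 14-subject subset occurs in ~11% of
  cohorts and the model is undefined there;
- two acute responders flip to non-responder at the long-term timepoint.

Covariate effects on the expansion factor default to −0.001/year (age),
+0.02 (female), +5e−8/mm³ (ICV) — each contributing on the order of one
to a few percent across its observed range, comparable to reported
age/size effects on subcortical structure and deliberately non-negligible
relative to the 5% feature noise so that the covariates are worth
modelling. The response effect is −0.15 at one patch (a 15% deficit).

*Feature mode* draws `Y = Xβ + ε`, ε ~ N(0, 0.05²), directly — the
statistics' own generative model, used for operating-characteristic
studies (error calibration, power, recovery). *Mesh mode* displaces the
template per subject: an isotropic scale `(ICV/1.47e6 mm³)^(1/3)` about
the centroid; smooth shape noise as a seeded linear combination of the
first 8 non-constant Laplace–Beltrami eigenfunctions (peak-normalized,
coefficient sd 0.1 mm) along vertex normals — smooth, anatomically
plausible variation that preserves shared topology, standing in for the
correspondence a diffeomorphic registration would supply; and, for
non-responders, an inward normal displacement supported on the target
patch (indicator softened by two neighbour-averaging passes), with its
scalar amplitude solved by root-bracketing so the patch's surface area
shrinks by exactly the requested fraction. What the downstream statistic
sees is the area change, which is therefore the quantity calibrated.

What mesh mode does *not* emulate: segmentation error, registration
error, topology differences between subjects, scanner effects, or
non-normal covariate distributions. Passing tests demonstrate the
pipeline's correctness and calibration under its own assumptions, not
robustness to those real-data failure modes.

## Problem sizes and defaults

Templates are icospheres (subdivision 3, 642 vertices) at hippocampus
scale (r = 10.37 mm, area ≈ 1345 mm² → 9 patches) and amygdala scale
(r = 6.91 mm, area ≈ 597 mm² → 4 patches); an ellipsoid and a bent-tube
generator provide less symmetric geometries for parcellation tests.
Production analyses use 10,000 permutations; calibration studies use 500
cohorts × 1,000 permutations, enough for ±1% Monte-Carlo precision on a
5% rate. The permutation inner loop is vectorized over batches of
permutations (einsum against precomputed residual-maker matrices), so a
full calibration run takes seconds on one core.

## Known limitations

- No diffeomorphic registration: real cohorts need externally established
  vertex correspondence before this pipeline applies.
- The literal feature-shuffle scheme's error control is approximate in
  the presence of covariate signal (measured mildly anticonservative,
  ~0.5–1 point above nominal at these effect sizes); Freedman–Lane is the
  principled alternative and is one flag away.
- Patches are geometry-driven, not anatomical: a patch index does not
  name a subfield, and mapping a flagged patch to anatomy is
  interpretation left to the user.
- The percent-atrophy readout is unadjusted by design (see above).
- Marching-cubes surfaces smooth sub-voxel detail; enclosed volume is
  accurate to a few percent at radius ≥ 10 voxels, cruder below.
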