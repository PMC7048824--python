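# Methods

This note documents the models behind `nasoflow`, the choices that were
genuinely open, and what the synthetic experiments do and do not show
about real nasal airflow.

## Synthetic anatomy

A subject is a pair of lateral ducts (left `x < 0`, right `x > 0`, the
mid-sagittal plane fixed at `x = 0`) plus a short shared pharynx tube.
Each duct is a stack of `n_stations` elliptical cross-section rings
(`n_ring` vertices, even, so the left-right symmetry map is a vertex
permutation) placed along a gently curved centerline; the main flow axis
is `y` and rings lie in planes perpendicular to it.  The default template
uses 21 stations (one per 5% of the normalized nostril-to-choana distance
s), 24-vertex rings, a monotone-segment interpolated area profile with its
unique interior minimum — the isthmus nasi — at s = 0.15 at 55% of the
nostril area, a mid-cavity at twice the nostril area, and slit-like
sections (height/width up to 3.5, kept ≤ 4 where Ramanujan's perimeter
approximation is accurate to < 0.05%).  Magnitudes (nostril ≈ 90 mm²,
nostril-to-choana length 70 mm) are of adult order but are generator
choices, not measurements.  Triangles carry 24 patch labels (12 per
cavity, 4 longitudinal bands × 3 angular sectors; the pharynx tube joins
the posterior patches).

**Ground-truth variation.**  Each shape mode modulates, smoothly in s
(4-term cosine series per side), the ring centroid and the two ellipse
semi-axes, then the stacked fields are translation-free and orthonormalised.
Rings therefore remain ellipses in `y`-planes, so the vertex-wise mean of
a corpus is again a member of the same geometric family — the regime the
averaging analysis assumes.  Torsion, ring rotation and topological
variation (accessory ostia, septal perforations) are deliberately absent.
Mode weight SDs are specified as target RMS surface displacements
(defaults 0.8/0.5/0.3 mm) times √V, so the same conditions scale across
mesh resolutions; the amplitudes were chosen once to give visible
millimetre-scale inter-subject variation while keeping the narrow isthmus
rings valid (a 300-seed stress run produced no degenerate rings).  I.i.d.
per-vertex Gaussian noise (default 0.05 mm, a sub-voxel segmentation-scale
residual) is added on top; the pharynx tube stays fixed.

By default the drawn weight matrix of a corpus is centered, orthogonalised
across modes and rescaled so its sample covariance equals diag(mode_sd²)
exactly ("empirical whitening").  A finite corpus then *realises* the
prescribed variance structure instead of merely sampling it, which makes
shape-model recovery checks deterministic; raw sampling is available via
`standardize_weights=False`, and whitening falls back to raw draws when
n − 1 < k.

**Profiles from vertices.**  Cross-sectional semi-axes are recovered from
each ring by second moments (exact for uniformly sampled ellipses:
mean x² = a²/2), area as πab, perimeter by Ramanujan's second
approximation, and the centerline as the polyline through ring centroids.
Ring validity requires simple, once-winding polygons about their centroid;
violations raise an error naming the side and station.  Because the
second-moment fit is quadratic, i.i.d. vertex noise inflates a fitted
semi-axis by ≈ σ²/a — a tiny (≈ 0.1%) but *systematic* effect discussed
under "Averaging bound" below.

## Shape model

PCA via SVD of the centered (n × 3V) coordinate matrix (numerically
stable for 3V ≫ n); variances are squared singular values over n − 1, and
modes with variance below max(10⁻¹² × the leading variance,
(10⁻¹⁰ × coordinate scale)²) are treated as numerical zeros, so a corpus
of identical shapes yields an empty mode list.  Mode signs are fixed by
making each mode's largest-magnitude component positive.  Coordinates are
never rescaled (raw geometric variation in mm).  Optional generalized
rigid alignment (iterated Kabsch to the evolving mean, no scaling) is off
by default because generated corpora are pre-aligned; whether real
training sets were aligned before correspondence is generally unknowable
from a finished model.  Surface QC uses exact point-to-triangle distances
(one-directional Hausdorff and mean surface distance, with a symmetric
Hausdorff variant).

In a mirror-augmented model every mode is either symmetric or
antisymmetric under the mirror map (the sample is closed under
reflection), and a member's mirror has the same weights up to those
per-mode signs — *not* a global sign flip, since symmetric size variation
keeps its sign.

## Flow proxy

Quasi-steady, incompressible, laminar; rigid walls.  Boundary conditions:
0 Pa at both nostrils, a prescribed total flow (default 200 ml/s from a
6 l minute volume at equal phase durations) through the common pharynx.
The viscous closure is the exact fully developed elliptical-duct gradient
dp/dx = 4μQ(a² + b²)/(πa³b³), trapezoidally integrated over the centroid
arc length — exact for the generator's sections, and the circular limit
gives a clean Poiseuille oracle (matched to 10⁻¹⁰ relative in the tests).
Minor losses are Borda–Carnot expansion losses K = (1 − A₁/A₂)² applied at
station transitions that expand in the flow direction (contraction
coefficient configurable, default 0).  They are the minimal mechanism that
breaks Stokes reversibility: losses off, inspiration and expiration
resistances agree to machine precision; losses on, they differ because the
two directions see different expansions.  With the default template the
proxy's inspiration resistance *exceeds* expiration (the isthmus-to-mid-
cavity expansion dominates); fully 3D inertial effects in real anatomies
give the opposite direction with ~30% magnitude.  The proxy reproduces the
existence and direction-dependence of the asymmetry, not its sign or size
for any particular anatomy.

Wall shear stress uses the fully developed axial force balance
τ = |dp/ds|_visc · A/P per station; minor-loss pressure drops model
separated flow whose momentum does not load the wall as developed shear
and are excluded from τ (configurable choice).  The bilateral partition is
solved by bisection on Q_left with a symmetric initial midpoint, so
mirror-symmetric geometries resolve to an exact 50/50 split; the solution
matches the two-resistor current divider to 10⁻⁶ ml/s when losses are off.
Units are SI internally; the API reports Pa, Pa·s/ml, ml/s and m/s.
Maximum Mach numbers are logged (≈ 10⁻² · u_max/340 ≪ 0.01 at restful
rates).

## Field mapping and statistics

Wall fields move between triangulations by exact nearest-vertex lookup
(k-d tree accelerated, ties broken deterministically by the lowest source
index).  Vertex-wise cohort statistics use the midpoint convention for
even-n medians and the n − 1 denominator for SDs.  The coefficient of
variation sd/mean is suppressed where |mean| < ε (defaults: 10⁻³ Pa for
WSS, 10⁻² Pa for pressure) because near-zero means make the ratio
noise-dominated; the masked fraction is reported and grows monotonically
with ε.

## Integral measures and reporting

Velocity statistics weight station velocities u = Q/A by station volume
A·Δℓ; WSS statistics weight triangle values (mean of vertex values) by
triangle area.  Percentiles (99.9th) interpolate linearly on the weighted
empirical CDF; true maxima are reported alongside, since "maximum" columns
in clinical tables are sometimes robust percentiles.  Boxplots use the
Tukey convention (1.5 IQR whiskers).  The expiration/inspiration ratio is
the mean of per-subject ratios computed from unrounded resistances, with
the median of ratios emitted alongside (the two differ for skewed
cohorts, and the ratio of cohort means is yet another, smaller number).
Printed tables round half-even on the decimal value (3 decimals for
resistances, 2 for velocities and WSS, 1 for partitioning) after
suppressing binary-float noise, so 0.0155 → 0.016 and 0.0205 → 0.020.
WSS histogram bin edges default to (0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5,
∞] Pa — only the first bin is a fixed convention, the rest span the
restful-breathing WSS range and are configurable.

## The averaging bound

The pipeline's central claim — the average geometry's total resistance
does not exceed the cohort mean total resistance — has an exact and an
empirical regime, and the distinction matters:

* **Theorem regime.**  For bilaterally symmetric, pure cross-sectional
  variation (mirror-equivariant semi-axis modes on a shared centerline,
  no noise; `section_variation_spec`), per-station semi-axes average
  linearly across subjects, the elliptical-duct gradient is convex in
  (a, b) on the positive orthant, each subject has R_l = R_r, and Jensen's
  inequality makes the bound strict whenever the shape variance is
  nonzero.  The acceptance suite verifies this over 100 seeded corpora.

* **Statistical regime.**  Under the general generator the bound holds in
  ≈ 99% of random small corpora but provably not always, for three
  reasons: (i) vertex noise inflates each member's fitted semi-axes by
  ≈ σ²/a while the vertex-wise mean suppresses the noise, shaving
  ~0.1–0.2% off the gap; (ii) left-right asymmetry — mirror-averaging
  symmetrizes the anatomy, and the parallel combination rewards
  asymmetry (for identical asymmetric members, symmetrization *raises*
  R_total, by convexity of r⁴ in r_l⁴ + r_r⁴); (iii) centerline
  variation makes resistance a product of a convex section term and a
  segment length, which is not jointly convex.  Real cohorts sit in this
  regime; the near-universal empirical finding reflects size variation
  dominating asymmetry, not a law.

## Problem sizes

Default study conditions: 25 subjects, 21 stations × 24-vertex rings
(1080 vertices, ~2000 triangles), 3 modes, mirror augmentation, both
phases with losses on.  The full pipeline completes in seconds; the test
suite and the acceptance script each run in well under a minute on one
CPU.  Recovery and averaging checks use a coarser 11 × 12 template with
n up to 200, which leaves every assertion scale-independent (mode
amplitudes are specified as RMS displacements).

## Known limitations

No 3D Navier–Stokes effects (secondary flows, jet impingement, vestibule
curvature losses): absolute resistances are several-fold below fully
resolved computations, while velocities and wall shear stresses are of
physiological order.  No turbulence, unsteady waveforms, compliant walls,
heat/humidity transport or particle deposition.  The synthetic anatomy has
no turbinate folds, so wall-area-dependent quantities (WSS histograms)
describe smooth-walled ducts.  Correspondence is by construction;
estimating correspondence on real meshes is out of scope, and external
STL/OFF meshes support mapping, distances and histograms but need
profile CSVs for the flow proxy.
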