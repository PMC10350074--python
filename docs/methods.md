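# Methods

## Problem and model

Multiplex tissue imaging (CODEX, IMC, Vectra mIF, MIBI) yields, per
subject, one or more segmented and phenotyped images: planar cell
coordinates with a cell-type label.  Given G >= 2 clinical groups of
subjects, the question is whether the *spatial co-occurrence* of a pair of
cell types (m, m') differs between groups.

The null model is complete spatial randomness and independence (CSRI):
each type m forms a homogeneous Poisson process with constant intensity
λ_m per image, and types are independent.  Co-occurrence at distance r is
quantified by the bivariate Ripley K function and, preferably, by the pair
correlation function

    g_mm'(r) = K'_mm'(r) / (2πr),

which equals 1 under CSRI for all r and — unlike the cumulative K —
isolates structure at distance exactly r.  Each image contributes

    K̂_mm'(r) = |W| / (l_m l_m') Σ_l Σ_l' 1{d_ll' <= r} e(l, l'),

with |W| the rectangle area, l_m/l_m' per-type counts and e(l, l') an edge
correction.  ĝ is obtained by numerical differentiation of K̂.  Group
comparison is a functional ANOVA on the resulting curves over a radius
grid: a one-way model on subject-averaged curves ("Univ") and a nested
two-way model on image-level curves ("Mult"), each summarised by the
integrated pointwise F statistic (GPF)

    F = ∫ [SSG(r)/(G−1)] / [SSE(r)/df_err] dr,

df_err = n_subjects − G (Univ) or N_images − Σ_g s_g (Mult).  In the
two-way decomposition SST = SSE + SSB + SSG (subject means weighted by
their image counts n_gi), the between-subject term SSB is computed and
reported but does not enter the statistic.

## Missing-tissue (hole) adjustment

Holes — torn or folded tissue with no observable cells — make every type
jointly inhomogeneous, inflating ĝ at small r for all pairs and breaking
the CSRI reference value of 1.  Instead of estimating an inhomogeneous
intensity (whose estimation error would propagate into K and g), the
package builds an empirical per-image null: cell-type labels are permuted
across all of the image's cells P times (default P = 50) with positions
fixed, and

    ĝ*(r) = ĝ(r) − mean_p ĝᵖ(r).

The envelope mean is the expected value of ĝ under no co-occurrence *given
the observed geometry*, so ĝ* is centred at 0 whatever the tissue shape;
group tests then run on adjusted curves.  All M types are permuted jointly
(preserving every type's abundance), and by default one permutation set
per image is shared across all pairs — this both saves work and makes the
results for (m, m') and (m', m) identical; independent per-pair streams
are selectable.  Only the envelope mean is subtracted (no variance
standardisation); a studentised option exists but is off by default,
matching the centring definition above.

## Numerical choices

* **Edge correction** — default is the translation correction
  e = |W|/|W ∩ W_shift| = ab/((a−|dx|)(b−|dy|)), exact, symmetric and
  cheap for rectangular windows; "none" and Ripley's isotropic correction
  (closed-form edge+corner arc accounting for rectangles) are selectable.
* **Differentiation** — default fits an interpolating not-a-knot cubic
  spline to K̂ and differentiates analytically; it reproduces polynomial K
  (e.g. the CSRI πr²) to machine precision, and since it is linear in K̂
  the resulting ĝ is unbiased wherever K̂ is.  A smoothing penalty (`lam`)
  and centred finite differences are available, plus a direct Epanechnikov
  kernel estimator (Stoyan-rule bandwidth 0.15/√λ̂) as an independent
  cross-check.
* **r = 0** — g is undefined at 0 (division by 2πr); the value is stored
  as NaN and every integral runs over (0, R] on the uniform grid
  (trapezoidal rule).  At step 1 this changes the integral negligibly.
* **Grids** — radius 0..100 step 1 for real-data-scale analyses, 0..200
  step 1 in the simulation frameworks; both fully configurable.
* **Pair counting** — one KD-tree pair enumeration per image (cutoff R),
  reused across all type pairs and all label permutations; results are
  identical to the brute-force double loop (tested exactly).
* **Eq. normalisation for m = m'** — the |W|/(l_m l_m') form is kept with
  self-pairs excluded; the (n−1)/n bias this implies is negligible at the
  cell counts in scope (hundreds per type).
* **Missing curves** — an image contributes a curve only if both types
  meet `min_count` (default 1; m = m' needs 2); failures are recorded as
  *missing*, never as zero.  Isolated NaN grid points inside a retained
  curve are linearly interpolated; NaN touching either end drops the
  curve; subjects with no retained curve are dropped; a pair whose groups
  do not retain >= 2 subjects each returns a flagged "untestable" result
  (p = NaN with a reason), never a silent number.
* **Weighted subject averaging** — optional; weights default to l_m·l_m',
  the number of contributing ordered cell pairs.

## Null approximation of the GPF statistic

Under H0 with Gaussian-process errors the pointwise ratio F(r) is
F_{d1,d2}-distributed (d1 = G−1, d2 = df_err).  The integrated statistic is
approximated by a scaled chi-square βχ²_d via two-moment matching:

    E = L · d2/(d2−2),
    V = 2 · c · ∬ ρ²(r, s) dr ds,   c = (d2/(d2−2))² (d1+d2−2)/(d1(d2−4)),
    d = 2E²/V,  β = V/(2E),  p = P(χ²_d > F/β),

with L the domain length and ρ the correlation of the error process,
estimated from centred residuals (subject-level for Univ, within-subject
image-level for Mult).  The plug-in ρ̂² is biased upward by roughly
(1−ρ²)²/d2 per grid pair; summed over a 200×200 grid this dominates when
curves decorrelate quickly in r (empirical g curves do) and makes null
p-values severely conservative.  The approximately unbiased estimator
ρ̂² − (1−ρ̂²)²/d2 is therefore integrated instead — deliberately without
clipping negative entries, which would reinstate the bias — and the double
integral is floored at its exact diagonal contribution.  On
Gaussian-process nulls with correlation lengths 1–8 grid steps this gives
empirical size 0.055–0.068 at α = 0.05 and Kolmogorov–Smirnov uniformity
p-values 0.25–0.95 (400 replicates per setting).  When d2 <= 4 the F
variance does not exist and the χ² form of the standardised between-group
integral is matched instead.  A subject-level group-relabelling
permutation p-value (p = (1 + #{F_perm >= F_obs})/(B+1)) is available
throughout as the assumption-free reference; the analytic approximation is
accepted because its null size and decisions track the permutation test.

If SSE(r) vanishes where SSG(r) does not, the analytic p-value is
meaningless and a degenerate-variance error points the user to the
permutation p-value.  If SSG is identically zero the statistic is 0 and
p = 1.

## Simulators: what they emulate, and what they do not

All three frameworks share the study geometry: N subjects (default 50) in
two equal groups, each subject one 1000×1000 super-image cut into three
equal-area horizontal bands (its "images", coordinates re-expressed per
band) — emulating how a large section is profiled as several fields of
view.  Counts are drawn per subject, uniform integers in [200, 400].

* **CSRI** — the exact null; used for calibration identities.
* **Mixed Poisson** — type A homogeneous Poisson; the space-varying
  density of A is computed with a uniform disc kernel (disc size Sigma for
  group 1, Sigma + Sigma_difference for group 2) on a 256² lattice
  (configurable), and type B is drawn from the inhomogeneous Poisson
  process with that density, expected count J_B, by rejection sampling
  against the lattice maximum with bilinear interpolation.  Smaller Sigma
  → stronger B-around-A co-localisation; Sigma_difference = 0 is a null
  with exchangeable groups.
* **Neyman-Scott** — Poisson parents (expected count J), Poisson(3)
  offspring per parent uniform in a disc of radius Radius (group 2:
  + Radius_difference), parents deleted, offspring outside the window
  discarded, labels A/B with probability 1/2.  Both types share parents,
  so g_AB > 1 at cluster scale in both groups; only the group *difference*
  is signal.
* **Holes** — 5 discs per super-image, centres uniform, radii U[50, 150]
  (removing roughly 5–30% of area, enough to visibly bias unadjusted ĝ),
  punched into one group's super-images before band splitting.

Real data differ from these generators in ways the tests therefore do not
probe: irregular (non-rectangular) tissue outlines, intensity gradients
not caused by holes, unequal and large per-subject image counts,
segmentation/phenotyping errors in the labels, and within-subject
dependence beyond a shared mean.  Passing the suite shows correct
estimators and calibrated tests under the stated models, not robustness to
those artefacts (the envelope adjustment addresses hole-type
inhomogeneity specifically).

Whether per-subject counts should be redrawn per image is ambiguous in a
multi-image design; they are drawn per subject (one super-image per
subject).  Group assignment is deterministic (first half of subjects →
group 1), which is exchangeable by construction.

## Monte-Carlo scales

The default test suite runs the statistical suites at desk scale, chosen
so each property is decided by its own binomial/KS envelope at the
replicate count actually used: CSRI identity 20 replicates of 2000+2000
cells; unadjusted hole scenario 40 study replicates (100 in
`scripts/acceptance.py`); adjusted hole scenario 30 replicates at P = 20;
mixed-Poisson null calibration 60 replicates; power grid 15 replicates per
cell; envelope centring properties 250 images.  Study conditions (N = 50
subjects, 3 images, count range, Sigma/Radius values, hole geometry) are
never scaled.

## Known limitations

* The two-way model treats images within a subject as independent given
  the subject mean; extra within-subject dependence would inflate the Mult
  test's size (the Univ test is the safer default).
* The βχ² approximation assumes Gaussian-process errors; heavy-tailed
  curve noise shifts size slightly (use the permutation p-value when in
  doubt).
* The isotropic edge correction's closed form assumes the exterior arcs of
  opposite rectangle edges do not meet (r well below the window diagonal).
* p-values across pairs are reported raw, matching common practice in this
  analysis style; Benjamini-Hochberg adjusted values are emitted as an
  extra column but do not change any default decision.
* No covariate adjustment; no inhomogeneous-intensity K/g variants.
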