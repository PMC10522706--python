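# Methods

## Scope and model of the data

The package evaluates agreement between 3D binary segmentation masks that
are already co-registered on a common voxel grid with known physical
spacing (mm per voxel along each axis). It performs no resampling,
registration or intensity processing: volumes and distances depend on the
grid only through the spacing, and a shape or spacing mismatch between two
masks of a case is a hard error rather than something to silently repair.
Masks are read and written as NIfTI-1; input values are binarised at 0.5,
so probabilistic outputs must be thresholded explicitly upstream. Affines
beyond the spacing are carried for provenance and compared only to warn.

The statistical design is asymmetric by construction: a *reference* rater
anchors the comparison (the rater a model was trained against), a
*comparison* rater supplies the inter-expert agreement (comparison vs
reference), and the model supplies the model-expert agreement (model vs
the same comparison rater). The reference rater is named explicitly in
every run configuration and never inferred from file names.

## Metrics

Seven metrics per ordered (prediction, reference) pair:

| metric | definition | units | better |
|---|---|---|---|
| VS | 1 − \|V₁−V₂\|/(V₁+V₂) | — | higher |
| AVD | \|V₁−V₂\| | ml | lower |
| Dice | 2TP/(2TP+FP+FN) | — | higher |
| Precision | TP/(TP+FP) | — | higher |
| Recall | TP/(TP+FN) | — | higher |
| HD95 | max of directed 95th-percentile surface distances | mm | lower |
| SDT(τ) | fraction of surface voxels within τ of the other surface | — | higher |

Surface voxels are foreground voxels with at least one face-adjacent
(6-connected) background neighbour; the grid boundary counts as
background, so a lesion touching the image edge has surface there. All
surface distances are voxel-centre to voxel-centre Euclidean distances
with the per-axis spacing applied before the norm; they are computed with
an exact Euclidean distance transform restricted to the union bounding box
of the two surfaces (exact, because nearest surface voxels always lie
inside that box) and are pinned against an all-pairs brute-force oracle in
the tests. Percentiles use linear interpolation between order statistics.
HD95 defaults to the maximum of the two directed 95th percentiles; the
pooled-distances variant is available behind a keyword (`hd95(...,
pooled=True)`) because the literature uses both conventions.

Raters may legitimately annotate nothing on a case, so empty-mask
conventions are explicit: two empty masks agree perfectly (VS, Dice,
precision, recall, SDT = 1; AVD, HD95 = 0); with exactly one empty mask
the overlap metrics are 0, AVD is the volume of the non-empty mask, HD95
is *undefined* (flagged, not invented), precision is undefined when the
prediction is empty, and recall is undefined when the reference is empty.
Undefined values propagate as NaN into the agreement table and are removed
pairwise-complete per metric: a case is dropped from one metric's test
only if either of its two compared values is undefined, and the number of
cases actually used is reported.

## Non-inferiority testing

For each metric with margin δ (defaults: 0.2 for unit-interval metrics,
3 ml for AVD, 3 mm for HD95) the per-case difference is oriented so that
positive values support non-inferiority:

* higher-is-better: dᵢ = modelᵢ − interᵢ + δ
* lower-is-better: dᵢ = interᵢ − modelᵢ + δ

and the one-sided null "median d ≤ 0" is tested. Shifting the differences
by δ is equivalent, under the paired shift model, to shifting one series
before ranking; it is done on the differences because signed-rank tests
are not shift-invariant in general and this keeps the orientation in one
place (derived from the metric's declared direction, so a caller cannot
accidentally invert a lower-is-better metric).

Test selection follows a normality gate: Shapiro–Wilk on the oriented
differences at α = 0.05; if normality is not rejected a one-sided paired
t-test is used, otherwise the one-sided Wilcoxon signed-rank test. The
test actually used is recorded in each result. The signed-rank p-value is
exact (full 2ⁿ sign-assignment distribution) for n ≤ 20 with no ties and
no zeros, and a normal approximation with continuity and tie correction
otherwise; zeros are discarded before ranking by default (Wilcoxon's
method), with Pratt's method as a config option. All-zero difference
vectors return p = 1: agreement exactly at the margin boundary cannot
support a non-inferiority claim.

P-values are adjusted with the Holm–Bonferroni step-down procedure across
all tests of one battery run. A battery cannot know about tests performed
outside it, so the family is the run by default and `family_size` lets the
caller enlarge the family (padding with p = 1). Non-inferiority is
declared when the adjusted p falls below α = 0.05.

Medians of both agreement series are reported with percentile-bootstrap
confidence intervals (default 10 000 resamples, level 0.95, seeded
generator; deterministic given the seed). Reports emit explicit
(lower, upper) bounds rather than a ± half-width, which is ambiguous for
asymmetric bootstrap intervals.

`derive_margins` implements the "average difference in inter-expert
agreements" reading of margin derivation: given two inter-expert pairings
against the same reference, it averages the mean absolute per-case
difference between the two series over the metrics of each family
(unit-interval; SI-units). This is one defensible interpretation of an
under-specified averaging scheme and is flagged as such; the rounded
defaults (0.2, 3 ml, 3 mm) remain the operative margins.

`spearman_rho` (average ranks for ties) supports volume-correlation
analyses between raters' and model's per-case volumes.

## Synthetic cohorts

The generator emulates the structure of a multi-reader lesion annotation
study, not its imaging content. A truth mask is a union of irregular
ellipsoids: an implicit ellipsoid function perturbed by a smooth random
field (Gaussian-filtered white noise, amplitude 0.15 of the implicit
range) and thresholded at zero. Lesion axis ratios are sampled from a
radii range and rescaled to a target volume sampled from 5–30 ml,
matching typical acute ischemic core volumes; centres are placed near the
grid centre with 15 mm jitter.

A rater is three parameters plus a seed offset. Per 6-connected truth
component: the component is missed entirely with probability
1 − sensitivity; otherwise the signed Euclidean distance function of the
component is perturbed by a smooth random field scaled to
`boundary_jitter_mm`, and the level set is shifted (monotone bisection on
the offset) until the foreground reaches a stochastic volume target —
`volume_bias` × true volume × a log-normal factor with
σ = 0.03 · jitter. Two numerical points matter here. First, perturbing
the level set of a smooth implicit function keeps redrawn masks compact
and connected, where independent voxel flips would produce surface
speckle that degenerates distance metrics. Second, the renormalisation
must happen *after* the jitter and must be *stochastic*: zero-mean
boundary noise alone inflates volumes (the shell just outside a convex
lesion contains more voxels than the shell just inside), while an exact
deterministic target would make any two raters sharing a bias produce
identical volumes and hence degenerate, exactly-zero volume differences.
The log-normal factor has median 1, so `volume_bias` remains recoverable
as the median ratio of rater to truth volume.

Default raters: A (jitter 1 mm, no bias, sensitivity 1 — the careful
reference), B (jitter 2 mm, bias 1.1, sensitivity 0.95), and C (jitter
2.5 mm, bias 0.6, sensitivity 0.75 — an under-reader whose median volume
falls well below the truth, a pattern seen in real multi-reader stroke
data). The "model" is deliberately just another rater parameterisation:
the statistical framework only ever sees agreement values, so a
rater-parameterised stand-in exercises it fully, with controllable
closeness to any expert.

Everything is deterministic under one master seed: per-case seeds are
spawned from a `SeedSequence`, raters consume independent streams keyed by
(case seed, rater seed offset), and reruns are byte-identical including
the optional on-disk NIfTI tree.

What the generator does **not** emulate: CT intensities and their noise,
anatomy (hemispheres, ventricles, skull), spatially correlated rater
errors driven by image ambiguity, multi-focal infarct topology beyond
simple unions, and reader drift over time. Passing tests therefore show
that the metrics and the statistical machinery behave correctly on masks
with realistic geometry and rater-like variability — they do not certify
any claim about real clinical images.

## Problem sizes and numerical choices

Desk-scale defaults keep full batteries fast: the default grid is
32×64×64 at (3.0, 3.6, 3.6) mm — a coarsened anisotropic CT-like grid —
on which a 32-case, 3-rater cohort generates and evaluates in about one
second. Metric-oracle tests use grids up to 12³ so the all-pairs
brute-force oracle stays exact and cheap; calibration tests simulate
agreement values directly (2000 boundary-null cohorts of n = 32); the
end-to-end battery test runs 100 cohort replicates per scenario. Tests
that probe sub-voxel boundary jitter use a finer 1.5 mm grid, since
jitter below the voxel size cannot flip coarse voxels.

Other fixed choices: binarisation threshold 0.5; spacing equality
tolerance 1e-4 relative; bisection for the volume offset runs 50 halvings
(resolution far below voxel granularity); bootstrap seeds for the two
series of one metric are derived from the run seed via spawned
`SeedSequence` children so battery results are reproducible and
per-metric independent; constant inputs to Shapiro–Wilk return p = 0 with
a warning (no normal fit exists) and constant inputs to Spearman return
NaN with a warning.

## Known limitations

* Surface distances are voxel-centre based; on very coarse grids SDT and
  HD95 quantise accordingly (τ should be at least the voxel diagonal to be
  meaningful).
* The HD95 of a pair where exactly one mask is empty is undefined and the
  case is dropped for that metric; cohorts where one rater frequently
  annotates nothing lose power on distance metrics, visible in the
  reported n.
* Margin derivation assumes exactly two inter-expert pairings; richer
  designs (more raters, crossed references) need the margins supplied
  explicitly.
* The t-branch of the normality gate assumes approximate symmetry of the
  differences; heavily skewed agreement distributions route to the
  signed-rank test, whose null is the symmetric-shift null.
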