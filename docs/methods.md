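# Methods

## Scope and data model

The package evaluates how well a human-trained single-cell H&E classifier
transfers to tumours from other species, and whether AI-derived spatial
immune scores carry prognostic signal.  Real inputs would be per-slide
cell tables (positions in µm with a class label in {cancer, lymphocyte,
stromal, other}), labelled nuclear masks with a paired grayscale image,
pathologist annotation tables and per-subject survival tables; all of
these are plain delimited text or TIFF/PNG.  Because whole-slide images
cannot ship with a library, every input can instead be produced by the
seeded generators in `panmorph.synthetic`, which expose the ground truth
the estimators are meant to recover.

Coordinates are stored in µm with the image convention (origin top-left,
y down); pixel inputs are converted via a `microns_per_pixel` scale.  The
class vocabulary is closed: unknown labels are an error, never remapped.
One checksum-pinned fixture ships in-package: the 20-species overall
balanced-accuracy table (codes, tumour types, annotation counts, BCAcc),
which drives the cohort statistics.

## Morphometry

`extract_features` computes 27 per-nucleus descriptors: a 14-feature
shape block (area, convex/filled area, perimeter, equivalent diameter,
major/minor axis, eccentricity, orientation, solidity, extent, Euler
number, circularity 4πA/P², aspect ratio) and a 13-feature intensity
block (mean, median, min, max, SD, MAD, range, 25th/75th percentiles,
IQR, skewness, kurtosis, 256-bin Shannon entropy in bits).  The list is a
documented reconstruction held in a data-driven registry whose SHA-based
hash is stamped on every output table, so an alternative feature list can
be swapped in without code changes.  Numerical choices: the perimeter is
scikit-image's weighted boundary approximation; the minor axis is floored
at one pixel when forming the aspect ratio so one-pixel-thin regions stay
finite; labels under 3 pixels are skipped (moments undefined); skewness
and kurtosis of a constant patch are defined as 0.  Lengths scale by
µm/px and areas by its square, and tests assert scale equivariance and
≤3% drift of rotation-invariant features under 90° rotations.

Annotation-to-centroid matching is greedy by ascending distance with
one-to-one use of both sides, using a KD-tree to enumerate candidate
pairs within the radius.  The default radius is 1.824 µm (4 px at the
0.456 µm/px working resolution of a 2×-downsampled 0.228 µm/px scan);
it is configurable.  Unmatched annotations are returned so the evaluation
stage can count them as detection misses.

## Morphospace and the port overlap

Feature vectors are z-scored per dimension (otherwise area dominates) and
embedded with exact-gradient 2-D t-SNE, perplexity 50, deterministic for
a fixed seed; the implementation is scikit-learn's `TSNE` with
`method="exact"`.  A precondition `n ≥ 3·perplexity + 2` is enforced.

Overlap between groups A and B uses dynamic-range-box logic on the two
embedding dimensions.  For a quantile ladder α ∈ {0.00, 0.01, …, 0.49}
(50 levels, configurable and reported), each dimension contributes the
ladder-mean of |I_α(A) ∩ I_α(B)| / |I_α(A)| with
I_α(G) = [Q_α(G), Q_{1−α}(G)]; the port score is the product of the two
per-dimension scores.  It is asymmetric ("fraction of A inside B", the
default orientation), lies in [0, 1], is invariant to joint affine maps,
equals 1 when A = B and 0 for disjoint supports; a symmetrised
geometric-mean variant is provided but not default.  Degenerate intervals
(all values equal) score 1 if the point lies inside B's interval, else 0,
with a warning.  Groups below 10 members are flagged and their matrix
entries left missing rather than fabricated.

Per-sample transferability is the mean of the four directed counterpart
overlaps (a-can↔h-can, a-lymp↔h-lymp) from a joint embedding of the human
reference cells and that sample's cells, so both groups live in one
space.  Whether non-counterpart pairs should enter the mean is genuinely
open; the counterpart-only default is exposed as a `pairs` argument.

## Evaluation statistics

Confusion matrices have three truth rows and five prediction columns
(three classes + `other` + `missed`).  Two conventions close gaps the
problem statement leaves open: unmatched annotations count against the
sensitivity of their true class via the `missed` pseudo-column, and
`other` predictions on annotated cells are errors for the true class.
Per class, sensitivity and specificity are one-vs-rest;
BCAcc_c = (sens + spec)/2 and the overall BCAcc averages the three
classes, excluding (with a warning) classes without annotations.

The cohort tests are rank-based: tie-corrected Kruskal–Wallis H (defined
as 0 when every observation is identical, where the tie-correction
denominator vanishes), p from χ²(k−1), and the rank epsilon-squared
effect size η² = (H − k + 1)/(N − k), which is negative for small H.  Its
95% CI is a percentile bootstrap resampling within groups (2000
replicates, seeded).  Pairwise contrasts are Dunn-style mean-rank z
contrasts with the tie-corrected variance and Benjamini–Hochberg
adjustment; estimates are therefore on the rank scale, a deliberate
approximation of mixed rank-test/contrast reporting.  Correlations are
Spearman (tie-handled ranks) or Pearson with two-sided p-values.

On the bundled 20-species table the package computes mean BCAcc 0.815
(printed elsewhere as 0.81), range 0.57–0.94, 19/20 species ≥ 0.70 and
12/20 ≥ 0.80.  Note that rank statistics on this table are computed from
two-decimal values, which introduces heavy ties; analyses run on
unrounded accuracies would break those ties and can differ noticeably in
H and in rank correlations.

## Spatial immune scores

Both point patterns are counted on one grid of square quadrats (default
width 250 µm — no canonical width exists, so it is configurable and
reported with every score) anchored at the joint bounding-box minimum,
with half-open cells so boundary points belong to the higher-index
quadrat.  The Morisita–Horn index of the two count vectors is symmetric,
translation-invariant, 1 for proportional occupancy and 0 for disjoint
occupancy; `coloc100 = 100·MH`.  Empty quadrats inside the bounding box
are retained (they carry information about joint absence); sensitivity to
the width is exposed as a diagnostic sweep (`width_sweep`) rather than
guessed away.  Lymphocyte relative abundance is the percentage of
lymphocytes among cancer + lymphocyte + stromal cells; `other` cells are
excluded from the denominator.

## Survival modelling

The multivariate Cox model uses coloc100 (per-point scale, so hazard
ratios near 1 such as 0.98/point are expected), age in years and
lymphocyte %.  Fitting is lifelines' Cox PH with Efron tie handling and
Wald CIs; covariates are screened first by VIF = 1/(1−R²) with the
keep-if-below-5 rule, exact collinearity reported as infinite and
dropped.  Dichotomisation uses the linear-interpolation lower quartile
(values ≤ Q1 are "low"); the convention is configurable since quartile
definitions differ across software.  Kaplan–Meier curves are
product-limit estimates per group; model-based adjusted curves evaluate
the fitted survival function per group level with the other covariates at
the cohort mean or at zero (both offered, since the reference point for
"adjusted" curves is itself a modelling choice).

## Synthetic generators

`gen_cell_image` rasterises nuclei as ellipses with low-frequency radial
perturbation (harmonics 2–4 scaled by an irregularity parameter) — the
simplest family spanning the shape features above.  Default class
profiles are chosen to match routine H&E nuclear morphometry: lymphocytes
median 28 µm², near-circular, dark (mean intensity 80/255); cancer nuclei
80 µm², mildly irregular, pale (130); stromal nuclei 45 µm², elongated
(aspect 2.5).  Log-normal areas (σ_log 0.2–0.3) reflect the right-skew of
real nuclear areas.  Packing is rejection-based; exceeding the attempt
budget raises with a suggestion to enlarge the canvas.

`gen_predictions` draws each kept cell's label from its row of a
row-stochastic confusion spec (default ~0.90 diagonal, in the range of a
well-transferring classifier), jitters positions by an isotropic Gaussian
(0.5 µm default, inside the matching radius), drops a 5% miss fraction
and adds 2% spurious detections with uniformly random class — no
false-positive class profile is assumed, so uniform is the neutral
choice.

`gen_point_pattern` is a Thomas-type process: uniform parents, Gaussian
offspring (exact requested counts, offspring resampled until inside the
field).  The mixing parameter θ routes each lymphocyte to a cancer parent
(probability θ) or to an independent parent set, making expected MH
monotone in θ — verified by simulation, with means rising from ≈0.24
(θ=0) through ≈0.74 (θ=0.5) to ≈0.97 (θ=1) at the default geometry.

`gen_survival` draws exponential event times scaled by
exp(β·x) with defaults β_coloc = ln 0.98 (protective colocalisation),
β_age = ln 1.05, β_lymph = 0 (abundance alone not prognostic), baseline
rate 0.0019/day (median survival near one year for an average subject,
the scale of a companion-dog oncology cohort), ages N(10, 2.5²) years.
Censoring marks an independent 20% of subjects and observes them at a
uniform fraction of their event time — a standard simulation scheme, not
a model of any specific study's censoring process.  Covariates can
alternatively be supplied from measured scores, closing the
pattern → score → survival loop.

`gen_transfer_cohort` builds the qualitative transfer experiment: 20
synthetic species whose cells are Gaussian class clouds (8 features,
class centres 6 SD apart) shifted away from the human reference by a
species-specific amount (0–5 SD along a random direction shared by the
classes, modelling species-level morphological drift).  Each species is
scored by (i) mean counterpart overlap from a joint embedding and (ii)
BCAcc of a nearest-centroid classifier trained on the human cells — a
deliberately simple classifier whose errors depend only on feature-space
geometry.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the estimators
consume — class-separable morphology, a known error process, tunable
spatial colocalisation, proportional hazards — but not the texture of
real H&E: no staining variability or artefacts, no touching/overlapping
nuclei, no tissue architecture, no 'other'-class morphology, and nuclei
are perturbed ellipses rather than segmented chromatin.  Passing tests
therefore validate the correctness and statistical behaviour of the
pipeline, not the claim that any particular classifier achieves a given
accuracy on real slides.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: 10,000 cells
for confusion recovery; 200 replicates per θ for MH monotonicity; 100
cohorts of n = 500 for Cox coverage (expecting ≥93/100 per coefficient
within 2 SE); 20 species × ~330 cells per joint embedding for the
transfer experiment.  These sizes keep every Monte-Carlo band well inside
its tolerance while the whole computation stays in the minutes range on
one CPU.  Every stochastic routine takes an explicit seed, pipeline
reports echo their seed and parameters, and identical configs produce
byte-identical reports.

## Known limitations

- The 27-feature registry is a reconstruction of a conventional
  regionprops-style panel, not a verbatim published list.
- Rank statistics on the bundled species table inherit the ties of its
  two-decimal accuracies (see above).
- Pairwise contrasts report rank-scale estimates, not raw-value
  differences.
- Quadrat width and grid anchoring are conventions; MH values should be
  compared only across identical grid settings.
- Exact t-SNE is O(n²); embeddings beyond a few thousand cells should
  reduce point counts or accept an approximate embedding outside this
  package's scope.
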