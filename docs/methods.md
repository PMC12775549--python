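# Methods

This note documents the statistical and numerical choices behind trapdiv:
the models, the places where the design was genuinely open and what was
decided, and what the synthetic-data generator does and does not emulate.

## Detection post-processing

**Boxes and tiling.** Boxes are 0-based, half-open pixel rectangles
(COCO `(x, y, w, h)` is the canonical form; YOLO normalized centers are
converted on read). Sliced inference on 4608 × 3465 px photographs uses
500 × 500 tiles; with zero overlap the plan partitions the image exactly
(edge tiles are smaller), and tile→image mapping is a pure translation with
an exact round trip.

**Cross-fold merging.** When ensemble folds disagree about the same insect,
duplicates are removed by greedy non-maximum suppression in descending
confidence: a candidate is kept iff its IoU with every kept box is ≤ 0.5
(strictly greater overlaps are suppressed). Merging is class-agnostic —
folds may disagree on the class, and the highest-confidence call wins. Ties
are broken by fold id, then class, then geometry, making the result
invariant to input order. Greedy NMS is a pinned choice: with overlap
chains (A–B and B–C overlap but A–C do not) a clustering rule would differ;
greedy suppression by confidence is the detection-community standard.

**Calibration.** Precision/recall/F1 are computed per class and fold against
held-out annotations, with one-to-one greedy matching (descending
confidence, IoU ≥ 0.5, class-specific — standard detection evaluation).
TP/FP status is fixed by the threshold-0 matching; the threshold grid
(0 to 0.99, step 0.01) only filters detections by confidence (kept when
confidence ≥ t, so t = 0 filters nothing). Precision at thresholds retaining
no detections is undefined (NaN), never 0, and never eligible as a maximum.
The selected threshold maximizes precision, breaking ties by higher F1 and
then by the lower threshold; this reading of "best accuracy" minimizes false
positives while retaining as many correct detections as possible. A class
is excluded when it is not an insect, has fewer than 30 training
annotations (strictly), or selects threshold 0 in every calibrated fold —
precedence non-insect > under-30 > threshold-zero.

Per-fold thresholds are applied fold-wise (each fold's detections filtered
by that fold's class threshold) *before* cross-fold merging; the
alternative order (merge, then threshold) is not distinguishable from the
procedure description and the fold-wise order uses each fold's calibration
where it was estimated.

A note on realistic threshold values: in crowded images, a high-confidence
detection that loses its truth box to an even higher-confidence neighbour
counts as a false positive, so precision-optimal thresholds drift into the
0.85–0.95 range. This matches the per-class optima the original survey
reported (~0.87–0.94) and is why only the lower bound of the recovered
threshold range is sharp in the end-to-end test; the clean
"threshold between the TP and FP confidence modes" recovery holds for
geometrically well-separated insects.

## Rarefaction and the N/SAD partition

Individual-based rarefaction is the exact hypergeometric expectation
`E[S_n] = Σ_i [1 − C(N−n_i, n)/C(N, n)]`, evaluated in log space (gammaln)
so large assemblages do not overflow; curves are vectorized over n. No
extrapolation beyond the observed N is performed anywhere.

Observed richness is partitioned on the additive richness scale:
`SAD-component = E[S_n_ref]`, `N-component = S_obs − E[S_n_ref]`, so the two
components sum to observed richness. `n_ref` defaults to the minimum total
abundance among *included* traps, where a trap is included iff its total
abundance strictly exceeds its observed richness (N > S); the filter is
applied before taking the minimum. A multiplicative (log-scale) variant is
available via `partition_diversity(..., scale="multiplicative")`. The
additive split is the implementable reading of the effective-number-of-
species transformation: the SAD-component is an effective number of groups
at the common subsample size and the N-component the richness surplus owed
to extra individuals.

## Coverage and β_C

Expected coverage at rarefied size n uses the slope identity
`C_n = 1 − (E[S_{n+1}] − E[S_n])`; full-sample coverage uses the
singleton/doubleton estimator
`1 − (f1/N)·((N−1)f1 / ((N−1)f1 + 2f2))` (coverage 1 with no singletons).
Richness at a target coverage interpolates E[S] linearly between the
bracketing integer sizes on the coverage scale; targets below C_1 floor at
n = 1 by default (an "extend to (0,0)" variant is used inside β_C so heavily
dominated pooled assemblages are not clipped), and targets above the
attainable coverage raise.

The maximum standardizable coverage (MC) of a trap group is the minimum over
included traps of the trap's full-sample coverage — the largest coverage to
which every trap can be rarefied by interpolation alone. β_C distributions
for the two lifecycle groups share the target
`C = min(MC_terrestrial, MC_aquatic) − 0.01`; each of the (default 9999)
randomizations draws (default) 99 traps without replacement and computes
`β_C = S_γ(C) / mean_i S_α_i(C)`.

**Two β_C variants.** The exact reference formulation is not reconstructible
from a procedure description alone, so two documented readings are
switchable via `method=`:

- `"coverage"` (default): hypergeometric richness-at-coverage of the raw
  pooled assemblage over the mean per-trap richness-at-coverage. Its mean
  under the individual-shuffle null is 1 within Monte-Carlo error at every
  scale we measured (two opposing finite-size biases cancel almost exactly),
  which is the property the null-model standardization exists for. The cost:
  identical traps give ≈ 0.99 rather than exactly 1 (at equal coverage a
  small sample sits slightly higher on its rarefaction curve than a large
  one), and adversarially dominated matrices can fall below 1 when the
  target coverage approaches the pooled assemblage's coverage at one
  individual.
- `"composition"`: with-replacement (Coleman) curves on relative abundances,
  all evaluated at the single real-valued depth n* where the *mean trap
  composition* reaches the target coverage (n* is clamped to ≥ 1; below one
  individual the standardization is meaningless). Because richness at fixed
  depth ≥ 1 is concave in the composition, this variant is provably ≥ 1 and
  exactly 1 when all traps share a composition — at the cost of a small
  positive bias (order 10⁻³–10⁻²) under the shuffle null.

No coverage-standardized γ/ᾱ ratio can satisfy all three idealized
properties (exactly 1 on identical traps, ≥ 1 always, exactly
null-calibrated) at finite sample sizes; the tests assert each property on
the variant that carries it.

**Limitation — dominated groups without extrapolation.** For a group whose
pooled assemblage is dominated by one taxon (e.g. an aquatic group that is
~85% mosquitoes), the shared coverage target is typically reached within the
first one or two individuals of the pooled curve, where richness-at-coverage
saturates near 1 regardless of genuine spatial turnover. Reference
implementations escape this regime by Chao-style extrapolation of trap
curves to sizes beyond the observed N; extrapolation is deliberately out of
scope here, so between-group comparisons of β_C are only informative when
both groups have comparable dominance structure. This is why the packaged
synthetic pipeline reports the per-group β_C distributions without asserting
an ordering between them.

The individual-shuffle null redistributes all individuals among traps
preserving per-trap totals and the pooled abundance distribution; because a
shuffle can lower a trap's attainable coverage below the requested target,
each draw's effective target is capped at that draw's own MC − 0.01.

## Ordination

Bray–Curtis (`Σ|x−y| / Σ(x+y)`) and Jaccard (`1 − |A∩B|/|A∪B|` on
presence/absence) dissimilarities feed a PCoA: Gower double-centering
`B = −½ J D² J`, symmetric eigendecomposition, axes with eigenvalue
> 1e-10 retained and scaled so the squared score norm equals the eigenvalue.
Negative eigenvalues (non-Euclidean distances) are reported, not corrected —
variance proportions use the sum of positive eigenvalues as denominator.
The first axis is sign-oriented so its correlation with the per-trap
proportion of terrestrial individuals is non-negative, making downstream
regressions reproducible across eigen-solvers; a degenerate first axis
triggers a warning. Ordination uses the same N > S trap filter as the
diversity partition.

## Landscape forest cover

Cover is the share of forest-class pixels among valid (non-nodata) pixels
whose *centers* lie within the buffer radius (default 100 m, radius 0
degenerates to the trap's own pixel); nodata pixels leave the denominator.
The pixel-center rule pins the circle-to-grid discretization so results are
exactly reproducible against per-pixel enumeration; fractional-area
weighting was rejected as unverifiable against satellite-classification
workflows. Coordinates must be projected meters — lon/lat-looking inputs
are refused unless forced. Whether open-water pixels should leave the
denominator is not determinable; pinned: all valid pixels count. Rasters
are ESRI ASCII grids (plain text) or single-band TIFFs with caller-supplied
georeferencing; the MapBiomas native-forest class codes {3, 4, 5, 6, 49}
ship as a preset, synthetic rasters use {1 = forest, 0 = non-forest}.

## Additive models

The regression `y ~ forest_cover * lifecycle + s(x, y)` is fit by penalized
IRLS. The spatial smooth is a Gaussian radial-basis expansion: k knots by
deterministic farthest-point sampling over trap locations, bandwidth equal
to the median inter-knot distance, columns centered; a ridge penalty on the
smooth block has its smoothing parameter chosen by GCV over a log-spaced
grid, with the standard degrees-of-freedom inflation (γ = 1.4) guarding
against undersmoothing. Effective degrees of freedom are the trace of the
influence matrix. With k = 1 the smooth degenerates to a constant absorbed
by the intercept, and the gaussian fit reduces exactly to OLS (verified to
1e-6, and against an independent GLM implementation for the Poisson case).

Families: gaussian (identity link), poisson (log link), quasipoisson
(poisson fit; dispersion = Pearson X²/(n − edf); standard errors scaled by
√dispersion). The model score is a small-sample corrected AIC — deviance
based with the effective degrees of freedom, plus the
`2p(p+1)/(n−p−1)` correction — and for the quasi family a QAIC
(deviance/dispersion + 2·edf), since quasi families have no true
likelihood. `select_k` scans k = 1–20 (ties to the smaller k); a k above
the number of distinct trap locations degrades to the largest feasible
basis, recorded in the fit. Coefficient covariance is the sandwich
`(XᵀWX + S)⁻¹ XᵀWX (XᵀWX + S)⁻¹ · φ`; p-values use t references (gaussian,
quasi) or z (poisson). IRLS converges on deviance (tolerance 1e-8, max 100
iterations).

The smooth's equivalence to any particular reference smoother is claimed at
the contract level only (absorption of broad spatial trend, verified by the
trend-recovery and Moran's I tests), not coefficient-for-coefficient.

Moran's I uses row-standardized inverse-distance weights (zero-distance
pairs get zero weight and are flagged), expectation −1/(n−1), the
normality-assumption variance, and a two-sided normal p-value.

## The synthetic generator

The generator emulates the archipelago survey the pipeline targets:

- **Design**: 236 traps = 72 on 17 islands (one island with two 5-trap
  transects, seven with one, nine small islands with 3 traps), 119
  open-water matrix traps (14 full 8-trap transects at distances
  10/30/80/200/500/1000/2000/4000 m plus one 7-trap transect) and 45
  continuous-forest traps (3 sites × 3 transects × 5 traps). The island and
  matrix splits are explicit configuration — the survey's per-island
  arithmetic is not derivable from size rules alone, and the printed
  continuous-site description (eight transects per site) is inconsistent
  with the printed total of 45, which the default follows. Coordinates are
  planar meters; traps sit 100 m apart along transects.
- **Land cover**: forest probability ramps from 1 within 250 m of any
  forest-stratum trap to 0 beyond 450 m, emulating 30-m-resolution
  classified scenes of forest patches in open water; matrix traps therefore
  see buffer cover decaying with distance from the focal island.
- **Counts**: negative binomial (gamma-mixed Poisson; Poisson at
  overdispersion 0) with
  `log mean = intercept_t + slope_t · forest + site effect`. Lifecycle
  slopes default to +1.36 (terrestrial) and −0.93 (aquatic); per-taxon
  overrides spread response strengths around these (real taxa differ
  widely), and site-level normal effects (SD 0.5 aquatic, 0.15 terrestrial)
  encode the clumping of aquatic insects among discrete breeding habitats.
  Intercepts make the realized community mosquito-dominated at roughly
  60–100 individuals per trap.
- **Boxes and detections**: lognormal body areas with taxon-specific forest
  effects on size; each individual lands on trap side A or B with equal
  probability. Per fold, truth boxes are detected with probability
  1 − miss_rate (default 0.75), jittered (SD 3 px, clipped to the image,
  never dropped) and confidence-scored from Beta(8, 2); false positives
  arrive Poisson(0.5) per image per fold with Beta(2, 8) confidences. Beta
  confidence distributions are a pinned choice — any (0,1) family works;
  Beta is flexible and bounded.

What it does **not** emulate: insect appearance or image pixels (boxes
only), within-image spatial structure of insects, inter-taxon detection
confusion (false positives get uniform random classes), temporal turnover,
and real land-cover texture. Passing recovery tests therefore demonstrate
the statistical pipeline's correctness under its stated generative model,
not the field performance of any detector.

## Problem sizes in tests and the acceptance script

Function defaults keep the study-scale settings (99-trap subsets, 9999
randomizations, k = 1–20). The test suite and `scripts/acceptance.py`
exercise reduced but non-trivial sizes chosen as sensible demo scales —
e.g. 199–499 β_C randomizations, 20–50 simulation replicates, and a demo
pipeline at ~12–30% of the study's abundance — so the full suite runs in a
few minutes on one CPU. The end-to-end demo keeps all 236 traps and the
full stage sequence.

## Known limitations

- β_C between-group comparisons are uninformative for strongly dominated
  groups without extrapolation (see above).
- Coverage standardization is approximate near the full-sample boundary;
  identical traps give ≈ 0.99 under the default β_C variant.
- The quasipoisson QAIC is one of several defensible quasi-model scores;
  comparisons are only meaningful within a fixed family.
- Moran's I uses the normal approximation; for n < ~20 a permutation test
  (easily built from `morans_i` on permuted residuals) is preferable.
- The landscape module performs no reprojection and fails loudly on
  geographic-looking coordinates.
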