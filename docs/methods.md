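# Methods

This note documents the models, conventions, parameter defaults and
validation experiments implemented in `actionrsa`, and what the
synthetic-data generators do and do not emulate.

## RDMs and comparison conventions

An `RDM` is a symmetric, zero-diagonal, non-negative matrix over an
ordered item list. Ingest symmetrizes inputs within a relative
tolerance of 1e-8 (`(M + Mᵀ)/2`) and rejects anything worse. All RDM
comparisons operate on the off-diagonal upper-triangle vector only:
including the forced zero diagonal would inflate every correlation by a
shared constant block, so it is excluded throughout.

- **Correlation methods**: Pearson (default for searchlight maps, since
  the maps are subsequently Fisher-transformed), Spearman, and Kendall
  tau-a. Tau-a uses the `m(m−1)/2` denominator, so ties — common in
  model RDMs with categorical structure (the binary people model,
  rating models on coarse scales) — reduce |τ| rather than being
  renormalized away. This is the conservative choice for model
  comparison. The correlation type of the standard searchlight analysis
  is a parameter, not a constant.
- **Normalization**: model and behavioral RDMs are divided by their
  maximum off-diagonal entry (max = 1 after normalization). An all-zero
  RDM has no scale and raises a `DegenerateRDMError` instead of
  producing NaN.
- **Rank rescaling** (display only): off-diagonal entries are replaced
  by average ranks mapped linearly to [0, 100]; an all-tied RDM maps to
  a constant 50.

## Multi-arrangement behavior

Each trial's on-screen distances are divided by the trial's maximum
pair distance before averaging. Subsets occupy variable screen area, so
some per-trial scale removal is required; max-scaling is the simplest
choice consistent with the final max-normalization of the aggregate. An
`evidence_weighted` aggregation mode additionally aligns each trial to
the running estimate by a least-squares scale factor and weights trials
by subset-size evidence — an iterative refinement in the spirit of the
original adaptive-arrangement literature — and agrees with the plain
mean to r > 0.98 on simulated sessions.

The adaptive subset selector implements a "lift the weakest" rule: seed
with the lowest-evidence pair (ties by item order), then add the item
with the lowest mean evidence toward the current subset while that mean
stays below the global mean pair evidence, between `min_items = 3` and
`max_items = n/2`. Pair evidence accumulates as `n_total / n_subset`
per co-occurrence (smaller subsets place items farther apart on screen
and therefore measure pairs better). This is a deliberate
simplification of the full evidence-propagation algorithm; the
properties that matter downstream — the weakest pair is always
remeasured, minimum evidence grows monotonically, adaptive sessions
beat random subsets of equal length — are asserted by tests.

The simulated arranger embeds the noise-perturbed true sub-RDM into the
arena with classical MDS and rescales to fill the arena radius. With
2-D latent ground truth and zero noise this round-trips (aggregate vs
truth r ≥ 0.99). Gaussian noise of sd 0.7 on normalized dissimilarities
reproduces a human-scale cohort reliability (leave-one-subject-out mean
r ≈ 0.6); the arranger does not model drag-and-drop kinematics, lapses,
or the 15-minute wall clock (a trial-count budget stands in for it).

Leave-one-subject-out reliability tests each subject's RDM against the
mean of the others with a permutation null (joint row/column relabeling
of the subject's RDM, 10,000 draws by default, add-one corrected,
one-sided) followed by Benjamini–Hochberg FDR across subjects. A
permutation null is used because RDM entries are not independent, so an
analytic correlation null would be anticonservative.

## The model set

Ten predictors in a fixed canonical order: semantic, body, scene,
movement, object (arrangement-derived), sociality, transitivity,
distance (rating-derived, |score difference|, per-subject normalized,
averaged, renormalized — averaging normalized RDMs keeps every subject
equally weighted), people (binary same/different), hmax_c1. The
distance ratings (1 = within reach, 2 = ≤ 3 m, 3 = > 3 m) are treated
as ordinal and differenced like the other ratings.

**HMAX-C1**: S1 units are zero-mean, unit-norm Gabors with the standard
size-dependent parameterization (σ = 0.0036·s² + 0.35·s + 0.18,
λ = σ/0.8, aspect 0.3) at 4 orientations; responses are rectified
magnitudes with reflect boundary handling (so constant images produce
exactly zero features). C1 takes the maximum over the two scales of a
band and over local spatial pools with 50% overlap. The default is a
reduced two-band configuration (Gabor sizes 7/9 and 11/13, pools 8 and
10) for 128×96 images; full-scale parameter tables can be supplied via
`C1Params`. The action-level RDM uses 1 − Pearson between mean-exemplar
C1 vectors (squared Euclidean available as an option). C1's shift
tolerance is tested as a relative property (a shifted image stays far
closer to itself than to other images, cosine > 0.97 for 3-px shifts)
rather than as an absolute error band: rectified Gabor maps fluctuate
at the carrier scale, so small absolute L2 bands are not attainable by
any standard C1.

VIF is computed per model by OLS on the remaining nine vectors with
intercept; perfect collinearity reports ∞ rather than raising, except
in `regression_rsa_map`, which refuses to run with an infinite-VIF
model set.

## Searchlight RSA

Searchlights are the `n_features = 100` nearest vertices by
breadth-first edge hops, the last ring tie-broken by Euclidean distance
(rounded to 9 decimals so symmetric vertices tie exactly) then vertex
index — fully deterministic and independent of evaluation order. The
approximate 12-mm radius of the original description is not enforced;
the feature count is the binding definition.

Neural RDMs use plain squared Euclidean distance (no cross-validated
estimators). Normalizations per analysis:

- *standard*: betas averaged across runs → squared Euclidean →
  max-normalized;
- *regression*: each vertex z-scored across the 28 conditions within
  run ("across images", removing univariate amplitude), averaged across
  runs, then each condition's member-vector z-scored ("across
  features", removing pattern-norm differences) → squared Euclidean,
  left on its native scale;
- *raw*: run-averaged, no normalization (used when coefficients must
  stay on the planted scale, e.g. in the exactness oracle).

The searchlight regression includes an intercept: max-normalized
distance vectors have nonzero mean, and omitting the intercept would
bias every coefficient. Predictors are not z-scored by default, so
coefficients live on the normalized-RDM scale and are comparable across
searchlights. Degenerate searchlights (no pattern variance) yield NaN
at their center and are excluded from group statistics.

The GLM that produces betas from simulated time series uses boxcars
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6, 32-s kernel), a pooled catch-trial regressor, optional
nuisance columns, and a constant; simulation followed by estimation at
zero noise is exact to 1e-8. Simulated noise is AR(1) Gaussian
(coefficient 0.3 by default) — no physiological noise, motion, or
distortion modeling.

## Group inference

Per vertex: optional Fisher transform, one-sample one-tailed t.
Zero-variance vertices get a large finite t (sign × 1e6) rather than a
crash. Cluster correction: initial threshold p0 = 0.001 converted to a
t cut-off with n−1 df; clusters are edge-connected components;
cluster statistic is the mass (sum of t, "max sum"); the null is
subject-level whole-map sign flipping (the standard one-sample scheme),
5000 iterations by default; corrected p = (1 + #{null ≥ observed}) /
(1 + n_perm), never zero, ties counted conservatively (≥); z is the
one-tailed normal quantile of the corrected p, significant at z > 1.65.
The z-map carries each significant cluster's z at all of its member
vertices (per-cluster, flag-equivalent to per-vertex thresholding
inside significant clusters).

## Synthetic data: what it emulates, what it does not

- **Ground truth**: 28 items in 6 clusters, isotropic-normal centers
  (sd 5) redrawn until pairwise center separation ≥ 5 × within-cluster
  sd (default; the planted K is unidentifiable in principle if centers
  may coincide), scatter sd 0.6, 2-D latent space.
- **Toy cortex**: an icosphere — the simplest connected closed
  2-manifold with near-uniform vertex density — with regions grown as
  edge-connected patches. It has no folding, no area distortions, and
  no hemispheric topology; searchlight and cluster machinery do not
  care.
- **Planted patterns**: each region's condition patterns realize a
  chosen non-negative mixture of model RDMs exactly (Torgerson
  embedding of weight × RDM read as squared distances; Euclidean,
  absolute-difference, binary and correlation distances are all of
  negative type, so the embedding is exact). Each model block's energy
  is spread over its whole vertex share by a random orthonormal map —
  squared-Euclidean geometry is invariant to it — so every region
  vertex carries signal. Behavioral-aggregate RDMs are not exactly
  embeddable (per-pair trial counts differ); `on_negative="clip"`
  plants the nearest embeddable RDM, and the chained pipeline plants
  the ground-truth geometry instead, treating the behavioral model as
  its noisy estimate, as in a real study.
- **Event sequences**: 12 runs × (56 experimental + 18 null + 7 catch
  events); every action × exemplar combination once per 6-run half;
  actors/scenes complementary within run; no action repeats except at
  catch trials (same action, different exemplar, as trial N−1); catch
  actions drawn without replacement within each 4-run block. The
  generator fixes 7 catch trials per run and reports the realized
  fraction (7/63 ≈ 11.1% of stimulus events) instead of targeting a
  percentage, because per-run arithmetic cannot hit 4.41% with these
  counts. Null events interleave at unconstrained random positions by
  default; a minimum-spacing option exists.
- **Images**: each action is a windowed-grating family (orientation ×
  frequency × window position); exemplars are jittered instances.
  Families are separable by C1 features at low jitter, which is the
  only property the image model needs; the images look nothing like
  photographs, and passing image tests says nothing about natural-image
  behavior. Luminance equalization shifts each image additively
  (iterated under clipping) to a target mean of 115.80.

Passing the recovery experiments therefore shows the *pipeline* is
correct and calibrated — not that real cortical data behave this way:
real noise is spatially correlated and non-Gaussian, real regions are
not orthonormal spreads of exact geometries, and real meshes are not
spheres.

## Validation experiments (problem sizes as shipped)

- **Mixture exactness**: 2-model mixture (weights 2 and 3) in an
  80-vertex region of a 642-vertex icosphere; recovered by OLS with
  max relative error ~1e-15 (tested at 1e-6).
- **Region recovery**: 20 seeds × 20 subjects × 12 runs, noise sd 0.4
  (per-subject in-region map r ≈ 0.16–0.19), searchlight 10 features on
  the 642-vertex mesh, 1000 permutations. Scored by Dice between
  significant region-overlapping clusters and the planted region
  (≥ 0.8) and by absence of non-overlapping significant clusters;
  isolated false positives occur at the designed 5% family-wise rate.
  The 10-feature searchlight is the desk-scale choice for this mesh
  resolution; the 100-feature definition remains the pipeline default.
- **FWER calibration**: 200 null cohorts (12 subjects, i.i.d. normal
  maps, 162-vertex mesh, 500 permutations); family-wise error must fall
  inside the binomial 95% band around 0.05 (measured ≈ 0.035).
- **Cluster-count recovery**: 50 cohorts at separation ratio 8 ("high
  separation"); silhouette-optimal K equals the planted 6 in ≥ 90%
  (measured 98%; at the default ratio 5 recovery is ~80%, which is why
  the high-separation regime defines the benchmark).
- **Primitive oracles**: brute-force double loops for distances,
  exhaustive pair counting for tau-a, Procrustes round-trips for MDS,
  direct least squares for VIF, hand-sorted step-up for BH-FDR.

## Numerical and degenerate-input conventions

Ties everywhere break by fixed item/vertex order for determinism. Every
stochastic operation takes an explicit seed and is bit-reproducible
given (config, seed). Degenerate inputs follow one rule: operations
whose *result* would be meaningless raise (`normalize_rdm` on zero
RDMs, correlations on zero-variance vectors); operations embedded in
larger maps record the degeneracy and continue (NaN map vertices,
zero RDMs flagged `degenerate`, infinite VIF values).

## Known limitations

No cross-validated distance estimators (crossnobis/LDC), no TFCE or
volumetric correction, no S2/C2 HMAX layers, no color processing, no
GUI for arrangement capture, no covariate group models. The chained
pipeline is desk-scale by default (subdivision-2 mesh, hundreds of
permutations); all sizes are configuration, not code.
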