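# Methods

This note documents the models implemented in `msnets`, the assumptions
behind them, the synthetic study conditions, and the numerical choices a
user should know before trusting or extending the results.

## Structural disconnectomes

A subject's disconnection matrix is computed from a binary lesion mask and
a normative streamline atlas living on the same voxel grid. For every
region pair connected in the atlas, the entry is the fraction of that
pair's streamlines with at least one traversed voxel lesioned. Choices:

* **Exact segment traversal.** Streamline–voxel intersection uses exact
  plane-crossing traversal of each polyline segment (interval midpoints
  identify voxels), not point sampling: deterministic and resolution
  independent. Coordinates are continuous voxel coordinates; voxel `i`
  spans `[i, i+1)`, so a point on a boundary belongs to the higher-index
  voxel.
* **Binary transection.** A streamline counts as transected as soon as one
  traversed voxel is lesioned. No partial-overlap weighting: the
  "proportion of streamlines" definition is binary per streamline. The
  alternative (a minimum-overlap criterion) is not implemented.
* **Undefined pairs.** Pairs with no atlas streamlines are flagged in
  `structural_mask` and stored as zero; edge-wise statistics on
  disconnection matrices run on the structural mask only.

Total lesion volume (TLV, mm³) is voxel count × voxel volume, and enters
models as `log(1+TLV)` to tame its right skew.

## Morphometric similarity

Each cortical region is represented by its vertices' joint distribution
over five features (cortical thickness, GM volume, surface area, mean
curvature, sulcal depth), pooled-standardized across all vertices so units
do not weight the metric. Similarity is `1/(1 + D_sym)` with `D_sym` the
symmetrized KL divergence between the two vertex clouds, estimated by the
classical k-nearest-neighbor density-ratio estimator
`(d/n) Σ log(ν_k/ρ_k) + log(m/(n−1))`.

* `k = 3` by default: a small neighbor count keeps bias low at the
  O(100)-vertex scale of parcellated surfaces; the estimator's variance at
  that k is acceptable once ~50+ vertices per region are available.
* Raw estimates can dip below zero for near-identical distributions; they
  are clamped at 0, which also guarantees `s ≤ 1`.
* The diagonal is set to 0 and excluded from every downstream statistic;
  only edges are analyzed.
* Subcortical structures are excluded by construction (no surface
  vertices).

Against the analytic Gaussian oracle (`KL(N(0,1)‖N(δ,1)) = δ²/2`), the
estimator is within ~5–10% at n = 5000 for δ in [0.5, 2]; at δ² ≪ 1 the
absolute error floor (~0.01–0.02) dominates the relative error.

## Network-based statistics

Cross-sectional models are OLS per edge with a contrast t-statistic
(`df = n − rank(X)`); longitudinal models are linear mixed models
`edge ~ time + nuisance` with random intercept and slope of follow-up time
per subject, fitted by profiled REML. Components are formed among edges
with `p < p_primary` (strict inequality; default 0.01), separately for
positive and negative statistics (sign split), and scored by the sum of
|t|. Family-wise error uses the maximum-component permutation null with
the add-one estimator.

* **Freedman–Lane permutation** for nuisance-adjusted GLMs: residuals of
  the nuisance-only fit are row-permuted, the nuisance fit added back, and
  the full model refitted. This is the standard scheme for permutation
  with covariates; all-zero design columns are dropped first so that a
  zero nuisance block reproduces the unadjusted analysis exactly.
* **Longitudinal permutation unit**: subject-level sign flip of the
  within-subject time-centered trajectory. Subject means and
  between-subject covariates are untouched, preserving exchangeability
  under the null of no time effect.
* **The edge-wise REML engine.** A generic mixed-model fit is far too slow
  inside permutation loops, so the engine evaluates the profiled REML
  criterion through the Woodbury identity on the 2×2 random-effect block:
  all V-parameter-independent pieces (`X'X`, `Z'Z`, `X'Z`, `Z'y`) are
  precomputed, making one criterion evaluation a handful of small batched
  matrix products. Variance parameters are optimized per edge by
  Nelder–Mead on a log-Cholesky parameterization (with one restart;
  permutation refits warm-start at the observed optimum with a reduced
  iteration budget, which is as accurate as a cold full-budget fit because
  sign flips leave the covariance structure unchanged). The engine matches
  `statsmodels` MixedLM to ~4 decimals where both converge, and attains a
  lower REML criterion where statsmodels does not.
* **Wald inference with a normal approximation** for edge-wise mixed
  models (no Satterthwaite correction): mild type-I inflation (~6–7% at
  40 subjects, nominal 5%) that shrinks with subject count. Scalar fits
  (`fit_scalar_lmm`, used for EDSS/TLV/BPF trajectories) go through
  statsmodels MixedLM, with the internal engine as a fallback on
  degenerate data. Edges whose slope variance collapses to the boundary
  are refitted with a random intercept only and flagged.

## Prediction of long-term progression

Binary CDP labels (EDSS increase ≥ 1 for baseline ≤ 5.5, else ≥ 0.5,
inclusive) are predicted from baseline edges by repeated stratified nested
CV. Per training fold: linear deconfounding fitted on the fold only (test
data residualized with training coefficients, scaled with training
statistics), then NBS-style selection — edge-wise GLM against the label,
threshold at `p_primary`, keep the largest connected component (an
"all components" option exists). The inner CV picks among logistic
regression, linear SVM, and LDA with a seeded randomized hyperparameter
search under a fixed evaluation budget (a surrogate-model optimizer could
be slotted in; randomized search at these budgets explores the same
ranges). Empty selections fall back to a majority-class classifier, which
keeps chance-level behavior honest. The 95% CI is the 2.5/97.5 percentile
of repeat-level mean accuracies; class imbalance is handled by
stratification only. Permutation significance reruns the pipeline on
shuffled labels at a reduced budget (documented in `PredictConfig`).

## Summaries, correlations, coupling

* Subnetwork burden per subject = mean |z| over a component's edges, each
  edge z-scored against a reference group; absolute values stop
  opposite-sign deviations canceling. Edges with zero reference SD are
  excluded with a warning. For similarity networks the reference is the
  healthy controls; for disconnection — where controls are lesion-free and
  degenerate — the pipeline uses the patients' baseline distribution as
  reference.
* Annualized change is (last − first)/years per subject by default (a
  regression-slope alternative is a one-line change on the summary table).
* Partial Spearman = Pearson correlation of rank residuals after linearly
  removing the ranked control variable, `df = n − 2 − k`.
* Coupling: subcortical rows are dropped from disconnection so both
  domains live on the shared cortical nodes; global = across-subject
  correlation of matrix means, edge = correlation of vectorized group-mean
  matrices, node = per-region correlation of paired row profiles
  (self-pairs excluded). `exclude_zero_disconnection` drops
  structural-mask-false edges plus zero-valued edges. The disease-duration
  split is at the median, ties joining the "shorter" group.
* Demographics-table tests: Welch t with Satterthwaite df directly from
  per-group summary statistics (so printed tables are sufficient input),
  and Pearson chi-square without continuity correction for 2×2 counts.

## The synthetic cohort

The generator is a deliberate geometric abstraction — an ellipsoidal
"brain" on a 48×56×48 grid of 2 mm voxels with a cortical shell of
Voronoi regions (labels ordered by azimuth, as anatomically ordered
atlases are), central subcortical blobs, a ventricle proxy, and
white-matter bands in between. Its purpose is identifiability: every
planted effect must be recoverable by the analysis that targets it.

* **Tract geometry.** Streamlines are spherical-interpolation arcs confined
  to radial bands: cortico-cortical tracts ride an outer association band,
  cortico-subcortical tracts cruise there and then dive along their blob's
  centroid axis (crossing deep bands only inside their own funnel), and
  subcortical–subcortical tracts stay deep. The planted disconnection
  component — by default the 10 edges of a clique over 5 neighboring
  cortical nodes — shares a deeper fascicle band, and all other tracts are
  rerouted around the fascicle's dilated voxel tube (distinct fascicles do
  not interpenetrate). This segregation is what makes a *focal* planted
  effect physically possible on a grid ~30× smaller than a real brain;
  with naive straight-line tracts, any lesion transects dozens of edges
  and no adjustment can isolate a subnetwork.
* **Lesions.** Counts are Poisson with mean `lesion_rate·(1+severity)`
  (default 18 at severity 0, severity ~ Gamma(2, 0.5)); centers sampled
  from non-GM voxels with density `exp(−0.04/mm · distance to the
  ventricle proxy)` (periventricular predominance); radii uniform
  1.5–2.5 mm; lesions clipped to non-GM voxels so disconnection acts only
  through streamline transection. Lesions accrue over visits (masks are
  nested in time) at 0.2/year at severity 0.
* **Planted disconnection and the clinic.** Targeted lesions are
  single-voxel and painted only on fascicle voxels hosting no other tract,
  at a Poisson rate of 3 per edge per unit of a subject "vulnerability"
  factor (Gamma(2, 0.5), independent of the global lesion propensity),
  accruing at 0.15/edge/year. The latent EDSS is
  `2.5 + 1.1·z(log TLV) + 1.0·z(targeted-transection score) +
  slope·t + noise`, rounded half-up to the 0.5 grid and clipped to
  [0, 10]; the SDMT (inverted scale) has analogous global (0.8) and
  subnetwork (0.6) terms. Tying the global disability channel to realized
  TLV (not to the latent lesion rate) means TLV adjustment removes it
  exactly, leaving the subnetwork channel — damage *location* carries
  information damage *amount* does not, which is precisely the phenomenon
  the adjusted analyses test. Long-term CDP is Bernoulli with log-odds
  `logit(0.446) + 1.0 · baseline score z`, and the long-term EDSS is then
  generated to agree with the label under the CDP rule.
* **Planted similarity.** For patients, the higher-id endpoint of each
  planted similarity edge (default: a 10-edge clique over cortical nodes
  21–25) has its vertex cloud shifted along the inter-centroid direction
  and inflated (negative effect: similarity drops) or pulled toward the
  partner (positive effect), growing 0.3/year.
* **Calibration.** Marginals were calibrated once to the published
  cohort-level values treated as study conditions: baseline EDSS median
  2.5 (IQR ≈ 1.5–3.6), SDMT z ≈ −1.3 ± 1.3, CDP rate ≈ 45–48%, EDSS
  mixed-model slope ≈ 0.17/year (0.084 intrinsic plus damage-mediated
  worsening), log-TLV slope ≈ 0.02, BPF z slope ≈ −0.09 with baseline
  ≈ −2.7 ± 2.1.
* **Determinism.** One global seed feeds a named per-stream, per-subject
  seed tree; any subject's data can be regenerated independently of cohort
  size, and full runs are byte-reproducible.

**What passing tests do and do not show.** The generator has no scanner
noise, registration error, anatomical topology, relapse dynamics or
treatment effects; its tract bundles are idealized and its planted effects
are, by design, orthogonal to global burden. Recovery of planted effects
demonstrates that the statistical machinery is correct and calibrated —
not that real MS subnetworks are detectable at these sample sizes.

## Problem sizes in the test suite

Simulation-based checks run at deliberately chosen desk scales: FWE
calibration on 200 null cohorts of 60 observations × 200 edges with 200
permutations; planted-component power on 100 replicates of 120-patient
baseline cohorts sharing one atlas (100 permutations each); mixed-model
recovery on 60 replicates of 50–60 subjects × 4 visits; prediction
calibration on 20 replicates of 200 subjects at a reduced search budget;
and the end-to-end reproducibility run on a 10+10-subject cohort with 26
cortical regions. The acceptance script reports the same quantities at
comparable sizes from a user-supplied seed.

## Known limitations

* Edge-wise mixed-model p-values use the normal approximation (no
  Satterthwaite df); with few subjects the primary threshold is slightly
  liberal, which the permutation FWE absorbs at the component level.
* The k-NN divergence estimator is biased at very small vertex counts;
  keep ≥ ~50 vertices per region and treat `k` as part of the estimand.
* The NBS null with strongly correlated edges has a heavy-tailed maximum
  component distribution; small planted effects can be swamped by a single
  shared damage mode, which is a property of the data structure, not of
  the implementation.
* Coupling analyses are purely correlational; no causal ordering between
  disconnection and similarity change is modeled.
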