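# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the evaluation protocols implemented in
`mutcr`, in enough detail to reproduce or critique them.

## Response and features

A cohort is a set of somatic point mutations from donors of one or more
tumor types, mapped onto a chromatin-state segmentation. For region *i*
(length *l_i* bp, count *C_i*, cohort total *T*):

* density `D_i = (C_i / (l_i/1000)) / (T/1e6)` — mutations per kb,
  normalized by the cohort's total in millions so cohorts of different
  depth are comparable;
* `D1_i = log2(D_i + 1)`; response `Y_i = (D1_i − Mean)/STD`.

`Mean`/`STD` are computed on the training regions only (sample standard
deviation, `ddof=1`; the convention is recorded in the output metadata) and
are stored so the transform inverts exactly — the Poisson background test
depends on that inversion. Mutation positions are 1-based; segmentations
0-based half-open; a mutation at position q belongs to [start, end) iff
start < q ≤ end. Blacklisted mutations are removed before counting, and
mutations on chromosomes absent from the segmentation are excluded from T
(reported as an unassigned tally), keeping T consistent with the modelled
universe.

Features: `X_ij = −log10(median p)` of motif j's FIMO occurrences with
p ≤ 1e−5 whose midpoint falls in region i; 0 when absent (equivalent to
p = 1; keeps the matrix sparse and monotone in evidence). Strand is read
but unused. Occurrence-to-region assignment is by midpoint; ties in all
top-k selections break toward the smaller motif index.

Donor-level cohort filters: metastatic donors removed; WGS preferred when a
donor has both assays; per-type IQR outliers removed (linear-interpolation
quartiles, 1.5×IQR fences); tumor types with fewer than 5 retained donors
or fewer than 30,000 total mutations dropped.

## The contextual-regression network

`Ŷ = x · β(x)` where β(x) is produced by a fully connected embedding:
dense(p/2, ReLU) → dropout 0.01 → dense(p/d3, ReLU) → dropout 0.01 →
dense(p/d5, ReLU) → dropout 0.1 → dense(p, linear). Divisors d3 ∈ [10,20]
and d5 ∈ [5,30] are configuration with defaults 15 and 10. The model has no
intercept anywhere: the prediction is literally the dot product, which is
what makes β(x) a per-region, per-motif effect readout. The identity
|Ŷ − β·x| is exact to float rounding and asserted in tests at 1e−5.

Training: Adam (lr 1e−3), mini-batches of 256, up to 200 epochs with early
stopping (patience 10) on a 10% validation split, all driven by one seed;
the best-validation parameters are restored, and the starting point itself
is scored so a warm start can never be degraded. Two numerical choices are
essential and are part of the package's design:

* **Near-zero context head.** With a conventionally initialised output
  layer, the initial predictions x·β(x) carry large random variance; the
  fastest descent direction is to silence the embedding by driving its
  activations to zero, after which β(x) is a constant vector and the model
  is stuck as a global linear fit. Initialising the head at 1% of Glorot
  scale starts training *at* the global-linear solution with a live
  embedding on top, and the contextual part can grow.
* **Scale-only feature normalisation.** Inputs are divided by their
  per-column training standard deviation (no centering — an offset would
  break the dot-product identity). The scaling folds exactly into the
  reported coefficients (β_j = β_internal_j / s_j).

* **Inverse-variance weighting.** The Poisson counting noise on D1 is
  heteroscedastic: by the delta method `sd(D1_i) = √λ_i / (ln2 · (λ_i + k_i))`
  with `k_i = (l_i/1000)(T/1e6)`. The pipeline fits with weights 1/var
  (λ estimated by the observed count, floored at 1, normalised to mean 1).
  This matters for the excess-region test: a fit error of fixed log2 size
  inflates a region's Poisson z-statistic by ≈ 0.7·err·√λ, so precisely
  measured (long, deeply covered) regions must be fitted tightly rather
  than sharing one average error budget. Plain unweighted MSE is available
  (`sample_weight=None` / `variance_weighting=False`) and is the loss the
  four reported fit metrics (Pearson r, MSE, MAE, Spearman ρ) describe.

Ensembling (`n_ensemble` seeds, predictions averaged) is available in the
refinement pipeline; it reduces the variance component of the background
error at linear cost.

## Background refinement and region classes

Expected counts come from inverting a prediction:
`D1 = Ŷ·STD + Mean`, `D = max(2^D1 − 1, 0)`, `λ = D·(l/1000)·(T/1e6)`.
Tail probabilities are exact Poisson sums: `p_upper = P(X ≥ C)`,
`p_lower = P(X ≤ C)`; λ = 0 with a positive count yields p_upper = 0
(flagged impossible event). T is held fixed at the original cohort total
throughout.

Iterative refinement: train on current training set → predict all regions →
λ → tails → flag regions with either tail p < 0.1 → retrain on the
unflagged. Flag sets are recomputed fresh against the current model each
iteration, so a region wrongly flagged once can re-enter training;
iterations warm-start from the previous parameters; the loop stops at
`max_iter` (default 2) or when the held-out MSE improves by < 1% (relative).
After each fit, λ is bias-corrected per predicted-λ decile by the trimmed
mean (10%) of observed/predicted over non-flagged regions — a robust
recalibration that removes smooth systematic bias, which would otherwise be
amplified by √λ in the test statistic. The history's `test_mse` is
evaluated on the held-out regions not flagged at iteration 1, against
iteration-1 response constants: a stable, background-like target on which
successive iterations are comparable (held-out excess regions would
otherwise dominate the error of an improving background model, and the
response rescaling would shift the target between iterations).

Final labels per cohort: **related** if Benjamini–Hochberg-adjusted
upper-tail FDR < 0.01 (takes precedence), **independent** if both tail
p-values > 0.1, otherwise **ambiguous**. The labels partition the regions.

FDR control here is conditional on the background being learnable: with a
fitted (not known) λ the Poisson test is mildly anti-conservative in
proportion to the residual fit error. Under the calibration conditions
below, the realised FDR of related calls stays under 5% at nominal 1%;
under badly misspecified backgrounds it will not, and that limitation is
intrinsic to background-based excess testing, not to this implementation.

## Motif importance, disruption, classification

*Importance*: per region, stage 1 keeps the ⌈0.1·p⌉ motifs with largest
|β_j·x_j| (contribution), stage 2 the ⌈0.1·⌈0.1·p⌉⌉ of those with largest
|β_j|; the profile holds β at kept motifs, 0 elsewhere. Profiles of
cancer-independent regions are clustered by K-means (10 restarts, seeded);
k is the elbow of the inertia curve (maximum distance to the chord, with a
k = 1 anchor so a low elbow is detectable) unless forced; clusters under 10
regions are dropped. Cluster mean-weight vectors are merged into groups by
agglomerative clustering (Manhattan distance, average linkage; default 10
groups). Group summaries: mean weights, region counts, z-score of
mean log2 density across groups, chromatin-state fold change (share in
group / share in all regions), and mutation-rate profiles around motif
site midpoints (±1 kb; ±50 bp means feed Student's t comparisons between
positive- and negative-weight motifs). The share of epigenetics-associated
motifs among important motifs is tested with a one-proportion z-test using
the null proportion in the standard error.

*Disruption*: for one donor and one region class, `rate = C/(M·N)` — C
binding sites overlapped by ≥1 of the donor's mutations (a site hit twice
counts once; overlap is positional, inclusive at both ends), M sites in the
class, N the donor's mutations in the class; undefined when M·N = 0 and the
donor is then excluded pairwise. Per tumor type, a one-sided paired t-test
(related > independent) across donors; zero-variance differences are
reported as t = 0, p = 0.5 (all-zero) or ±∞ with p = 0/1 (constant shift),
flagged rather than NaN. Significantly disrupted motifs: top 5% by
donor-averaged related-region rate intersected with p < 0.05.

*Classification*: donor feature rows are mutation counts over the union of
cancer-related regions; the union and any feature selection are functions
of training donors only (the leakage guard is itself tested). A
scikit-learn gradient-boosting classifier is tuned over a six-parameter
grid by stratified 5-fold CV, selecting the combination with the minimal
mean |train − validation| accuracy gap (ties: higher validation accuracy,
then grid order) — an overfitting-averse rule. The published optimum
settings ship as presets (`PRESET_ALL_REGIONS`, `PRESET_TOP150`); the
default grid is small (16 points) and user-extensible. A second pass keeps
the top-k regions (default 150) by feature importance and re-trains.

## The synthetic-cohort generator

The generator emulates the statistical structure of the real inputs while
staying inside the model family the network represents:

* region lengths log-uniform on [1 kb, 100 kb], tiled over 8 synthetic
  chromosomes; chromatin-state labels drawn with context-dependent bias;
* each region has a hidden context; context c's marker-motif block is
  present with probability 0.8 vs 0.15 for background motifs (zero-inflation
  0.2 vs 0.85); nonzero scores are 5 + Gamma(2,1), mimicking −log10 p of
  occurrences that survived the 1e−5 cutoff. Markers make the context
  identifiable from x — without them a context-switching rate model would
  be unlearnable from features alone;
* per-context sparse coefficients (10% nonzero, standard-normal), centered
  against the context's expected feature vector on their support so the
  latent response is mean-zero: the network has no intercept, and an
  uncentered latent would place the truth outside the representable family
  and cap measurable fidelity regardless of fit quality;
* the standardized latent (plus Gaussian noise of sd `noise_sd`) maps to
  log2 density with spread `density_log2_sd` (default 1.0) and an offset
  solved by root-finding so that the expected counts sum to the requested
  cohort depth; expected counts are `λ_i = D_i·(l_i/1000)·(T/1e6)`;
* a `spike_fraction` of regions (each owned by one tumor type, round-robin)
  has λ multiplied by `spike_multiplier` in that type only; observed counts
  are Poisson; counts materialise as uniformly placed point mutations
  attributed multinomially to donors;
* the emitted FIMO table has one occurrence per nonzero X_ij at the region
  midpoint with p = 10^(−X_ij), so featurizing the emitted files reproduces
  the stored matrix exactly — an end-to-end consistency that is tested.

Defaults describe a deeply sampled merged cohort: 5,000 regions, 100
motifs, 4 contexts, ~100 expected mutations per region, 40 donors per type.
What the generator does *not* emulate: nucleotide sequence and
trinucleotide signature structure, intra-region rate profiles (uniform
placement = null profile), donor-specific mutational processes, and
correlated features across neighbouring regions. Tests passing on these
cohorts show the machinery is correct and calibrated under the stated
assumptions; they do not show the biological model is adequate for real
tumors.

## Evaluation protocols (problem sizes and conditions)

All protocol runs use `max_epochs=3000, patience=100` — the default
patience of 10 is tuned for interactive use and stops long before the
optimum on these cohorts.

* **Fidelity**: 5,000 regions, p=100, 4 contexts, noise_sd 0.1, no spikes,
  depth 100/region; 10% held-out regions; 3-seed ensemble with
  inverse-variance weights. Reported: Pearson r between the ensemble
  prediction and the noiseless latent response on held-out regions
  (~0.91–0.94 across seeds), and the maximum dot-product identity
  deviation (~1e−15).
* **Attribution**: 3,000 regions, single context, noise_sd 0.1. Sign of the
  region-averaged β versus the true coefficients over features with
  above-median |true β| (the nonzero support): 100% in our runs.
* **Poisson machinery**: tails checked against brute-force pmf sums at
  λ ∈ {0.5, 5, 50} (agreement ~1e−15); null calibration on 10,000 regions
  with λ ~ lognormal(ln 5, 1) — kilobase-realistic depths where the
  discreteness of the Poisson support keeps the strict-tail exceedance
  visibly below each α.
* **Region detection**: 8,000 regions, single context, noise_sd 0, depth
  100/region, 5% spiked ×3; refinement with max_iter=3, 3-seed ensemble.
  The single-context noise-free background isolates the detection
  machinery (flagging, refinement, recalibration, BH) from embedding
  approximation error, which the fidelity protocol measures separately.
  Realised FDR 0.01–0.04, sensitivity 0.82–0.90 across seeds; held-out
  background MSE decreases over iterations.
* **Disruption calibration**: 500 null cohorts (20 donors, 120 sites,
  ~100 mutations per donor per class, uniform placement): paired-test
  rejection at α = 0.05 lands inside the 95% binomial interval.
* **Classification**: 2,500 regions, 4 types × 40 donors, type-private
  spikes ×3, depth 50/region; related-region union detected from the 80%
  training donors only; small tuning grid. Held-out accuracy ≈ 1.0;
  label-shuffled control ≈ chance (0.25).

## Known limitations

* FDR control degrades with background misfit (unavoidable for any
  background-based excess test); multi-context cohorts with substantial
  latent noise show realised FDR above nominal, as the README example
  discusses.
* The elbow criterion for k is a heuristic; for irregular inertia curves
  forcing k (`--k`) is more reliable.
* The disruption test treats sites as exchangeable within a class; it does
  not model site-specific mutability.
* Minimal VCF import handles single-sample point variants only; indels are
  out of scope beyond positional overlap.
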