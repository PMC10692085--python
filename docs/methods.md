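# Methods

`strangertest` implements a fully automated ("human-free") analysis of
the dog Stranger Test: a behavioral assay in which a dog moves freely in
a 4.7 × 4.7 m fenced arena for about 40 s while an unfamiliar test
person (TP) sits motionless at the arena center and a familiar person
(FP, the owner or handler) sits in a corner. The dog's coping style
toward the stranger — reacting *towards* ('+'), *neutrally* ('0') or
*away* ('−') — is traditionally scored by experts from video. The
package replaces that scoring chain with: trajectory preprocessing →
convolutional-autoencoder embedding → unsupervised clustering →
statistical validation against expert scores and owner-completed C-BARQ
questionnaire categories → supervised predictors.

## Trajectory preprocessing (`trajio`)

Input is per-frame tracker output: a bounding box per object (dog, TP)
per detected frame, with a pixel-to-meter calibration. The object
center (bbox midpoint) proxies the center of mass. Preprocessing:

1. **Quality gate.** Trials are kept only if both objects are detected
   in at least 80% of frames (inclusive boundary).
2. **Gap filling.** Interior gaps are linearly interpolated between
   flanking detections; leading/trailing gaps hold the nearest detected
   value (slope extrapolation could leave the arena, so clamping is
   used, and each hold is recoverable from the imputation mask). A
   centered moving average of width 5 frames (~0.2 s at 24 fps,
   edges shrunk) then suppresses detection jitter; width 1 disables
   smoothing. Post-fill coverage is 100%, comfortably above the 95%
   requirement. `fill_gaps` is idempotent: an already post-processed
   trial passes through unchanged.
3. **Rate standardization.** Linear resampling to 24 fps; durations are
   preserved to within one frame period.
4. **Duration standardization.** Every trial is truncated to the
   shortest trial's frame count, anchored at the trial start (the test
   phase begins at arena entry; tails are the most variable part).

The operation order (fill → smooth → resample → truncate) keeps all
interpolation on native timestamps. Each preprocessed trial is a sample
`s = (d, p)` with `d, p ∈ R^{m×2}`; the cohort matrix `D` has shape
`n × (4·m_time)`, flattened time-major with channel order
(dog_x, dog_y, person_x, person_y).

## Movement-space embedding (`embedding`)

A 1-D convolutional autoencoder with the fixed layer sequence:
encoder = conv(window 3, same padding, ReLU) → dropout(p = 0.1) →
max-pool(window 2); decoder = upsample-by-repeat(2) → conv(window 3,
linear) back to 4 channels. Channels are embedded jointly (a 4-channel
convolution) since the sample concatenates dog and person series.
Training minimizes mean-absolute-error reconstruction loss with Adam;
inputs are z-scored per channel across the cohort (required for stable
optimization; validation MAE is reported in meters via the inverse
transform). Hyperparameters are grid-searched — default grid
n_filters ∈ {4, 8, 16} × learning rate ∈ {1e-3, 1e-4}, batch size 8, up
to 200 epochs with early stopping (patience 20) on a 25%-by-trial
validation split — and the grid point with the lowest validation MAE
wins. The implementation is plain numpy (the forward/backward passes
are a handful of einsums), which makes training bit-reproducible given
the seed. A trial's movement-space vector is the flattened encoder
output, length `⌊m_time/2⌋ × n_filters`.

## Clustering (`clustering`)

Because embedding vectors are aligned and of equal length, time-series
k-means reduces to Euclidean k-means: Lloyd's algorithm with k-means++
initialization, best of 10 restarts (scikit-learn). The number of
clusters is chosen by the elbow method implemented as the
max-distance-to-chord (kneedle-style) rule over k = 1..8 on the
min-max-normalized inertia curve; a curve with no elbow (all chord
distances < 1e-6) yields k = 1, and the rule is invariant under affine
rescaling of the inertia axis. Before clustering, a single-pass outlier
rule excludes embeddings whose distance to the cohort medoid exceeds
median + 3.5 × MAD (raw MAD, no consistency constant). Cluster-vs-score
concordance is reported as a label-by-cluster contingency table with
margins; t-SNE (standard implementation, seeded, perplexity
min(30, (n−1)/3)) min-max normalized to [0, 1]² is used for plots only.

## Agreement and validation statistics (`stats`)

Raw expert scores on −2..+2 collapse by sign to {−, 0, +}; the trial
label is the majority over the three raters, with three-way ties
flagged and excluded rather than imputed. Trials labeled '−' are
reported but excluded from clustering validation and classification by
default (they are rare in this test population); a flag re-includes
them. Observed agreement Po is the Fleiss pairwise statistic (mean over
subjects of agreeing rater pairs out of 3); chance correction uses
Randolph's free-marginal kappa, κ = (Po − 1/c)/(1 − 1/c) with c = 3,
appropriate because raters are not constrained to fixed category
frequencies.

Cluster differences in the eight C-BARQ categories (SDA, ODA, SDF, NSF,
SRB, ASB, EXC, PS; each on a 0–4 scale) are tested per category with a
two-sided Mann-Whitney U test: midranks for ties, min-side U, and a
tie-corrected normal approximation with continuity correction (at
n1 = n2 = 6 the corrected two-sided p stays within 0.016 of the exact
enumeration; uncorrected it can deviate by 0.07). For pooled samples of
≤ 12 the exact p (full enumeration) is also computed and used as the
oracle in tests. Raw p-values are reported per category — matching the
single-category reporting convention of this design — with a
Holm-adjusted column added as a clearly labeled extension.

## Supervised predictors (`models`)

A budgeted pipeline search stands in for an AutoML system: a seeded
evolutionary search (population 20, tournament size 3, single-gene
mutation) over scikit-learn pipelines
{optional scaler} → {optional SelectKBest} → {estimator}, with
estimators spanning linear models, SVMs, k-NN, random forests and
gradient boosting. Candidates are scored by mean stratified 5-fold CV
accuracy (classification) or negative MSE (regression); the evaluation
count is capped (hard cap 10,000; the bundled analyses use 200, which
this search saturates quickly on n = 46 cohorts). Duplicate genomes
count toward the budget but are not refit. Features are the flattened
movement embeddings by default. Classification metrics are accuracy and
macro-averaged precision/recall/F1 (micro would duplicate accuracy in
the 2-class design); regression metrics are MAE, MSE and R², with one
independent model per C-BARQ category. Whether to use CV estimates or a
held-out split was an open choice; CV was chosen for stability at
n = 46.

## Synthetic cohort generator (`synthgen`)

No public trajectory data exist for this assay, so the generator
produces cohorts with the statistical structure the analysis assumes:

* **Motion model.** A discrete-time Ornstein-Uhlenbeck-like walk,
  `x_{t+1} = x_t + a·(target − x_t)·Δt + a_fp·(fp − x_t)·Δt + σ·√Δt·ε`,
  with reflecting arena walls plus a soft inward drift within 0.3 m of
  a wall. `target` is the point at the style's preferred distance from
  the TP along the dog-TP line: towards-dogs hold ~0.5 m (a = 0.9,
  σ = 0.35), neutral dogs ~2.0 m with high exploration noise (a = 0.25,
  σ = 0.55), away-dogs ~3.1 m (a = 0.9, σ = 0.30). The familiar-person
  term `a_fp` (towards 0.02, neutral 0.15, away 0.35 s⁻¹) reflects that
  non-stranger-focused dogs orient toward their owner in the corner; it
  also breaks the radial symmetry around the TP — without it the
  towards/neutral position distributions are concentric with identical
  means, a structure Euclidean k-means cannot separate in principle.
  Dogs enter near the front gate. Trial durations are jittered ±2 s
  around 40 s so downstream truncation is exercised. The person path is
  constant at the TP chair (2.35, 2.35).
* **Detection corruption.** Each frame is independently missed per
  object with probability `miss_rate` (default 0.05) and detected
  centers get isotropic Gaussian noise (default sd 0.05 m); identity
  calibration by default, pixel cohorts via the calibration scale.
* **Expert ratings.** Generated directly on the collapsed 3-class
  scale: unanimous with probability 0.76 (the printed cohort breakdown,
  38/50), otherwise a 2:1 split with the dissenting rater in an
  adjacent category, so the majority label always equals the true
  style. The −2..+2 → sign collapse is exercised on real-format tables
  in `stats`.
* **C-BARQ coupling.** Each category is a clipped-to-[0,4] linear
  function of the style indicator and two activity covariates
  (near_frac: fraction of frames within 1.5 m of the TP; speed_norm:
  mean speed / 0.8 m s⁻¹, clipped to [0,1]) plus Gaussian noise.
  Stranger-directed fear carries the style signal (effect 0 neutral /
  0.42 towards / 1.2 away, noise sd 0.15, clip at 0 — so the
  asymptotic medians are exactly 0.00 and 0.42); Excitability tracks
  activity (0.3 + 1.4·near_frac + 1.0·speed_norm, noise sd 0.10,
  coefficients chosen so typical scores stay inside (0, 4) and the
  noiseless limit is exactly linear); the other six categories are
  weakly coupled background.
* **Defaults.** n = 46 trials with deterministic largest-remainder
  counts 28 neutral / 18 towards (away proportion 0 by default, as
  negative-scored dogs are excluded from the main analysis); all
  randomness flows from a single config seed, and identical configs
  produce byte-identical output files.

**What the generator does not emulate:** the TP's three scripted
actions as time-locked stimuli, multi-dog or occluded scenes,
systematic (non-independent) detection dropout, rater biases beyond the
2:1 adjacent-split structure, and real C-BARQ inter-category
correlation. Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind assumed*, at realistic arena geometry,
frame rates and noise levels — not that it would perform identically on
real videos.

## Problem sizes and numerical choices

* The elbow/cluster-recovery and separation Monte-Carlo suites run on
  reduced cohorts (n = 18, 15 s trials, single-point embedding grid,
  60 epochs) over 20 seeds; the elbow check runs 5 study-size cohorts
  (n = 46) with the single-point grid. The headline classifier and
  regressor checks use the full n = 46 cohort, budget 200.
* k-means ties break toward the lowest cluster index (scikit-learn
  convention); empty clusters are re-seeded internally by k-means++.
* Degenerate inputs: constant rating matrices give Po = 1; all-tied
  Mann-Whitney samples give z = 0, p = 1; constant regression targets
  give R² = NaN with a warning; an object never detected in a trial is
  an error rather than a silent fill.
* Reproducibility is a contract: seeded weight init, seeded shuffles,
  no nondeterministic kernels; per-stage seeds derive from one global
  seed via CRC-keyed SeedSequence spawning.

## Known limitations

* The autoencoder is single-layer (the fixed conv/dropout/pool
  sequence); it halves the temporal dimension only, so embeddings stay
  high-dimensional and the clustering signal rests on spatial rather
  than fine temporal structure.
* The evolutionary search explores a deliberately small component grid;
  it is a budget-matched stand-in for a full AutoML system, not a
  re-implementation of one.
* Free-marginal kappa assumes raters are unconstrained in category
  usage; if real raters quota-balance their scores, fixed-marginal
  Fleiss kappa would be the right statistic instead.
* With n = 46 and stratified 5-fold CV, metric estimates carry
  fold-assignment variance of several percentage points; seeds are
  fixed and reported rather than averaged away.
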