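# Methods

## Setting and notation

A rating matrix `V` has one row per user and one column per item; entries
r_{u,i} are real-valued judgments (emotion intensities, valence samples,
decision amounts) and missing entries are NaN. An optional declared scale
(r_min, r_max) states the legal rating range; an optional time axis
declares the items to be consecutive samples at a fixed interval (1 Hz in
the continuous-annotation setting). Validation works by masking: a fraction
of the *observed* cells is hidden uniformly at random (not stratified by
user), models train on the rest, and the hidden cells are the test set.
Because masking is uniform, a user can lose every rating at high masking
fractions; every predictor therefore has a defined fallback cascade (item
mean over observed training ratings, then global training mean) and the
record of which rule fired travels with each prediction.

## Predictors

**Mean baseline.** The item's mean over observed training ratings.

**User-based KNN.** User similarity is computed pairwise-complete: each
pair is correlated over the items both have rated, requiring at least
`min_overlap = 2` shared items; pairs below the overlap floor or with a
zero-variance overlap are *undefined* and are never treated as similarity
zero (that would silently change neighbor counts). For a target cell
(u, i), candidates are users with defined, strictly positive similarity to
u and an observed rating of i; the top-k by similarity (ties broken by
user order) contribute sim-weighted: r̂ = Σ r·s / Σ s. Fewer than k
candidates simply means fewer terms; the weight normalization is by the
similarities actually used. Pearson similarity on a 2-item overlap is
returned as exactly ±1 (the correlation is determined by two points), so
tie-breaking is reproducible across implementations. Predictions are not
clipped to the rating scale.

**NNMF with biases via SGD.** Predictions are r̂ = μ + b_u + b_i + q_iᵀp_u,
with μ the training mean, biases initialized at zero, and non-negative
factors W, H initialized as |N(0,1)| / f. Each pass shuffles the observed
cells (seeded) and, for each cell, computes one error e = r − r̂ and
updates

    b_i ← b_i + γ (e − λ_bi b_i)
    b_u ← b_u + γ (e − λ_bu b_u)
    q_i ← q_i + γ (e p_u − λ_qi q_i)
    p_u ← p_u + γ (e q_i − λ_pu p_u)

all from the same e and the pre-update parameter values, clipping each
factor coordinate at zero immediately after its update. The simultaneous
form matters: feeding the freshly updated q_i into the p_u step acts as an
inflated effective step size and empirically diverges at the default
learning rate on dense 0–100-scale matrices, while the simultaneous form
is stable. Defaults: γ = 0.001, all λ = 0, f = min(n_users, n_items);
training stops when the change in mean squared training error between
passes is ≤ 1e-6 or after 1000 passes. A non-finite training error aborts
with a learning-rate diagnostic. γ = 0 is accepted as a degenerate no-op
(parameters stay at initialization; predictions sit at μ up to the O(1/f)
initial factor products). Predictions are unbounded — no clipping.

*Identifiability note.* On purely additive data (no true user×item
interaction) the non-negative factor can degenerate into a second per-user
intercept, so the fitted b_u recovers the true user offsets only up to
that shared component (correlation ≈ 0.9 across replicate fits), while
b_u plus the factor's row mean recovers them almost exactly. Interpret
fitted bias vectors accordingly.

**NNMF via multiplicative updates.** The classic two-factor rule
H ← H·(WᵀV)/(WᵀWH), W ← W·(VHᵀ)/(WHHᵀ) needs a dense non-negative matrix,
so missing cells are zero-filled and negative data are shifted by the
declared scale minimum (restored at prediction). An exact factorization is
a fixed point (update ratios equal one; the 1e-12 denominator guard
perturbs a fixed point by less than 1e-10). Zero-filling is the variant's
documented weakness: on sparse data it reconstructs the zeros and its
held-out error is worse than the mean baseline, which is why it is kept
only as a comparator.

**MICE.** Chained-equations imputation: missing cells start at item means;
each of 10 rounds visits items in a fresh seeded random order and
regresses each item on all other items (current imputed state) over the
rows where the target was originally observed, re-imputing the originally
missing cells; after the final round imputations are clipped to the
observed training range. Per-column fits use ordinary least squares
(scikit-learn's `LinearRegression`). An item column with no observed
rating, or fewer than two observed rows, makes the run fail with an
explicit `ImputationError` rather than a silent guess — at extreme
sparsity these failures are the expected behavior and the harness records
them as failed runs.

## Dilation of time-series ratings

Continuous annotations are strongly autocorrelated, so an observed rating
is informative about neighboring seconds. Dilation convolves the training
ratings with a boxcar: each train-observed rating spreads to the
±⌊w/2⌋ surrounding samples, where w = round(width_s / interval), at least
1 and forced odd so windows are symmetric; windows truncate at the series
edges. A point covered by several windows takes the unweighted mean of the
contributing ratings (a boxcar weights contributions equally, so the
weighted average degenerates to the mean). Train-observed values are never
altered, and the operation sees only the training mask — applied after
masking, held-out cells cannot leak into training, which the test suite
checks by sentinel-poisoning all held-out cells and asserting bit-identical
behavior. Filled cells are "pseudo-observed": they are used for model
fitting but never scored, and consequently coverage is monotone
non-decreasing in kernel width and every filled value lies within that
user's observed training range.

## Evaluation

Errors are scored per user: for each (masking fraction, iteration), RMSE
over that user's held-out cells, divided by the declared scale range
(observed data range when no scale is declared) to give normalized error
in [0, 1] for scale-bounded predictors — interpretable as percentage
inaccuracy relative to the scale. Aggregation is user-first: mean over
iterations within user, then mean across users, with a seeded bootstrap
over users (1000 resamples) for 95% intervals. This weights each person
equally rather than each rating, which is the appropriate convention when
conclusions generalize across individuals; pooling all ratings flatters
models that do well on prolific raters. Every algorithm and every dilation
setting at a given (fraction, iteration) sees the identical training mask,
so comparisons are paired. Per-user prediction–truth Pearson correlations
are recorded alongside (undefined for users with fewer than two test cells
or constant vectors, and excluded from averages). Algorithm crashes and
imputation failures are recorded per run with their diagnostic, never
silently dropped. The long-form score table is shaped for downstream
mixed-model analysis, which is outside this package's scope.

## Synthetic archetypes

The generators emit dense matrices (masking induces sparsity afterwards)
that reproduce three agreement regimes, each calibrated so its measured
mean pairwise ISC falls in a ±0.10 band around the regime's target in at
least 9 of seeds 0–9:

- **Normed static stimuli** (52 users × 112 items, scale 0–100, target
  ISC 0.72): r = clip(s_i + b_u + a_u·g_i + ε). Item signal s_i ~ N(50, 17)
  dominates; individual deviation (total SD 10.6) splits into a stable
  4-dimensional low-rank "taste" profile (SD 8.2) plus trial noise
  (SD 6.7); user offsets are small (SD 4).
- **Affect time-series** (30 users × 600 s at 1 Hz, bipolar 0–100 scale,
  target ISC 0.20): a shared AR(1) latent (lag-1 coefficient 0.9,
  stationary SD 1) with per-user loadings N(1, 0.4), three further latent
  AR(1) time-courses (total SD 2) with signed loadings N(0, 1), a small
  unique AR(1) residual (SD 0.5), gain 10 to rating units, and large
  stable offsets (SD 18) reflecting how differently raters center a
  bipolar scale. 600 samples keeps the across-seed variance of the mean
  ISC inside the band (an AR(1) at 0.9 has an effective sample size an
  order of magnitude below its length).
- **Sub-group decisions** (60 users × 76 trials, scale 0–100, target ISC
  0.34): four groups with proportions 0.10/0.15/0.35/0.40; r = clip(c_i +
  g_{group(u),i} + b_u + ε) with common/group/noise SDs 4.7/13.4/4.7 and
  offsets SD 8. Within-group agreement exceeds between-group agreement by
  construction; the true labels are returned as a sidecar for stratified
  scoring and are never an input to any predictor.

A deliberate design decision runs through all three: most individual
deviation is *structured* (low-rank profiles, offsets, group membership)
rather than independent cell noise. Stable response tendencies are what
makes a person's unobserved ratings inferable from other people's, and
pairwise correlation cannot distinguish structured deviation from noise
(nor see offsets at all), so the ISC calibration pins the variance totals
while the structured/noise split controls learnability. Had the deviations
been modeled as pure noise, no method could beat the item mean — a
property of that generative choice, not of the algorithms. The split
fractions were calibrated once, by measuring held-out error of the factor
model against the mean baseline across generator seeds, to reproduce the
qualitative regime each archetype stands for: near-parity on
high-consensus data, a ≥5-point win (plus further gains from 5 s dilation)
on sparse time-series, and a win at every masking level on sub-group data.

What the generators do not emulate: real response distributions (values
are clipped Gaussians, not the pile-ups at scale endpoints and round
numbers that human VAS data show), rater drift and lapses, item-difficulty
heteroskedasticity, or any economic structure of the decision task.
Passing tests on these archetypes show the algorithms and harness behave
correctly in the intended agreement regimes, not that a particular error
level will be achieved on any real dataset.

## Numerical and design choices

- Missingness is NaN throughout; a declared scale is validated on
  construction and used only for normalized error, the multiplicative
  variant's shift, and MICE clipping.
- Every stochastic operation takes an explicit integer seed; the harness
  derives per-(fraction, iteration, algorithm) seeds from its base seed
  with `numpy` seed sequences, so runs are bit-reproducible and splits are
  shared across algorithms by construction.
- Duplicate (user, item) records in long-form input are averaged (the
  natural treatment for repeated-condition designs); long-form order of
  first appearance fixes row/column order.
- Masked-cell count is round(fraction × n_observed), exact to ±1 cell of
  the requested fraction.
- Temporal downsampling averages observed values within non-overlapping
  blocks (an all-missing block stays missing); a trailing partial block
  averages what it holds; upsampling repeats samples and rescales the
  interval.
- In the SGD update for b_u the penalty uses λ_bu (the user-bias penalty),
  keeping the update symmetric with the loss; regularization defaults to
  off, matching the reference protocol.
- Convergence "error" is the mean squared training error and "change" the
  absolute difference between consecutive passes; both are recorded in the
  fit history along with the converged flag.
- The SGD inner loop is JIT-compiled with numba; the first call in a fresh
  environment pays a one-time compilation cost of a few seconds.

## Known limitations

- KNN recomputes the full pairwise-complete similarity matrix per fit;
  for matrices beyond a few hundred users this is the dominant cost.
- The multiplicative NNMF variant is intentionally naive (zero-filling,
  no biases); do not use it for inference on sparse data.
- MICE failure reporting is column-granular and conservative: a single
  too-thin item column fails the whole run, mirroring how chained
  equations degrade at extreme sparsity.
- No hyperparameter search, ensembling, implicit-feedback or hybrid
  models; the factor count, learning rate and penalties are taken as
  given.
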