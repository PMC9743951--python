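# sparsecf

Collaborative filtering for sparse subjective ratings: inferring the
emotion ratings, continuous affect annotations, and social decisions a
participant did *not* report, from the ones they (and everyone else) did.

## The problem

Measuring feelings densely is expensive and reactive: asking a participant
to rate every image on every emotion dimension, or to annotate every second
of a video, changes the experience being measured. A cheaper design asks
each participant for a sparse sample of ratings and infers the rest. With a
users × items rating matrix `V` (users = participants; items = stimuli,
trials, or time points) that is mostly empty, the inference task is matrix
completion — the recommender-systems setting, transplanted to affective and
social data where "items" can be seconds of a film and "ratings" can be
trust-game decisions.

`sparsecf` implements the two standard collaborative-filtering families and
the harness to evaluate them under controlled sparsity:

- **Mean baseline** — predict the item's mean over observed ratings.
- **User-based KNN** — predict r̂ᵤᵢ = Σᵥ r_{v,i}·sim(u,v) / Σᵥ sim(u,v)
  over the top-k users with positive similarity to u (Pearson by default;
  Spearman, Kendall τ-b, cosine available) who rated item i, with
  item-mean and global-mean fallbacks when no neighbor exists.
- **NNMF via SGD** — r̂ᵤᵢ = μ + bᵤ + bᵢ + qᵢᵀpᵤ with non-negative factor
  matrices W (rows pᵤ) and H (columns qᵢ), trained by per-rating
  stochastic gradient descent on observed cells only, with optional L2
  penalties on each parameter group (defaults: γ = 0.001, λ = 0,
  f = min(n_users, n_items), at most 1000 shuffled passes).
- **NNMF via multiplicative updates** — the classic dense-matrix rule;
  it must zero-fill missing cells, which is exactly why it underperforms
  on sparse data. Kept as a documented comparator.
- **MICE** — multivariate imputation by chained equations with per-item
  linear regressions, the standard missing-data comparator; it reports an
  explicit failure when columns are too thin to regress.

For time-series ratings, a **boxcar dilation** step can spread each
observed rating across its temporal neighborhood before fitting (strictly
on the training side, after masking), exploiting the autocorrelation of
continuous affect annotation.

The **evaluation harness** masks a random fraction of observed cells,
trains every model on the remainder, and scores predictions on the masked
cells with normalized error, RMSE / (r_max − r_min) ∈ [0, 1] — first
averaged over cross-validation iterations within each user, then across
users. Pairwise intersubject correlation (ISC) summarizes how much users
agree, and three seeded synthetic generators reproduce the agreement
regimes where collaborative filtering matters: high-consensus static
stimuli (ISC ≈ 0.72), idiosyncratic 1 Hz valence time-series (ISC ≈ 0.20),
and decisions driven by latent user sub-groups (ISC ≈ 0.34).

## Worked example

```python
from sparsecf import (
    gen_subgroup_decisions, isc_summary, cross_validate, make_algorithm,
)

ratings, groups = gen_subgroup_decisions(seed=0)   # 60 users x 76 decisions
isc_mean, isc_sd = isc_summary(ratings)
print(f"ISC mean = {isc_mean:.2f}, SD = {isc_sd:.2f}")

table = cross_validate(
    ratings,
    {"mean": make_algorithm("mean"),
     "knn": make_algorithm("knn", k=10),
     "nnmf_sgd": make_algorithm("nnmf_sgd")},
    sparsity_levels=[0.5],     # mask half of the observed cells
    n_iterations=5,
    base_seed=0,
)
print(table.aggregate(seed=0).round(3).to_string(index=False))
```

```
ISC mean = 0.30, SD = 0.40
algorithm  dilation_width_s  sparsity_level  n_users  normalized_error  ci_low  ci_high
      knn               NaN             0.5       60             0.098   0.089    0.107
     mean               NaN             0.5       60             0.147   0.140    0.154
 nnmf_sgd               NaN             0.5       60             0.069   0.067    0.071
```

Users agree only moderately (ISC 0.30) because they belong to latent
decision sub-groups, so the item mean is a poor stand-in for any single
person: with half the ratings masked, mean imputation is off by 14.7% of
the rating scale per user on average. The factor model cuts that to 6.9%
(KNN to 9.8%) by learning each user's position relative to the others —
without ever being told the groups exist. The confidence intervals are
bootstrapped over users.

The same workflows are available from the shell:

```bash
sparsecf simulate --archetype timeseries --seed 0 --out ratings.csv
sparsecf evaluate --input ratings.csv --models mean,nnmf-sgd \
    --sparsity 0.1:0.9:0.2 --iterations 5 --dilate-width-s 0,5 \
    --scale 0,100 --seed 7 --out results.csv
sparsecf fit --input ratings.csv --model knn --k 10 --out predictions.csv
```

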