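# Methods

## The circle model and its estimator

An ego's grooming output is treated as a finite resource divided over its
`L` partners. In the discrete maximum-entropy formulation, ties fall into
`r` cost categories `s_1 > … > s_r` with probabilities
`p_k ∝ exp(−μ̂ s_k)`; the expected cumulative fraction of ties in circles
1..k is `χ_k = (e^{kμ} − 1)/(e^{rμ} − 1)` with
`μ = μ̂ (s_max − s_min)/(r − 1)`, and consecutive circle sizes scale
asymptotically as `e^μ`. The continuum limit replaces the layer index by a
normalized distance `t ∈ [0, 1]` and a single parameter `η`, with
cumulative tie fraction `χ(t) = (e^{ηt} − 1)/(e^η − 1)` and density
`f(t; η) = η e^{ηt}/(e^η − 1)`. The two formalisms are linked by
`η ≈ (r − 1)(e^μ − 1)`; `η = 0` is the uniform (unstructured) boundary and
`η < 0` the inverted regime in which most ties are maximally strong.

The density above is an exponential family with sufficient statistic `t`,
so the maximum-likelihood estimate of `η` solves the moment condition

```
t̄ = g(η) ≡ e^η/(e^η − 1) − 1/η ,
```

with `t̄` the mean normalized distance. `g` is strictly increasing, odd
about `(0, 1/2)`, and has a removable singularity at `η = 0`. We solve by
Brent bisection on `[0, 2/(1 − t̄) + 2]` after reflecting to `t̄ > 1/2`
(which makes the antisymmetry `η(1 − t̄) = −η(t̄)` hold exactly), with
tolerance `1e−8`; within `1e−6` of `t̄ = 1/2` the linearization
`η ≈ 12(t̄ − 1/2)` is used. All exponentials are evaluated via `expm1`
forms that are overflow-safe to `|η| ≈ 700` and beyond for `χ` (rescaled by
`e^{−η}`); `|η| < 1e−4` switches to series expansions
(`g ≈ 1/2 + η/12 − η³/720`, `χ ≈ t + ηt(t−1)/2`, `χ_k ≈ k/r + μk(k−r)/2r`).

Confidence intervals invert the likelihood ratio: the endpoints of the
`1 − 2δ` interval satisfy `2(ℓ(η̂) − ℓ(η)) = χ²₁(1 − 2δ)`, found by
bracket expansion (never beyond `η̂ ± 100`) and Brent root-finding. The
default `δ = 0.025` gives nominal 95% intervals; simulated coverage at
`L = 200`, `η = 3` over 1000 replicates is 94–96%, and the interval width
agrees with the Fisher-information prediction
`I(η) = 1/η² − e^η/(e^η − 1)²` to a few percent at large `L`.

## Normalization convention

`s_max` and `s_min` are taken per ego from the observed tie weights, so
every fitted ego has one tie at `t = 0` and one at `t = 1`; dataset-wide
bounds are a documented alternative but not the default. This convention
has an estimation consequence worth knowing: if tie weights are imagined
as i.i.d. draws from the continuous model with *external* bounds, the
observed extremes sit well inside `[0, 1]` at small `L` and re-normalizing
by them attenuates `η̂` noticeably (tens of percent at `L ≈ 50`, `η ≈ 6`).
We therefore read the convention as part of the model: the strongest and
weakest tie *define* the ego's cost scale, and the remaining `L − 2` ties
are distributed by `χ(t)` between them. The synthetic generator plants
exactly this structure (one tie at each bound, `L − 2` interior draws),
which makes generation and estimation mutually consistent; residual
finite-`L` bias of order `(1 − 2g(η))/(L·g'(η))` remains and shrinks like
`1/L` (full-pipeline recovery regression at `L ∈ [50, 200]`: slope 0.97,
intercept 0.04). At the small ego-network sizes typical of real groups
(`L` of 5–20), per-ego fits carry substantial shrinkage toward the middle
of the regime — visible in the cohort examples — which is a property of
any per-ego normalization at these sizes, not of the solver.

Egos whose weights are all equal carry no distributional information
(`s_max = s_min`); they are excluded with an audit entry rather than
assigned a value. Zero-weight partners are not ties.

## Inclusion filters

Whole groups with fewer than 6 individuals are dropped; within retained
groups, egos with fewer than 5 distinct groomed partners (or degenerate
weights) are excluded. Group size is demographic: individuals present in
the metadata but never observed interacting count toward it. An ego's
distribution is its *outgoing* grooming; mutual grooming enters as two
directed records. Every exclusion is recorded with a reason, and the audit
reconciles exactly with the retained set.

## Modularity

Directed grooming graphs are symmetrized by summing the two directions
(weight conservation is asserted in tests). Weighted Newman modularity
`Q = Σ_c (e_cc − a_c²)` is implemented directly and cross-checked against
networkx's implementation. Community detection runs three seeded
heuristics — greedy agglomerative modularity, Louvain multilevel and
leading eigenvector — and keeps the max-Q partition; on graphs of ≤ 8
nodes the result never exceeds the exhaustive-enumeration optimum. The
igraph leading-eigenvector routine draws from a process-global generator,
which we pin to the supplied seed for run-to-run determinism.

## Synthetic cohorts

The generator emulates the study system: 24 groups by default (15 bonobo /
9 chimpanzee in expectation), 6–20 individuals each, ~36% male, ages 5–55,
zoo or sanctuary habitat, integer interaction counts on a 1–50 weight
scale. Each ego's planted `η` is a linear predictor over its covariates
(indicators chimpanzee/male/zoo = 1, age standardized by cohort mean/SD
recorded in the truth table, interactions as products) plus Gaussian noise
(SD 0.5). Default coefficients encode the qualitative pattern expected of
real apes — ego-network size dominant and positive (+0.25 per partner),
species +1.0 for chimpanzees, group size +0.05, habitat +0.3, sex −0.3
for males, species×age −0.5 per SD (chimpanzee `η` declining with age) —
chosen so planted `η` spans roughly 0–8 with a small inverted tail.
Partner counts are uniform on `[5, group_size − 1]` (configurable), so a
generated cohort passes the filters by construction.

An optional two-block structure assigns each group's members alternately
to two blocks, draws partners with a configurable within-block preference
and gives the smallest distances (strongest ties) to own-block partners.
Group modularity then rises with planted `η` through the model's own
weight concentration; with per-group means 0.5 / 3 / 6 the Spearman
correlation between mean `η̂` and Q is positive in every one of 20 seeded
replicates.

What the generator does **not** emulate: the observation process (scan
intervals, visibility bias), kinship or rank structure, temporal dynamics,
and any dependence between an ego's ties beyond the planted blocks.
Passing recovery tests therefore demonstrates correctness of the estimator
and pipeline under the model's own data-generating process, not robustness
to real-world observational noise.

## Attribution

An XGBoost regressor (squared-error loss, depth 3, 300 rounds, learning
rate 0.1, exact tree method, single thread, fixed seed) predicts `η` from
the eight predictors. The model is explanatory: it is fit on all rows —
there is no held-out split because the object of interest is the fitted
surface, not generalization error. Global importance is total gain
normalized to sum 1. Per-ego attributions use the booster's built-in exact
TreeSHAP; partial-dependence curves condition at a single point (numeric
features at their median, categorical at their mode) over a quantile grid
for numeric features and observed levels for categorical ones, rather than
averaging over the data distribution.

Shapley local accuracy (base value + attributions = prediction) is exact
in the tree arithmetic; because the booster stores and accumulates in
single precision, the identity is verified at single-precision resolution
(observed residuals ≲ 2×10⁻⁵ at prediction magnitudes ~10 with 300
rounds).

## Problem sizes

Simulation-based checks use: 1000 replicates at `L = 200` for CI coverage;
200 replicates at `L = 500` per planted `η` for recovery bias; 200 random
egos for the solver-vs-likelihood oracle; cohorts of ~400 egos for the
pipeline recovery regression; 20 seeded replicates each for the
η–modularity association and the attribution recovery. These sizes give
Monte-Carlo error comfortably below the tolerances they are checked
against while keeping the full suite under ten seconds.

## Known limitations

- Per-ego normalization shrinks `η̂` at small `L` (see above); comparative
  conclusions across egos with very different `L` should account for this.
- The likelihood treats ties as independent draws; reciprocity and triadic
  structure in real grooming violate this.
- The discrete model is provided for the layer-count connection
  (`η ≈ (r−1)(e^μ−1)`) and is not itself fitted to data.
- Community detection is heuristic; on large graphs the portfolio's best Q
  may be below the true optimum.
- Boosted-tree importance and Shapley orderings are stable for dominant
  effects but can reorder weak, correlated covariates across seeds.
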