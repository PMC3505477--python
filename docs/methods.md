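# Methods

## The model

`plps` fits sparse logistic-regression models over *patterns* of binary
predictors. A pattern is the product of up to three 0/1 variables (or the
constant 1); it equals 1 for a subject exactly when all of its variables
do. With basis functions `B_l` and log odds

    f(x) = mu + sum_l c_l B_l(x),

the penalized estimate minimizes

    I(y, f) = L(y, f) + sum_l w_l |c_l|,
    L(y, f) = (1/n) sum_i [ -y_i f(x_i) + log(1 + exp(f(x_i))) ],

where the per-column weights `w_l` encode either a single penalty `lambda`
on every non-constant column or, in the aggregation stage, `lambda1` on
main-effect columns and `lambda2` on interaction columns. The intercept is
never penalized.

A single LPS pass is: (i) solve the l1 path and keep the active set of the
BGACV-selected fit; (ii) refit the survivors by unpenalized maximum
likelihood; (iii) backward-eliminate terms under BGACV.

## Partitioned screening

The full pattern basis has `sum_{v<=q} C(p, v)` columns, quadratic or cubic
in `p`. The two-stage architecture divides the `p` variables into `k`
contiguous partitions of `g` variables (the last possibly smaller) and, for
q=2, solves one reduced LPS subproblem per pair of partitions (mains of
both plus all cross products; `g^2 + 2g + 1` patterns) and one per single
partition (mains plus within-partition pairs; `1 + g(g+1)/2` patterns).
Every pair of variables is a candidate in exactly one subproblem and every
main effect in `k` of them. For q=3 there is one subproblem per size-3
multiset of partition labels; size-3 products live in the subproblem whose
label multiset matches theirs, mains and within-partition pairs are
attached to the diagonal (s,s,s) subproblem, and a cross-partition pair
{a,b}, a<b, to the (a,a,b) subproblem, preserving exactly-once coverage of
pairs and triples (verified by `patterns.verify_coverage`).

Subproblems are pure functions of (data, spec); they can run serially or on
any pool and the results are merged as an order-independent set union. The
variables appearing in any surviving pattern form `p*`; the aggregation
stage then runs a two-penalty LPS over `p*`'s mains and all its
interactions up to order q, selected by BGACV2 (q=2) or BGACV3 (q=3),
followed by the parametric refit and backward elimination.

Defaults: `g = 200` for q=2 and `g = 35` for q=3 (sized for a commodity
machine; results are insensitive to `g`), 50-point geometric penalty path
spanning 3 decades below `lambda_max`, and a 12x12 geometric
(lambda1, lambda2) grid spanning 3 decades below each block's own
`lambda_max`.

## Solver

Cyclic coordinate-wise proximal Newton descent with an active-set outer
loop: a full-gradient KKT screen adds violating columns, and sweeps run
over the active set only, exploiting that binary columns make a column's
gradient a sum of residuals over its supporting rows. Stationarity is
verified to 1e-6 (absolute, gradient scale) on and off the active set;
sweeps are capped at 10^4 per solve. Warm starts carry coefficients down
the path and along each `lambda2` row of the aggregation grid.

Two guards keep the path well-behaved where no criterion can select:

* fits whose linear predictor exceeds +-30 are flagged as (near-)separated
  and returned capped; flagged fits are skipped by the selectors, since
  degrees-of-freedom-based criteria are meaningless at a separating
  solution. Unpenalized refits cap at the same +-30 and flag
  quasi-separation.
* the path (and each aggregation-grid row) stops once
  `stringency * s/n` exceeds the best criterion value seen so far — every
  score is bounded below by that quantity because the likelihood term is
  non-negative — and hard-stops at `s >= n`. This prunes the saturated
  small-penalty tail, which is also where solves are most expensive.

## Tuning criteria

GACV and BGACV are implemented with an active-set complexity surrogate:
`s`, the number of nonzero coefficients including the intercept, estimates
the degrees of freedom of the l1 fit, and

    GACV  = OBS + s/n,          BGACV = OBS + (log(n)/2) (s/n),

i.e. AIC- and BIC-type charges on the per-observation likelihood scale.
Leave-one-out optimism estimates proportional to `sum_i y_i (y_i - p_i)`
were evaluated and rejected: that sum collapses to zero as a path fit
saturates, making the score decrease monotonically along the entire path
and always prefer near-saturated fits, which contradicts the intended
(stringent, BIC-like) behavior of BGACV.

The path-selection BGACV is deliberately permissive — shrinkage already
penalizes the penalized fits, and the screen is meant to pass candidates
on. The *unpenalized* refit and backward elimination instead charge each
term an extended-BIC cost

    (log n)/2 + 0.5 log(m_v),

where `m_v` is the number of candidate patterns of the term's order in the
pool it was screened from (the intercept costs `(log n)/2` alone). The
per-order pool matters: an interaction kept as the best of tens of
thousands of candidate pairs has its apparent deviance inflated by about
`log m`, far more than a main effect picked among a few hundred variables.
Charging both equally lets a spurious "true variable x noise partner" pair
displace the genuine main effect; with per-order pools the criterion
prefers the main, while a true interaction still beats its two split
mains. This is the standard extended-BIC model-class prior applied per
pattern order.

The aggregation stage multiplies BGACV by the balance factor

    BGACV2 = BGACV * (1 + 0.5 |nb1 - nb2| / (nb1 + nb2)),
    BGACV3 = BGACV * (1 + 0.5 (|nb1-na| + |nb2-na| + |nb3-na|) / (nb1+nb2+nb3)),

with `nb_v` the number of selected terms of order v and `na` their mean;
the factor is 1 when the counts are balanced or all zero. Because the
factor multiplies the whole score, a true model with intrinsically
unbalanced counts (e.g. one main and two pairs) sits within a hair of the
intercept-only score, and an occasional empty aggregation model is an
intrinsic failure mode of the balanced criteria — visible in the original
selection frequencies (94-99 per 100, not 100) and reproduced here.

Penalty-selection ties break toward the larger penalty (single path) or
larger `lambda1 + lambda2` then larger `lambda2` (grid), i.e. toward
sparser models.

## Backward elimination

Two deterministic greedy descents run from the refit model, each deleting
one term per step and refitting the MLE, stopping when no single deletion
lowers the criterion:

* best-first: delete the single term whose removal gives the lowest score
  (ties prefer the higher-order term, then the lexicographically later
  pattern);
* interactions-first: in that same preference order, take the first
  deletion that improves.

The criterion picks the better end point. The two orders cover
complementary traps: best-first correctly strips null mains sitting beside
a true interaction but deletes a true main whose signal has been absorbed
by spurious pairs; interactions-first does the reverse. Single-path greedy
cannot reach the better optimum in both cases.

## Synthetic data

Independent blocks draw iid Bernoulli(0.5). Correlated blocks draw a
latent Gaussian vector with banded Toeplitz correlation (`rho1` at lag 1,
`rho2` at lag 2, independence beyond) and threshold at zero, so marginals
are exactly Bernoulli(0.5) and the binary lag-1 correlation is
`(2/pi) arcsin(rho1)` (about 0.465 for rho1 = 2/3). Both stated band
profiles — (2/3, 1/3) and (-1/3, -1/6) — are singular on the
positive-semidefinite boundary, so a 1e-8 ridge is added before the banded
Cholesky factorization; the distributional effect is negligible. The
response is Bernoulli with the scenario's logit. Replicate `r` uses seed
`base + r` for covariates and `base + 10^6 + r` for the response, keeping
the two streams independent.

The four built-in scenarios reproduce the simulation designs exactly
(sample sizes, covariate laws, intercepts and signed pattern weights). One
caveat: the fourth design's printed logit contains six main effects while
the surrounding text speaks of seven; the printed logit is implemented.
The generator emulates dichotomized gene-expression-barcode data only in
its binary, sparse-signal structure; it has no probe effects, batch
structure, linkage beyond lag 2, or realistic prevalence spectra, so
passing tests demonstrate correctness of the machinery and reproduction of
the simulation studies, not performance on real expression data.

## Problem sizes used in the checks

The packaged checks run the first and fourth simulation designs at
reduced replication (8-20 replicates rather than 100) and compare
selection frequencies by exact binomial (Poisson for false-pattern totals)
consistency tests at the published rates. The second and third designs
are cluster-scale at full size (p = 8000; third-order screening); the
suite instead checks planted-pattern recovery on analogues with the same
correlation law at p = 200 (n = 1000 for the second-order analogue, n =
600 for the third-order one), and the full-size configurations remain
available through the same API (`make_scenario(2)`, `make_scenario(3)`).
Five-fold cross-validation is validated on synthetic data: null AUC near
0.5, planted-signal AUC above 0.8.

## Numerical choices and edge cases

* Degenerate response (all 0 or all 1): the solver returns an
  intercept-only fit at the +-30 cap, flagged.
* All-zero pattern columns stay at coefficient zero (their gradient and
  curvature vanish).
* Collinear refits fall back to least-squares Newton steps and flag a
  singular Hessian; duplicate patterns are rejected.
* Criterion comparisons treat scores within 1e-12 as ties.
* Pattern materialization refuses lists above 5x10^6 entries per
  subproblem; partition sizes are the user's memory/time dial.

## Known limitations

* The exact GACV/BGACV of the original method is unpublished; the
  BIC/extended-BIC surrogates here are calibrated to its documented
  qualitative behavior, not to its formula.
* No strong-heredity constraints: patterns are free-standing bases.
* No q > 3 and no continuous predictors; dichotomization is upstream.
* Greedy elimination (even dual-path) is not best-subset selection.
* The permutation-robustness of partitioning is verified at desk scale on
  the fourth design only.
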