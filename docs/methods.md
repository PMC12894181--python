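# Methods

## Setting and estimand

Each unit carries an outcome `Y` (binary in the main profile), a
received treatment `D ∈ {0,1}`, a randomised encouragement `Z ∈ {0,1}`
used as an instrument, and indicator covariates `X`.  Under instrument
relevance, the exclusion restriction and monotonicity (no defiers), the
population splits into compliers (`D = Z`), always-takers (`D ≡ 1`) and
never-takers (`D ≡ 0`), and the conditional local average treatment
effect for compliers is the conditional Wald ratio

    tau(x) = Cov[Y, Z | X = x] / Cov[D, Z | X = x].

The structural view is `Y = m(X) + tau(X) D + eps` with `E[eps | X, Z] =
0`; `m` is an unspecified nuisance surface.  The package estimates
`tau(x)` (CLATE), its population aggregate (LATE), and summaries of how
`tau(x)` varies.

## Principal-strata accounting

From the 2x2 table of `D` by `Z`: `P(always) = P(D=1|Z=0)`,
`P(never) = P(D=0|Z=1)`, `P(complier)` their complement, equal to the
first-stage difference.  Two reporting conventions are implemented.
`raw` keeps unrounded proportions, with the complier share exactly the
first stage.  `one_decimal_percent` rounds the always/never shares to
one decimal in percent units and takes the complier share as the
complement to 100; this is the convention under which the three shares
are mutually consistent at one printed decimal, and is the reporting
default.  A negative raw complier share flags a monotonicity violation
(warning, never silently clipped).

Balance diagnostics use standardised mean differences with the pooled
standard deviation `sqrt((s0^2 + s1^2)/2)` (the usual two-group
convention; a control-group-SD variant was considered and rejected for
symmetry).  Continuous covariates are discretised into terciles at the
inclusive (linear-interpolation) empirical 1/3 and 2/3 quantiles, ties
to the lower tercile, yielding three indicators per family that
partition the sample.  The package labels `q1` as the *lowest* tercile.

## Honest forests

All forests share one chassis.  Each tree draws a subsample **without
replacement** (`sample_fraction`, default 0.5) and, under honesty
(default on), splits it into a structure half that places splits and an
estimation half that supplies every leaf statistic; no unit influences
both.  Splits maximise

    (sum_L rho)^2 / n_L + (sum_R rho)^2 / n_R

over `mtry` randomly drawn candidate covariates, where the node score
`rho` is the regression target for nuisance forests and the IV
pseudo-outcome (below) for the instrumental forest.  Constraints: each
child holds at least `min_node_size` structure units and at least an
`alpha` share of its parent.  Without-replacement subsampling is
required for the honesty/out-of-bag contract (a bootstrap would place
duplicated units on both sides of the honesty split).

Defaults where the protocol is silent: `mtry = min(p, ceil(sqrt(p)) +
20)`, `sample_fraction = 0.5`, `honesty_fraction = 0.5`, `alpha = 0.05`,
`min_node_size = 5`, ensemble size 2000 — community-standard values for
honest forests; all tunable, and the ensemble size is routinely reduced
in experimentation profiles.  Binary/indicator covariates split at 0.5;
numeric covariates at midpoints between observed values.  Equal-criterion
ties break to the lowest covariate index, then the lowest threshold, so
fits are bit-reproducible given the seed.  A single seed drives all
subsampling and candidate draws; forests serialise to JSON and reload
with bit-identical predictions.

Out-of-bag (OOB) prediction averages leaf estimates over trees whose
subsample excluded the unit.  At `sample_fraction = 1` no OOB trees
exist: OOB prediction raises, and in-sample prediction (all trees) is
the documented alternative — it is also what makes the single-leaf
Wald-equivalence oracle exact, since only a full-sample, non-honest,
single-leaf tree gives every unit identical weight.

A forest induces similarity weights
`alpha_i(x) = avg_b 1{i in leaf_b(x)} / |leaf_b(x)|` over estimation
halves; they are non-negative and sum to one.

## The instrumental forest

Nuisances `m(x) = E[Y|X]`, `e(x) = P(D=1|X)`, `g(x) = P(Z=1|X)` are
fitted by three regression forests with OOB prediction; propensities are
clipped to [0.01, 0.99] with clip counts logged.  The treatment
propensity excludes supply-side-tagged covariates by default, because
supply-side readiness entered programme eligibility; the exclusion is
structural (the forest never sees those columns) and assertable from the
stored model.

Trees grow on residuals `Yr = Y − m̂`, `Dr = D − ê`, `Zr = Z − ĝ`.  At a
parent with local Wald estimate `tau_P` and `A_P = mean(Zr · Dr)`, the
per-unit pseudo-outcome is

    rho_i = Zr_i (Yr_i − tau_P Dr_i) / A_P,

the influence-function surrogate for the local effect: splitting on
`rho` targets within-leaf heterogeneity of the IV estimate.  This
gradient-style surrogate replaces exhaustively re-solving local 2SLS at
every candidate split; it is the standard computational shortcut for
this estimator family and is exact to first order.  Degenerate nodes
(`|A_P|` or the first-stage covariance below 1e-10) stop splitting; a
degenerate root on the full sample raises a weak-instrument error.

Leaf estimates are honest local Wald ratios on the estimation half;
degenerate leaves inherit the nearest non-degenerate ancestor (flagged).
Prediction solves the alpha-weighted moment condition — equivalently the
weighted covariance ratio of (Yr, Zr) to (Dr, Zr) under the forest
weights — with OOB weights for training units; a degenerate weighted
first stage falls back to the global Wald estimate, flagged per unit.

Hyperparameter tuning is a grid search minimising the OOB squared
moment violation `mean[((Yr − tau_oob(X) Dr) Zr)^2]`, an R-loss-style
proxy; ties break toward smaller `mtry`, then larger `min_node_size`.
The proxy's curvature in `tau` is mild, so grids should differ
structurally (e.g. feature pools, leaf sizes) rather than marginally.

## Doubly robust scores and the LATE

With the compliance score `delta(x) = E[D|X,Z=1] − E[D|X,Z=0]` estimated
by the self-instrumented auxiliary causal forest (outcome `D`, treatment
and instrument both `Z`), the per-unit AIPW score is

    Gamma_i = tau(X_i)
            + [(Z_i − g)/(g(1−g))]/delta(X_i) · ((Y_i − m_i) − (D_i − e_i) tau(X_i)).

The correction residual reads `(Y − m̂) − (D − ê)·taû`: each factor is
conditionally mean-zero under either a correct outcome model or correct
propensity/instrument models, which is what makes the score doubly
robust (any other bracketing would break the mean-zero structure).
`deltâ` is floored at 0.01 with per-unit flags — near-zero conditional
compliance otherwise produces unbounded scores; an everywhere-floored
score vector (no compliers) is an error.  The LATE is `mean(Gamma)` with
the i.i.d. standard error `SD(Gamma)/sqrt(N)`; no cluster adjustment is
applied (units are treated as independent given X).  The reported LATE
equals the mean of the emitted scores by construction, to machine
precision.

The 2SLS baseline is the just-identified linear IV estimator with
optional linear covariate adjustment; with no covariates it equals the
unconditional Wald ratio exactly.  Standard errors use the IV sandwich,
homoskedastic by default, heteroskedasticity-robust by flag.

## Heterogeneity summaries

**BLP.** OLS of `Gamma` on the indicator covariates, one reference level
dropped per tercile family, heteroskedasticity-robust (HC1) standard
errors by default (the scores are heteroskedastic by construction;
classical SEs by flag).  Coefficients are partial linear associations
with the effect surface, never causal effects of the covariates.

**CLAN.** Units are ranked (stable sort) and cut into four near-equal
groups; for each modifier, the most- vs least-affected group means are
compared with a two-sample SE, one modifier at a time.  The default
ranking key is `Gamma` itself.  A practical caveat discovered in
validation: the AIPW correction term dominates the variance of `Gamma`
(on the planted-modifier benchmark its SD is about five times the effect
spread), so `Gamma`-quartiles largely rank noise and the comparison has
little power.  Ranking by the estimated CLATE `taû(X_i)` — available via
the `rank_by` argument and used in the recovery tests — orders units by
the effect proxy and restores power.  Both keys are legitimate readings
of "ranking observations from low to high estimated treatment effects";
outputs record which was used.

**Variable importance.** Depth-weighted split frequency: the share of
depth-`d` splits using covariate `k`, weighted by `d^(−decay)` over
`d ≤ max_depth` (defaults 4 and 2, root depth 1), normalised to sum to
one.  A variance-weighted variant (each split weighted by the
between-child spread of the leaf effect estimates) is provided because
both conventions circulate; frequency is the default and outputs label
the mode.  Only the ranking is meaningful.

## Policy trees

Policies are depth-≤3 binary trees on indicator covariates (thresholds
fixed at 0.5, which makes exhaustive search exact), maximising
`Â(π) = (1/N) Σ (2π(X_i) − 1) Γ_i`.  The search solves each node
exactly: stop with the best constant action, or split on any covariate
and solve both children to the remaining depth; depth-1 subproblems are
vectorised over covariates.  Ties break lexicographically (stop before
split, lowest covariate index, not-treat before treat on a zero score
sum), so the learned tree is deterministic.  Values are evaluated
in-sample on the training scores (an evaluation split is a caller-side
choice); the learned value is never below the better constant policy,
and is non-decreasing in depth because deeper classes nest shallower
ones.

## The synthetic-trial generator

The generator emulates the statistical structure the estimators assume:
a ~50/50 randomised encouragement (optionally cluster-constant),
principal strata drawn independently of X with configurable shares, and
binary outcomes from a clipped linear-probability model

    P(Y(d)=1 | x) = clip(m(x) + tau(x) d, 0.01, 0.99),

so the true effect is expressed directly in risk-difference units (a
latent-index link would put the truth on a different scale than the
estimates).  Monotonicity and exclusion hold by construction: `D = 1`
iff always-taker or (complier and `Z = 1`); potential outcomes are drawn
without reference to `Z`, coupled through a shared uniform per unit.
One integer seed drives four independent sub-streams (covariates,
strata, assignment, outcome noise), so the assignment can be resampled
with everything else bit-identical.  `noise_sd` applies only to the
optional continuous-outcome mode; for binary outcomes the Bernoulli draw
is the noise.

Preset study conditions: `pkh2009` / `pkh2013` use strata shares
(complier, always, never) = (0.398, 0.096, 0.506) and (0.344, 0.137,
0.519), a covariate battery of household/maternal indicators plus
supply-side tercile families (tagged), baseline outcome rates inside the
0.3–0.85 band, and effect heterogeneity driven by supply availability
and household amenities.  `homogeneous` fixes `tau ≡ 0.2` under the 2009
strata.  `planted_binary` switches `tau` between 0 and 0.4 on a single
binary covariate with a 0.5 complier share — a strong, identifiable
first stage for recovery studies.

What the generator does **not** emulate: multi-stage survey sampling and
attrition, within-cluster outcome correlation (units are i.i.d. given X;
no published value was available for the intra-cluster correlation),
covariate dependence of strata membership (off by default; a logistic
tilt hook exists), and measurement error.  Passing recovery tests
therefore demonstrate estimator correctness under the maintained
identification assumptions, not robustness to their failure.

## Validation design and problem sizes

Oracle checks pin the arithmetic: the single-leaf instrumental forest
must equal the global residualised Wald ratio to 1e-8; the learned
depth-2 policy value must equal brute-force enumeration; the DR-score
pipeline must reproduce hand-computed fixtures to 1e-12; 2SLS is
cross-checked against an independent library implementation.
Statistical checks use the generator's ground truth: LATE recovery
within 2 SE at n = 4000 with 200-tree forests; 95% CI coverage ≥ 90%
over 200 replications with 50-tree forests; planted-modifier recovery
(CLATE contrast, BLP, CLAN, importance ranking) at n = 4000 over 50
replications.  These sizes give stable pass/fail behaviour at modest
cost; the ensemble-size reduction for replication studies trades only
Monte-Carlo smoothness, which the CI-based criteria absorb.  Dispersion
of the CLATEs under a homogeneous truth is checked to contract as n
doubles using leaf sizes proportional to n (the consistency regime for
honest forests).

## Known limitations

No confidence intervals for individual `taû(x)` (inference aggregates
through the scores); no continuous-treatment dose-response; no
cluster-robust variance; no missing-data handling beyond complete-case
filtering; exhaustive policy search is limited to indicator covariates
and depth 3.  Variable-importance rankings can be distorted when a
confounder also drives heterogeneity; they are reported for qualitative
comparison only.
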