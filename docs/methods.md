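# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator used for validation, and the known limitations of
each.

## Model

For an ordered wave pair (t, t+1) and p dichotomous symptoms, the
cross-lagged panel network is estimated by p separate node-wise logistic
regressions: symptom j at wave t+1 on all p symptoms at wave t,

    logit P(x_j^(t+1) = 1 | x^(t)) = c_j + Σ_i B[i, j] x_i^(t),

with an L1 penalty on the slopes (never on the intercept):

    min  (1/n) Σ_i [log(1 + e^{η_i}) − y_i η_i]  +  λ_j Σ_i f_i |B[i, j]|.

`B[j, j]` is the autoregressive path; the off-diagonal entries are
cross-lagged paths. Edges are reported both as log-odds and as odds ratios
(`exp(B)`), where OR = 1 is "no edge". The model conditions only on the
previous wave; it cannot separate within-person from between-person
variance, and estimates describe prediction, not intervention effects.

## Estimation

**Solver.** Penalized fits use an iteratively reweighted least squares /
cyclic coordinate descent scheme with covariance updates (the weighted
p × p Gram matrix is formed once per reweighting, so coordinate sweeps cost
O(p²)), soft-thresholding for the L1 term, warm starts along a decreasing
penalty path, and IRLS weights floored at 1e-5. Convergence is declared
when the largest parameter change in a full reweighting falls below `tol`
(default 1e-7); non-convergence and diverging parameters (separation)
raise. For λ ≥ λ_max = max_j |x_j·(y − ȳ)|/n with unit penalty factors the
exact solution is returned in closed form (zero slopes, intercept =
logit(ȳ)), since it satisfies the KKT conditions there. The suite verifies
the solver against two independent routes: a hand-written Newton–IRLS fit
at λ = 0 and scikit-learn's saga L1 solver at λ > 0 (both to 1e-4 or
better).

**Penalty selection.** Per outcome, 10-fold stratified cross-validation
over a 100-point log-spaced path from λ_max down to λ_max/1000, scoring
mean out-of-fold binomial deviance. The default rule is the
one-standard-error rule (largest λ within one SE of the deviance minimum);
`cv_min` (the minimum itself, ties resolved toward the sparser model) and
`fixed` are available. The 1-SE default is deliberate: with deviance-minimum
selection a network fitted to structureless data retains roughly 6–7
spurious cross-lagged edges out of 56 (we reproduced the same behavior with
an independent reference implementation), whereas the 1-SE rule brings the
null network down to ≈0–2 spurious edges while still recovering the
fixture edges of |b| ≥ 0.4 at n = 7000. The trade-off is not free: under
unlucky draws the 1-SE rule can still zero the weakest fixture edges
(|b| ≈ 0.45–0.5, especially those touching the ~90%-endorsement items,
whose indicators carry the least variance); `cv_min` recovers these more
reliably at the cost of its null specificity. CV path fits run at a relaxed
tolerance (1e-5) — only the deviance ranking matters — while final fits use
the strict tolerance.

**Standardization.** Predictors are standardized internally for the
penalty only and coefficients are returned on the original 0/1 scale
(odds-ratio interpretation unchanged), matching glmnet's default. Without
this, items endorsed very rarely or near-universally (such as reverse-keyed
wellbeing items at ~90% endorsement) carry lower variance and receive a
harsher effective penalty; in recovery experiments a true |b| = 0.5 edge
out of such an item was systematically dropped. The flag can be turned off.

**Other estimation choices.** The autoregressive coefficient is penalized
like any other (a penalty-factor mechanism can exempt it). Reverse-keyed
items are recoded toward depression before fitting by default
(`direction_convention="recode_reverse_first"`); `"raw"` mode fits items as
coded, in which case positively worded items produce negative associations
with the depressive items. Exactly collinear predictors raise at λ = 0
rather than being resolved by a pseudo-inverse; any positive penalty
resolves the degeneracy. Estimation expects complete data for the wave
pair: run the imputer or complete-case filter first.

## Centrality

Out-expected influence of item i is Σ_{j≠i} B[i, j]; in-expected influence
of j is Σ_{i≠j} B[i, j]. Sums are on the log-odds scale so an absent edge
contributes exactly 0 (sums of odds ratios have no meaningful zero point).
The autoregressive path is excluded by default — self-prediction is not
inter-symptom influence — with a flag to include it. z-columns standardize
each index across the network's items (sample SD); a zero-spread vector is
reported as z = 0 with a degenerate flag. Conservation (Σ out-EI = Σ in-EI
= off-diagonal sum of B) holds to machine precision and is tested.

## Bootstrap procedures

*Edge accuracy*: persons are resampled with replacement (default 1000
draws) and the network refit per resample; per-edge percentile intervals at
the configured level (BCa was considered and rejected for transparency and
cost). By default λ is re-selected within each resample so selection
variability is part of the interval; `reselect_lambda=False` freezes the
per-outcome penalties at their full-sample values, which is roughly two
orders of magnitude faster and is what the validation suite and the
acceptance script use at their problem sizes. Resamples with a constant
item column are redrawn (logged, at most 10 attempts).

*Case-drop stability*: for each drop proportion (default grid 0.10–0.75,
step 0.05) persons are subsampled without replacement and the subsample
expected-influence vector is correlated with the full-sample one. The
CS-coefficient is the largest proportion at which the 5% quantile of these
correlations stays ≥ 0.70 at that proportion and every smaller one
(cumulative reading of "maintained"; threshold and quantile configurable).
Proportions whose retained sample falls below 10 × items are skipped.

*Difference tests*: two edges (or two items' expected influences) differ
"significantly" when the percentile interval of the bootstrap distribution
of their difference excludes zero. No multiple-testing correction is
applied — the convention in the network literature — so the tests are
descriptive; with 56 cross-lagged edges the family of pairwise comparisons
is large and individual flags should not be over-read.

## Imputation

A minimal chained-equations single imputer for binary items: missing cells
are initialized from each column's observed marginal, then for a fixed
number of cycles (default 10) each incomplete item-wave column is regressed
(unpenalized logistic) on all other item-wave columns plus the auxiliary
covariates, and missing cells are re-drawn as Bernoulli(fitted
probability) — stochastic draws rather than rounded probabilities, to
preserve binary marginals. Observed cells are never altered; everything is
seeded. A column whose fit fails (single observed class, solver failure,
non-finite coefficients) falls back to a marginal draw with a logged
warning. Single imputation mirrors common practice for these panels; for
multiple imputations run the imputer over seeds — pooling is out of scope.
Predictive mean matching and multilevel structure are not implemented.

## Synthetic data generator

The generator is the package's ground truth. Wave 1 is drawn independently
per item from Bernoulli prevalences; waves t ≥ 2 follow exactly the
node-wise logistic transition law above, so the estimator is evaluated
against a correctly specified model. Intercepts can be calibrated so that
post-transition marginals hit target prevalences: the calibration solves
E[sigmoid(c_j + B[:, j]·X)] = target_j by 1-D root finding, with the
expectation computed by exact enumeration over the 2^p predecessor states
for p ≤ 12 (Monte Carlo beyond), residual ≤ 1e-4.

The default 8-item fixture emulates a brief depression screener: wave-1
prevalences (0.12, 0.20, 0.36, 0.92, 0.12, 0.91, 0.20, 0.20) over 4 waves,
items 4 and 6 positively worded and reverse-keyed, autoregressive weights
0.9–1.4, and a dozen cross-lagged edges (0.25–0.9 in magnitude, negative
where a wellbeing item meets a depressive item in raw coding) whose pattern
echoes the strong effort ↔ could-not-get-going, happy → enjoy and
lonely → depressed couplings typical of such instruments.

Missingness is introduced at the person-wave level (a whole interview
missing, as in panel wave non-response) for waves ≥ 2, with probability
sigmoid(m₀ + m'·aux + m_s · wave-1 sum score); the default fixture uses
m₀ = −2.3, +0.6 for non-white ethnicity, +0.1 for male sex and +0.15 per
baseline symptom, i.e. roughly 10–20% per-wave missingness that increases
with baseline severity. Because the indicator is drawn from wave-1 data and
covariates only, the mechanism is missing-at-random by construction; an
optional item-level MCAR sprinkle exists.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: cross-sectional dependence at baseline
(wave-1 items are independent, so wave-1 internal consistency is ≈ 0 by
design and rises only at later waves), unobserved heterogeneity /
between-person effects, item-level non-response within an interview (by
default), measurement error, time-varying transition structure (supported
via per-wave-pair matrices but not used by the default fixture), and
missingness-not-at-random.

## Descriptives

Endorsement uses the non-missing denominator per item and wave. Item
skewness and excess kurtosis use the population Bernoulli closed forms
(1−2p)/√(p(1−p)) and (1−6p(1−p))/(p(1−p)) — these reproduce published
item-moment tables computed from endorsement percentages, which
sample-adjusted estimators do not. Internal consistency is KR-20 with
population variances throughout (so k identical items give exactly 1),
computed after recoding reverse-keyed items; the full scale and the
5-item affect / 3-item somatic subscales are reported. Rows with missing
items are dropped from KR-20 with a warning (the total-score variance
requires complete rows). Paired t-tests on sum scores are classical
two-sided tests on the per-person differences.

## Validation problem sizes

The test suite and `scripts/acceptance.py` exercise the pipeline at sizes
chosen to make each property measurable while keeping a full run in the
minutes range on one CPU: solver equivalence on 20 datasets of n = 200;
parameter recovery on three n = 7000 fixture panels; null false-positive
control on ten n = 5000 structureless panels; difference-test calibration
over 100 replications of n = 2000 with 200 bootstrap draws each (fixed
λ = 0.02, frozen across resamples — the type-I property concerns the
exchangeability of equal-weight edges under resampling, not the selection
rule); case-drop stability on an n = 5000 panel with 100 subsamples per
drop proportion. Bootstrap runs in the validation suite freeze λ at
full-sample values; re-selection per resample remains the library default.

## Known limitations

- Gaussian or graded-response variants of the network model are out of
  scope; items must be strictly binary.
- The CLPN conflates within- and between-person dynamics.
- CS-coefficients are reported on the standard coarse grid; values are
  lower bounds at grid resolution.
- The imputer is a minimal chained-equations implementation, not a full
  MICE replacement (no predictive mean matching, no pooling).
- Difference tests are uncorrected for multiplicity by design.
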