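# Methods

This note documents the models, algorithms, defaults and limitations of
`vaxdce`, in the order a study flows through the package.

## Study structure and coding

A study is a `StudyDesignSpec`: ordered attributes, each either
categorical (dummy-coded against a declared reference level) or
continuous (price, with a numeric value per design level).  The shipped
HZ configuration has seven attributes — effectiveness (45/60/75/90%,
reference 45), protection duration (2/5/10/20 years, ref 2), doses (1/2,
ref 1), influenza-like-symptom risk and skin-reaction risk (each
1/5/10/20 per 100, ref 1/100), origin (domestic/imported, ref domestic)
and price (0/400/800/1200 CN¥) — giving a fixed coefficient order of
constant + 14 dummies + price (16 terms).  The opt-out alternative is a
row of zeros: no constant, no dummies, zero price.  The constant is
therefore the alternative-specific constant shared by both designed
vaccines, measuring the preference for being vaccinated at all.

Price enters in yuan, not rescaled.  The default per-yuan price
coefficient used as simulation truth is −0.00282: the published
monetary values imply this value (e.g. 0.958/339.843 ≈ 2.746/973.724 ≈
0.00282), whereas the display-rounded −0.003 per yuan is too coarse to
reproduce any of them.

## Orthogonal design generation

Run sizes are powers of two.  Each factor with 2^k levels is assigned a
k-dimensional subspace of GF(2)^m characters (m = log2 of the run
size); two factor columns are mutually balanced (strength 2) exactly
when their subspaces intersect only in zero, so a backtracking search
for pairwise trivially-intersecting subspaces yields an orthogonal
main-effects array.  For the HZ structure (five 4-level, two 2-level
attributes; 17 main-effect degrees of freedom) the smallest feasible
run size is 32, matching the study's 32 choice questions.  The builder
is verified by `design_diagnostics` (exact level balance, zero
between-attribute correlation) rather than trusted as a catalogue.

The second alternative of each task is built by a cyclic level shift
(+1 modulo the level count per attribute), which preserves balance and
guarantees non-degenerate tasks; a seeded random-offset pairing is
available (`pairing="random"`).  Whether the original study used one or
two arrays is unknowable from the publication; the shift rule is the
default and both are supported.

Blocking into questionnaire versions starts from a seeded random equal
split and hill-climbs pairwise swaps to minimize the squared deviation
of within-block level counts from uniform.  Non-divisible task counts
are an error, not a warning.  The Johnson–Orme rule is implemented as
`floor(500·c/(t·a))`; floor is the convention that reproduces 83 for
(c=4, t=8, a=3).

## Synthetic respondents

The generator's defaults mirror the surveyed population: 2864
respondents, 8 tasks each from one of 4 uniformly assigned blocks,
demographics drawn from the published category proportions, and true
coefficient means equal to the published preference estimates.  The
published study reports no coefficient spreads, so heterogeneity
defaults to sd = 0.5·|mean| per coefficient — a moderate, clearly
conventional choice — with the price coefficient non-random (sd 0) so
that true WTP is a well-defined ratio.  Choice noise is standard Gumbel,
the distribution under which argmax choice produces softmax
probabilities.  One global seed fans out to stage seeds by fixed
offsets (+1 design, +2 blocking, +3 population, +4 choices, +5
demographics), keeping every stage independently reproducible.

What the generator does *not* emulate: lexicographic or inattentive
responders, attribute non-attendance, correlated coefficients, scale
heterogeneity across respondents, or demographic effects on preferences
(an optional per-group truth supports subgroup power experiments).
Passing recovery tests therefore shows the estimator is correct under
its own assumptions, not that real survey data meet them.

## Estimation

The panel simulated log-likelihood averages, per respondent, the
product over tasks of softmax probabilities across draws of the
coefficient vector (average-of-products; one draw spans all of a
respondent's tasks).  Draws are scrambled Halton sequences
(`scipy.stats.qmc.Halton`) mapped through the normal quantile, fixed
across iterations; pseudo-random draws are an option.  Defaults are 500
draws and seed 12345.  Internally all covariate columns are
standardized before optimization — price in yuan otherwise makes the
Hessian condition number ~10^5 and stalls quasi-Newton methods — and
estimates, gradients and the covariance matrix are transformed back
afterwards.

Optimization is L-BFGS-B on the negative simulated log-likelihood with
an analytic gradient (verified against finite differences in the test
suite); the conditional logit (no random coefficients, one draw) serves
both as the starting-value provider for the means and as the
zero-heterogeneity special case, with spreads started at 0.1.  Spread
parameters are unconstrained during optimization and reported as
absolute values (the sign is unidentified under normal mixing).
Standard errors come from the inverse observed information, computed by
central finite differences of the analytic gradient; a
respondent-clustered sandwich estimator is available (`robust_se`).
Confidence intervals are the symmetric normal approximation
(±1.96·SE), and significance is flagged at p ≤ .05.  Non-convergence
is reported on the result object, never silently ignored.

Degenerate inputs: a covariate with no variation raises an
identifiability error naming the column; tasks with no chosen
alternative are an error in strict loading and are dropped with a
logged count otherwise (a task with several chosen rows is always an
error); respondents with fewer tasks than others are padded internally
with a single zero-covariate pseudo-alternative whose likelihood
contribution and score are exactly zero.

## Willingness to pay

Point WTP is the ratio of means, `b_k/(−b_price)`, in yuan — the
published WTP table is internally consistent with ratio-of-means (every
value divided by its coefficient gives the same constant), which is why
that convention is implemented rather than a ratio of random
coefficients.  Intervals are percentile bootstrap at 95%:

* **parametric** (default, 1000 replicates): coefficient vectors drawn
  from N(b̂, V̂) of the mean block (Krinsky–Robb); fast and requires
  only the fitted covariance;
* **nonparametric**: respondents resampled with replacement and the
  model refitted per replicate; rigorous, slow, requires the data.

Ratios are scale-invariant (rescaling all coefficients leaves WTP
unchanged) and linear in the numerator, so bundle values are sums of
component WTPs.  A zero price coefficient raises an error; a positive
one warns.  Currency conversion is a display-layer multiplication with
a user-supplied rate only.

## Uptake and tornado analysis

Scenarios specify levels for the categorical attributes only; including
price is an error (uptake is reported free of hypothetical cost
levels).  The default comparison is one scenario vaccine versus the
opt-out, `P = e^V/(e^V+1)`, since the base case describes a single
program.  Heterogeneity is integrated by averaging the probability over
normal coefficient draws using the fitted spreads; with a conditional
logit fit the plug-in value is returned exactly (zero Monte-Carlo
error).  The tornado table varies one attribute level at a time from
the all-reference base case, shares common random numbers across
scenarios so deltas are not dominated by simulation noise, reports
deltas in percentage points to 2 decimals, and sorts by magnitude.
Published uptake deltas depend on the unavailable survey data and
unreported spread estimates, so only their qualitative ordering (the
three effectiveness deltas decreasing, dose schedule smallest) is used
as a check.

## Numerical choices and problem sizes

Softmax is computed with max-subtraction; the likelihood of a
respondent across draws uses log-sum-exp.  The optimizer stops on a
sup-norm gradient tolerance of 1e-6 (conditional logit) / 1e-5 (mixed)
in standardized units.  Test-suite experiments use sizes chosen to make
sampling error small relative to the tolerances they assert: parameter
recovery uses 1000 respondents × 8 tasks × 200 draws (mean absolute
coefficient error ≲ 0.06 in practice), bootstrap coverage uses 200
replicate studies of 300 respondents (the study's per-city recruitment
target) with 500 parameter draws each, and the oracle comparisons use
tiny instances where adaptive quadrature is exact to ~1e-6.

## Known limitations

* Only independent normal mixing; no lognormal, latent-class or
  correlated random coefficients.
* The array builder covers power-of-two run sizes and 2/4-level
  factors (the relevant DCE case); other structures raise a clear
  infeasibility error rather than falling back to a catalogue.
* WTP under a random price coefficient (ratio of distributions) is out
  of scope; the price coefficient should be held fixed when simulating
  if true WTP must be well-defined.
* The published headline coefficient estimates and their intervals are
  not reproducible from first principles (the survey data were not
  deposited and spread estimates were not printed); the package
  reproduces the study's *procedure* and its self-contained design
  arithmetic, and validates the estimator on synthetic data.
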