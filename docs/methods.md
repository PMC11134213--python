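# Methods

This note documents the statistical procedures `metadyad` implements, the
assumptions behind them, the defaults that matter, and the limits of what
the synthetic-data experiments can show.

## Data model and preprocessing

A cohort is a set of independent mother–infant dyads. Each compartment
(maternal third-trimester serum, placenta at delivery, cord serum at
delivery) is a samples × metabolites matrix of absolute concentrations
from quantitative NMR — serum in nmol/L, placental tissue in nmol/g.
Units are never converted across compartments: every downstream method is
either rank-based (scale-free per column) or standardizes columns, so the
difference in units is immaterial by construction.

Non-detected entries are *missing*, not zero. Targeted-profiling software
usually assigns a concentration to every fitted compound, but where
blanks occur the package keeps them as missing: screens use
pairwise-complete observations and the multivariate stage uses complete
rows. No imputation is performed — inventing an imputation model would
add an assumption the analysis does not need. Whether explicit zeros mean
"true zero" or "below detection" is genuinely ambiguous in quantified
NMR output, so the reader exposes both interpretations
(`zeros_as_missing`), and the log transform treats zeros as missing
either way.

**Detection filter.** A metabolite identified in fewer than `min_frac`
(default 0.80) of samples is excluded, along with anything on an explicit
exclusion list (preparation contaminants). The boundary is kept: exactly
80% detection survives, because the exclusion rule is a strict
inequality. The filter is idempotent.

**Pairing rules.** A dyad qualifies for an analysis only with samples in
every required compartment. A mother enrolled through several pregnancies
contributes only the earliest qualifying one, and an infant whose older
sibling is already retained (same family link) is excluded, so the
pregnancies analyzed are independent. All exclusions are recorded in a
JSON manifest.

**Scales.** Spearman screens are rank-based and invariant to any
monotone transform, so their scale is immaterial. The rank-*regression*
screens are monotone-invariant in the response ranks but not in the
design: raw lognormal concentrations put extreme leverage points into
the predictor column, and the Wald-t reference then becomes grossly
anticonservative in the far tail (at n = 60 with log-sd ≈ 1.3 the
nominal 0.001 tail is hit ~15× too often). The pipeline therefore runs
the adjusted screens on natural-log concentrations by default, where the
reference is close to calibrated; `wilcoxon_rank_fit` itself is
scale-agnostic and the raw-concentration option remains a config switch
for data without heavy tails. The multivariate stage and outcome models
also use natural-log concentrations: NMR concentrations are positive and
right-skewed, and log-scale linear structure is the generative
assumption of the synthetic model as well.

## Spearman screens and FDR

Each screen — all pairs within one compartment, or all bipartite pairs
between two — is one family. Spearman ρ is the Pearson correlation of
midranks on the pairwise-complete rows; two-sided p comes from the t
approximation `t = ρ√((n−2)/(1−ρ²))` (the standard reference at the
cohort sizes involved, n ≈ 60–110), with full-enumeration exact
permutation p available and used automatically below n = 10. Pairs with
fewer than 5 complete observations or a constant column are flagged and
excluded from the family rather than given a fabricated p.

Benjamini–Hochberg adjusted values are computed by the step-up rule
`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1. The reporting rule downstream
is two-sided q < 0.10. Under positive dependence of the kind the data
exhibit (correlated metabolite panels), BH controls FDR at or below the
nominal level.

## Rank-based covariate adjustment

For each metabolite pair (x, y) and covariate set, the package fits
`y ~ x + covariates` by minimizing Jaeckel's dispersion with Wilcoxon
scores. The dispersion is convex and piecewise linear and does not depend
on an intercept; the intercept is the median of the residuals at the
solution. The minimizer is the classical Newton-type iteration:
from the least-squares start, step `τ̂ (XᵀX)⁻¹ Xᵀ a(R(e))` with
step-halving whenever the dispersion fails to decrease, on internally
standardized columns, declaring convergence when slopes move less than
1e-8 (relative). A derivative-free polish was evaluated and discarded:
it changed estimates by less than the numerical tolerance and cost an
order of magnitude more time at screen scale.

The scale parameter `τ = (√12 ∫f²)⁻¹` is estimated by the
Koul–Sievers–McKean device: the signed-rank confidence interval over the
Walsh averages of the residuals has asymptotic length `2 z_{α/2} τ/√n`,
so τ is read off the realized length (α = 0.05 as the bandwidth-like
constant, with a `√(n/(n−p−1))` degrees-of-freedom correction). Wald p
values use a t reference with n − p − 1 degrees of freedom. Under
Gaussian errors this estimator is ≈ 95.5% efficient relative to least
squares and it is resistant to gross response outliers, which is the
reason it is the adjustment engine for concentration data.

## Canonical sparse PLS

Given complete-case rows, every column of both blocks is replaced by its
least-squares residual on the model-2 covariate design (with intercept);
residuals are exactly orthogonal to every covariate column. Blocks are
then centered and scaled to unit column variance (ddof = 1).

Per component, unit-norm weight vectors maximize `cov(Xa, Yb)` by
alternating updates `a ∝ S(Xᵀu, k_x)`, `t = Xa`, `b ∝ S(Yᵀt, k_y)`,
`u = Yb`, where the soft-threshold `S(v, k)` keeps the k
largest-magnitude entries and shrinks them toward zero by the (k+1)-th
magnitude. With full budgets this is the power iteration on `XᵀY`, whose
fixed point is the leading singular-vector pair — the test suite checks
agreement to 1e-8 against an SVD computed independently. *Canonical*
deflation removes each block's own score
(`X ← X − t tᵀX/tᵀt`, `Y ← Y − u uᵀY/uᵀu`), modelling a bidirectional
relationship; scores are therefore mutually orthogonal within a block.
Sign ambiguity is resolved by making the largest-magnitude entry of each
x-loading positive, flipping (a, b, t, u) together so the latent
covariance is unchanged. Iterations stop when the loading change drops
below 1e-10 (2000-iteration cap).

**Sparsity rule.** Sparse budgets are used when the number of dyads is
below the summed width of the two blocks (n < p + q), dense otherwise.
Budgets are tuned sequentially (keep_x with Y dense, then keep_y) over a
grid {5, 10, …, width} by maximizing first-component leave-one-out Q².
Permutation refits reuse the tuned budgets rather than re-tuning per
permutation: re-tuning inside the null would test a different statistic
and costs two orders of magnitude more; a config option restores it.

**Q² component selection.** For component h, PRESS_h is the leave-one-out
prediction error of the deflated Y residual from the component-h X score
(the held-out sample is walked through the train-set deflation chain),
and RSS_{h−1} is the full-fit residual sum of squares after h − 1
components. Components are retained while `Q²_h = 1 − PRESS_h/RSS_{h−1}`
is at least 0.0975, the conventional retention rule for this statistic.
Centering/scaling is done once on the full data rather than per fold — at
these n the difference is negligible and the single preprocessing keeps
the permutation and Q² stages on identical inputs.

**Permutation test.** The statistic is the sample covariance of the first
latent pair. Rows of the residualized Y are permuted uniformly B times
(default 9999) and the first component is refit per permutation;
`p = (count_ge + 1)/(B + 1)` is one-sided with the add-one estimator, so
p ≥ 1/(B+1) and the null distribution is super-uniform up to
discreteness. Permuting after residualization preserves the covariate
structure under the null.

**Variance explained** of component h for block X is the squared
Frobenius norm of the rank-1 reconstruction of the preprocessed X from
t_h divided by ‖X‖²_F (likewise u_h for Y); the "pair" value averages the
two blocks. This functional is one of several in use for PLS
variance-explained summaries; it is stated here precisely because the
literature often leaves it undefined. Orthogonal scores make the
per-block proportions sum to at most 1.

**Relevance network.** With retained components H ≥ 1, the similarity
between x_i and y_j is `s_ij = Σ_h corr(x_i, z_h)·corr(y_j, z_h)` with
the shared reference variate `z_h = (t_h + u_h)/2` — the symmetric choice
matching canonical (bidirectional) mode. Edges connect only variables
from different blocks, require |s_ij| ≥ threshold (default 0.5,
configurable; published network figures rarely state their cutoff), and
carry the sign of s_ij.

**Gating.** The pipeline runs PLS for a block pair only when the
Spearman screen or the fully-adjusted rank screen reports at least one
q < 0.10 pair. A consequence worth stating plainly: on a truly null
pair, the probability that BH makes at least one (false) discovery on a
null screen equals the FDR level, so a 0.10 gate falsely opens roughly
10% of the time per screen no matter how well calibrated the p-values
are. A falsely opened gate is almost always closed again by the
permutation test (its null rejection rate is the test level), so the
*reported association structure* — which pairs show a significant latent
covariance — is far more stable than the skip/run event itself.

## Outcome models

Multinomial logistic regression (TD reference) is fit by Newton maximum
likelihood via statsmodels, with covariance from the inverse observed
information. Exponentiated coefficients are reported as relative risks
with 95% Wald intervals — strictly they are relative risk *ratios* of the
multinomial logit; the conventional label is kept, with this caveat.
Latent-variate scores and metabolite predictors enter as z-scores of
natural-log concentrations by default (a raw-scale option exists), so an
RR is per SD of log concentration. Quasi-complete separation (any fitted
probability above 1 − 1e-8) is flagged and reported, never silently
regularized — with a small non-TD class this is a live concern and wide
CIs are the honest output.

Probability curves draw coefficient vectors from the asymptotic normal
sampling distribution, set the predictor of interest to each grid value
for *every observed covariate row* (observed-value averaging, not
at-means), and report per-class mean and 2.5/97.5 percentile bands over
draws. Probabilities sum to 1 at every grid point by softmax
normalization; zero covariance collapses the band onto the plug-in
prediction.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with every planted quantity returned as ground truth:

- **Concentrations** are log-normal:
  `log C = intercept + Λ f + E c + ε`, with independent standard-normal
  factor scores f, sparse Gaussian loadings Λ, standardized covariates c
  with sparse Gaussian effects E, and Gaussian noise (sd 0.5 on the log
  scale). Intercepts are N(log 100, 1), putting concentrations in the
  tens-to-thousands range typical of nmol-scale NMR panels.
- **Factors** come in two kinds: *shared* factors linking a block pair
  (default: one placenta↔cord factor, strength 1.0, no maternal sharing —
  the structure the pipeline is designed to detect) and *within-block*
  factors (default two per compartment, strength 0.6) reproducing the
  dense within-tissue correlation real metabolite panels show. The
  within-block factors also make bipartite null test statistics
  positively dependent, the regime BH is known to tolerate.
- **Covariates** mirror the dyad covariate model: an ordinal birth year
  over six levels, gestational ages (sd 10 days), a fasting time, and
  Bernoulli(0.5) binaries for the dichotomized social and clinical
  covariates (education, race/ethnicity as a structural-inequity proxy,
  home ownership, prenatal vitamin use, fetal sex, delivery mode,
  metabolic condition).
- **Outcome** is drawn from a three-class multinomial logit with base
  rates 57/30/13% (TD/ASD/non-TD), matching the imbalance such high-risk
  cohorts show and deliberately exercising small-cell behavior; the
  default planted effect is protective of non-TD per SD of the shared
  factor (coefficient −2, RR ≈ 0.14).
- **Defaults**: 107 dyads with complete fully-adjusted covariates and
  panels of 48/54/44 metabolites; options add missing covariates (e.g. a
  111-dyad cohort with 4 incomplete), missing outcomes, and left-censored
  low-detection metabolites for filter tests.

What passing tests on these cohorts shows: the pipeline detects the
planted cross-compartment structure, controls its error rates under the
generator's null, and recovers planted effect sizes. What it cannot
show: robustness to features the generator omits — non-lognormal tails,
batch effects, informative missingness, nonlinear covariate effects, or
misspecified outcome links. Conclusions about real cohorts rest on the
methods' published properties, not on these simulations.

## Problem sizes and numerical choices

Test-suite simulations are sized to what the checks need, not to the full
study scale: permutation calibration uses n = 60 blocks of width 20/15
with B = 199 over 200 replicates; the end-to-end recovery check runs 50
seeds of a 60-dyad tri-compartment cohort with 10/12/9 metabolites and
B = 99; rank-regression recovery uses n = 1000. The acceptance script
runs the full 107-dyad, 48/54/44 configuration with B = 9999.

Fixed numerical choices: NIPALS tolerance 1e-10 (cap 2000 iterations);
rank-fit slope tolerance 1e-8 with a 100-iteration cap and tiny-move
fallback near the piecewise-linear valley floor; Q² retention 0.0975;
FDR level 0.10; network threshold 0.5; permutation add-one estimator.
Ties everywhere use midranks. Degenerate inputs (constant columns,
rank-deficient designs, empty outcome classes, all-zero thresholded
loadings) raise errors rather than being patched over, except inside
permutation replicates and leave-one-out folds, where a degenerate refit
is skipped and counted conservatively.

## Reproducibility

Every random stage consumes an independently derived child seed from the
master seed (NumPy `SeedSequence`); the run log records them, and
re-running any stage with its logged seed reproduces its output.
`summary.json` contains no timestamps, so identical config + seed yields
byte-identical summaries.

## Known limitations

- Spearman p-values from the t reference are approximate in extreme tails
  at small n; the exact option is exponential in n and capped at n ≤ 9.
- The KSM τ estimator's O(n²) Walsh-average set is fine to a few thousand
  observations but would need subsampling beyond that.
- Q² leave-one-out refits the model n times per candidate budget; tuning
  cost grows linearly in the grid size.
- The multinomial models are unpenalized; with a small outcome class,
  separation produces unbounded RRs, which are flagged but not shrunk.
- Relevance-network similarities can exceed 1 in magnitude with several
  retained components (each term is a correlation product); the single
  component case is bounded by 1.
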