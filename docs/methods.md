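# Methods

## The model

`mrnm` estimates genome-wide genotype–covariate correlation and interaction
(GCCI) and residual–covariate correlation and interaction (RCCI) for a
quantitative trait `y` modulated by a continuous covariate `c` that is itself
a heritable trait.  The observation model for individual *i* (interaction
order *k* = 1 throughout) is

    y_i = b_i + a0_i + a1_i * c_i + t0_i + t1_i * c_i
    c_i = mu_i + beta_i + eps_i

with fixed effects `b_i`, `mu_i` (an intercept per trait by default) and six
random effects: genetic reaction-norm intercept and slope (`a0`, `a1`),
residual intercept and slope (`t0`, `t1`), and the covariate's genetic and
residual parts (`beta`, `eps`).  The genetic vectors are jointly normal with
covariance `Sigma_g (x) A`, where `A` is the genomic relationship matrix
(GRM) and `Sigma_g` the 3x3 coefficient covariance over `(a0, beta, a1)`; the
residual vectors have covariance `Sigma_r (x) I` over `(t0, eps, t1)`.

Because every individual carries exactly one record and one covariate value,
the joint covariance of the stacked observations assembles in closed blocks
(`Phi = [1 c]`, `Dc = diag(c)`):

    V_yy = A o (Phi K_y Phi') + Diag(Phi M_y Phi')
    V_yc = (kyc0 I + kyc1 Dc) A + (myc0 I + myc1 Dc)
    V_cc = var(beta) A + var(eps) I

`K_y = cov(a0, a1)` and `M_y = cov(t0, t1)` are the 2x2 genetic and residual
regression-coefficient covariances, `K_yc`/`M_yc` their covariances with
`beta`/`eps`.  The incidence matrices of the general random-regression
formulation reduce to identity selectors here, so no `Z` matrices are ever
materialised; the Hadamard/diagonal assembly is algebraically identical and
O(n^2) in memory.

Model variants are free-parameter masks over this structure:

| variant    | free parameters (k = 1)                             | count |
|------------|-----------------------------------------------------|-------|
| GREML      | var(a0), var(t0)                                    | 2     |
| RNM G-C    | K_y (3), var(t0)                                    | 4     |
| RNM R-C    | var(a0), M_y (3)                                    | 4     |
| RNM Full   | K_y (3), M_y (3)                                    | 6     |
| MVGREML    | var(a0), cov(a0,beta), var(beta), var(t0), cov(t0,eps), var(eps) | 6 |
| MRNM G-C   | + K_y off/slope terms and cov(a1,beta)              | 9     |
| MRNM R-C   | + M_y off/slope terms and cov(t1,eps)               | 9     |
| MRNM Full  | everything                                          | 12    |

Two comparison estimators stratify the covariate into discrete groups
(quartiles by default): RR-GREML regresses the genetic effect on the group
representative value (the mean standardised covariate within the group) and
frees one residual variance per group; GCI-GREML adds a same-group
interaction component `(A o S) s2_gxe` with homogeneous residual variance and
`s2_gxe` constrained non-negative.  Each group is represented by its mean
covariate value because only the existence of "four arbitrary strata" is
prescribed, not their parameterisation; the random-regression-on-group-value
form is adopted so that the stratified alternative literally fits
`a0 + a1*c` with a discretised `c`.

## Estimation

Parameters are estimated by restricted maximum likelihood.  The criterion
(constants dropped, so only differences are meaningful) is

    logL = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ],
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1.

Maximisation is average-information (AI) REML: one EM-style warm-up update of
the variance parameters, then AI quasi-Newton steps with step-halving
whenever a proposal decreases the likelihood or leaves the positive-definite
cone.  Since every variant is linear in its parameters, the derivative
matrices are fixed patterns computed once per fit.  Two boundary devices keep
the line search honest near constraints: parameters sitting at a bound with
an outward-pointing score are frozen and the AI system re-solved over the
remainder, and when a full step would cross a bound a second candidate pins
the crossing parameters at the bound and re-solves the rest (this prevents
slow crawls along the boundary).  Convergence is declared when the
log-likelihood changes by less than 1e-4 or the relative parameter change is
below 1e-6 (defaults; `RemlOptions`).  Standard errors come from the inverse
AI matrix at the optimum and are reported only for interior parameters.

Constraint policy: the base variances (var(a0), var(t0), var(beta), var(eps),
per-group residuals) are floored at zero; the reaction-norm interaction
variances var(a1) and var(t1) are left unconstrained, matching the practice
of the REML software this engine mirrors — their estimates may go negative
under the null, which is what makes the interaction LRT behave as a plain
chi-square rather than a boundary mixture.  GCI-GREML's `s2_gxe` is the one
hard-constrained (clamped-at-zero) parameter, which is also why its test is
conservative (empirical type-I error ~0.03–0.04 at nominal 0.05).

Two execution paths produce identical likelihoods.  Variants whose covariance
is `Bg (x) A + Br (x) I` (GREML, MVGREML) are rotated into the eigenbasis of
`A` — one eigendecomposition per GRM, cached — after which every likelihood,
score and AI evaluation is O(n) over per-individual 1x1 or 2x2 blocks.  All
other variants run on a dense path with explicit pattern matrices.  H1 fits
in an LRT are warm-started from the H0 optimum, which both accelerates them
and structurally guarantees logL(H1) >= logL(H0).

Hypothesis tests are two-model-fit likelihood-ratio tests: statistic
`max(0, 2 dlogL)` referred to a chi-square with degrees of freedom equal to
the free-parameter difference (no boundary-mixture correction, matching the
convention of the results this package reproduces).

## The simulator

`simulate_full` draws the six effect vectors from the Kronecker-structured
normal above, using `A^(1/2)` by eigendecomposition with negative eigenvalues
clipped at zero (sample GRMs are near- but not exactly PSD).  Three named
designs ship as presets, all with unit variances for `a0`, `beta`, `t0`
(= `e`), `eps`, so `var(c) = 2`:

* `null_independent` — diagonal structures, no interaction: the type-I-error
  design.
* `gc_interaction` — var(a1) = 0.25, cov(a0,a1) = 0.05: the power design;
  the interaction contributes var(a1)*var(c) = 0.5, i.e. var(a1)/var(y) = 10%
  of the total variance of 2.5.
* `gc_correlation_null` — cov(a0,beta) = 0.5 and cov(e,eps) = 0.3 with no
  interaction: the design under which a univariate analysis manufactures
  spurious interaction signal.

The covariate enters the product term *unstandardised* (variance 2); this is
the only convention under which the interaction-share bookkeeping
(10% share -> 1.5x residual inflation, 25% -> 3x) is self-consistent.  The
fitting harness, by contrast, standardises the covariate to mean zero and
unit variance before building the polynomial basis (both behaviours are
flags).  The LRT is invariant to this affine rescaling — the model family
spans the same set of covariance matrices — so calibration and power results
do not depend on it; raw-scale fits are used where estimates are compared
against simulation truth.  On the inflation grid the slope/intercept
covariance 0.05 is used only at positive interaction variance, because
`[[1, 0.05], [0.05, 0]]` is not a valid (PSD) coefficient covariance.

Replicate `r` of an experiment uses seed `base_seed + r`, recorded in the
checkpoint file, so interrupted grids resume deterministically.

What the generator emulates — and does not.  Genotypes are unlinked SNPs in
Hardy–Weinberg proportions with frequencies uniform on the retained MAF
range; the GRM is `W W'/m` with sample-frequency standardisation.  All models
under study are covariance-level, so linkage disequilibrium, per-SNP causal
architectures, ascertainment and non-normal phenotypes are deliberately not
simulated; passing tests therefore certify the estimators' behaviour under
their own assumptions, not robustness to real-data violations (the RINT
utility exists for the latter).

## Simulation studies and problem sizes

The replicate studies run at n = 1000 individuals and m = 5000 SNPs — sizes
chosen so a full study completes in minutes on one core — with 100–200
replicates for rejection-rate studies and 100 for bias studies; p-value
calibration uses 500 replicates at n = 500.  Type-I error, residual-variance
inflation and (at these effect sizes) RNM power are effectively invariant to
this down-scaling.  One quantity is not: the *spurious* rejection rate of the
misspecified univariate model under `gc_correlation_null` grows with sample
size (≈0.4 at n = 1000, ≈0.6 at n = 2000, approaching 1 at cohort scale),
because it is a power-like quantity for a misspecification signal.
Full-scale runs (n = 7263) are a configuration change, not a code change.

A second finite-sample effect shows up in the bivariate test when the trait
and covariate are strongly correlated: the MRNM interaction LRT statistic is
heavier-tailed than its chi-square(3) reference at small n (empirical type-I
error ~0.13 at n = 500 and ~0.09 at n = 1000 under the correlated null,
attenuating towards the nominal 0.05 as n grows).  This is a property of
referring a statistic whose "design" (the polynomial basis of the observed
covariate) is random and correlated with the response to a fixed-design
asymptotic distribution — not an optimization artifact: refitting both
hypotheses to 1e-7 tolerance from multiple starts leaves the rejection rate
unchanged, and the likelihood evaluations agree with an independent dense
oracle to 1e-8.  The univariate interaction test, whose null design has the
covariate independent of the trait, is calibrated at the same sample sizes.
At cohort scale the bivariate test is calibrated as well.

Rejection proportions are computed over converged replicates only, with the
exclusion count reported (non-convergence is a flagged result, never an
exception, so unattended grids are robust).  The inflation factor lambda is
the median observed chi-square(1) statistic over its expected median 0.4549.

## Workflow utilities

Confounder pre-adjustment takes least-squares residuals on the confounders
plus an intercept.  Stratification defaults to quartiles, with explicit
breakpoints supported (e.g. a zero breakpoint isolates never-exposed
individuals).  RINT uses the Blom offset `(rank - 3/8)/(n + 1/4)` with
averaged ties.  Fisher's method combines p-values as `-2 sum ln p` against
chi-square with `2k` df.  The residual-variance difference between additive
GREML and the reaction norm is tested by a two-tailed Wald test whose
standard error comes from a delete-a-group jackknife over individuals
(default 50 groups) — an analytic SE theory for this difference is not
exposed by the main-text sources this package follows, so the jackknife is
used and validated against replicate-to-replicate SDs in the test suite.

## Numerical choices and limitations

* GRM: monomorphic SNPs are dropped with a warning under `maf_min = 0`;
  relatedness pruning compares the signed entry against the threshold and
  removes a random pair member (seeded).
* Non-PD proposals during fitting are handled by step-halving; eigenvalue
  clipping (at 1e-8 of trace) repairs near-PSD inputs where a matrix square
  root is required.
* Fits require n >= 50 by default; REML surfaces below that are routinely
  degenerate (boundary optima), and the optimizer-agreement tests run at
  n = 60–80 with multi-start comparison for exactly that reason.
* Only order k = 1 ships in the tested model specs; the polynomial basis
  supports general k but higher orders are unvalidated.
* Multiple-covariate reaction norms assume uncorrelated random effects
  across covariates.
* The package does not implement LD-score-based estimation, genomic
  partitioning, epistasis, causal-direction inference, or real-cohort QC
  beyond MAF filtering.
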