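# mrnm — whole-genome (multivariate) reaction norm models

`mrnm` disentangles **genotype–covariate correlation** from
**genotype–covariate interaction** (GxE at the whole-genome level) for
quantitative traits.  The motivating situation: a trait `y` (say BMI) is
modulated by a covariate `c` (say smoking) that is itself heritable, so the
same SNPs can act on both traits (pleiotropy / genetic correlation) *and*
the covariate can modify the SNP effects on the trait (interaction).
Univariate interaction methods conflate the two; this package fits them
jointly and tests them separately.

## The models

The trait and covariate are modelled as (interaction order k = 1)

    y_i = b_i + α0_i + α1_i·c_i + τ0_i + τ1_i·c_i        c_i = μ_i + β_i + ε_i

where `(α0, α1)` are per-individual genetic reaction-norm intercepts and
slopes with coefficient covariance **K**ᵧ, `(τ0, τ1)` their residual
counterparts with covariance **M**ᵧ, and `(β, ε)` the genetic and residual
parts of the covariate.  Genetic effects are structured by the genomic
relationship matrix **A** = WW′/m (standardised SNPs); the genetic block of
the phenotypic covariance is **V**_g = Φ**K**ᵧΦ′ elementwise with **A**,
where Φ = [1 c].  The bivariate form (MRNM) adds
**K**ᵧ𝒸 = [cov(α0,β), cov(α1,β)]′ and **M**ᵧ𝒸 = [cov(τ0,ε), cov(τ1,ε)]′ —
the G–C and R–C correlations.  Nested variants (GREML, RNM G–C/R–C/Full,
MVGREML, MRNM G–C/R–C/Full, plus the stratified comparison methods RR-GREML
and GCI-GREML) are REML-fitted by an average-information algorithm and
compared by likelihood-ratio tests.  `var(α1) > 0` is G–C interaction;
`var(τ1) > 0` is residual heteroscedasticity along the covariate
(R–C interaction).

Why it matters: if interactions are present and ignored, a standard additive
model absorbs `var(α1·c)` into the residual — the residual variance is
inflated (up to 3-fold when the interaction is a quarter of the phenotypic
variance) and SNP-heritability is correspondingly underestimated.  The
`inflation_experiment` driver reproduces this effect from scratch.

## Worked example

Simulate a cohort with genetic correlation 0.5 and residual correlation 0.3
between trait and covariate but **no** interaction, then test for G–C
interaction with the misspecified univariate reaction norm and with the
bivariate MRNM:

```python
import numpy as np
from mrnm import (simulate_genotypes, compute_grm, simulate_full, PRESETS,
                  run_interaction_test)

A = compute_grm(simulate_genotypes(n=1000, m=5000, seed=7), maf_min=0.01)
sim = simulate_full(A, PRESETS["gc_correlation_null"], seed=42)

uni = run_interaction_test(A, sim, "rnm")    # GREML vs univariate RNM G-C
biv = run_interaction_test(A, sim, "mrnm")   # MVGREML vs MRNM G-C
print(f"univariate RNM : LRT={uni['lrt'].statistic:6.2f} df={uni['lrt'].df} p={uni['p']:.4f}")
print(f"MRNM           : LRT={biv['lrt'].statistic:6.2f} df={biv['lrt'].df} p={biv['p']:.4f}")
print("MRNM G-C correlation estimate:",
      round(biv['fit1'].params['kyc0'] / np.sqrt(biv['fit1'].params['ky00']
            * biv['fit1'].params['vbeta']), 3))
```

prints

```
univariate RNM : LRT= 11.61 df=2 p=0.0030
MRNM           : LRT=  3.85 df=3 p=0.2779
MRNM G-C correlation estimate: 0.573
```

The univariate test mistakes the unmodelled genetic correlation for
interaction (p < 0.01 despite the simulated truth having none), while the
MRNM — which estimates that correlation explicitly (truth 0.5) — stays
calibrated.  Replicated over hundreds of such data sets, the univariate
rejection rate is far above the nominal 0.05 and grows with sample size,
whereas the MRNM rate stays at ~0.05; the test suite and acceptance script
measure exactly this.

A command-line interface mirrors the library (`mrnm simulate`, `mrnm fit`,
`mrnm experiment`, `mrnm grm`, `mrnm adjust`, `mrnm rint`); run
`mrnm --help`.

```bash
mrnm experiment --kind typeI --preset null_independent \
    --methods rnm,rr_greml,gci_greml --n 1000 --m 5000 --reps 200 \
    --seed 1 --out scratch/null
```

writes per-replicate p-values (with resume-on-interrupt checkpointing) and a
summary table of rejection rates and the median-based inflation factor λ.

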