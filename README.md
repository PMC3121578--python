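# cnvlatent

Copy-number variant (CNV) association analysis that takes calling
uncertainty seriously.

CNV genotypes are inferred from a continuous probe signal (MLPA peak
intensities, qPCR ratios, summarised aCGH log-ratios), and the inference
is often uncertain: the per-class signal distributions overlap. Testing
a phenotype against the *best-guess* copy number treats those noisy calls
as exact, biasing effect estimates toward the null and understating their
uncertainty. `cnvlatent` is for epidemiologists and statistical
geneticists running CNV (or imputed-SNP) association studies who want
that uncertainty propagated instead of ignored.

The package does two things:

1. **Calling** — fit a finite Gaussian mixture to the univariate signal
   (optionally per assay batch with pooled class prevalences, with an
   optional zero-copy threshold and BIC selection of the class count) and
   produce an n×C matrix of posterior copy-class probabilities. Matrices
   from external callers or IMPUTE/SNPTEST-style genotype-probability
   files plug in directly.
2. **Association** — fit latent-class regression models that weight each
   individual's likelihood contribution by those posteriors,

       ℓ(θ) = Σᵢ log Σ_c w_ic · f(yᵢ | η_ic, ν),

   with η_ic = β_c + xᵢᵀγ (model-free design) or β₀ + β₁·c + xᵢᵀγ
   (additive design), for binomial, Poisson, Gaussian and right-censored
   Weibull proportional-hazards responses, by Newton–Raphson with an EM
   fallback. Results objects carry coefficients, the observed-information
   covariance, Wald summaries (OR/RR/HR with 95% CIs), global LRT and
   Wald tests, and batch testing across many CNVs with
   Benjamini–Hochberg adjustment.

With certain calls (0/1 posteriors) every model reduces exactly to the
ordinary GLM or parametric-survival fit; the test suite verifies this to
1e-6 against independent fitters.

## Worked example

Simulate an MLPA-like case-control study (651 individuals, three copy
classes with overlapping signal), call copy number, and test association:

```python
import cnvlatent as cl
from cnvlatent import simulate as sim

d = sim.sim_casecontrol(360, 291, w=[0.1306, 0.4187, 0.4507],
                        mu_surrog=[0.0, 0.24, 0.45],
                        sd_surrog=[0.01, 0.06, 0.10],
                        p0=0.6, or_per_copy=0.6, seed=42)

res = cl.GaussianSignalMixture(d.surrog).fit(n_components="auto",
                                             max_components=5)
print(res.summary())
cnv = res.posterior(copies=[0, 1, 2])

fit = cl.fit_latent_model(d.resp, cnv, family="binomial",
                          model="multiplicative")
print(fit.summary())
print(fit.lrt())
```

Output:

```
Gaussian mixture signal fit
  classes:     3
  means:       [-0.0006, 0.2398, 0.4627]
  variances:   [0.0001, 0.003, 0.0085]
  proportions: [0.149, 0.3991, 0.4519]
  loglik: 397.3161   BIC: -742.8042   n_used: 651
  converged: True
  goodness-of-fit p-value: 0.095099

Latent-class CNV association model (family: binomial, design: multiplicative)
Deviance: 871.6224
Number of parameters: 3
Number of individuals: 651

Coefficients:
         OR  lower.lim  upper.lim     SE    stat  pvalue
CNV0 1.0000        NaN        NaN    NaN     NaN     NaN
CNV1 0.4348     0.2560     0.7386 0.2703 -3.0809  0.0021
CNV2 0.2945     0.1750     0.4957 0.2656 -4.6015  0.0000

(Dispersion parameter for binomial family taken to be 1)

----CNV Likelihood Ratio Test----
Chi = 23.5281 (df = 2), pvalue = 7.77906e-06
```

Reading: BIC picked three copy classes; the goodness-of-fit test does not
reject the mixture; carrying one copy multiplies the odds of being a case
by 0.43 (95% CI 0.26–0.74) and two copies by 0.29 (0.18–0.50) relative to
zero copies — both consistent with the generating odds ratio of 0.6 per
copy — and the global likelihood-ratio test (χ² = 23.5, 2 df) confirms
the association. All of this is computed on the posterior probability
matrix, not on hard calls.

A command-line interface mirrors the library:

```sh
cnvlatent simulate --family casecontrol --n-cases 400 --n-controls 400 \
    --sd 0.2 --seed 11 --out d
cnvlatent call --signal d_signal.tsv --components auto --out called
cnvlatent assoc --probs called.tsv --pheno d_pheno.tsv --response resp \
    --family binomial --model free --test lrt --out result
cnvlatent multi --gen variants.gen --pheno d_pheno.tsv --response resp \
    --model add --workers 4 --adjust bh --out screen
```

Every run writes its results as TSV plus a JSON sidecar with the full
configuration, seeds and package version.

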