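# Methods

## Problem

Copy-number variants (CNVs) are usually genotyped from a continuous probe
signal (an MLPA peak intensity, a qPCR ratio, a summarised aCGH log-ratio)
rather than observed directly. Calling the integer copy number from that
signal carries real uncertainty whenever the per-class signal
distributions overlap, and an association analysis that conditions on the
best-guess call treats noisy calls as exact: effect estimates attenuate
toward the null and their standard errors understate the true
uncertainty. `cnvlatent` separates the two halves of the analysis —
probabilistic calling and uncertainty-aware association testing — and lets
probability matrices from any external caller (including SNP-imputation
genotype probabilities) flow into the same association machinery.

## Signal model and calling

The signal y for an individual carrying c copies is modelled as Gaussian,
so marginally

    y ~ Σ_c w_c · φ(y; μ_c, σ_c),

with w_c the population prevalence of copy class c. The posterior
probability that individual i carries c copies is the Bayes ratio
w_ic = w_c φ(y_i; μ_c, σ_c) / Σ_k w_k φ(y_i; μ_k, σ_k); the n×C matrix of
these posteriors is the object the association models consume.

Estimation is by EM with deterministic initial values (the sorted signal
split into k equal-mass groups; no random initialisation, so a fit is
reproducible from the data alone), convergence declared when the relative
log-likelihood change drops below 1e-8 (at most 500 iterations), and a
variance floor of 1e-6 times the signal variance to stop components
collapsing onto single points. Hitting the floor marks the fit
non-converged; a seeded multi-start fallback runs only when the
log-likelihood itself fails to settle, because restarting after a floor
hit (the signature of asking for more components than the data support)
just re-collapses. Components are always relabelled by ascending mean, so
column c of the posterior matrix is the c-th smallest signal class
regardless of the path EM took.

Two fitting flavours share this EM core: `em_raw` works on the raw values;
`em_binned` works on histogram counts at bin midpoints (Sturges' rule),
the way grouped-data mixture fitters operate. They agree up to binning
coarseness; `em_raw` is the default.

**Zero-copy threshold.** Deleted-on-both-chromosomes individuals produce
essentially no signal, a spike that no Gaussian should chase. With
`threshold_zero` set, intensities strictly below it are called 0 copies
with certainty: a point-mass class (mean 0, sd 0) whose weight is the
below-threshold sample fraction; the EM runs on the remaining signal and
its weights are scaled to the complement. Copy labels default to 0..C−1
when this class exists and 1..C otherwise; `relabel_copies` changes labels
without touching probabilities.

**Model selection.** The number of Gaussian components minimises
BIC = −2ℓ + (3k−1)·log(n_used) over k = 1..max_components (default 6),
with 3k−1 free parameters (k−1 weights, k means, k SDs) and ties broken
toward the smaller model; the zero point mass, having no free parameters,
is not counted but does count toward the reported number of classes.

**Batch effects.** Assay batches shift and rescale the signal, and if
batch composition correlates with the phenotype an ignored shift
manufactures association. Per-batch means and SDs are estimated
separately (component count chosen once on the pooled signal, each
batch's EM initialised from the pooled fit so classes stay aligned),
while class prevalences — a property of the population, not the plate —
are pooled as the batch-size-weighted mean ŵ_c = Σ_b n_b ŵ_cb / n.
Posteriors then use the individual's batch-specific (μ, σ) with the
pooled w.

**Diagnostics.** `goodness_of_fit` is a Pearson chi-square over
Sturges-binned counts versus the fitted mixture's expected counts
(open-ended outer bins; bins with expected < 5 merged with the smaller
neighbour), referred to chi-square with df = bins − 1 − (3k−1). That df
correction is exact when parameters minimise the binned chi-square; for
the EM flavours fitted here the statistic is stochastically somewhat
larger (the Chernoff–Lehmann phenomenon), so small p-values are mildly
anti-conservative — borderline rejections should not be over-read. With
`params_estimated=False` (externally fixed parameters) df = bins − 1 and
the p-value is exactly calibrated, which the test suite verifies by
simulation.

Two uncertainty summaries are available. The `class` score,
(1/n) Σ_i max_c w_ic, is the expected proportion of correctly classified
individuals (1 means certain calls). The `cnvtools`-style score averages
the standardised distances |μ_{c+1} − μ_c| / ((σ_c + σ_{c+1})/2) of
adjacent component pairs with weights (w_c + w_{c+1}); with unit-spaced
means and common σ it is exactly 1/σ. As a rule of thumb, values below ~3
mean calling uncertainty is substantial and must be propagated, values
above ~4.5 mean it is negligible. The exact formula used by other
packages for their headline score is defined in their own documentation
and may weight pairs differently; this one is a documented convention,
not a cross-package reproduction.

## Latent-class association model

Copy number enters the phenotype model as a latent class. With posterior
weights w_ic from the calling step, the observed-data log-likelihood is

    ℓ(θ) = Σ_i log Σ_c w_ic · f(y_i | η_ic, ν),

where the linear predictor is η_ic = β_c + x_iᵀγ under the model-free
("multiplicative") design — one intercept per copy class, effects
reported as contrasts against the lowest-copy reference class — or
η_ic = β_0 + β_1·copies_c + x_iᵀγ under the additive design (constant
effect per copy). Certain calls (0/1 rows) collapse the inner sum and the
model reduces exactly to the ordinary single-class fit, which the test
suite verifies against independent fitters to 1e-6.

Response families and densities f:

* **binomial** — f = p^y (1−p)^{1−y}, p = logit⁻¹(η); dispersion fixed at 1;
* **poisson** — f = e^{−μ} μ^y / y!, μ = e^η;
* **gaussian** — Normal(y; η, σ), nuisance σ estimated on the log scale;
  the reported covariance uses the ML dispersion (RSS/n), not the
  small-sample n−p convention;
* **weibull** — proportional hazards with right censoring:
  f = [α t^{α−1} e^η]^δ · exp(−t^α e^η) with event indicator δ, so e^β is
  a hazard ratio; the shape α is estimated jointly on the log scale or
  optionally fixed (α = 1 gives the exponential model). The
  accelerated-failure-time parameterisation is out of scope.

**Estimation.** Newton–Raphson on ℓ with the analytic score (responsibility-
weighted family score: ∂ℓ/∂θ = Σ_ic h_ic ∂log f/∂θ, where
h_ic ∝ w_ic f(y_i|c) are the response-informed class responsibilities),
a central finite-difference Hessian of that score, and step-halving line
search. Starting values are the closed-form naive best-guess-class
estimates (class-wise means / rates / crude hazards, covariates at zero).
If Newton–Raphson stalls, an EM pass runs — E-step computes h_ic, M-step
applies a few Newton steps to the minorant Q(θ|h) — and Newton–Raphson is
retried from its solution. Convergence requires a relative log-likelihood
change below 1e-10 and a score below 1e-8 in absolute value, tight enough
that the reported optimum is reproducible across optimisers to ~1e-7.
The coefficient covariance is the inverse observed information
(finite-difference Hessian at the optimum, symmetrised); copy classes
with total posterior mass below 1e-6 are dropped with a warning, and rows
with missing response/covariate values are dropped listwise with a
logged count.

**Inference.** `coef_table` reports per-contrast estimates on the scale
the field reads: odds ratios (binomial), rate ratios (poisson), hazard
ratios (weibull) or mean differences (gaussian, identity scale), with
normal-quantile 95% Wald intervals, the log-scale SE, the Wald z and
two-sided p-value; the reference class shows 1. Global tests of the CNV
block: the likelihood-ratio test (deviance difference against the matching
no-CNV model, chi-square with df = parameter difference) and a Wald
quadratic form on the CNV contrasts. `multi_assoc` maps either test over
many CNVs sharing one phenotype (joblib workers; per-CNV failures are
recorded with a reason, never fatal; output is identical for any worker
count), and `bh_adjust` applies Benjamini–Hochberg step-up adjustment.

## Simulators

Each generator draws a true copy class from prevalences w, a surrogate
signal from N(μ_c, σ_c) — emulating a univariate MLPA-like probe — and a
phenotype from the family model: binary cohort
(logit p = logit p₀ + log OR · c), retrospective case-control (rejection
sampling from the binary model until the requested case/control counts,
capped at 10⁷ candidate draws), Poisson (rate λ₀·RR^c), Normal
(mean m₀ + Δ·c), and Weibull (hazard α t^{α−1} λ_c, λ_c = incid₀·HR^c,
administrative censoring at a fixed time). The censoring-time helper
returns the `perc_obs` quantile of a Weibull with the given shape and a
scale anchor: the mean of the per-class scales (default, matching the
convention of the worked example this package's headline check
reproduces) or the zero-copy baseline scale, under which the zero-copy
event fraction equals `perc_obs` exactly.

`make_uncertainty_scenario(q, ...)` builds case-control configurations
with unit-spaced signal means and common σ = 1/q, so the generating
mixture's separation score equals q exactly — the dial used to study how
calling uncertainty affects convergence, type-I error and power. Default
scenario conditions: w = (0.25, 0.5, 0.25), baseline prevalence 0.10,
OR 1.5 per copy.

What the generators emulate, and what they do not: a single univariate,
Gaussian-per-class signal with class-independent sampling across
individuals. Real probe data bring non-Gaussian tails, batch structure
(which the caller models but the generators produce only if asked),
linkage between nearby CNVs, and genome context — none of which are
simulated. Passing the simulation-based checks therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
assay artefacts.

## Verification and problem sizes

The suite checks, among others: exact reduction to statsmodels GLM /
R `survival::survreg` fits under certain calls (1e-6, all four families);
the full simulate→call→fit pipeline on the Weibull cohort example
(n = 5000, 50 seeds: mean HR within 0.1 of the generating 1.5);
convergence robustness (100 replicates each at Q = 4.5 with 500+500 and
Q = 3.0 with 2000+2000); LRT type-I error under the null (Q = 4,
1000+1000, 500 replicates, 99% binomial envelope around 5%); and BIC
selection accuracy (σ = 0.1, n = 1000, ≥95/100 correct). Replicate counts
are sized so the whole suite runs on one CPU in minutes while keeping
Monte-Carlo error well inside each tolerance.

## Known limitations

* Overdispersion is not modelled (binomial/Poisson dispersion fixed at 1).
* No CNV×covariate or CNV×CNV interactions, no Poisson exposure offsets,
  no frailty terms.
* The GOF p-value after EM estimation is approximate (see above).
* The likelihood surface of overlapping mixtures is multimodal; with
  heavy overlap (separation score below ~3) the global optimum on a given
  sample can sit away from the generating parameters, which is a property
  of maximum likelihood at that signal quality, not of the optimiser. The
  latent-class association estimates remain approximately unbiased in
  this regime, at the price of wider intervals.
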