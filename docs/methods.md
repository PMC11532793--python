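# Methods

## The problem

Transcript-level counts from lightweight quantifiers (kallisto, Salmon) are
not observed but inferred: a read compatible with several transcripts of the
same gene is assigned probabilistically among them. This read-to-transcript
ambiguity (RTA) inflates the technical variance of a transcript's count well
beyond the Poisson level, by a factor that depends on the annotation topology
of its gene and can span several orders of magnitude between transcripts. If
the inflation is ignored, the transcript-level mean-variance relationship is
distorted and differential-expression tests are miscalibrated.

The divided-count approach measures the inflation from technical resamples of
each library (bootstrap or Gibbs re-quantifications), divides it out of the
counts, and then analyses the scaled counts with the quasi-likelihood
negative-binomial machinery developed for gene-level counts.

## Model

Let `y_ti` be the (fractional) count of transcript `t` in sample `i`. The
systematic part follows a log-linear model

    log mu_ti = x_i' beta_t + log L_i

with `x_i` the covariates of sample `i` and `L_i` its effective library size.
Technical replication is quasi-Poisson: `var(y_ti) = tau_t sigma2_t mu_ti`,
with `tau_t >= 1` the RTA dispersion and `sigma2_t` the quasi-dispersion from
other technical sources. Biological variation with squared coefficient of
variation `psi_t` yields the quadratic mean-variance relationship

    var(y_ti) = tau_t sigma2_t mu_ti + psi_t mu_ti^2 .

Dividing the counts by an accurate estimate `tau~_t` gives `z_ti = y_ti /
tau~_t` with

    var(z_ti) = sigma2_t (nu_ti + phi_t nu_ti^2),    nu_ti = E(z_ti),

the standard quasi-NB variance with NB dispersion `phi_t = psi_t / sigma2_t`
and quasi-dispersion `sigma2_t`. Any consistent multiplicative bias in
`tau~_t` is absorbed by `sigma2_t`, so only proportionality to the true
`tau_t` matters.

## RTA-dispersion estimation (`rta`)

With `B` resamples for each of `N` samples, the estimator pools the
quasi-Poisson Pearson statistic over the whole study:

    raw_t = sum_{i,b} (y_tib - ybar_ti)^2 / ybar_ti,    df = N (B - 1),

with (transcript, sample) cells of zero resample mean contributing to neither
numerator nor df. The pooled statistic is moderated toward 1 with a small
prior weight (`prior_df`, default 3; the moderation is deliberately light and
only stabilizes near-zero counts) and floored at 1:

    tau~_t = max(1, (raw_t + prior_df) / (df_t + prior_df)).

The floor is applied after the moderation so the moderation stays linear and
the bound exact. Because the df pool over all samples, precision depends on
the total `N(B-1)` rather than on `B` alone; two resamples per sample suffice
for a study with hundreds of samples.

Divided counts are fractional and never rounded; the downstream GLM accepts
fractional counts through its gamma-function likelihood extension.

## Bias-corrected quasi-likelihood (`dte`, `glmfit`)

Per transcript, a NB GLM with log link, library-size offsets and a *common*
NB dispersion is fitted by vectorized Fisher scoring with step-halving
(convergence `1e-8` relative deviance, 50 iterations). The common dispersion
is the maximizer of the Cox-Reid adjusted profile likelihood over the top 5%
most abundant transcripts (ranked after filtering).

The classical quasi-dispersion estimate `deviance / (N - p)` relies on the
chi-square approximation to the residual deviance, which is biased for small
counts. We instead compute an adjusted deviance `D*` and adjusted degrees of
freedom `df*` whose first two moments match a chi-square law under the fitted
model, via two backends:

* **Exact conditional backend** (one-way layouts, integer counts, equal
  within-group offsets). Conditionally on a group's sum `S`, Poisson counts
  are multinomial(S, 1/n) and NB counts are Dirichlet-multinomial with equal
  shapes `1/phi`, so the conditional mean `E[D|S]` and variance `V[D|S]` of
  the group's residual deviance are *free of the unknown mean* and are
  tabulated exactly (double sums over the count lattice, cached per group
  size and dispersion; groups with sums above 300 fall back to the general
  backend, where the approximation error is already negligible). The raw
  quasi-dispersion `s2 = D / E` is then exactly mean-unbiased at every count
  level; simulation checks give mean `s2` within 0.5% of 1 at means 1-20
  where the classical estimate is 7-20% biased.
* **General backend** (fractional counts, arbitrary designs or offsets). Per
  observation, the exact first two moments of the NB unit deviance are
  computed on a log-spaced grid of means (interpolated in log-log space) and
  combined with hat-matrix leverages: `E = sum (1-h) e(mu)`, `V = sum (1-h)
  v(mu)` — the weighting that is exact in the Gaussian linear model.

In both cases `df* = min(2 E^2 / V, N - p)` and `D* = (D / E) df*`, so
`s2 = D*/df* = D/E`. The same per-transcript scale maps deviance *drops* to
the adjusted scale in the F-test. Dispatch between backends is automatic; the
pipeline's divided counts are fractional with unequal offsets and therefore
use the general backend, whose residual low-count bias is absorbed by the
dispersion trend below.

Quasi-dispersions are squeezed by trended empirical Bayes: `log s2` is
bias-corrected with digamma terms, its abundance trend is removed by locally
weighted regression (span 0.4), and the prior degrees of freedom `d0` solve
`trigamma(d0/2) = var(resid) - mean(trigamma(df*/2))` via Newton inversion
(reported infinite above 1e6, or when the observed spread is below the
chi-square floor — in that degenerate case the trend interpolates `log s2`
directly, so constant input is reproduced exactly). The posterior value is
`s2_post = (df* s2 + d0 trend) / (df* + d0)`.

The quasi-F statistic for a `k`-dimensional contrast divides the adjusted
deviance drop between the null and full fits by `k` and by `s2_post`, and is
referred to `F(k, d0 + df*)`. FDR control is Benjamini-Hochberg.

## Equivalence-class quantifier (`ecquant`)

A miniature quantifier exercises the whole path from EC counts to
dispersions. The working parameter is the per-transcript read proportion
`rho_t` (proportional to `theta_t / l_t` for nucleotide-fraction abundance
`theta` and effective length `l`), so the class probability is the
length-normalized sum of member abundances:

* **EM** — uniform initialization; each iteration allocates class reads
  proportionally to `rho` within the class and renormalizes; the multinomial
  log-likelihood is non-decreasing and the solution matches a dense simplex
  grid search on small instances.
* **Bootstrap** — class counts redrawn multinomially from observed class
  proportions, EM re-run per replicate (re-run to convergence; whether
  production quantifiers rerun their full optimizer per replicate is not
  modelled). If all reads of a gene land in one class, every bootstrap
  replicate reproduces the same EM solution and the estimated RTA dispersion
  is exactly 1 — the known blind spot of bootstrap resampling.
* **Gibbs** — uncollapsed sampler alternating multinomial allocation of each
  class's reads (weights `theta/l`, i.e. gamma-distributed read rates) with
  gamma draws of the rates, shape `allocated + prior_count`. Every sweep
  conserves the sample's total reads. The prior gives unallocated member
  transcripts re-entry probability; `prior_count` defaults to 1.0 — a strong
  prior in the spirit of production Gibbs implementations — because much
  smaller values (e.g. 0.01) make Gamma(prior) weights vanish almost surely
  and freeze dominated transcripts for hundreds of sweeps, defeating the
  resolution advantage the sampler exists to provide. Burn-in 100 sweeps and
  thinning 4 are configurable placeholders, not claims about any production
  tool.

Transcripts never observed in any class get zero abundance under EM and
bootstrap and prior-only mass under Gibbs. Sub-division of classes by
fragment-length or bias models is not represented.

## Synthetic experiments (`simulate`)

The generator emulates a designed two-group bulk RNA-seq comparison at count
level:

* baseline relative abundances log-normal (sd 1.8 on the natural-log scale),
  a deliberate stand-in for a real expression profile — no external data are
  downloaded;
* biological dispersion `BCV^2_t = trend(abundance) * prior_df / chi2` with
  plateau `bcv0^2` (default 0.2^2) at high abundance, inflation
  `(bcv0 + 1/sqrt(c+1))^2` at expected count `c`, and heterogeneity prior df
  40;
* a uniformly chosen subset of transcripts (default 1000 of 10 000) receives
  a symmetric two-fold change, half up and half down;
* library sizes alternate between samples (default 0.25 and 1.0 million
  reads, a ~100x depth reduction of the 25/100 million full-scale design that
  preserves the alternating pattern; the calibration quantities studied —
  FDR, type-I error — are depth-robust, and a `full_scale` preset retains the
  printed 41 372 / 3000 / 25-100 Mi configuration);
* gene topologies of 1-4 transcripts with singleton and shared equivalence
  classes, including single-shared-class "degenerate" genes (default 5% of
  multi-transcript genes) in which bootstrap resampling sees no ambiguity;
* true RTA dispersions: 1 for unambiguous transcripts, `2^|N(0, 2)|` for
  transcripts of ambiguous topologies.

Technical resamples come from either the *direct* route — observed counts and
resamples drawn as scaled Poisson with variance `tau * mean`, matching the
quasi-Poisson repeatability model exactly — or the *equivalence-class* route,
which distributes reads over classes and re-quantifies with EM plus
bootstrap/Gibbs. The direct route is used for the large calibration studies
(20 replicates of the 10 000-transcript configuration run in ~20 s); the EC
route exercises the quantifier end to end at smaller scale. Direct-route
resamples do not conserve per-sample totals (each is an independent
quasi-Poisson draw); EC-route resamples do, and that conservation is checked.

What the generator does *not* emulate: read sequences and alignment,
positional or GC bias, fragment-length effects, unbalanced fold changes,
correlated genes, or outlier samples. Passing calibration tests on these
simulations therefore demonstrates correctness of the statistical machinery
under its own assumptions, not robustness to real-data artifacts.

## Numerical choices

* IRLS: linear-predictor clamp at ±45, mean floor 1e-8, ridge 1e-10 on the
  normal equations, step-halving up to 12 times per iteration.
* Unit-deviance moment grid: 192 log-spaced means up to 5e4, exact summation
  of the NB pmf to the 1 - 1e-12 quantile at each grid point.
* Conditional tables: cached per (group size, dispersion); conditional
  variances clipped at 0; adjusted df capped at `N - p`.
* Common-dispersion search: bounded scalar minimization of the negative APL
  on the log scale over [1e-6, 5].
* Trend smoother: lowess with span 0.4, three robustness iterations.
* `d0` cap 1e6 (reported infinite beyond); F-test denominator df uses
  `min(d0, 1e6) + df*`.
* Ties in the false-discovery curve break by |logFC| descending then index,
  making curves reproducible.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  (input, seed) pairs give bit-identical resamples, simulations and results.

## Known limitations

* The RTA estimator assumes resamples are exchangeable within a sample;
  autocorrelated Gibbs chains with insufficient thinning would bias `tau~`
  downward.
* The conditional-exact deviance backend applies only to integer one-way
  data; the general backend retains a small (<2% above mean counts ~5,
  ~15% at mean 1) positive bias in raw quasi-dispersions that the abundance
  trend absorbs before testing.
* Only the common-NB-dispersion quasi-likelihood path is implemented; the
  legacy path with transcript-wise trended NB dispersions is out of scope.
* Gene-level aggregation, multi-factor designs beyond what a full-rank design
  matrix expresses, and comparisons against other DTE tools are out of scope.
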