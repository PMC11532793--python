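# dividedcounts

Differential transcript expression (DTE) from divided counts: estimate the
read-to-transcript-ambiguity (RTA) overdispersion of transcript-level RNA-seq
counts from bootstrap or Gibbs technical resamples, divide it out, and test
for differential expression with a bias-corrected quasi-likelihood
negative-binomial pipeline.

## Why

Lightweight quantifiers (Salmon, kallisto) assign reads to transcripts
probabilistically via equivalence classes, so transcript counts carry
technical overdispersion far beyond Poisson — by a factor `tau_t >= 1` that
varies over orders of magnitude between transcripts depending on gene
annotation topology. Under the quasi-Poisson repeatability model
`var(y_ti) = tau_t sigma2_t mu_ti`, `tau_t` is estimable from the B technical
resamples each quantifier can emit per library, pooled over all N samples
with residual degrees of freedom `N(B-1)`. Dividing the counts by the
estimate, `z_ti = y_ti / tau~_t`, restores the standard quasi-NB
mean-variance relationship

    var(z_ti) = sigma2_t (nu_ti + phi nu_ti^2)

so the scaled counts can be analysed exactly like gene-level counts: TMM
normalization, a common NB dispersion `phi` from the top 5% most expressed
transcripts, per-transcript GLMs with *moment-matched adjusted deviances*
(unbiased quasi-dispersion estimation even at very small counts), trended
empirical-Bayes squeezing of the quasi-dispersions `sigma2_t`, and quasi-F
tests with Benjamini–Hochberg FDR control.

The package is aimed at methodologists and pipeline developers who want a
self-contained, fully scriptable implementation of this approach, including:

* `ecquant` — a miniature equivalence-class quantifier (EM point estimation,
  multinomial bootstrap, uncollapsed Gibbs sampling), so the whole method is
  exercisable end to end without any aligner;
* `rta` — RTA-dispersion estimation, count division, and readers/writers for
  a `quant.sf`-style per-sample layout (plus a kallisto-style HDF5 reader);
* `dte` — filtering, TMM, common-dispersion estimation, adjusted-deviance NB
  GLMs, empirical-Bayes squeezing, quasi-F tests;
* `simulate` — a two-group count-level experiment generator (NB biological
  variation with abundance-dependent BCV, two-fold changes, alternating
  library sizes, gene/EC topologies that create ambiguity);
* `benchmark` — power, observed FDR, type-I error, false-discovery curves
  and resample-budget sweeps against simulation truth;
* a `dividedcounts` command-line interface wrapping the above.

## Worked example

Simulate a two-group experiment (4000 transcripts, 400 with a two-fold
change, 5 samples per group, 30 Gibbs-tagged resamples) and run the full
pipeline:

```python
import numpy as np
from dividedcounts import SimConfig, simulate_experiment, run_dte_pipeline
from dividedcounts.benchmark import observed_power_fdr

config = SimConfig(T=4000, n_de=400, n_per_group=5, B=30, seed=7)
exp = simulate_experiment(config, seed=7)
out = run_dte_pipeline(exp.counts, exp.resamples, exp.group)

res, keep = out["result"], out["keep"]
power, fdr = observed_power_fdr(res, exp.truth.is_de[keep])
print(f"median tau: {np.median(out['rta'].tau):.3f}")
print(f"tested: {keep.sum()}  phi: {out['phi']:.4f}  d0: {out['ql'].d0:.1f}")
print(f"DE calls at FDR 0.05: {(res.fdr <= 0.05).sum()}")
print(f"observed power: {power:.3f}  observed FDR: {fdr:.3f}")
print(out["table"].sort_values("PValue").head(3).to_string(index=False))
```

Output:

```
median tau: 1.109
tested: 2338  phi: 0.0555  d0: 37.5
DE calls at FDR 0.05: 81
observed power: 0.329  observed FDR: 0.037
    logFC    logCPM         F       PValue      FDR
-1.366792 12.262742 41.651788 6.310894e-08 0.000148
-1.328706 12.072010 32.045069 9.612821e-07 0.000872
 0.957847 15.676723 31.543204 1.119012e-06 0.000872
```

The median estimated RTA dispersion is 1.11 (70% of transcripts show some
ambiguity inflation), the common NB dispersion 0.056 corresponds to a BCV of
about 0.24, and the 81 calls at the nominal 5% FDR contain 3.7% false
discoveries — the error rate is controlled. Power is modest at this reduced
sequencing depth and rises quickly with samples per group.

The same analysis from the shell:

```sh
dividedcounts simulate --preset small_scale --seed 1 --out sim/
dividedcounts dte --quant-dir sim/ --design a,b,a,b,a,b,a,b,a,b --out results/
dividedcounts benchmark --preset small_scale --seed 1 --replicates 5 --out bench/
dividedcounts budget-sweep --preset small_scale --seed 1 -B 2,10,30 --out sweep/
```

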