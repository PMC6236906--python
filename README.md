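# hseghmm

Allele-specific somatic copy number alteration (SCNA) calling from paired
tumor/normal sequencing summaries.  `hseghmm` embeds per-locus logR (log2
tumor/normal depth ratio) and logOR (tumor-vs-normal allelic log odds ratio)
in a hidden Markov model over allele-specific genotype states, and jointly
estimates tumor purity, ploidy, and the per-locus genotype by EM.  A
heavy-tailed Student-t emission for logR (the `t` family) suppresses the
hypersegmentation that outlying observations cause under a normal emission
(the `normal` family); the squared logOR is modeled as a scaled noncentral
chi-square, and homozygous loci (no logOR) contribute through logR alone.

## Library overview

| module | contents |
| --- | --- |
| `hseghmm.state_space` | genotype states (default 12, from `0` to `AAAAA`), expected logR/logOR per state |
| `hseghmm.emission` | Student-t / normal logR densities, noncentral-χ²₁ logOR² density, joint emission matrix |
| `hseghmm.hmm_core` | scaled forward–backward, smoothed posteriors, posterior-mode and Viterbi decoding |
| `hseghmm.em_fit` | EM driver (closed-form chain M-step, L-BFGS-B global M-step), Hessian SEs, AIC/BIC |
| `hseghmm.simulate` | three ground-truth simulators (t-noise, normal-mixture noise, raw read counts) and the probability-of-identification metric |
| `hseghmm.io_cli` | TSV readers/writers, count-derived logR/logOR, thinning, segment BED output, CLI |

```python
import hseghmm as h

ds = h.simulate(h.SimConfig(n_loci=2000, seed=1))       # known ground truth
res = h.fit(ds.loci, ds.space_true, family="t")
res.globals.purity, res.globals.ploidy, res.aic          # fitted parameters
(res.decoded == ds.truth).mean()                         # decoding accuracy
```

## Command line

```bash
# fit a locus table (chrom  pos  logR  logOR  het; NA for missing logOR)
hseghmm fit --input loci.tsv --family t --out results/sample
# ... or raw allele counts (8-column TSV), thinned to every 10th locus
hseghmm fit --input counts.tsv --counts --thin 10 --out results/sample

# write replicate simulations, then fit them all and score identification
hseghmm simulate --scenario t --n 10000 --reps 20 --seed 1 --out sim/
hseghmm evaluate --dir sim/ --family t --out sim/accuracy.tsv
```

`fit` writes `<out>.params.json` (purity, ploidy, variance components,
degrees of freedom, SEs, log-likelihood, AIC/BIC), `<out>.profile.tsv`
(per-locus decoded genotype and copy numbers), `<out>.segments.bed`
(run-length-encoded 0-based half-open segments), `<out>.log` (iteration
trace), and optionally `<out>.posteriors.tsv`.  Defaults: the 12-state
space (`--states` for a restricted space such as `A,AB`), one chain across
all chromosomes (`--per-chrom` to restart at boundaries).

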