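# rtadte

Transcript-level RNA-seq quantifications are noisier than gene-level
counts because reads are often compatible with several isoforms of a gene.
`rtadte` estimates that read-to-transcript-ambiguity (RTA) overdispersion
from the bootstrap resamples emitted by lightweight quantifiers
(Salmon/kallisto), divides it out of the counts, and runs a
quasi-negative-binomial differential-transcript-expression (DTE) pipeline
on the scaled counts. A synthetic-data module generates quantifier-like
experiments with known ground-truth overdispersion so every stage is
testable offline.

## What it does

1. **quant_io** — read Salmon directories (`quant.sf`,
   `aux_info/bootstrap/bootstraps.gz`), kallisto `abundance.h5`, or a plain
   TSV dialect into a `QuantBundle`; write fixture directories in both
   quantifier dialects (round-trip exact).
2. **rta** — per-transcript quasi-Poisson overdispersion from bootstrap
   counts (Pearson-residual moment estimator, `d_t = sum_i (B_i - 1)`),
   empirical-Bayes moderation toward a shared prior (prior df 3, clamped at
   1), and count scaling `z = y / sigma2_tilde` (fold changes preserved
   exactly, fractional counts never rounded).
3. **prep** — expression filtering (CPM rule with group-aware sample
   threshold) and trimmed-mean-of-M-values (TMM) normalization.
4. **nbglm** — continuous-NB GLM fits with trended dispersion,
   quasi-likelihood F-tests with empirical-Bayes squeezing of the
   quasi-dispersions, BH-adjusted p-values, BCV diagnostics, and the full
   `run_dte` pipeline (identical code path for scaled vs raw counts).
5. **simulate** — class-level generative model: gamma expression, NB
   replicate counts, equivalence-class multinomial bootstraps with
   correlated probabilistic re-assignment, brute-force ground-truth
   overdispersion, null/DE scenario builders and power/FDR/type-I scoring.
6. **cli** — `rtadte` subcommands tying the stages together with
   provenance sidecars.

## CLI

```sh
# simulate a DE experiment as Salmon-dialect sample directories
rtadte simulate --scenario de --n-per-group 5 --seed 1 -o sim/

# estimate and moderate RTA overdispersions
rtadte estimate --salmon sim/sample1 --salmon sim/sample2 ... -o overdisp.tsv

# full DTE pipeline (add --no-scale to run on raw counts)
rtadte dte --salmon sim/sample1 ... --design sim/design.tsv \
       --contrast g2-g1 -o results.tsv

# score a run against simulation truth
rtadte score --results results.tsv --truth sim/truth.tsv
```

Other subcommands: `scale` (write scaled counts), `prep` (filter + TMM
factors), `bcv` (dispersion diagnostics, optional `--plot`).

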