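# clonaltiming

Molecular timing of somatic copy-number gains, clonal mutation-rate
estimation, and a Bayesian waiting-time model of cancer age incidence.

The package implements, as a tested pipeline with fully synthetic inputs:

- **`synthetic`** — ground-truth generators: multi-region mutation tables
  under a clone tree with a timed arm gain, allele-specific copy-number
  profiles, incidence cohorts from a gamma + exponential + gamma waiting-time
  model, and breakpoint clusters (chromothripsis-like or sequential).
- **`ccf`** — VAF → mutation-copies-per-cell conversion
  (`vaf·(p·CN_t + (1−p)·CN_n)/p`), pre/post-gain classification of mutations
  in a single-copy-gained region, and cross-sample consensus voting.
- **`subclones`** — truncated stick-breaking Dirichlet-process clustering of
  mutations on cancer cell fraction (Binomial read emission, low-CCF
  sensitivity adjustment), pigeonhole ordering of clusters into a clone
  tree, and root-to-leaf branch burdens.
- **`rate_model`** — no-intercept random-slope mixed model for mutations per
  year (REML via statsmodels), shrunken per-patient slopes, a
  quadratic-in-age sensitivity comparison, and a parametric-bootstrap CI.
- **`gain_timing`** — age of a clonal single-copy gain by two methods
  (fraction of clonal molecular time, `π = 3·n_pre/(2·n_pre + n_single)`,
  and directly from the pre-gain count with region/genome-size correction),
  MRCA age, and parametric-bootstrap CIs.
- **`driver_rate`** — per-cell per-year driver mutation rate for a coding
  sequence: 96-class trinucleotide spectrum → per-site class rates,
  exhaustive CDS substitution enumeration with protein consequences, driver
  summation, and an indel rate from the cohort indel:substitution slope.
- **`incidence`** — Gibbs/Metropolis-Hastings sampler for the
  three-waiting-time age-incidence model (Dirichlet split proposals for
  uncensored individuals, rejection sampling for censored ones, MH updates
  of the gamma shape/rate pairs against their conjugate prior, exact
  conjugate λ updates), the derived precursor clone size ν = λ/μ, and
  intervention counterfactual incidence curves for a clone-size fraction ρ.
- **`hallmarks`** — chromothripsis hallmark statistics: orientation
  uniformity of rearrangement joins (χ² against the uniform 4-class
  multinomial) and two-state copy-number oscillation, combined into a
  rule-based classifier.

## CLI

```sh
clonaltiming simulate --out-dir sim --seed 1           # synthetic inputs
clonaltiming fit-clones --mutations sim/mutations.tsv \
    --cn-segments sim/cn_segments.tsv --out-dir clones
clonaltiming fit-rate --burdens burdens.tsv --out rate_model.json
clonaltiming time-gains --mutations sim/mutations.tsv \
    --cn-segments sim/cn_segments.tsv --rate-model rate_model.json \
    --region 5:0-133000000 --clonal-burden 3480 --out timings.tsv
clonaltiming driver-rate --cds-fasta cds.fa --driver-set drivers.tsv \
    --spectrum spectrum.tsv --context-counts contexts.tsv \
    --total-rate 87 --out rates.json
clonaltiming fit-incidence --incidence sim/incidence.csv \
    --timing-ages ages.txt --mu 2.1e-6 --out-dir fit
clonaltiming intervene --draws fit/draws.csv --mu 2.1e-6 --rho 0.5 \
    --out curves.csv
clonaltiming hallmarks --breakpoints breakpoints.tsv --cn-track cn.tsv \
    --out report.json
```

All tables are plain TSV/CSV with 0-based half-open coordinates; formats are
documented in `clonaltiming.io`.

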