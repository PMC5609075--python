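# bayesr

Hybrid EM+MCMC Bayesian mixture-model ("Bayes R"-style) genomic prediction
for multi-breed panels, with scheduled dropping of low-posterior-inclusion
variants and split-and-merge per-chromosome analysis strategies.  A
synthetic-data module generates multi-breed genotype panels, QTL
architectures, phenotypes and MAF-dependent imputation errors so the whole
pipeline is testable end to end without any external data.

## What is implemented

- **`bayesr.simdata`** — multi-breed haplotype/genotype simulation
  (founder-copying generator with tunable F_ST, plus a coalescent-backed
  generator via `msprime` for realistic shared LD), three-class QTL
  sampling (default 3485/500/15 with effect variances 1e-4/1e-3/1e-2 of
  the additive genetic variance), TBV computation, phenotype simulation at
  a target within-breed heritability with per-breed effects, allele-error
  injection with `e = r / sqrt(MAF)`, MAF filtering and annotation-tiered
  LD pruning (NSC > REG > HD > OTHER).
- **`bayesr.pedigree`** — pedigree sorting and the numerator relationship
  matrix `A` (Henderson's tabular method) for the polygenic term.
- **`bayesr.model`** — the core engine: `y = Xb + Za + Wv + e` with a
  four-class normal-mixture prior on variant effects (`gamma = [0, 1e-4,
  1e-3, 1e-2] * sigma_g2`, `P ~ Dirichlet(alpha)`), weighted residuals, a
  monotone mean-field EM warm start, a Gibbs sampler (no burn-in),
  per-variant posterior inclusion probabilities, and scheduled dropping
  with Dirichlet pseudo-count prior compensation.
- **`bayesr.strategies`** — scenario orchestration: `HD_FULL`, `S_FULL`,
  `S_CHR` (per-chromosome analysis against phenotypes corrected by
  HD-estimated effects of the other chromosomes), `S_KEPT` (genome-wide
  re-analysis of the retained variants with the prior passed from an
  earlier run) and `S_KEPT_HD` (retained variants plus the HD panel).
- **`bayesr.evaluation`** — GEBV prediction, accuracy (Pearson, per
  group), bias (regression slope), and the imputation-error sensitivity
  experiment over a grid of `r` values and target populations.
- **`bayesr.fileio` / `bayesr.cli`** — PLINK `.bed/.bim/.fam` read/write
  (variant-major), dosage-matrix text, phenotype/pedigree/annotation CSV,
  YAML run configs (unknown keys are errors) and run manifests with input
  hashes.

## CLI

```sh
bayesr simulate --config sim.yaml --out-prefix out/toy --seed 3
bayesr fit      --config run.yaml --out-prefix out/fit1
bayesr pipeline --scenario S_KEPT_D0.9 --config run.yaml --out-prefix out/run1
bayesr predict  --genotypes out/toy --effects out/run1.S_KEPT.effects.csv --out gebv.csv
bayesr evaluate --gebv gebv.csv --truth out/toy.trait.csv --out report.json
```

Scenario labels follow the `<data>_<analysis>_D<drop>` convention, e.g.
`HD_FULL_D0`, `S_FULL_D0.9`, `S_CHR_D0.7`, `S_KEPT_D0.9`,
`S+HD_KEPT+HD_D0.9`.  Example run config keys: `genotypes`, `phenotypes`,
`annotations`, `validation_file`, `n_iter`, `drop_point`, `h2_prior`,
`prior_from`, `seed` (see `bayesr/fileio.py` for the full schema).

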