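# icmeth

A toolkit for building and applying a DNA-methylation predictor of
intrinsic capacity (IC) — the composite of cognition, locomotion,
psychological well-being, sensory ability and vitality — and for the
downstream analyses that such a predictor supports: age-trend statistics,
cell-type deconvolution, transcriptome association, mortality models and
health screens. Because the cohorts this kind of analysis targets are
controlled-access, the package ships a first-class synthetic-data
generator with ground-truth labels so every stage is testable offline.

## What's inside

| module | purpose |
| --- | --- |
| `icmeth.simulate` | synthetic cohorts, methylomes, expression, cell mixtures and proportional-hazards survival, with ground truth |
| `icmeth.score` | composite IC score: domain rescaling, sensory averaging, z-transform, min-max normalization, complete-case rule |
| `icmeth.trends` | Spearman correlations with t-approximated p, Wilcoxon rank-sum sex tests (exact for small groups), continuous two-phase (hinge) regression for age of decline |
| `icmeth.clock` | 0.05-bin training filter, ten-fold cross-validated elastic net over an alpha grid (MAE metric), three-criterion rank-sum model selection, linear-clock prediction, age acceleration, quintile groups |
| `icmeth.deconvolution` | constrained projection of betas onto a cell-type reference (simplex-constrained least squares) |
| `icmeth.association` | per-gene linear models, Benjamini-Hochberg FDR, CpG-gene permutation linkage test, hypergeometric over-representation, one-signed preranked GSEA |
| `icmeth.survival` | Cox proportional hazards per s.d. of acceleration (Efron ties, via lifelines), Kaplan-Meier, log-rank, restricted-mean survival contrasts |
| `icmeth.health` | overall-health PC1 with an anchored sign convention, logistic associations with extreme predictor groups, Spearman lifestyle screens |
| `icmeth.io` / `icmeth.cli` / `icmeth.pipeline` | delimited-text formats (CpG-first-column matrices, GMT, coefficient files), the `icmeth` CLI and the end-to-end pipeline with a deterministic manifest |

## CLI

Every stage is a subcommand; `run` chains them on synthetic data:

```sh
icmeth simulate --outdir out/sim --seed 1
icmeth score    --cohort out/sim/cohort.csv --out out/scores.csv
icmeth trends   --scores out/scores.csv --cohort out/sim/cohort.csv --out out/trends.csv
icmeth train    --betas out/sim/betas.csv --scores out/scores.csv \
                --out out/model.csv --seed 1
icmeth predict  --model out/model.csv --betas out/sim/betas.csv --out out/pred.csv
icmeth deconvolve --betas out/sim/betas.csv --reference out/sim/reference.csv \
                  --out out/props.csv
icmeth run --config config.yaml --outdir out/full --seed 1
```

Beta matrices are CSV with the CpG identifier as the first column and one
column per sample. Clock coefficient files are `cpg,weight` CSVs with an
`(Intercept)` row, so externally published linear clocks can be applied
with `icmeth predict` unchanged (use `--impute-mean` to fill missing
model CpGs from stored training means).

A minimal pipeline config:

```yaml
seed: 1
simulate: {n_participants: 400, n_cpgs: 1000}
clock: {folds: 10, n_lambdas: 50}
associate: {n_perm: 1000}
survival: {tau: 20}
health: {}
```

Running `icmeth run` twice with the same config and seed produces
byte-identical outputs and manifest.

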