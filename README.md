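# modae

Multi-task deconfounding autoencoder for joint modelling of patient-tumour
and cancer cell-line expression profiles.

A single encoder maps both domains into a partitioned latent space (shared
indices plus patient-private and cell-line-private indices).  A Wasserstein
critic with gradient penalty adversarially removes the domain difference
from the shared coordinates, while two supervised heads train on top of
them: a deep Cox survival head (Efron tie correction, log-sum-exp
stabilized, event-normalized) for patients and a masked multi-output
drug-sensitivity regression head (AAC targets, missing entries excluded
from the loss) for cell-lines.  Training alternates autoencoder/multi-task
epochs with critic epochs over domain-balanced oversampled mini-batches.

The networks run on a small, self-contained reverse-mode autodiff engine
(`modae.autodiff`, numpy-only, supports the double backprop needed by the
gradient penalty), so no deep-learning framework is required.

## Layout

| module | contents |
|---|---|
| `modae.synthetic` | synthetic paired cohorts with shared latent factors, domain shift, survival and drug layers |
| `modae.data` | table I/O, gene filtering (mean log-expression ≥ 1.0 in both datasets), per-dataset standardization, 3000-day follow-up cap, survival-stratified folds (10 time quantiles × event) |
| `modae.autodiff` / `modae.networks` | tensor engine; encoder/decoder/critic/survival/drug SELU MLPs, latent partition and masking |
| `modae.losses` | reconstruction, adversarial, deconfounding, gradient penalty, Efron Cox partial log-likelihood, masked drug MSE, weighted multi-task sum |
| `modae.training` | Adam (critic betas 0/0.9), balanced mini-batching, staged schedule 300/100/100/300 epochs with 5 critic epochs per epoch, checkpointing |
| `modae.evaluation` | Harrell C-index, per-drug R² and its 90th percentile, linear-SVM domain AUROC, Pareto fronts, risk-tertile transfer, drug-target dysregulation screen |
| `modae.baselines` | elastic-net Cox and per-drug elastic-net regression on univariate top-k or PCA features, nested-CV grid search |
| `modae.search` | 100-iteration random hyper-parameter search with multi-objective bookkeeping and composite-score selection |
| `modae.cli` | `modae` command-line interface |
| `modae.bench` | self-contained synthetic benchmark used by the test-suite |

## CLI

All stages write a manifest (config snapshot, input digests, seeds) into the
output directory.  Expression inputs are expected on the log2(TPM+1) scale.

```sh
# generate a synthetic paired cohort
modae simulate --out runs/sim --seed 1 --n-patients 300 --n-celllines 300

# filter, standardize, cap follow-up, assign stratified folds
modae preprocess --patients runs/sim/patients_expression.tsv \
    --celllines runs/sim/celllines_expression.tsv \
    --survival runs/sim/survival.tsv --out runs/prep

# staged training (pre-training + joint), then evaluation
modae train --config config.yaml --workdir runs/sim --out runs/model
modae evaluate --config config.yaml --workdir runs/sim \
    --checkpoint runs/model --out runs/eval

# random hyper-parameter search (use --budget small for a quick pass)
modae search --config config.yaml --workdir runs/sim --out runs/search \
    --budget small --seed 1

# downstream: risk tertiles transferred from a discovery cohort,
# and the drug-target dysregulation screen
modae stratify --discovery-risk disc_risk.tsv --new-risk val_risk.tsv --out groups.tsv
modae dysregulation --expression runs/sim/patients_expression.tsv \
    --checkpoint runs/model --drug-targets targets.tsv --out dys.tsv
```

A config file (YAML or JSON) has four sections — `inputs`, `network`,
`schedule`, `loss_weights` — mirroring `NetworkConfig`, `TrainingSchedule`
and `LossWeights`; see `tests/test_cli.py` for a complete example.

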