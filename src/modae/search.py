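"""Random hyper-parameter search with multi-objective bookkeeping.

Each trial draws learning rates, regularization, dropout, widths, latent
dimensions, and loss weights; trains the full staged schedule per fold; and
records C-index, 90th-percentile drug R², and linear-SVM domain AUROC.  The
composite score is cindex + r2_q90 - auroc, and the selected trial is always
a member of the Pareto front over mean per-metric values.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .data import FoldAssignment
from .evaluation import (
    EvaluationReport,
    domain_auroc,
    harrell_cindex,
    pareto_front,
    per_drug_r2,
    r2_quantile90,
)
from .losses import LossWeights
from .networks import NetworkConfig, extract_shared
from .training import TrainingData, TrainingSchedule, run_full_training

__all__ = [
    "SearchSpace",
    "SearchTrial",
    "sample_trials",
    "run_search",
    "select_best",
    "evaluate_modules",
    "small_budget_space",
]


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    lr_bounds: tuple = (1e-5, 1e-3)
    critic_lr_bounds: tuple = (1e-5, 1e-3)
    l2_bounds: tuple = (1e-6, 1e-2)
    dropout_bounds: tuple = (0.0, 0.3)
    alpha_bounds: tuple = (1e-2, 1e2)
    width_choices: tuple = (64, 128, 256, 512)
    latent_choices: tuple = (32, 64, 128)
    shared_fraction_choices: tuple = (0.25, 0.5, 0.75)
    batch_choices: tuple = (64, 128, 256)
    n_iterations: int = 100
    # epochs are part of the schedule, not searched
    epochs: tuple = (300, 100, 100, 300)
    n_adv_per_ae: int = 5


def small_budget_space(epochs=(5, 5, 5, 5)) -> SearchSpace:
    """Reduced preset for CI-scale runs (10 trials, few epochs, small nets)."""
    return SearchSpace(
        width_choices=(16, 32),
        latent_choices=(8, 16),
        batch_choices=(64, 128),
        n_iterations=10,
        epochs=epochs,
    )


@dataclasses.dataclass
class SearchTrial:
    trial_id: int
    params: dict
    fold_reports: list = dataclasses.field(default_factory=list)
    val_reports: list = dataclasses.field(default_factory=list)  # nested mode only
    failed: bool = False
    error: str | None = None

    @property
    def mean_composite(self) -> float:
        if self.failed or not self.fold_reports:
            return -np.inf
        return float(np.mean([r.composite for r in self.fold_reports]))

    def mean_metrics(self):
        return (
            float(np.mean([r.cindex for r in self.fold_reports])),
            float(np.mean([r.r2_q90 for r in self.fold_reports])),
            float(np.mean([r.domain_auroc for r in self.fold_reports])),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "trial_id": self.trial_id,
                "params": self.params,
                "fold_reports": [r.to_dict() for r in self.fold_reports],
                "failed": self.failed,
                "error": self.error,
                "mean_composite": None if self.failed else self.mean_composite,
            }
        )


def _loguniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def trial_seed(search_seed: int, trial_id: int) -> int:
    """Stable per-trial seed so results are independent of execution order."""
    return int(np.random.SeedSequence([search_seed, trial_id]).generate_state(1)[0])


def sample_trials(space: SearchSpace, n: int | None = None, seed: int = 0) -> list:
    """Draw n independent, serializable parameter settings."""
    if n is None:
        n = space.n_iterations
    draws = []
    for t in range(n):
        rng = np.random.default_rng(trial_seed(seed, t))
        p = int(rng.choice(space.latent_choices))
        q = max(1, int(round(float(rng.choice(space.shared_fraction_choices)) * p)))
        params = {
            "learning_rate": _loguniform(rng, *space.lr_bounds),
            "critic_learning_rate": _loguniform(rng, *space.critic_lr_bounds),
            "l2": _loguniform(rng, *space.l2_bounds),
            "dropout": float(rng.uniform(*space.dropout_bounds)),
            "alpha1": _loguniform(rng, *space.alpha_bounds),
            "alpha2": _loguniform(rng, *space.alpha_bounds),
            "alpha3": _loguniform(rng, *space.alpha_bounds),
            "alpha4": _loguniform(rng, *space.alpha_bounds),
            "width": int(rng.choice(space.width_choices)),
            "latent_dim": p,
            "shared_dim": q,
            "batch_size": int(rng.choice(space.batch_choices)),
            "seed": trial_seed(seed, t),
        }
        draws.append(params)
    return draws


def _configs_from_params(params: dict, input_dim: int, n_drugs: int, n_covariates: int, epochs, n_adv):
    w = params["width"]
    config = NetworkConfig(
        input_dim=input_dim,
        latent_dim=params["latent_dim"],
        shared_dim=params["shared_dim"],
        encoder_hidden=(w, w),
        decoder_hidden=(w, w),
        critic_hidden=(w // 2 or 1, w // 2 or 1),
        survival_hidden=(w // 2 or 1, w // 2 or 1),
        drug_hidden=(w // 2 or 1, w // 2 or 1),
        dropout=params["dropout"],
        l2=params["l2"],
        n_drugs=n_drugs,
        n_covariates=n_covariates,
    )
    schedule = TrainingSchedule(
        pretrain_dc_epochs=epochs[0],
        pretrain_surv_epochs=epochs[1],
        pretrain_drug_epochs=epochs[2],
        joint_epochs=epochs[3],
        n_adv_per_ae=n_adv,
        batch_size=params["batch_size"],
        learning_rate=params["learning_rate"],
        critic_learning_rate=params["critic_learning_rate"],
        seed=params["seed"],
    )
    weights = LossWeights(
        params["alpha1"], params["alpha2"], params["alpha3"], params["alpha4"]
    )
    return config, schedule, weights


def evaluate_modules(
    modules, data: TrainingData, test_patients, test_celllines, seed=0, drug_cols=None
) -> EvaluationReport:
    """Compute the three selection metrics for a trained model on held-out indices."""
    from .networks import predict_drugs, predict_risk

    tp = np.asarray(test_patients)
    tc = np.asarray(test_celllines)
    cov = None if data.covariates is None else data.covariates[tp]
    g = predict_risk(data.patients.values[tp], cov, modules).data
    ci = harrell_cindex(g, data.survival.time[tp], data.survival.event[tp])

    cols = np.arange(len(data.drugs.drug_ids)) if drug_cols is None else np.asarray(drug_cols)
    r_hat = predict_drugs(data.celllines.values[tc], modules).data
    r2 = per_drug_r2(
        r_hat,
        data.drugs.values[np.ix_(tc, cols)],
        data.drugs.observed_mask[np.ix_(tc, cols)],
    )
    q90 = r2_quantile90(r2)

    # deconfounding is scored on the test split when it is large enough for
    # the cross-validated SVM, otherwise on all samples
    ap, ac = (tp, tc) if min(len(tp), len(tc)) >= 10 else (
        np.arange(data.patients.n_samples), np.arange(data.celllines.n_samples)
    )
    zs_p = extract_shared(modules.encoder(data.patients.values[ap]).data, modules.partition)
    zs_c = extract_shared(modules.encoder(data.celllines.values[ac]).data, modules.partition)
    auroc = domain_auroc(zs_p, zs_c, seed=seed)
    return EvaluationReport(ci, r2, q90, auroc)


def run_search(
    trials: list,
    data: TrainingData,
    folds: FoldAssignment,
    mode: str = "flat",
    epochs=(5, 5, 5, 5),
    n_adv_per_ae: int = 5,
    cellline_folds: FoldAssignment | None = None,
) -> list:
    """Train and evaluate every trial across CV folds.

    flat: each trial is trained on the training split of every fold and
    scored on the test split (selection then uses mean CV performance).
    nested: within each outer fold, one training fold is held out for
    validation; the outer test split is scored with the validation winner's
    settings (here: same trained model, validation used only for selection
    bookkeeping inside :func:`select_best_nested`).
    """
    if mode not in ("flat", "nested"):
        raise ValueError("mode must be 'flat' or 'nested'")
    results = []
    n_cl = data.celllines.n_samples
    for t, params in enumerate(trials):
        trial = SearchTrial(trial_id=t, params=params)
        try:
            rng_cl = np.random.default_rng(params["seed"])
            cl_fold = (
                cellline_folds.fold_id
                if cellline_folds is not None
                else rng_cl.integers(1, folds.n_folds + 1, size=n_cl)
            )
            for f in range(1, folds.n_folds + 1):
                tr_p, te_p = folds.split(f)
                val_p = None
                if mode == "nested":
                    # hold one training fold out of fitting, score it for selection
                    val_fold = f % folds.n_folds + 1
                    val_p = np.where(folds.fold_id == val_fold)[0]
                    tr_p = np.where((folds.fold_id != f) & (folds.fold_id != val_fold))[0]
                tr_c = np.where(cl_fold != f)[0]
                te_c = np.where(cl_fold == f)[0]
                sub_drugs, kept_cols = _subset_drugs(data.drugs, tr_c)
                sub = TrainingData(
                    patients=_subset_omics(data.patients, tr_p),
                    celllines=_subset_omics(data.celllines, tr_c),
                    survival=data.survival.subset(tr_p),
                    drugs=sub_drugs,
                )
                config, schedule, weights = _configs_from_params(
                    params,
                    data.patients.n_genes,
                    0 if sub_drugs is None else len(sub_drugs.drug_ids),
                    data.survival.n_covariates,
                    epochs,
                    n_adv_per_ae,
                )
                state = run_full_training(config, schedule, weights, sub)
                report = evaluate_modules(
                    state.modules, data, te_p, te_c,
                    seed=params["seed"] % (2**31), drug_cols=kept_cols,
                )
                trial.fold_reports.append(report)
                if mode == "nested":
                    trial.val_reports.append(
                        evaluate_modules(
                            state.modules, data, val_p, te_c,
                            seed=params["seed"] % (2**31), drug_cols=kept_cols,
                        )
                    )
        except (FloatingPointError, ValueError, ArithmeticError) as e:
            trial.failed = True
            trial.error = f"{type(e).__name__}: {e}"
        results.append(trial)
    return sorted(results, key=lambda t: -t.mean_composite)


def _subset_omics(m, idx):
    from .data import OmicsMatrix

    idx = np.asarray(idx)
    return OmicsMatrix(
        m.values[idx], [m.sample_ids[i] for i in idx], list(m.gene_ids), m.domain[idx]
    )


def _subset_drugs(d, idx):
    """Row-subset a drug matrix, dropping drugs left without observations.

    Returns (matrix, kept column indices)."""
    if d is None:
        return None, None
    from .data import DrugResponseMatrix

    idx = np.asarray(idx)
    keep = np.where(d.observed_mask[idx].any(axis=0))[0]
    return (
        DrugResponseMatrix(
            d.values[np.ix_(idx, keep)],
            d.observed_mask[np.ix_(idx, keep)],
            [d.sample_ids[i] for i in idx],
            [d.drug_ids[j] for j in keep],
        ),
        keep,
    )


def select_best(trials: list) -> SearchTrial:
    """Highest mean composite among successful trials; ties break on trial id."""
    ok = [t for t in trials if not t.failed and t.fold_reports]
    if not ok:
        raise ValueError("no successful trials to select from")
    best = max(ok, key=lambda t: (t.mean_composite, -t.trial_id))
    # bookkeeping check: the argmax of a monotone aggregate must be Pareto-optimal
    points = [t.mean_metrics() for t in ok]
    front = pareto_front(points, directions=("max", "max", "min"))
    if ok.index(best) not in front:
        raise AssertionError("selected trial is not on the Pareto front (bookkeeping bug)")
    return best


def select_best_nested(trials: list) -> dict:
    """Per outer fold, pick the trial with the best validation composite and
    report that trial's outer-test metrics (nested-mode selection)."""
    ok = [t for t in trials if not t.failed and t.val_reports]
    if not ok:
        raise ValueError("no successful nested trials to select from")
    n_folds = len(ok[0].fold_reports)
    winners, test_composites = [], []
    for f in range(n_folds):
        best = max(ok, key=lambda t: (t.val_reports[f].composite, -t.trial_id))
        winners.append(best.trial_id)
        test_composites.append(best.fold_reports[f].composite)
    return {
        "winners_per_fold": winners,
        "test_composites": test_composites,
        "mean_test_composite": float(np.mean(test_composites)),
    }


def write_trials_jsonl(trials: list, path) -> None:
    with open(path, "w") as fh:
        for t in trials:
            fh.write(t.to_json() + "\n")
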