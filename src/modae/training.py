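"""Staged multi-task training.

Implements the training procedure: deconfounding-autoencoder pre-training
with alternating critic epochs, survival and drug head pre-training, and the
joint multi-task phase, all over domain-balanced oversampled mini-batches.
The critic uses Adam with betas (0, 0.9); everything else uses Adam with the
default momenta.  L2 regularization is applied to all weight matrices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, tsum
from .data import DrugResponseMatrix, OmicsMatrix, SurvivalRecordSet
from .losses import (
    LossWeights,
    adversarial_loss,
    build_efron_grouping,
    deconfounding_loss,
    efron_cox_loglik,
    gradient_penalty,
    masked_drug_loss,
    mtl_loss,
    reconstruction_loss,
)
from .networks import (
    ModuleSet,
    NetworkConfig,
    build_modules,
    extract_shared,
    latent_mask,
    load_checkpoint,
    save_checkpoint,
)

__all__ = [
    "TrainingSchedule",
    "TrainingState",
    "TrainingData",
    "Adam",
    "make_balanced_minibatches",
    "critic_epoch",
    "pretrain_deconfounding",
    "pretrain_survival",
    "pretrain_drugs",
    "train_joint",
    "run_full_training",
    "save_state",
    "load_state",
    "write_loss_history",
]


@dataclasses.dataclass(frozen=True)
class TrainingSchedule:
    pretrain_dc_epochs: int = 300
    pretrain_surv_epochs: int = 100
    pretrain_drug_epochs: int = 100
    joint_epochs: int = 300
    n_adv_per_ae: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    critic_learning_rate: float = 1e-3
    adam_betas: tuple = (0.9, 0.999)
    critic_adam_betas: tuple = (0.0, 0.9)
    lambda_gp: float = 10.0
    freeze_encoder_in_pretrain: bool = False
    pretrain_plain_ae_epochs: int = 0  # plain AE warm-up; off by default
    seed: int = 0

    def __post_init__(self):
        for name in ("pretrain_dc_epochs", "pretrain_surv_epochs",
                     "pretrain_drug_epochs", "joint_epochs",
                     "pretrain_plain_ae_epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_adv_per_ae < 1:
            raise ValueError("n_adv_per_ae must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclasses.dataclass
class TrainingData:
    patients: OmicsMatrix
    celllines: OmicsMatrix
    survival: SurvivalRecordSet
    drugs: DrugResponseMatrix | None = None

    def __post_init__(self):
        if self.survival.sample_ids != self.patients.sample_ids:
            raise ValueError("survival records must align 1:1 with patient samples")
        if self.drugs is not None and self.drugs.sample_ids != self.celllines.sample_ids:
            raise ValueError("drug matrix must align 1:1 with cell-line samples")

    @property
    def covariates(self):
        return self.survival.covariates


class Adam:
    """Adam on raw parameter arrays; optional decoupled L2 on weight matrices."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, l2=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = float(l2)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = np.asarray(g, dtype=np.float64)
            if not g.any():
                continue  # parameter untouched by this loss: no decay either
            if self.l2 and p.data.ndim == 2:  # weights, not biases
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_arrays(self):
        out = {"t": np.array(self.t)}
        for i in range(len(self.params)):
            out[f"m{i}"] = self.m[i]
            out[f"v{i}"] = self.v[i]
        return out

    def load_state_arrays(self, arrays):
        self.t = int(arrays["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(arrays[f"m{i}"])
            self.v[i] = np.asarray(arrays[f"v{i}"])


@dataclasses.dataclass
class TrainingState:
    modules: ModuleSet
    schedule: TrainingSchedule
    weights: LossWeights
    rng: np.random.Generator
    optimizers: dict
    epoch: int = 0
    history: list = dataclasses.field(default_factory=list)

    def record(self, phase: str, **losses):
        row = {"epoch": self.epoch, "phase": phase}
        for key in ("l_rec", "l_adv", "l_dc", "l_surv", "l_drug", "l_mtl"):
            row[key] = losses.get(key, np.nan)
        for k, v in losses.items():
            # nan marks a component absent from this phase; inf is a bug
            if v is not None and np.isinf(v):
                raise FloatingPointError(f"infinite loss {k} recorded in phase {phase}")
        self.history.append(row)


def init_state(
    config: NetworkConfig,
    schedule: TrainingSchedule,
    weights: LossWeights | None = None,
) -> TrainingState:
    modules = build_modules(config, seed=schedule.seed)
    rng = np.random.default_rng(schedule.seed + 1)
    opts = _make_optimizers(modules, schedule)
    return TrainingState(modules, schedule, weights or LossWeights(), rng, opts)


def _make_optimizers(modules: ModuleSet, schedule: TrainingSchedule) -> dict:
    l2 = modules.config.l2
    opts = {}
    for name, mod in modules.named_modules().items():
        if name == "critic":
            opts[name] = Adam(
                mod.parameters,
                schedule.critic_learning_rate,
                betas=schedule.critic_adam_betas,
                l2=l2,
            )
        else:
            opts[name] = Adam(
                mod.parameters, schedule.learning_rate, betas=schedule.adam_betas, l2=l2
            )
    return opts


# -- batching ------------------------------------------------------------


def make_balanced_minibatches(n_patients, n_celllines, batch_size, seed):
    """Paired index batches with equal counts from both domains.

    The larger dataset is shuffled and partitioned once (no replacement);
    the smaller is resampled with replacement to match each chunk.  When the
    two sizes are equal both sides are partitioned.  ``seed`` may be an int
    or a ``numpy.random.Generator``.
    """
    if n_patients < 1 or n_celllines < 1:
        raise ValueError("both domains need at least one sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm_p = rng.permutation(n_patients)
    perm_c = rng.permutation(n_celllines)
    n_big = max(n_patients, n_celllines)
    n_batches = -(-n_big // batch_size)
    batches = []
    for b in range(n_batches):
        lo, hi = b * batch_size, min((b + 1) * batch_size, n_big)
        size = hi - lo
        if n_patients == n_celllines:
            p_idx, c_idx = perm_p[lo:hi], perm_c[lo:hi]
        elif n_patients > n_celllines:
            p_idx = perm_p[lo:hi]
            c_idx = rng.choice(n_celllines, size=size, replace=True)
        else:
            c_idx = perm_c[lo:hi]
            p_idx = rng.choice(n_patients, size=size, replace=True)
        batches.append((p_idx, c_idx))
    return batches


def _grads(loss: Tensor, params):
    gs = ad.grad(loss, params)
    return [g.data for g in gs]


# -- critic --------------------------------------------------------------


def critic_epoch(state: TrainingState, data: TrainingData) -> TrainingState:
    """One critic epoch: adversarial loss + gradient penalty, critic-only updates."""
    sch = state.schedule
    mods = state.modules
    batches = make_balanced_minibatches(
        data.patients.n_samples, data.celllines.n_samples, sch.batch_size, state.rng
    )
    adv_vals = []
    for p_idx, c_idx in batches:
        xp = data.patients.values[p_idx]
        xc = data.celllines.values[c_idx]
        zp = extract_shared(mods.encoder(xp), mods.partition).detach()
        zc = extract_shared(mods.encoder(xc), mods.partition).detach()
        z_all = ad.concatenate([zp, zc], axis=0)
        s = np.concatenate([np.zeros(len(p_idx)), np.ones(len(c_idx))])
        c_out = mods.critic(z_all, train=True, rng=state.rng)
        l_adv = adversarial_loss(c_out, s)
        gp = gradient_penalty(mods.critic, zp, zc, sch.lambda_gp, rng=state.rng)
        loss = l_adv + gp
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite critic loss")
        params = mods.critic.parameters
        state.optimizers["critic"].step(_grads(loss, params))
        adv_vals.append(float(l_adv.data))
    state.record("critic", l_adv=float(np.mean(adv_vals)))
    return state


# -- pre-training phases -------------------------------------------------


def _ae_epoch(state: TrainingState, data: TrainingData, alpha1, alpha2, phase: str):
    """One autoencoder epoch minimizing a1*L_rec + a2*L_dc over balanced batches."""
    sch, mods = state.schedule, state.modules
    batches = make_balanced_minibatches(
        data.patients.n_samples, data.celllines.n_samples, sch.batch_size, state.rng
    )
    recs, dcs = [], []
    for p_idx, c_idx in batches:
        xp, xc = data.patients.values[p_idx], data.celllines.values[c_idx]
        x = np.concatenate([xp, xc], axis=0)
        s = np.concatenate([np.zeros(len(p_idx)), np.ones(len(c_idx))])
        z = mods.encoder(x, train=True, rng=state.rng)
        x_hat = mods.decoder(latent_mask(z, s, mods.partition), train=True, rng=state.rng)
        l_rec = reconstruction_loss(Tensor(x), x_hat)
        loss = l_rec * Tensor(float(alpha1))
        l_dc_val = np.nan
        if alpha2 > 0:
            zs_c = extract_shared(z, mods.partition)[np.where(s == 1)[0].tolist()]
            c_out = mods.critic(zs_c)  # critic frozen; gradients flow into encoder
            l_dc = deconfounding_loss(c_out, np.ones(len(c_idx)))
            loss = loss + l_dc * Tensor(float(alpha2))
            l_dc_val = float(l_dc.data)
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite autoencoder loss")
        params = mods.encoder.parameters + mods.decoder.parameters
        grads = _grads(loss, params)
        ne = len(mods.encoder.parameters)
        state.optimizers["encoder"].step(grads[:ne])
        state.optimizers["decoder"].step(grads[ne:])
        recs.append(float(l_rec.data))
        dcs.append(l_dc_val)
    state.record(phase, l_rec=float(np.mean(recs)),
                 l_dc=float(np.mean(dcs)) if alpha2 > 0 else np.nan)


def pretrain_deconfounding(state: TrainingState, data: TrainingData) -> TrainingState:
    """Alternate deconfounding-AE epochs with ``n_adv_per_ae`` critic epochs."""
    sch = state.schedule
    w = state.weights
    for _ in range(sch.pretrain_plain_ae_epochs):
        _ae_epoch(state, data, w.alpha1, 0.0, "pretrain_ae")
        state.epoch += 1
    for _ in range(sch.pretrain_dc_epochs):
        _ae_epoch(state, data, w.alpha1, w.alpha2, "pretrain_dc")
        for _ in range(sch.n_adv_per_ae):
            critic_epoch(state, data)
        state.epoch += 1
    return state


def _plain_batches(n, batch_size, rng):
    perm = rng.permutation(n)
    return [perm[i : i + batch_size] for i in range(0, n, batch_size)]


def pretrain_survival(state: TrainingState, data: TrainingData) -> TrainingState:
    """Minimize the negative Efron log-likelihood on patient batches."""
    sch, mods = state.schedule, state.modules
    if data.survival.event.sum() == 0:
        raise ValueError("survival pre-training requires at least one event")
    update_encoder = not sch.freeze_encoder_in_pretrain
    for _ in range(sch.pretrain_surv_epochs):
        vals = []
        for idx in _plain_batches(data.patients.n_samples, sch.batch_size, state.rng):
            ev = data.survival.event[idx]
            if ev.sum() == 0:
                continue
            loss = _survival_batch_loss(state, data, idx)
            vals.append(float(loss.data))
            _step_heads(state, loss, ("survival",), update_encoder)
        state.record("pretrain_surv", l_surv=float(np.mean(vals)))
        state.epoch += 1
    return state


def _survival_batch_loss(state, data, idx):
    mods = state.modules
    x = data.patients.values[idx]
    cov = None if data.covariates is None else data.covariates[idx]
    from .networks import predict_risk

    g = predict_risk(x, cov, mods, train=True, rng=state.rng)
    grouping = build_efron_grouping(data.survival.time[idx], data.survival.event[idx])
    return -efron_cox_loglik(g, grouping)


def _step_heads(state, loss, head_names, update_encoder):
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite loss in pre-training")
    mods = state.modules
    groups = list(head_names) + (["encoder"] if update_encoder else [])
    params, bounds = [], []
    for name in groups:
        ps = mods.named_modules()[name].parameters
        bounds.append((name, len(params), len(params) + len(ps)))
        params.extend(ps)
    grads = _grads(loss, params)
    for name, lo, hi in bounds:
        state.optimizers[name].step(grads[lo:hi])


def pretrain_drugs(state: TrainingState, data: TrainingData) -> TrainingState:
    """Minimize the masked drug MSE on cell-line batches."""
    sch, mods = state.schedule, state.modules
    if data.drugs is None or data.drugs.n_observed == 0:
        raise ValueError("drug pre-training requires an observed drug matrix")
    update_encoder = not sch.freeze_encoder_in_pretrain
    from .networks import predict_drugs

    for _ in range(sch.pretrain_drug_epochs):
        vals = []
        for idx in _plain_batches(data.celllines.n_samples, sch.batch_size, state.rng):
            mask = data.drugs.observed_mask[idx]
            if not mask.any():
                continue
            r_hat = predict_drugs(
                data.celllines.values[idx], mods, train=True, rng=state.rng
            )
            loss = masked_drug_loss(r_hat, Tensor(data.drugs.values[idx]), mask)
            vals.append(float(loss.data))
            _step_heads(state, loss, ("drug",), update_encoder)
        state.record("pretrain_drug", l_drug=float(np.mean(vals)))
        state.epoch += 1
    return state


# -- joint phase ---------------------------------------------------------


def train_joint(state: TrainingState, data: TrainingData) -> TrainingState:
    """Joint multi-task epochs, each followed by ``n_adv_per_ae`` critic epochs."""
    sch, mods, w = state.schedule, state.modules, state.weights
    from .networks import predict_drugs  # noqa: F401  (kept close for readers)

    for _ in range(sch.joint_epochs):
        batches = make_balanced_minibatches(
            data.patients.n_samples, data.celllines.n_samples, sch.batch_size, state.rng
        )
        comps = {k: [] for k in ("l_rec", "l_dc", "l_surv", "l_drug", "l_mtl")}
        for p_idx, c_idx in batches:
            losses = _joint_batch_losses(state, data, p_idx, c_idx)
            l_mtl = mtl_loss(
                losses["l_rec"], losses["l_dc"], losses["l_surv"], losses["l_drug"], w
            )
            params, bounds = [], []
            for name in ("survival", "drug", "decoder", "encoder"):
                ps = mods.named_modules()[name].parameters
                bounds.append((name, len(params), len(params) + len(ps)))
                params.extend(ps)
            grads = _grads(l_mtl, params)
            for name, lo, hi in bounds:
                state.optimizers[name].step(grads[lo:hi])
            for key in comps:
                comps[key].append(float(getattr(losses.get(key), "data", losses.get(key, np.nan)))
                                  if key != "l_mtl" else float(l_mtl.data))
        state.record("joint", **{k: float(np.nanmean(v)) for k, v in comps.items()})
        for _ in range(sch.n_adv_per_ae):
            critic_epoch(state, data)
        state.epoch += 1
    return state


def _joint_batch_losses(state: TrainingState, data: TrainingData, p_idx, c_idx):
    mods = state.modules
    xp, xc = data.patients.values[p_idx], data.celllines.values[c_idx]
    x = np.concatenate([xp, xc], axis=0)
    s = np.concatenate([np.zeros(len(p_idx)), np.ones(len(c_idx))])
    z = mods.encoder(x, train=True, rng=state.rng)
    x_hat = mods.decoder(latent_mask(z, s, mods.partition), train=True, rng=state.rng)
    l_rec = reconstruction_loss(Tensor(x), x_hat)

    zs = extract_shared(z, mods.partition)
    cl_rows = np.where(s == 1)[0].tolist()
    c_out = mods.critic(zs[cl_rows])
    l_dc = deconfounding_loss(c_out, np.ones(len(cl_rows)))

    # survival on the patient half; covariates appended to shared embedding
    zs_p = zs[np.where(s == 0)[0].tolist()]
    if data.covariates is not None:
        feats = ad.concatenate([zs_p, Tensor(data.covariates[p_idx])], axis=1)
    else:
        feats = zs_p
    g = mods.survival(feats, train=True, rng=state.rng)
    ev = data.survival.event[p_idx]
    if ev.sum() > 0:
        grouping = build_efron_grouping(data.survival.time[p_idx], ev)
        l_surv = -efron_cox_loglik(g.reshape(g.data.size), grouping)
    else:  # no events in this batch: survival term contributes nothing
        l_surv = Tensor(0.0)

    zs_c = zs[cl_rows]
    if data.drugs is not None and data.drugs.observed_mask[c_idx].any():
        r_hat = mods.drug(zs_c, train=True, rng=state.rng)
        l_drug = masked_drug_loss(
            r_hat, Tensor(data.drugs.values[c_idx]), data.drugs.observed_mask[c_idx]
        )
    else:  # all entries missing in this batch: skip the drug term
        l_drug = Tensor(0.0)
    return {"l_rec": l_rec, "l_dc": l_dc, "l_surv": l_surv, "l_drug": l_drug}


def run_full_training(
    config: NetworkConfig,
    schedule: TrainingSchedule,
    weights: LossWeights,
    data: TrainingData,
) -> TrainingState:
    """Full staged schedule: deconfounding -> survival -> drugs -> joint."""
    state = init_state(config, schedule, weights)
    pretrain_deconfounding(state, data)
    if schedule.pretrain_surv_epochs:
        pretrain_survival(state, data)
    if schedule.pretrain_drug_epochs and data.drugs is not None:
        pretrain_drugs(state, data)
    train_joint(state, data)
    return state


# -- persistence ---------------------------------------------------------


def write_loss_history(state: TrainingState, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "phase", "l_rec", "l_adv", "l_dc", "l_surv", "l_drug", "l_mtl"]
        )
        writer.writeheader()
        for row in state.history:
            writer.writerow(row)


def save_state(state: TrainingState, outdir) -> Path:
    out = Path(outdir)
    save_checkpoint(state.modules, out)
    opt_arrays = {}
    for name, opt in state.optimizers.items():
        for key, arr in opt.state_arrays().items():
            opt_arrays[f"{name}.{key}"] = arr
    np.savez(out / "optimizer.npz", **opt_arrays)
    meta = {
        "schedule": dataclasses.asdict(state.schedule),
        "loss_weights": dataclasses.asdict(state.weights),
        "epoch": state.epoch,
        "rng_state": state.rng.bit_generator.state,
        "history": state.history,
    }
    (out / "training_state.json").write_text(json.dumps(meta, indent=2, default=float))
    return out


def load_state(indir) -> TrainingState:
    indir = Path(indir)
    modules = load_checkpoint(indir)
    meta = json.loads((indir / "training_state.json").read_text())
    sched_dict = meta["schedule"]
    for key in ("adam_betas", "critic_adam_betas"):
        sched_dict[key] = tuple(sched_dict[key])
    schedule = TrainingSchedule(**sched_dict)
    weights = LossWeights(**meta["loss_weights"])
    rng = np.random.default_rng(0)
    rng_state = meta["rng_state"]
    if "state" in rng_state and isinstance(rng_state["state"], dict):
        rng_state["state"] = {k: int(v) for k, v in rng_state["state"].items()}
    rng.bit_generator.state = rng_state
    opts = _make_optimizers(modules, schedule)
    with np.load(indir / "optimizer.npz") as npz:
        for name, opt in opts.items():
            arrays = {
                key.split(".", 1)[1]: npz[key]
                for key in npz.files
                if key.startswith(name + ".")
            }
            opt.load_state_arrays(arrays)
    state = TrainingState(modules, schedule, weights, rng, opts, epoch=meta["epoch"])
    state.history = [
        {k: (v if isinstance(v, str) else float(v)) for k, v in row.items()}
        for row in meta["history"]
    ]
    return state
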