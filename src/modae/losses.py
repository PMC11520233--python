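"""Training objectives: reconstruction, adversarial / deconfounding,
gradient penalty, Efron-corrected Cox partial log-likelihood, masked drug
regression, and the weighted multi-task sum.

Every function accepts plain numpy arrays (returning floats) or autodiff
Tensors (returning Tensors), so the same code serves tests and training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor, exp, log, logsumexp, mul, power, sqrt, sub, tmean, tsum

__all__ = [
    "LossWeights",
    "EfronGrouping",
    "reconstruction_loss",
    "adversarial_loss",
    "deconfounding_loss",
    "gradient_penalty",
    "build_efron_grouping",
    "efron_cox_loglik",
    "masked_drug_loss",
    "mtl_loss",
]


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Task weights: alpha1 reconstruction, alpha2 deconfounding,
    alpha3 survival (negative log-likelihood), alpha4 drugs."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 1.0
    alpha4: float = 1.0

    def __post_init__(self):
        vals = (self.alpha1, self.alpha2, self.alpha3, self.alpha4)
        if not np.all(np.isfinite(vals)) or any(v < 0 for v in vals):
            raise ValueError("loss weights must be finite and non-negative")


def _ret(value, *inputs):
    """Return a Tensor if any input was one, else a float."""
    if any(isinstance(x, Tensor) for x in inputs):
        return value
    return float(value.data)


def reconstruction_loss(x, x_hat):
    """Mean squared reconstruction error normalized by n*d.

    The 1/d factor keeps the scale comparable to the other objectives.
    """
    xt, ht = astensor(x), astensor(x_hat)
    if xt.shape != ht.shape:
        raise ValueError(f"shape mismatch: x {xt.shape} vs x_hat {ht.shape}")
    n, d = xt.shape if xt.ndim == 2 else (1, xt.shape[0])
    diff = sub(ht, xt)
    out = mul(tsum(power(diff, 2.0)), Tensor(1.0 / (n * d)))
    return _ret(out, x, x_hat)


def adversarial_loss(critic_values, s):
    """(1/n) * sum_i C_i * (1 - 2 s_i) — the critic's Wasserstein objective."""
    c = astensor(critic_values)
    c = c.reshape(c.data.size)
    sv = np.asarray(getattr(s, "data", s), dtype=float).reshape(-1)
    if sv.shape[0] != c.shape[0]:
        raise ValueError("critic values and domain indicators differ in length")
    out = tmean(mul(c, Tensor(1.0 - 2.0 * sv)))
    return _ret(out, critic_values)


def deconfounding_loss(critic_values, s):
    """Mean critic value over cell-line samples only."""
    c = astensor(critic_values)
    c = c.reshape(c.data.size)
    sv = np.asarray(getattr(s, "data", s), dtype=float).reshape(-1)
    n_cl = sv.sum()
    if n_cl < 1:
        raise ValueError("deconfounding loss needs at least one cell-line in the batch")
    out = mul(tsum(mul(c, Tensor(sv))), Tensor(1.0 / n_cl))
    return _ret(out, critic_values)


def gradient_penalty(
    critic,
    z_patient,
    z_cellline,
    lambda_gp: float = 10.0,
    rng: np.random.Generator | None = None,
):
    """WGAN-GP penalty: lambda * E[(||grad C(z_hat)|| - 1)^2] on interpolates.

    Interpolation points lie between paired patient and cell-line shared
    embeddings; batch sizes are trimmed to the smaller one.  Returns a
    Tensor on the critic's tape so it can be minimized directly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    zp = np.asarray(getattr(z_patient, "data", z_patient), dtype=float)
    zc = np.asarray(getattr(z_cellline, "data", z_cellline), dtype=float)
    n = min(zp.shape[0], zc.shape[0])
    zp, zc = zp[:n], zc[:n]
    u = rng.uniform(size=(n, 1))
    z_hat = Tensor(u * zp + (1.0 - u) * zc, requires_grad=True)
    c_out = critic(z_hat)
    (g,) = ad.grad(tsum(c_out), [z_hat])
    norms = sqrt(tsum(power(g, 2.0), axis=1))
    penalty = mul(tmean(power(sub(norms, Tensor(1.0)), 2.0)), Tensor(float(lambda_gp)))
    return penalty


@dataclasses.dataclass
class EfronGrouping:
    """Tied-event structure for the Efron partial likelihood.

    ``event_times`` are the unique event times; ``tied_sets[i]`` holds the
    indices with an event at that time; ``risk_sets[i]`` all indices with
    follow-up >= that time.
    """

    event_times: np.ndarray
    tied_sets: list
    risk_sets: list
    n_events: int


def build_efron_grouping(time, event) -> EfronGrouping:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be binary")
    if e.sum() == 0:
        raise ValueError("partial likelihood undefined without any events")
    uniq = np.unique(t[e == 1])
    tied, risk = [], []
    for ti in uniq:
        tied.append(np.where((t == ti) & (e == 1))[0])
        risk.append(np.where(t >= ti)[0])
    return EfronGrouping(uniq, tied, risk, int(e.sum()))


def efron_cox_loglik(g, grouping: EfronGrouping):
    """Efron-corrected Cox partial log-likelihood, averaged over events.

    Computed with log-sum-exp stabilization; larger is better.  Training
    minimizes the negation of this value.
    """
    gt = astensor(g)
    gt = gt.reshape(gt.data.size)
    if not np.all(np.isfinite(gt.data)):
        raise ValueError("risk scores must be finite")
    total = Tensor(0.0)
    for tied, risk in zip(grouping.tied_sets, grouping.risk_sets):
        g_tied = gt[list(tied)]
        g_risk = gt[list(risk)]
        total = total + tsum(g_tied)
        lse_risk = logsumexp(g_risk)
        m = len(tied)
        if m == 1:
            total = sub(total, lse_risk)
        else:
            lse_tied = logsumexp(g_tied)
            for ell in range(m):
                # ln(sum_risk e^g - (l/m) sum_tied e^g), stabilized:
                # lse_risk + ln(1 - (l/m) e^{lse_tied - lse_risk})
                frac = mul(Tensor(float(ell) / m), exp(sub(lse_tied, lse_risk)))
                total = sub(total, lse_risk + log(sub(Tensor(1.0), frac)))
    out = mul(total, Tensor(1.0 / grouping.n_events))
    return _ret(out, g)


def masked_drug_loss(r_hat, r, mask):
    """Mean squared error over observed entries only."""
    ht, rt = astensor(r_hat), astensor(r)
    m = np.asarray(mask, dtype=bool)
    if ht.shape != rt.shape or m.shape != rt.shape:
        raise ValueError("prediction, target and mask shapes must agree")
    n_obs = int(m.sum())
    if n_obs == 0:
        raise ValueError("no observed drug entries in the batch")
    diff = mul(sub(ht, rt), Tensor(m.astype(float)))
    out = mul(tsum(power(diff, 2.0)), Tensor(1.0 / n_obs))
    return _ret(out, r_hat, r)


def mtl_loss(l_rec, l_dc, l_surv_negloglik, l_drug, w: LossWeights):
    """Weighted multi-task sum: a1*rec + a2*dc + a3*(-loglik) + a4*drug."""
    comps = {
        "reconstruction": l_rec,
        "deconfounding": l_dc,
        "survival": l_surv_negloglik,
        "drug": l_drug,
    }
    for name, c in comps.items():
        val = getattr(c, "data", c)
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite {name} loss component")
    out = (
        mul(astensor(l_rec), Tensor(w.alpha1))
        + mul(astensor(l_dc), Tensor(w.alpha2))
        + mul(astensor(l_surv_negloglik), Tensor(w.alpha3))
        + mul(astensor(l_drug), Tensor(w.alpha4))
    )
    return _ret(out, l_rec, l_dc, l_surv_negloglik, l_drug)
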