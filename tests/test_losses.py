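"""Loss functions against hand arithmetic and independent oracles."""

import itertools

import numpy as np
import pytest

from modae import autodiff as ad
from modae.autodiff import Tensor
from modae.losses import (
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


# -- independent oracle: standard Cox partial log-likelihood ------------


def cox_loglik_bruteforce(g, time, event):
    """Breslow/standard partial likelihood by direct enumeration (no ties)."""
    total = 0.0
    for i in np.where(np.asarray(event) == 1)[0]:
        risk = [j for j in range(len(g)) if time[j] >= time[i]]
        total += g[i] - np.log(np.sum(np.exp([g[j] for j in risk])))
    return total / int(np.sum(event))


# -- reconstruction ------------------------------------------------------


def test_reconstruction_zero_when_equal():
    x = np.random.default_rng(0).normal(size=(3, 4))
    assert reconstruction_loss(x, x) == 0.0


def test_reconstruction_hand_case():
    assert reconstruction_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])) == 0.5


def test_reconstruction_padding_halves():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(4, 3))
    xh = rng.normal(size=(4, 3))
    base = reconstruction_loss(x, xh)
    pad = rng.normal(size=(4, 3))
    x2 = np.hstack([x, pad])
    xh2 = np.hstack([xh, pad])  # extra columns perfectly reconstructed
    assert np.isclose(reconstruction_loss(x2, xh2), base / 2)


def test_reconstruction_shape_mismatch():
    with pytest.raises(ValueError):
        reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))


# -- adversarial / deconfounding ----------------------------------------


def test_adversarial_balanced_constant_zero():
    assert adversarial_loss(np.full(4, 3.0), np.array([0, 0, 1, 1])) == 0.0


def test_adversarial_hand_case():
    assert adversarial_loss(np.array([2.0, 3.0]), np.array([0, 1])) == -0.5


def test_adversarial_all_patients_constant():
    assert adversarial_loss(np.full(3, 1.7), np.zeros(3)) == pytest.approx(1.7)


def test_deconfounding_all_celllines_constant():
    assert deconfounding_loss(np.full(5, 2.5), np.ones(5)) == pytest.approx(2.5)


def test_deconfounding_ignores_patients():
    assert deconfounding_loss(np.array([4.0, 100.0]), np.array([1, 0])) == 4.0


def test_deconfounding_no_celllines_errors():
    with pytest.raises(ValueError):
        deconfounding_loss(np.ones(3), np.zeros(3))


def test_deconfounding_adversarial_identity():
    """L_dc = -(n / sum(s)) * cell-line term of L_adv, checked numerically."""
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = rng.integers(2, 30)
        s = rng.integers(0, 2, n)
        if s.sum() == 0:
            s[0] = 1
        c = rng.normal(size=n)
        cl_term = np.mean(c * (1 - 2 * s) * (s == 1))  # cell-line part of L_adv
        assert np.isclose(deconfounding_loss(c, s), -(n / s.sum()) * cl_term)


# -- gradient penalty ----------------------------------------------------


class _LinearCritic:
    def __init__(self, weight):
        self.w = Tensor(np.asarray(weight, dtype=float).reshape(-1, 1), requires_grad=True)

    def __call__(self, z, **kw):
        return ad.matmul(z, self.w)


class _ConstantCritic:
    def __call__(self, z, **kw):
        return ad.mul(ad.tsum(z, axis=1, keepdims=True), Tensor(0.0)) + Tensor(5.0)


@pytest.mark.parametrize("wnorm,expected", [(0.0, 10.0), (1.0, 0.0), (2.0, 10.0)])
def test_gradient_penalty_linear_closed_form(wnorm, expected):
    rng = np.random.default_rng(3)
    critic = _LinearCritic([wnorm, 0.0, 0.0])
    gp = gradient_penalty(critic, rng.normal(size=(6, 3)), rng.normal(size=(6, 3)), 10.0, rng=rng)
    assert abs(float(gp.data) - expected) < 1e-6


def test_gradient_penalty_constant_critic():
    rng = np.random.default_rng(4)
    gp = gradient_penalty(_ConstantCritic(), rng.normal(size=(4, 2)), rng.normal(size=(4, 2)), 7.0, rng=rng)
    assert float(gp.data) == pytest.approx(7.0)


def test_gradient_penalty_nonnegative_and_trims():
    rng = np.random.default_rng(5)
    critic = _LinearCritic(rng.normal(size=4))
    gp = gradient_penalty(critic, rng.normal(size=(3, 4)), rng.normal(size=(8, 4)), 10.0, rng=rng)
    assert float(gp.data) >= 0.0


def test_gradient_penalty_differentiable_wrt_critic():
    rng = np.random.default_rng(6)
    critic = _LinearCritic([2.0, 0.0])
    gp = gradient_penalty(critic, rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), 10.0, rng=rng)
    (g,) = ad.grad(gp, [critic.w])
    # d/dw of 10 (|w| - 1)^2 = 20 (|w| - 1) * w/|w| -> (20, 0) at w=(2, 0)
    assert np.allclose(g.data.ravel(), [20.0, 0.0], atol=1e-8)


# -- Efron grouping ------------------------------------------------------


def test_grouping_ties_and_risk_sets():
    grp = build_efron_grouping([5.0, 5.0, 3.0], [1, 1, 0])
    assert len(grp.event_times) == 1 and grp.event_times[0] == 5.0
    assert sorted(grp.tied_sets[0]) == [0, 1]
    assert sorted(grp.risk_sets[0]) == [0, 1]  # censored at 3 is not at risk at 5


def test_grouping_unique_events():
    grp = build_efron_grouping([1.0, 2.0, 3.0], [1, 1, 1])
    assert all(len(h) == 1 for h in grp.tied_sets)


def test_grouping_all_censored_errors():
    with pytest.raises(ValueError):
        build_efron_grouping([1.0, 2.0], [0, 0])


# -- Efron partial log-likelihood ---------------------------------------


def test_efron_two_at_risk_one_event():
    grp = build_efron_grouping([1.0, 2.0], [1, 0])
    assert efron_cox_loglik(np.zeros(2), grp) == pytest.approx(-np.log(2), abs=1e-12)


def test_efron_tied_pair_hand_case():
    grp = build_efron_grouping([1.0, 1.0, 2.0], [1, 1, 0])
    assert efron_cox_loglik(np.zeros(3), grp) == pytest.approx(-np.log(6) / 2, abs=1e-12)


def test_efron_matches_bruteforce_no_ties():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = rng.integers(2, 9)
        time = rng.permutation(np.arange(1.0, n + 1))  # distinct times
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[rng.integers(n)] = 1
        g = rng.normal(size=n)
        grp = build_efron_grouping(time, event)
        assert efron_cox_loglik(g, grp) == pytest.approx(
            cox_loglik_bruteforce(g, time, event), abs=1e-9
        )


def test_efron_shift_invariance():
    rng = np.random.default_rng(8)
    g = rng.normal(size=6)
    grp = build_efron_grouping([1, 2, 2, 3, 4, 5.0], [1, 1, 1, 0, 1, 0])
    assert efron_cox_loglik(g, grp) == pytest.approx(efron_cox_loglik(g + 3.7, grp))


def test_efron_logsumexp_large_shift():
    rng = np.random.default_rng(9)
    g = rng.normal(size=10)
    time = rng.permutation(np.arange(1.0, 11))
    event = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
    grp = build_efron_grouping(time, event)
    assert abs(efron_cox_loglik(g + 1000, grp) - efron_cox_loglik(g, grp)) < 1e-6


def test_efron_nonfinite_scores_error():
    grp = build_efron_grouping([1.0, 2.0], [1, 0])
    with pytest.raises(ValueError):
        efron_cox_loglik(np.array([np.inf, 0.0]), grp)


def test_efron_gradient_matches_numeric():
    rng = np.random.default_rng(10)
    g = rng.normal(size=5)
    grp = build_efron_grouping([1, 2, 2, 3, 4.0], [1, 1, 1, 0, 1])
    gt = Tensor(g, requires_grad=True)
    (grad_g,) = ad.grad(efron_cox_loglik(gt, grp), [gt])
    eps = 1e-6
    num = np.zeros(5)
    for i in range(5):
        gp, gm = g.copy(), g.copy()
        gp[i] += eps
        gm[i] -= eps
        num[i] = (efron_cox_loglik(gp, grp) - efron_cox_loglik(gm, grp)) / (2 * eps)
    assert np.allclose(grad_g.data, num, atol=1e-5)


# -- masked drug loss ----------------------------------------------------


def test_masked_loss_ignores_unobserved():
    r = np.array([[1.0, 99.0], [0.0, 1.0]])
    mask = np.array([[True, False], [True, True]])
    r_hat = r.copy()
    r_hat[0, 1] = -123.0  # arbitrary at masked position
    assert masked_drug_loss(r_hat, r, mask) == 0.0


def test_masked_loss_hand_case():
    r = np.array([[1.0, 0.0], [0.0, 1.0]])
    mask = np.array([[True, False], [True, True]])
    r_hat = np.full((2, 2), 0.5)
    assert masked_drug_loss(r_hat, r, mask) == pytest.approx(0.25)


def test_masked_loss_full_mask_is_mse():
    rng = np.random.default_rng(11)
    r = rng.uniform(size=(4, 3))
    r_hat = rng.uniform(size=(4, 3))
    full = np.ones((4, 3), dtype=bool)
    assert masked_drug_loss(r_hat, r, full) == pytest.approx(np.mean((r_hat - r) ** 2))


def test_masked_loss_empty_mask_errors():
    with pytest.raises(ValueError):
        masked_drug_loss(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2), dtype=bool))


def test_masked_loss_invariance_random():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n, m = rng.integers(1, 6, 2)
        mask = rng.integers(0, 2, (n, m)).astype(bool)
        if not mask.any():
            mask[0, 0] = True
        r = rng.normal(size=(n, m))
        rh = rng.normal(size=(n, m))
        base = masked_drug_loss(rh, r, mask)
        rh2 = rh.copy()
        rh2[~mask] = rng.normal(size=(~mask).sum()) * 100
        assert masked_drug_loss(rh2, r, mask) == pytest.approx(base)


# -- multi-task sum ------------------------------------------------------


def test_mtl_all_zero_weights():
    assert mtl_loss(1.0, 2.0, 3.0, 4.0, LossWeights(0, 0, 0, 0)) == 0.0


def test_mtl_one_hot():
    assert mtl_loss(0.7, 9, 9, 9, LossWeights(1, 0, 0, 0)) == pytest.approx(0.7)


def test_mtl_hand_case():
    out = mtl_loss(0.2, -0.3, 0.4, 99.0, LossWeights(0.5, 1.0, 2.0, 0.0))
    assert out == pytest.approx(0.6)


def test_mtl_nonfinite_named():
    with pytest.raises(ValueError, match="survival"):
        mtl_loss(0.0, 0.0, np.nan, 0.0, LossWeights())


def test_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha1=-1.0)
    with pytest.raises(ValueError):
        LossWeights(alpha2=np.inf)
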