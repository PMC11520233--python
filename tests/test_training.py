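"""Batching, staged training phases, determinism, and persistence."""

import copy
import dataclasses

import numpy as np
import pytest

from modae.data import standardize
from modae.losses import LossWeights
from modae.networks import NetworkConfig
from modae.synthetic import SyntheticConfig, generate_cohorts
from modae.training import (
    TrainingData,
    TrainingSchedule,
    critic_epoch,
    init_state,
    load_state,
    make_balanced_minibatches,
    pretrain_deconfounding,
    pretrain_drugs,
    pretrain_survival,
    save_state,
    train_joint,
    write_loss_history,
)


def _weights_snapshot(modules):
    return {
        name: [w.data.copy() for w in mod.parameters]
        for name, mod in modules.named_modules().items()
    }


def _weights_equal(a, b):
    return all(
        all(np.array_equal(x, y) for x, y in zip(a[k], b[k])) for k in a
    )


def _toy_data(seed=0, n_p=60, n_c=50, genes=12, drugs=4):
    co = generate_cohorts(
        SyntheticConfig(n_patients=n_p, n_celllines=n_c, n_genes=genes, n_drugs=drugs, seed=seed)
    )
    p, stats = standardize(co.patients)
    c, _ = standardize(co.celllines, stats)
    return TrainingData(p, c, co.survival, co.drugs), co


def _toy_config(genes=12, drugs=4, **kw):
    defaults = dict(
        input_dim=genes, latent_dim=6, shared_dim=3,
        encoder_hidden=(16,), decoder_hidden=(16,), critic_hidden=(8,),
        survival_hidden=(8,), drug_hidden=(8,), dropout=0.1, l2=1e-4, n_drugs=drugs,
    )
    defaults.update(kw)
    return NetworkConfig(**defaults)


def _toy_schedule(**kw):
    defaults = dict(
        pretrain_dc_epochs=2, pretrain_surv_epochs=2, pretrain_drug_epochs=2,
        joint_epochs=2, n_adv_per_ae=2, batch_size=32, seed=0,
    )
    defaults.update(kw)
    return TrainingSchedule(**defaults)


# -- schedule ------------------------------------------------------------


def test_schedule_defaults_match_protocol():
    sch = TrainingSchedule()
    assert sch.pretrain_dc_epochs == 300
    assert sch.pretrain_surv_epochs == 100
    assert sch.pretrain_drug_epochs == 100
    assert sch.joint_epochs == 300
    assert sch.n_adv_per_ae == 5
    assert sch.critic_adam_betas == (0.0, 0.9)


def test_schedule_validation():
    with pytest.raises(ValueError):
        TrainingSchedule(n_adv_per_ae=0)
    with pytest.raises(ValueError):
        TrainingSchedule(batch_size=1)
    with pytest.raises(ValueError):
        TrainingSchedule(joint_epochs=-1)


# -- balanced minibatches ------------------------------------------------


def test_batches_equal_sizes_no_oversampling():
    batches = make_balanced_minibatches(100, 100, 20, seed=0)
    assert len(batches) == 5
    p_all = np.concatenate([b[0] for b in batches])
    c_all = np.concatenate([b[1] for b in batches])
    assert sorted(p_all) == list(range(100))
    assert sorted(c_all) == list(range(100))


def test_batches_oversampling_smaller_domain():
    batches = make_balanced_minibatches(100, 30, 20, seed=1)
    assert len(batches) == 5
    p_all = np.concatenate([b[0] for b in batches])
    c_all = np.concatenate([b[1] for b in batches])
    assert sorted(p_all) == list(range(100))  # larger side: each exactly once
    assert len(c_all) == 100  # smaller side: drawn with replacement
    assert set(c_all) <= set(range(30))
    for p_idx, c_idx in batches:
        assert len(p_idx) == len(c_idx)


def test_batches_deterministic():
    a = make_balanced_minibatches(50, 20, 16, seed=7)
    b = make_balanced_minibatches(50, 20, 16, seed=7)
    for (pa, ca), (pb, cb) in zip(a, b):
        assert np.array_equal(pa, pb) and np.array_equal(ca, cb)


# -- critic epoch --------------------------------------------------------


def test_critic_epoch_updates_only_critic():
    data, _ = _toy_data()
    state = init_state(_toy_config(), _toy_schedule())
    before = _weights_snapshot(state.modules)
    critic_epoch(state, data)
    after = _weights_snapshot(state.modules)
    assert not _weights_equal({"critic": before["critic"]}, {"critic": after["critic"]})
    for name in ("encoder", "decoder", "survival", "drug"):
        assert _weights_equal({name: before[name]}, {name: after[name]})


def test_critic_zero_lr_unchanged():
    data, _ = _toy_data()
    state = init_state(_toy_config(), _toy_schedule(critic_learning_rate=0.0))
    before = _weights_snapshot(state.modules)
    critic_epoch(state, data)
    assert _weights_equal(before, _weights_snapshot(state.modules))


def test_critic_learns_to_separate():
    """On well-separated embeddings the adversarial loss decreases."""
    data, _ = _toy_data()
    # plant a strong offset so shared embeddings differ between domains
    data.celllines.values += 4.0
    state = init_state(_toy_config(), _toy_schedule())
    critic_epoch(state, data)
    first = state.history[-1]["l_adv"]
    for _ in range(10):
        critic_epoch(state, data)
    assert state.history[-1]["l_adv"] < first


# -- pre-training phases -------------------------------------------------


def test_zero_epochs_no_op():
    data, _ = _toy_data()
    sch = _toy_schedule(pretrain_dc_epochs=0, pretrain_surv_epochs=0, pretrain_drug_epochs=0)
    state = init_state(_toy_config(), sch)
    before = _weights_snapshot(state.modules)
    pretrain_deconfounding(state, data)
    pretrain_survival(state, data)
    pretrain_drugs(state, data)
    assert _weights_equal(before, _weights_snapshot(state.modules))
    assert state.epoch == 0


def test_plain_ae_reconstruction_decreases():
    data, _ = _toy_data()
    sch = _toy_schedule(pretrain_dc_epochs=20)
    state = init_state(_toy_config(dropout=0.0), sch)
    state.weights = LossWeights(1.0, 0.0, 0.0, 0.0)  # alpha2=0: plain autoencoder
    pretrain_deconfounding(state, data)
    recs = [r["l_rec"] for r in state.history if r["phase"] == "pretrain_dc"]
    assert np.mean(recs[-5:]) < np.mean(recs[:5])


def test_survival_pretraining_without_events_errors():
    data, _ = _toy_data()
    data.survival.event[:] = 0
    state = init_state(_toy_config(), _toy_schedule())
    with pytest.raises(ValueError):
        pretrain_survival(state, data)


def test_drug_pretraining_requires_drugs():
    data, _ = _toy_data()
    data = TrainingData(data.patients, data.celllines, data.survival, None)
    state = init_state(_toy_config(), _toy_schedule())
    with pytest.raises(ValueError):
        pretrain_drugs(state, data)


def test_survival_pretraining_fits_training_data():
    from modae.evaluation import harrell_cindex
    from modae.networks import predict_risk

    data, co = _toy_data(seed=4, n_p=120, genes=15)
    sch = _toy_schedule(pretrain_surv_epochs=60, batch_size=64)
    state = init_state(_toy_config(genes=15, dropout=0.0), sch)
    pretrain_survival(state, data)
    g = predict_risk(data.patients.values, None, state.modules).data
    ci = harrell_cindex(g, data.survival.time, data.survival.event)
    assert ci > 0.6


def test_drug_pretraining_fits_training_data():
    from modae.evaluation import per_drug_r2
    from modae.networks import predict_drugs

    data, co = _toy_data(seed=5, n_c=100, genes=15)
    sch = _toy_schedule(pretrain_drug_epochs=60, batch_size=32, learning_rate=5e-3)
    state = init_state(_toy_config(genes=15, dropout=0.0), sch)
    pretrain_drugs(state, data)
    r_hat = predict_drugs(data.celllines.values, state.modules).data
    r2 = per_drug_r2(r_hat, data.drugs.values, data.drugs.observed_mask)
    sig = r2[co.signal_drugs]
    assert np.nanmean(sig) > 0


# -- joint ---------------------------------------------------------------


def test_joint_critic_updates_per_epoch():
    data, _ = _toy_data()
    sch = _toy_schedule(joint_epochs=3, n_adv_per_ae=5)
    state = init_state(_toy_config(), sch)
    train_joint(state, data)
    critic_rows = [r for r in state.history if r["phase"] == "critic"]
    assert len(critic_rows) == 3 * 5


def test_joint_all_zero_weights_freezes_non_critic():
    data, _ = _toy_data()
    state = init_state(_toy_config(), _toy_schedule(joint_epochs=2))
    state.weights = LossWeights(0, 0, 0, 0)
    before = _weights_snapshot(state.modules)
    train_joint(state, data)
    after = _weights_snapshot(state.modules)
    for name in ("encoder", "decoder", "survival", "drug"):
        assert _weights_equal({name: before[name]}, {name: after[name]})


# -- invariants ----------------------------------------------------------


def test_training_determinism():
    results = []
    for _ in range(2):
        data, _ = _toy_data()
        state = init_state(_toy_config(), _toy_schedule())
        pretrain_deconfounding(state, data)
        train_joint(state, data)
        results.append(_weights_snapshot(state.modules))
    assert _weights_equal(results[0], results[1])


def test_l2_shrinks_weights():
    norms = {}
    for l2 in (0.0, 0.1):
        data, _ = _toy_data()
        sch = _toy_schedule(pretrain_dc_epochs=0, pretrain_surv_epochs=0,
                            pretrain_drug_epochs=30, joint_epochs=0)
        state = init_state(_toy_config(l2=l2, dropout=0.0), sch)
        pretrain_drugs(state, data)
        norms[l2] = sum(
            float(np.sum(w.data**2)) for w in state.modules.drug.weights
        )
    assert norms[0.1] < norms[0.0]


def test_checkpoint_roundtrip_bitwise(tmp_path):
    data, _ = _toy_data()
    sch = _toy_schedule(joint_epochs=2)

    # reference: continuous run of 2 + 2 joint epochs
    state_a = init_state(_toy_config(), sch)
    train_joint(state_a, data)
    train_joint(state_a, data)

    # interrupted: 2 epochs, save, load, 2 more
    state_b = init_state(_toy_config(), sch)
    train_joint(state_b, data)
    save_state(state_b, tmp_path / "ckpt")
    state_c = load_state(tmp_path / "ckpt")
    train_joint(state_c, data)

    assert _weights_equal(_weights_snapshot(state_a.modules), _weights_snapshot(state_c.modules))


def test_loss_history_csv(tmp_path):
    data, _ = _toy_data()
    state = init_state(_toy_config(), _toy_schedule())
    pretrain_deconfounding(state, data)
    write_loss_history(state, tmp_path / "log.csv")
    import csv

    with open(tmp_path / "log.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert rows and set(rows[0]) == {"epoch", "phase", "l_rec", "l_adv", "l_dc", "l_surv", "l_drug", "l_mtl"}
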