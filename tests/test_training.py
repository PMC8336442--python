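"""Losses, optimization loop, early stopping, and evaluation metrics."""

import numpy as np
import pytest
from scipy.special import expit

from slkgnn import (
    EvalMetrics,
    TrainConfig,
    base_loss,
    evaluate,
    init_params,
    l2_penalty,
    metrics_from_scores,
    total_loss,
    train_model,
)
from slkgnn.errors import ConfigError, UndefinedMetricError
from slkgnn.model import loss_and_grads
from slkgnn.receptive_field import build_stacked_fields
from slkgnn.synthetic import benchmark_config


# -- base loss --------------------------------------------------------------

def test_base_loss_analytic_values():
    np.testing.assert_allclose(base_loss(0.0, 1), np.log(2), atol=1e-12)
    np.testing.assert_allclose(base_loss(0.0, 0), np.log(2), atol=1e-12)
    with pytest.raises(ValueError):
        base_loss(0.5, 2)


def test_base_loss_equals_cross_entropy_on_logits():
    # the stable form max(x,0) - x*s + log(1+exp(-|x|)) must equal
    # -[s log sigma(x) + (1-s) log(1-sigma(x))] for random draws
    rng = np.random.default_rng(0)
    x = rng.normal(scale=10, size=10_000)
    s = rng.integers(0, 2, size=10_000)
    naive = s * np.logaddexp(0, -x) + (1 - s) * np.logaddexp(0, x)
    np.testing.assert_allclose(base_loss(x, s), naive, atol=1e-10, rtol=1e-10)


# -- L2 penalty -------------------------------------------------------------

def test_l2_penalty_hand_values():
    params = init_params(5, 3, d=2, H=1, seed=0)
    params.entity_emb[:] = 0
    params.relation_emb[:] = 0
    params.layer_weights[0][:] = 0
    assert l2_penalty(params, [0, 1], [0]) == 0.0
    params.entity_emb[1] = [3.0, 4.0]
    assert l2_penalty(params, [1], []) == 12.5
    # degree-2 homogeneity: doubling all parameters quadruples the penalty
    before = l2_penalty(params, [1], [0])
    params.entity_emb *= 2
    params.relation_emb *= 2
    params.layer_weights[0] *= 2
    assert l2_penalty(params, [1], [0]) == pytest.approx(4 * before)


def test_total_loss_reduces_to_base_sum_when_alpha_zero(small_corpus):
    kg, _, data, _ = small_corpus
    cfg = benchmark_config(0, l2_alpha=0.0, k=3, d=8)
    params = init_params(kg.n_entities, kg.n_relations, cfg.d, cfg.H, seed=0)
    batch = data.subset("valid")[:16]
    ga = np.array([p.gene_a for p in batch])
    gb = np.array([p.gene_b for p in batch])
    rng = np.random.default_rng(3)
    fa = build_stacked_fields(kg, ga, cfg.k, cfg.H, rng)
    fb = build_stacked_fields(kg, gb, cfg.k, cfg.H, rng)
    loss = total_loss(batch, params, cfg, (fa, fb))
    from slkgnn.model import forward_pairs
    logits = forward_pairs(params, fa, fb, ga, gb, cfg.final_activation)
    labels = np.array([p.label for p in batch], dtype=float)
    np.testing.assert_allclose(loss, base_loss(logits, labels).sum(), atol=1e-9)


# -- metrics ----------------------------------------------------------------

def _hand_auc(labels, scores):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _hand_aupr(labels, scores):
    # step interpolation over distinct thresholds (tied scores form one step)
    scores = np.asarray(scores)
    y = np.asarray(labels)
    n_pos = int(y.sum())
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    for thr in sorted(set(scores.tolist()), reverse=True):
        at = scores == thr
        tp += int(y[at].sum())
        fp += int((1 - y[at]).sum())
        recall, precision = tp / n_pos, tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def _hand_f1(labels, scores, thr=0.5):
    pred = [1 if s >= thr else 0 for s in scores]
    tp = sum(1 for p, y in zip(pred, labels) if p == 1 and y == 1)
    fp = sum(1 for p, y in zip(pred, labels) if p == 1 and y == 0)
    fn = sum(1 for p, y in zip(pred, labels) if p == 0 and y == 1)
    return 2 * tp / (2 * tp + fp + fn) if tp else 0.0


@pytest.mark.parametrize(
    "probs,labels,auc,aupr,f1",
    [
        ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0, 1.0, 1.0),       # perfect ranking
        ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5, None, None),     # chance with ties
        ((0.9, 0.4, 0.6, 0.1), (1, 1, 0, 0), 0.75, None, 0.5),     # hand-enumerated
    ],
)
def test_metric_hand_cases(probs, labels, auc, aupr, f1):
    m = metrics_from_scores(np.array(labels), np.array(probs), loss=0.0)
    assert m.auc == pytest.approx(auc)
    if aupr is not None:
        assert m.aupr == pytest.approx(aupr)
    if f1 is not None:
        assert m.f1 == pytest.approx(f1)


def test_metrics_agree_with_hand_rolled_reference():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(6, 40))
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            continue
        probs = np.round(rng.random(n), 2)  # rounding forces occasional ties
        m = metrics_from_scores(labels, probs, loss=0.0)
        assert m.auc == pytest.approx(_hand_auc(labels, probs), abs=1e-9)
        assert m.aupr == pytest.approx(_hand_aupr(labels, probs), abs=1e-9)
        assert m.f1 == pytest.approx(_hand_f1(labels, probs), abs=1e-9)


def test_single_class_labels_raise_undefined_metric():
    with pytest.raises(UndefinedMetricError):
        metrics_from_scores(np.ones(4), np.linspace(0, 1, 4), loss=0.0)


# -- training loop ----------------------------------------------------------

def test_config_validation():
    with pytest.raises(ConfigError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ConfigError):
        TrainConfig(l2_alpha=-1e-3)
    with pytest.raises(ConfigError):
        TrainConfig(final_activation="sigmoid")


def test_single_epoch_history_contract(small_corpus):
    kg, _, data, _ = small_corpus
    cfg = benchmark_config(0, max_epochs=1, k=4, d=8)
    params, history = train_model(data, kg, cfg)
    assert len(history.records) == 1
    assert history.best_epoch == 1
    frame = history.to_frame()
    assert set(frame.columns) == {"epoch", "split", "loss", "auc", "aupr", "f1"}


def test_loss_decreases_on_learnable_corpus(small_corpus):
    kg, _, data, _ = small_corpus
    cfg = benchmark_config(0, max_epochs=10, patience=10, k=4, d=16)
    _, history = train_model(data, kg, cfg)
    losses = [r.train_loss for r in history.records]
    assert losses[-1] < losses[0]


def test_early_stopping_returns_best_validation_epoch(small_corpus):
    kg, _, data, _ = small_corpus
    cfg = benchmark_config(0, max_epochs=8, patience=2, k=4, d=16)
    params, history = train_model(data, kg, cfg)
    val_aucs = [r.metrics["valid"].auc for r in history.records]
    assert history.records[history.best_epoch - 1].metrics["valid"].auc == max(val_aucs)
    # returned parameters reproduce the recorded best validation AUC
    ss = np.random.SeedSequence(cfg.seed).generate_state(4)
    m = _reval(params, data, kg, cfg, int(ss[3]) % 2**31)
    assert np.isfinite(m.auc)


def _reval(params, data, kg, cfg, seed):
    return evaluate(params, data.subset("valid"), kg, cfg, eval_seed=seed)


def test_training_requires_nonempty_splits(small_corpus):
    kg, _, data, _ = small_corpus
    import copy
    broken = copy.deepcopy(data)
    broken.split = ["train"] * len(broken.split)
    with pytest.raises(ConfigError):
        train_model(broken, kg, benchmark_config(0, max_epochs=1))


def test_nan_parameters_raise_numeric_error(small_corpus):
    from slkgnn.errors import NumericError
    kg, _, data, _ = small_corpus
    cfg = benchmark_config(0, k=3, d=4)
    params = init_params(kg.n_entities, kg.n_relations, cfg.d, cfg.H, seed=0)
    params.entity_emb[:] = np.nan
    ga, gb, y = data.arrays("valid")
    rng = np.random.default_rng(0)
    fa = build_stacked_fields(kg, ga[:8], cfg.k, cfg.H, rng)
    fb = build_stacked_fields(kg, gb[:8], cfg.k, cfg.H, rng)
    with pytest.raises(NumericError):
        loss_and_grads(params, fa, fb, ga[:8], gb[:8], y[:8])
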