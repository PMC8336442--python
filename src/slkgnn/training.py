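"""Loss functions, the Adam training loop with early stopping, and evaluation.

The objective is the summed binary cross-entropy on pair logits plus an L2
regularizer: per mini-batch, only the embedding rows actually touched by the
batch's receptive fields decay (sparse decay — full-table decay would scale
the effective alpha with corpus size), while every layer weight matrix always
decays.  Optimization is plain mini-batch Adam; training receptive fields are
re-drawn fresh every epoch (a stochastic regularizer), while validation and
test pairs are scored on fields drawn once under a fixed evaluation seed so
metrics are stable across epochs.  Early stopping tracks validation AUC and
restores the best parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .errors import ConfigError, NumericError, UndefinedMetricError
from .kg_store import KnowledgeGraph, SLDataset, SLPair
from .model import (
    ModelParams,
    forward_pairs,
    init_params,
    l2_penalty_from_indices,
    loss_and_grads,
    touched_indices,
    zero_grads,
)
from .receptive_field import StackedFields, build_stacked_fields

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyper-parameters; defaults follow the reference setting (k=64, d=256,
    H=2, lr=0.002, alpha=0.0039)."""

    learning_rate: float = 0.002
    l2_alpha: float = 0.0039
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 10
    k: int = 64
    d: int = 256
    H: int = 2
    seed: int = 0
    final_activation: str = "tanh"
    loss_on_logit: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.l2_alpha < 0:
            raise ConfigError(f"l2_alpha must be >= 0, got {self.l2_alpha}")
        for name in ("batch_size", "max_epochs", "patience", "k", "d", "H"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.final_activation not in ("tanh", "relu"):
            raise ConfigError(f"final_activation must be 'tanh' or 'relu', got {self.final_activation!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalMetrics:
    auc: float
    aupr: float
    f1: float
    loss: float


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    metrics: dict  # split -> EvalMetrics


@dataclass
class History:
    records: list = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for split, m in rec.metrics.items():
                rows.append(dict(epoch=rec.epoch, split=split, loss=m.loss,
                                 auc=m.auc, aupr=m.aupr, f1=m.f1))
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, columns=["epoch", "split", "loss", "auc", "aupr", "f1"])


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def base_loss(logit, label):
    """Numerically stable cross-entropy on logits:
    ``max(x, 0) - x*s + log(1 + exp(-|x|))``, algebraically equal to
    ``-[s log sigma(x) + (1-s) log(1-sigma(x))]``.
    """
    logit = np.asarray(logit, dtype=np.float64)
    label = np.asarray(label)
    if not np.isin(label, (0, 1)).all():
        raise ValueError(f"labels must be 0 or 1, got {np.unique(label)}")
    label = label.astype(np.float64)
    out = np.maximum(logit, 0.0) - logit * label + np.log1p(np.exp(-np.abs(logit)))
    return float(out) if out.ndim == 0 else out


def l2_penalty(params: ModelParams, batch_entities, batch_relations) -> float:
    """Half-sum of squared entries: touched entity rows + touched relation rows
    + all layer weight matrices (biases excluded)."""
    return l2_penalty_from_indices(
        params, np.asarray(batch_entities, dtype=np.int64), np.asarray(batch_relations, dtype=np.int64)
    )


def total_loss(batch: list[SLPair], params: ModelParams, cfg: TrainConfig,
               fields: tuple[StackedFields, StackedFields]) -> float:
    """Sum of base_loss over the batch plus ``l2_alpha * l2_penalty``."""
    fa, fb = fields
    ga = np.array([p.gene_a for p in batch], dtype=np.int64)
    gb = np.array([p.gene_b for p in batch], dtype=np.int64)
    y = np.array([p.label for p in batch], dtype=np.float64)
    logits = forward_pairs(params, fa, fb, ga, gb, cfg.final_activation)
    xin = logits if cfg.loss_on_logit else expit(logits)
    base = float(base_loss(xin, y).sum())
    ent_idx, rel_idx = touched_indices(fa, fb, ga, gb)
    return base + cfg.l2_alpha * l2_penalty_from_indices(params, ent_idx, rel_idx)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam (beta1=0.9, beta2=0.999, eps=1e-8) over the parameter tensors."""

    def __init__(self, params: ModelParams, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = zero_grads(params)
        self.v = zero_grads(params)

    @staticmethod
    def _walk(params: ModelParams, *dicts):
        yield (params.entity_emb, *[d["entity_emb"] for d in dicts])
        yield (params.relation_emb, *[d["relation_emb"] for d in dicts])
        for i in range(params.H):
            yield (params.layer_weights[i], *[d["layer_weights"][i] for d in dicts])
            yield (params.layer_biases[i], *[d["layer_biases"][i] for d in dicts])

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in self._walk(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _score_fixed(params: ModelParams, fa: StackedFields, fb: StackedFields,
                 ga: np.ndarray, gb: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Logits over pre-built evaluation fields, batched to bound memory."""
    n = len(ga)
    logits = np.empty(n)
    for lo in range(0, n, cfg.batch_size):
        sl = slice(lo, min(lo + cfg.batch_size, n))
        logits[sl] = forward_pairs(params, fa.take(sl), fb.take(sl), ga[sl], gb[sl], cfg.final_activation)
    return logits


def metrics_from_scores(labels: np.ndarray, probs: np.ndarray, loss: float) -> EvalMetrics:
    """AUC (average-rank ties), AUPR (step interpolation) and F1 at 0.5."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC/AUPR undefined: evaluation pairs contain a single class")
    return EvalMetrics(
        auc=float(roc_auc_score(labels, probs)),
        aupr=float(average_precision_score(labels, probs)),
        f1=float(f1_score(labels, (probs >= 0.5).astype(int), zero_division=0)),
        loss=float(loss),
    )


def _eval_fixed(params, fa, fb, ga, gb, labels, cfg) -> EvalMetrics:
    logits = _score_fixed(params, fa, fb, ga, gb, cfg)
    xin = logits if cfg.loss_on_logit else expit(logits)
    mean_base = float(base_loss(xin, labels).mean())
    return metrics_from_scores(labels, expit(logits), mean_base)


def evaluate(params: ModelParams, pairs: list[SLPair], kg: KnowledgeGraph,
             cfg: TrainConfig, eval_seed: int) -> EvalMetrics:
    """Score pairs on receptive fields drawn once under ``eval_seed``.

    The reported ``loss`` is the mean per-pair cross-entropy (no regularizer),
    comparable across splits of different sizes.
    """
    ga = np.array([p.gene_a for p in pairs], dtype=np.int64)
    gb = np.array([p.gene_b for p in pairs], dtype=np.int64)
    y = np.array([p.label for p in pairs], dtype=np.float64)
    rng = np.random.default_rng(eval_seed)
    fa = build_stacked_fields(kg, ga, cfg.k, cfg.H, rng)
    fb = build_stacked_fields(kg, gb, cfg.k, cfg.H, rng)
    return _eval_fixed(params, fa, fb, ga, gb, y, cfg)


def predict_pairs(params: ModelParams, kg: KnowledgeGraph, genes_a, genes_b,
                  cfg: TrainConfig, eval_seed: int) -> np.ndarray:
    """SL probabilities for gene index pairs, on fields drawn under ``eval_seed``."""
    ga = np.asarray(genes_a, dtype=np.int64)
    gb = np.asarray(genes_b, dtype=np.int64)
    rng = np.random.default_rng(eval_seed)
    fa = build_stacked_fields(kg, ga, cfg.k, cfg.H, rng)
    fb = build_stacked_fields(kg, gb, cfg.k, cfg.H, rng)
    return expit(_score_fixed(params, fa, fb, ga, gb, cfg))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train_model(data: SLDataset, kg: KnowledgeGraph, cfg: TrainConfig) -> tuple[ModelParams, History]:
    """Mini-batch Adam on the total loss with early stopping on validation AUC.

    Fully deterministic given ``cfg.seed`` (single-threaded): the seed drives
    parameter init, per-epoch receptive-field resampling, batch shuffling and
    the fixed evaluation fields.  Returns the parameters of the best epoch.
    """
    for tag in ("train", "valid"):
        if not data.subset(tag):
            raise ConfigError(f"training requires a nonempty {tag!r} split")
    ss = np.random.SeedSequence(cfg.seed).generate_state(4)
    init_seed, field_seed, shuffle_seed, eval_seed = (int(x) % 2**31 for x in ss)
    params = init_params(kg.n_entities, kg.n_relations, cfg.d, cfg.H, init_seed)
    adam = Adam(params, cfg.learning_rate)
    field_rng = np.random.default_rng(field_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)

    split_arrays = {tag: data.arrays(tag) for tag in ("train", "valid", "test")}
    eval_rng = np.random.default_rng(eval_seed)
    eval_fields = {}
    for tag in ("train", "valid", "test"):
        ga, gb, _ = split_arrays[tag]
        if len(ga):
            eval_fields[tag] = (
                build_stacked_fields(kg, ga, cfg.k, cfg.H, eval_rng),
                build_stacked_fields(kg, gb, cfg.k, cfg.H, eval_rng),
            )

    ga_tr, gb_tr, y_tr = split_arrays["train"]
    n_tr = len(ga_tr)
    history = History()
    best_auc, best_epoch, best_params = -np.inf, 0, params.copy()
    wait = 0
    for epoch in range(1, cfg.max_epochs + 1):
        fa = build_stacked_fields(kg, ga_tr, cfg.k, cfg.H, field_rng)
        fb = build_stacked_fields(kg, gb_tr, cfg.k, cfg.H, field_rng)
        order = shuffle_rng.permutation(n_tr)
        epoch_loss = 0.0
        for lo in range(0, n_tr, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            try:
                loss, grads, _ = loss_and_grads(
                    params, fa.take(idx), fb.take(idx), ga_tr[idx], gb_tr[idx], y_tr[idx],
                    l2_alpha=cfg.l2_alpha, final_activation=cfg.final_activation,
                    loss_on_logit=cfg.loss_on_logit,
                )
            except NumericError as err:
                raise NumericError(f"divergence at epoch {epoch}: {err}") from err
            adam.step(params, grads)
            epoch_loss += loss
        if not params.all_finite():
            raise NumericError(f"non-finite parameters after epoch {epoch}")
        metrics = {}
        for tag, (efa, efb) in eval_fields.items():
            ga, gb, y = split_arrays[tag]
            metrics[tag] = _eval_fixed(params, efa, efb, ga, gb, y, cfg)
        history.records.append(EpochRecord(epoch=epoch, train_loss=epoch_loss / n_tr, metrics=metrics))
        val_auc = metrics["valid"].auc
        log.info("epoch %d: train loss %.4f, valid AUC %.4f", epoch, epoch_loss / n_tr, val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, best_params = val_auc, epoch, params.copy()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                log.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                break
    history.best_epoch = best_epoch
    return best_params, history
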