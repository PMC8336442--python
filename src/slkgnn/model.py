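"""Model math: embeddings, partner-conditioned relation weighting, aggregation,
layer updates, pair scoring, and hand-written reverse-mode gradients.

The encoder turns a gene's sampled receptive field into a d-dimensional
vector.  For a candidate pair (i, j), every edge (e, e') inside gene i's
subgraph is scored by the inner product between the *partner* gene j's raw
entity embedding and the relation-type embedding of that edge,

    omega = <e_j, r_{e,e'}> ,

softmax-normalized over the k sampled children of e, and used as the weight
of a weighted-average neighborhood aggregation.  Each sweep step then updates
the parent as

    e_new = act( W (e + e_P(e)) + b ) ,

with ReLU on hidden layers and (by default) tanh on the final, hop-0 update:
an all-ReLU encoder can only produce non-negative encodings, hence only
logits >= 0, which makes the probability range below 0.5 unreachable and
degenerates the 0.5-threshold classification; tanh restores sign while
keeping the rest of the architecture literal.  ``final_activation="relu"``
restores the all-ReLU reading.

One bottom-up sweep runs from the leaves (hop H, raw embeddings) to the seed
gene (hop 0): layer weights are indexed by sweep step, ``layer_weights[0]``
applied at the deepest level and ``layer_weights[H-1]`` producing the final
encoding.  The pair score is the sigmoid of the inner product of the two
encodings, classified at threshold 0.5.

Everything is float64 numpy; the backward pass mirrors the forward pass
exactly and is validated against central finite differences in the tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import ConfigError, FormatError, NumericError
from .receptive_field import ReceptiveField, StackedFields

_ACTIVATIONS = ("tanh", "relu")


@dataclass
class ModelParams:
    """Entity/relation embedding tables plus per-layer transform weights."""

    entity_emb: np.ndarray          # (|V_e|, d)
    relation_emb: np.ndarray        # (|V_r|, d)
    layer_weights: list[np.ndarray]  # H matrices (d, d)
    layer_biases: list[np.ndarray]   # H vectors (d,)

    @property
    def d(self) -> int:
        return self.entity_emb.shape[1]

    @property
    def H(self) -> int:
        return len(self.layer_weights)

    def tensors(self) -> list[tuple[str, np.ndarray]]:
        out = [("entity_emb", self.entity_emb), ("relation_emb", self.relation_emb)]
        for i, (w, b) in enumerate(zip(self.layer_weights, self.layer_biases)):
            out.append((f"layer_weight_{i}", w))
            out.append((f"layer_bias_{i}", b))
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.entity_emb.copy(),
            self.relation_emb.copy(),
            [w.copy() for w in self.layer_weights],
            [b.copy() for b in self.layer_biases],
        )

    def all_finite(self) -> bool:
        return all(np.all(np.isfinite(a)) for _, a in self.tensors())


@dataclass(frozen=True)
class PairScore:
    """Raw inner-product logit, sigmoid probability, and the 0.5-threshold label."""

    logit: float
    probability: float
    predicted_label: int


def init_params(n_entities: int, n_relations: int, d: int, H: int, seed: int) -> ModelParams:
    """Glorot-style uniform init, biases zero, deterministic given seed.

    Every weight matrix and embedding table is drawn uniformly from
    ``±sqrt(6 / (fan_in + fan_out))`` for its own shape.
    """
    if d <= 0 or H <= 0:
        raise ConfigError(f"need d >= 1 and H >= 1, got d={d}, H={H}")
    if n_entities < 1 or n_relations < 1:
        raise ConfigError("need at least one entity and one relation type")
    rng = np.random.default_rng(seed)

    def glorot(shape):
        bound = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-bound, bound, size=shape)

    return ModelParams(
        entity_emb=glorot((n_entities, d)),
        relation_emb=glorot((n_relations, d)),
        layer_weights=[glorot((d, d)) for _ in range(H)],
        layer_biases=[np.zeros(d) for _ in range(H)],
    )


# ---------------------------------------------------------------------------
# Scalar / per-gene primitives
# ---------------------------------------------------------------------------

def relation_scores(partner_emb: np.ndarray, relation_emb_rows: np.ndarray) -> np.ndarray:
    """Inner products between the partner gene's embedding and k relation rows."""
    partner_emb = np.asarray(partner_emb, dtype=np.float64)
    relation_emb_rows = np.asarray(relation_emb_rows, dtype=np.float64)
    if partner_emb.ndim != 1 or relation_emb_rows.ndim != 2 or relation_emb_rows.shape[1] != partner_emb.shape[0]:
        raise ValueError(
            f"shape mismatch: partner {partner_emb.shape} vs relation rows {relation_emb_rows.shape}"
        )
    return relation_emb_rows @ partner_emb


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Max-shifted softmax; sums to 1, each entry in (0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 1:
        raise ValueError("cannot normalize an empty score vector")
    if np.isnan(scores).any():
        raise NumericError("NaN in relation scores")
    e = np.exp(scores - scores.max())
    return e / e.sum()


def aggregate_neighborhood(neighbor_embs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of the k sampled neighbor embeddings."""
    neighbor_embs = np.asarray(neighbor_embs, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if neighbor_embs.ndim != 2 or weights.shape != (neighbor_embs.shape[0],):
        raise ValueError(f"shape mismatch: embs {neighbor_embs.shape} vs weights {weights.shape}")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"aggregation weights must sum to 1, got {weights.sum()!r}")
    return weights @ neighbor_embs


def layer_update(
    self_emb: np.ndarray,
    agg_emb: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    is_last: bool = False,
    final_activation: str = "tanh",
) -> np.ndarray:
    """One sum-aggregator update: ``act(W (self + agg) + b)``."""
    if final_activation not in _ACTIVATIONS:
        raise ConfigError(f"final_activation must be one of {_ACTIVATIONS}")
    self_emb = np.asarray(self_emb, dtype=np.float64)
    agg_emb = np.asarray(agg_emb, dtype=np.float64)
    if self_emb.shape != agg_emb.shape or W.shape != (self_emb.shape[0],) * 2 or b.shape != self_emb.shape:
        raise ValueError(
            f"shape mismatch: self {self_emb.shape}, agg {agg_emb.shape}, W {W.shape}, b {b.shape}"
        )
    z = W @ (self_emb + agg_emb) + b
    if is_last and final_activation == "tanh":
        return np.tanh(z)
    return np.maximum(z, 0.0)


def encode_gene(
    field: ReceptiveField,
    partner_gene: int,
    params: ModelParams,
    final_activation: str = "tanh",
) -> np.ndarray:
    """Encode one gene from its receptive field, conditioned on its partner.

    Bottom-up sweep built from the scalar primitives above; the batched path
    (:func:`encode_batch`) is the production implementation and must agree
    with this one to numerical precision.
    """
    H = params.H
    if field.H != H:
        raise ConfigError(f"field has H={field.H} but params have H={H}")
    partner = params.entity_emb[partner_gene]
    reps = params.entity_emb[field.hop_entities[H]]
    for h in range(H, 0, -1):
        parents = field.hop_entities[h - 1]
        k = len(field.hop_entities[h]) // len(parents)
        rel_rows = params.relation_emb[field.hop_relations[h - 1]].reshape(len(parents), k, -1)
        child = reps.reshape(len(parents), k, -1)
        layer = H - h
        new = np.empty((len(parents), params.d))
        for i, p in enumerate(parents):
            w = normalize_scores(relation_scores(partner, rel_rows[i]))
            agg = aggregate_neighborhood(child[i], w)
            new[i] = layer_update(
                params.entity_emb[p], agg,
                params.layer_weights[layer], params.layer_biases[layer],
                is_last=(h == 1), final_activation=final_activation,
            )
        reps = new
    return reps[0]


def score_pair(enc_a: np.ndarray, enc_b: np.ndarray) -> PairScore:
    """Sigmoid inner-product pair score with the 0.5 classification threshold."""
    enc_a = np.asarray(enc_a, dtype=np.float64)
    enc_b = np.asarray(enc_b, dtype=np.float64)
    if enc_a.shape != enc_b.shape or enc_a.ndim != 1:
        raise ValueError(f"shape mismatch: {enc_a.shape} vs {enc_b.shape}")
    logit = float(enc_a @ enc_b)
    prob = float(expit(logit))
    return PairScore(logit=logit, probability=prob, predicted_label=int(prob >= 0.5))


# ---------------------------------------------------------------------------
# Batched forward / backward
# ---------------------------------------------------------------------------

def encode_batch(
    params: ModelParams,
    fields: StackedFields,
    partner_idx: np.ndarray,
    final_activation: str = "tanh",
    want_cache: bool = False,
):
    """Batched bottom-up encoder; returns ``(B, d)`` encodings (and caches)."""
    if final_activation not in _ACTIVATIONS:
        raise ConfigError(f"final_activation must be one of {_ACTIVATIONS}")
    H = params.H
    if fields.H != H:
        raise ConfigError(f"fields have H={fields.H} but params have H={H}")
    B = fields.batch
    partner = params.entity_emb[partner_idx]          # (B, d)
    reps = params.entity_emb[fields.ent[H]]           # (B, k^H, d)
    caches = []
    for h in range(H, 0, -1):
        Kp = fields.ent[h - 1].shape[1]
        k = fields.ent[h].shape[1] // Kp
        rel_idx = fields.rel[h - 1].reshape(B, Kp, k)
        rel_rows = params.relation_emb[rel_idx]       # (B, Kp, k, d)
        child = reps.reshape(B, Kp, k, -1)
        scores = np.einsum("bd,bpkd->bpk", partner, rel_rows)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        w = e / e.sum(axis=-1, keepdims=True)
        agg = np.einsum("bpk,bpkd->bpd", w, child)
        parent_idx = fields.ent[h - 1]
        x = params.entity_emb[parent_idx] + agg
        layer = H - h
        z = x @ params.layer_weights[layer].T + params.layer_biases[layer]
        if h == 1 and final_activation == "tanh":
            out = np.tanh(z)
        else:
            out = np.maximum(z, 0.0)
        if want_cache:
            caches.append(
                dict(h=h, layer=layer, rel_idx=rel_idx, w=w, child=child,
                     x=x, z=z, out=out, parent_idx=parent_idx)
            )
        reps = out
    enc = reps[:, 0, :]
    return (enc, caches) if want_cache else enc


def zero_grads(params: ModelParams) -> dict:
    return {
        "entity_emb": np.zeros_like(params.entity_emb),
        "relation_emb": np.zeros_like(params.relation_emb),
        "layer_weights": [np.zeros_like(w) for w in params.layer_weights],
        "layer_biases": [np.zeros_like(b) for b in params.layer_biases],
    }


def _backward_encode(
    params: ModelParams,
    caches: list[dict],
    leaf_idx: np.ndarray,
    partner_idx: np.ndarray,
    d_out: np.ndarray,
    grads: dict,
    final_activation: str,
) -> None:
    """Accumulate gradients of one encoded side into ``grads`` (in place)."""
    B, d = d_out.shape
    partner = params.entity_emb[partner_idx]
    d_partner = np.zeros_like(partner)
    dact = d_out.reshape(B, 1, d)
    for c in reversed(caches):
        if c["h"] == 1 and final_activation == "tanh":
            dz = dact * (1.0 - c["out"] ** 2)
        else:
            dz = dact * (c["z"] > 0)
        W = params.layer_weights[c["layer"]]
        grads["layer_weights"][c["layer"]] += np.einsum("bpd,bpe->de", dz, c["x"])
        grads["layer_biases"][c["layer"]] += dz.sum(axis=(0, 1))
        dx = dz @ W                                   # (B, Kp, d)
        np.add.at(grads["entity_emb"], c["parent_idx"].reshape(-1), dx.reshape(-1, d))
        dagg = dx
        dw = np.einsum("bpkd,bpd->bpk", c["child"], dagg)
        dchild = c["w"][..., None] * dagg[:, :, None, :]
        ds = c["w"] * (dw - (c["w"] * dw).sum(axis=-1, keepdims=True))
        rel_rows = params.relation_emb[c["rel_idx"]]
        d_partner += np.einsum("bpk,bpkd->bd", ds, rel_rows)
        drel = ds[..., None] * partner[:, None, None, :]
        np.add.at(grads["relation_emb"], c["rel_idx"].reshape(-1), drel.reshape(-1, d))
        Kp, k = c["w"].shape[1], c["w"].shape[2]
        dact = dchild.reshape(B, Kp * k, d)
    np.add.at(grads["entity_emb"], leaf_idx.reshape(-1), dact.reshape(-1, d))
    np.add.at(grads["entity_emb"], partner_idx, d_partner)


def touched_indices(fields_a: StackedFields, fields_b: StackedFields,
                    genes_a: np.ndarray, genes_b: np.ndarray):
    """Unique entity/relation rows visible to a batch (for sparse L2 decay)."""
    ents = np.concatenate(
        [e.reshape(-1) for e in fields_a.ent + fields_b.ent]
        + [np.asarray(genes_a).reshape(-1), np.asarray(genes_b).reshape(-1)]
    )
    rels = np.concatenate([r.reshape(-1) for r in fields_a.rel + fields_b.rel])
    return np.unique(ents), np.unique(rels)


def l2_penalty_from_indices(params: ModelParams, entity_idx: np.ndarray, relation_idx: np.ndarray) -> float:
    """Half the squared L2 norm of touched embedding rows plus all layer weights."""
    pen = float(np.sum(params.entity_emb[entity_idx] ** 2))
    pen += float(np.sum(params.relation_emb[relation_idx] ** 2))
    pen += float(sum(np.sum(w ** 2) for w in params.layer_weights))
    return 0.5 * pen


def forward_pairs(
    params: ModelParams,
    fields_a: StackedFields,
    fields_b: StackedFields,
    genes_a: np.ndarray,
    genes_b: np.ndarray,
    final_activation: str = "tanh",
) -> np.ndarray:
    """Logits for a batch of pairs (each side conditioned on the other gene)."""
    enc_a = encode_batch(params, fields_a, genes_b, final_activation)
    enc_b = encode_batch(params, fields_b, genes_a, final_activation)
    return np.einsum("bd,bd->b", enc_a, enc_b)


def loss_and_grads(
    params: ModelParams,
    fields_a: StackedFields,
    fields_b: StackedFields,
    genes_a: np.ndarray,
    genes_b: np.ndarray,
    labels: np.ndarray,
    l2_alpha: float = 0.0,
    final_activation: str = "tanh",
    loss_on_logit: bool = True,
):
    """Total batch loss (summed cross-entropy + alpha * L2) and its gradients.

    ``loss_on_logit=True`` feeds the raw inner-product logit to the
    numerically stable cross-entropy ``max(x,0) - x*s + log(1+exp(-|x|))``;
    the alternative feeds the sigmoid probability through the same formula.
    Returns ``(loss, grads, logits)``.
    """
    genes_a = np.asarray(genes_a, dtype=np.int64)
    genes_b = np.asarray(genes_b, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.float64)
    enc_a, ca = encode_batch(params, fields_a, genes_b, final_activation, want_cache=True)
    enc_b, cb = encode_batch(params, fields_b, genes_a, final_activation, want_cache=True)
    logits = np.einsum("bd,bd->b", enc_a, enc_b)
    xin = logits if loss_on_logit else expit(logits)
    J = np.maximum(xin, 0.0) - xin * labels + np.log1p(np.exp(-np.abs(xin)))
    base = float(J.sum())
    ent_idx, rel_idx = touched_indices(fields_a, fields_b, genes_a, genes_b)
    pen = l2_penalty_from_indices(params, ent_idx, rel_idx) if l2_alpha else 0.0
    loss = base + l2_alpha * pen
    if not np.isfinite(loss):
        raise NumericError("non-finite loss in forward pass")

    dxin = expit(xin) - labels
    dlogit = dxin if loss_on_logit else dxin * expit(logits) * (1.0 - expit(logits))
    grads = zero_grads(params)
    _backward_encode(params, ca, fields_a.ent[-1], genes_b, dlogit[:, None] * enc_b, grads, final_activation)
    _backward_encode(params, cb, fields_b.ent[-1], genes_a, dlogit[:, None] * enc_a, grads, final_activation)
    if l2_alpha:
        grads["entity_emb"][ent_idx] += l2_alpha * params.entity_emb[ent_idx]
        grads["relation_emb"][rel_idx] += l2_alpha * params.relation_emb[rel_idx]
        for i, w in enumerate(params.layer_weights):
            grads["layer_weights"][i] += l2_alpha * w
    return loss, grads, logits


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_checkpoint(path, params: ModelParams, meta: dict) -> None:
    """Write one .npy per parameter tensor plus a JSON sidecar with shapes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    shapes = {}
    for name, arr in params.tensors():
        np.save(path / f"{name}.npy", arr)
        shapes[name] = list(arr.shape)
    sidecar = dict(meta)
    sidecar["shapes"] = shapes
    sidecar["H"] = params.H
    sidecar["d"] = params.d
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path):
    """Load a checkpoint directory; validates tensor shapes against the sidecar."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    arrays = {}
    for name, shape in meta["shapes"].items():
        arr = np.load(path / f"{name}.npy")
        if list(arr.shape) != shape:
            raise FormatError(f"checkpoint tensor {name} has shape {arr.shape}, sidecar says {shape}")
        arrays[name] = arr
    H = meta["H"]
    params = ModelParams(
        entity_emb=arrays["entity_emb"],
        relation_emb=arrays["relation_emb"],
        layer_weights=[arrays[f"layer_weight_{i}"] for i in range(H)],
        layer_biases=[arrays[f"layer_bias_{i}"] for i in range(H)],
    )
    return params, meta
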