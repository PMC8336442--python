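"""Model math: primitives, the per-gene encoder, batching, and pair scoring."""

import numpy as np
import pytest

from slkgnn import (
    KnowledgeGraph,
    ModelParams,
    ReceptiveField,
    SamplerConfig,
    aggregate_neighborhood,
    build_receptive_field,
    encode_batch,
    encode_gene,
    init_params,
    layer_update,
    load_checkpoint,
    normalize_scores,
    relation_scores,
    save_checkpoint,
    score_pair,
    stack_fields,
)
from slkgnn.errors import ConfigError, NumericError


# -- initialization ---------------------------------------------------------

def test_init_is_deterministic_and_glorot_bounded():
    a = init_params(10, 3, d=4, H=2, seed=0)
    b = init_params(10, 3, d=4, H=2, seed=0)
    for (_, x), (_, y) in zip(a.tensors(), b.tensors()):
        assert np.array_equal(x, y)
    assert a.entity_emb.shape == (10, 4)
    assert np.abs(a.entity_emb).max() <= np.sqrt(6 / (10 + 4))
    assert np.abs(a.layer_weights[0]).max() <= np.sqrt(6 / 8)
    assert all(np.all(bias == 0) for bias in a.layer_biases)
    with pytest.raises(ConfigError):
        init_params(10, 3, d=0, H=2, seed=0)


# -- primitives -------------------------------------------------------------

def test_relation_scores_hand_values_and_loop_oracle(rng):
    assert relation_scores(np.array([1.0, 0.0]), np.array([[2.0, 5.0], [0.0, 3.0]])).tolist() == [2.0, 0.0]
    assert np.all(relation_scores(np.zeros(3), rng.normal(size=(5, 3))) == 0)
    partner = rng.normal(size=16)
    rows = rng.normal(size=(8, 16))
    loop = np.array([sum(partner[t] * rows[i, t] for t in range(16)) for i in range(8)])
    np.testing.assert_allclose(relation_scores(partner, rows), loop, atol=1e-12)
    with pytest.raises(ValueError):
        relation_scores(np.zeros(3), np.zeros((4, 2)))


def test_softmax_normalization_cases():
    np.testing.assert_allclose(normalize_scores([0.0, 0.0, 0.0, 0.0]), [0.25] * 4)
    np.testing.assert_allclose(normalize_scores([np.log(2), 0.0]), [2 / 3, 1 / 3], atol=1e-12)
    big = normalize_scores([1000.0, 0.0])
    assert np.isfinite(big).all() and big[0] > 0.999
    with pytest.raises(NumericError):
        normalize_scores([np.nan, 1.0])


def test_aggregation_cases(rng):
    np.testing.assert_allclose(
        aggregate_neighborhood(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0.5, 0.5])), [0.5, 0.5]
    )
    embs = rng.normal(size=(4, 3))
    one_hot = np.eye(4)[2]
    np.testing.assert_allclose(aggregate_neighborhood(embs, one_hot), embs[2])
    w = normalize_scores(rng.normal(size=6))
    embs = rng.normal(size=(6, 5))
    loop = np.array([sum(w[i] * embs[i, t] for i in range(6)) for t in range(5)])
    np.testing.assert_allclose(aggregate_neighborhood(embs, w), loop, atol=1e-12)
    with pytest.raises(ValueError):
        aggregate_neighborhood(embs, np.full(6, 0.5))  # weights don't sum to 1


def test_layer_update_cases():
    I = np.eye(2)
    z = np.zeros(2)
    np.testing.assert_allclose(layer_update([1.0, -1.0], [0.0, 0.0], I, z), [1.0, 0.0])
    np.testing.assert_allclose(layer_update([5.0, 5.0], [1.0, 1.0], np.zeros((2, 2)), np.array([1.0, -2.0])), [1.0, 0.0])
    np.testing.assert_allclose(
        layer_update([1.0, -1.0], [-1.0, 1.0], I, z, is_last=True, final_activation="tanh"), [0.0, 0.0]
    )


# -- encoder ----------------------------------------------------------------

def _two_node_kg():
    return KnowledgeGraph.from_raw([("g", "participates", "p")], {"g": "gene", "p": "pathway"})


def test_encode_gene_matches_hand_walk_on_two_node_graph():
    # H=1, k=1: softmax of a single score is 1, aggregation selects the single
    # neighbor, update is tanh(W (e_g + e_p) + b)
    kg = _two_node_kg()
    g, p = kg.entity_index["g"], kg.entity_index["p"]
    params = init_params(kg.n_entities, kg.n_relations, d=2, H=1, seed=0)
    params.entity_emb[g] = [1.0, 2.0]
    params.entity_emb[p] = [0.5, -1.0]
    params.layer_weights[0] = np.array([[1.0, 0.5], [0.0, 2.0]])
    params.layer_biases[0] = np.array([0.1, -0.1])
    field = build_receptive_field(kg, g, SamplerConfig(k=1, H=1, seed=0))
    enc = encode_gene(field, partner_gene=g, params=params)
    x = np.array([1.5, 1.0])  # e_g + e_p
    expected = np.tanh(params.layer_weights[0] @ x + params.layer_biases[0])
    np.testing.assert_allclose(enc, expected, atol=1e-12)


def test_zero_parameters_propagate_to_zero_encoding(small_corpus):
    kg, _, _, _ = small_corpus
    params = init_params(kg.n_entities, kg.n_relations, d=4, H=2, seed=0)
    params.entity_emb[:] = 0
    params.relation_emb[:] = 0
    for b in params.layer_biases:
        b[:] = 0
    gene = int(kg.genes()[0])
    field = build_receptive_field(kg, gene, SamplerConfig(k=2, H=2, seed=0))
    np.testing.assert_allclose(encode_gene(field, gene, params), 0.0)


def test_encoding_invariant_to_child_permutation(small_corpus, rng):
    kg, _, _, _ = small_corpus
    genes = kg.genes()
    gene, partner = int(genes[0]), int(genes[1])
    params = init_params(kg.n_entities, kg.n_relations, d=8, H=1, seed=2)
    field = build_receptive_field(kg, gene, SamplerConfig(k=4, H=1, seed=3))
    enc = encode_gene(field, partner, params)
    perm = rng.permutation(4)
    permuted = ReceptiveField(
        [field.hop_entities[0], field.hop_entities[1][perm]],
        [field.hop_relations[0][perm]],
    )
    np.testing.assert_allclose(encode_gene(permuted, partner, params), enc, atol=1e-12)


def test_encoder_rejects_hop_count_mismatch(small_corpus):
    kg, _, _, _ = small_corpus
    params = init_params(kg.n_entities, kg.n_relations, d=4, H=2, seed=0)
    field = build_receptive_field(kg, int(kg.genes()[0]), SamplerConfig(k=2, H=1, seed=0))
    with pytest.raises(ConfigError):
        encode_gene(field, int(kg.genes()[1]), params)


def test_batched_encoder_matches_per_gene_path(small_corpus):
    kg, _, _, _ = small_corpus
    genes = [int(g) for g in kg.genes()[:6]]
    partners = [int(g) for g in kg.genes()[6:12]]
    params = init_params(kg.n_entities, kg.n_relations, d=8, H=2, seed=4)
    fields = [build_receptive_field(kg, g, SamplerConfig(k=3, H=2, seed=i)) for i, g in enumerate(genes)]
    batched = encode_batch(params, stack_fields(fields), np.array(partners))
    for i, (f, p) in enumerate(zip(fields, partners)):
        np.testing.assert_allclose(batched[i], encode_gene(f, p, params), atol=1e-9)


# -- pair scoring -----------------------------------------------------------

def test_score_pair_analytic_values_and_symmetry(rng):
    s = score_pair(np.zeros(4), rng.normal(size=4))
    assert s.probability == 0.5 and s.predicted_label == 1
    s = score_pair(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
    assert s.logit == 2.0
    np.testing.assert_allclose(s.probability, 1 / (1 + np.exp(-2)), atol=1e-12)
    a, b = rng.normal(size=4), rng.normal(size=4)
    assert score_pair(a, b) == score_pair(b, a)


# -- checkpoints ------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path):
    params = init_params(12, 4, d=6, H=2, seed=7)
    save_checkpoint(tmp_path / "ckpt", params, dict(k=3, note="test"))
    loaded, meta = load_checkpoint(tmp_path / "ckpt")
    for (_, x), (_, y) in zip(params.tensors(), loaded.tensors()):
        assert np.array_equal(x, y)
    assert meta["k"] == 3 and meta["d"] == 6 and meta["H"] == 2
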