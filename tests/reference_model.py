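"""Independent nested-loop reference implementation of the forward pass.

Pure-python lists and ``math`` only — no shared code with the package's
vectorized encoder — so agreement between the two is a genuine cross-check
of the message-passing math, not a tautology.
"""

import math


def _softmax(xs):
    m = max(xs)
    es = [math.exp(x - m) for x in xs]
    s = sum(es)
    return [e / s for e in es]


def reference_encode(field, partner_gene, params, final_activation="tanh"):
    """Encode one gene by explicit loops over hops, parents, children, dims."""
    ent_emb = params.entity_emb.tolist()
    rel_emb = params.relation_emb.tolist()
    Ws = [w.tolist() for w in params.layer_weights]
    bs = [b.tolist() for b in params.layer_biases]
    H = len(field.hop_relations)
    d = len(ent_emb[0])
    partner = ent_emb[partner_gene]
    reps = [list(ent_emb[int(e)]) for e in field.hop_entities[H]]
    for h in range(H, 0, -1):
        parents = field.hop_entities[h - 1]
        k = len(field.hop_entities[h]) // len(parents)
        layer = H - h
        new = []
        for i, p in enumerate(parents):
            scores = []
            for j in range(k):
                r = int(field.hop_relations[h - 1][i * k + j])
                scores.append(sum(partner[t] * rel_emb[r][t] for t in range(d)))
            w = _softmax(scores)
            agg = [sum(w[j] * reps[i * k + j][t] for j in range(k)) for t in range(d)]
            x = [ent_emb[int(p)][t] + agg[t] for t in range(d)]
            z = [sum(Ws[layer][a][t] * x[t] for t in range(d)) + bs[layer][a] for a in range(d)]
            if h == 1 and final_activation == "tanh":
                new.append([math.tanh(v) for v in z])
            else:
                new.append([max(v, 0.0) for v in z])
        reps = new
    return reps[0]


def reference_pair_logit(field_a, field_b, gene_a, gene_b, params, final_activation="tanh"):
    ea = reference_encode(field_a, gene_b, params, final_activation)
    eb = reference_encode(field_b, gene_a, params, final_activation)
    return sum(x * y for x, y in zip(ea, eb))


def reference_base_loss(logit, label):
    return max(logit, 0.0) - logit * label + math.log1p(math.exp(-abs(logit)))


def reference_l2(params, entity_rows, relation_rows):
    tot = 0.0
    for i in entity_rows:
        tot += sum(v * v for v in params.entity_emb[i])
    for i in relation_rows:
        tot += sum(v * v for v in params.relation_emb[i])
    for w in params.layer_weights:
        tot += sum(v * v for row in w.tolist() for v in row)
    return 0.5 * tot


def reference_total_loss(pairs_fields, labels, params, l2_alpha, final_activation="tanh"):
    """pairs_fields: list of (field_a, field_b, gene_a, gene_b)."""
    base = 0.0
    ent_rows, rel_rows = set(), set()
    for (fa, fb, ga, gb), y in zip(pairs_fields, labels):
        base += reference_base_loss(reference_pair_logit(fa, fb, ga, gb, params, final_activation), y)
        for f in (fa, fb):
            for arr in f.hop_entities:
                ent_rows.update(int(e) for e in arr)
            for arr in f.hop_relations:
                rel_rows.update(int(r) for r in arr)
        ent_rows.update((int(ga), int(gb)))
    return base + l2_alpha * reference_l2(params, sorted(ent_rows), sorted(rel_rows))
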