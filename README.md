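# slkgnn

Knowledge-graph message passing for synthetic-lethality (SL) gene-pair
prediction.

Two genes are synthetic-lethal when losing both kills a cell while losing
either alone does not — a prized source of anti-cancer drug targets
(PARP1/BRCA1 being the canonical example). Treating known SL pairs as
independent samples ignores the shared biology (common processes, pathways,
complexes) that generates them. `slkgnn` addresses this by predicting SL
pairs with a graph neural network that passes messages over a heterogeneous
biomedical *knowledge graph* (KG): typed entities (genes, biological
processes, compounds, diseases, ...) connected by typed triplets
*(head, relation, tail)*. Latent mechanisms become nodes the model can
aggregate over, replacing manual feature engineering.

It is intended for computational biologists who have (a) a KG as a typed
triplet edge list and (b) a list of labelled (or positives-only) SL gene
pairs, and want calibrated SL probabilities for new gene pairs — plus an
ablation tool to check that the KG is actually contributing.

## The model

For a candidate pair (i, j), each gene gets a fixed-shape receptive field:
`k` neighbors sampled uniformly with replacement per entity, repeated for
`H` hops (hop `h` has `k^h` entries). Inside gene *i*'s subgraph, the edge
from entity *e* to its sampled neighbor *e′* is weighted by the **partner**
gene's embedding:

    ω_{e,e′} = ⟨ e_j , r_{e,e′} ⟩ ,      ω̃ = softmax over the k children,

where `r_{e,e′}` is the relation-type embedding. Each sweep step aggregates
the weighted neighborhood and updates the parent with a sum aggregator

    e ← φ( W (e + Σ_{e′} ω̃_{e,e′} e′) + b ) ,

with ReLU on hidden layers and tanh on the final (hop-0) update — an
all-ReLU stack can only emit non-negative logits, which would make the
below-0.5 probability range unreachable (`final_activation="relu"` restores
the literal all-ReLU variant). After `H` sweeps the pair score is the
sigmoid inner product `ŝ_ij = σ(⟨ê_i, ê_j⟩)`, classified at threshold 0.5.
Training minimizes the summed logit cross-entropy

    J = max(ŝ, 0) − ŝ·s + log(1 + e^{−|ŝ|})

plus `α/2` times the squared L2 norm of the embedding rows touched by the
batch and all layer weights, with Adam (defaults: lr 0.002, α 0.0039,
k = 64, d = 256, H = 2). Everything — forward pass, reverse-mode gradients,
Adam — is implemented in numpy (float64) and verified against finite
differences and a nested-loop reference in the test suite.

Because real SL corpora are large external downloads, the package ships a
first-class synthetic generator: genes participate in latent "factor"
entities with skewed popularity, SL labels are planted through factor
sharing, and decoy entities/relations carry no signal. A degree-preserving
KG edge shuffle provides the matched ablation control.

## Worked example

`python examples/02_train_and_evaluate.py` trains on the default
planted-factor corpus (300 genes, 3000 balanced pairs, 8:1:1 split) and
prints:

```
stopped after 23 epochs, best epoch 17
train loss at best epoch: 0.2152 (mean per-pair total loss)
train: AUC=0.9827  AUPR=0.9833  F1=0.9335
valid: AUC=0.8435  AUPR=0.8420  F1=0.7884
test : AUC=0.8714  AUPR=0.8563  F1=0.7672
```

Test AUC 0.87 against a 0.5 chance level means the model recovered the
planted shared-factor mechanism from the KG on pairs it never saw.
`python examples/03_kg_ablation.py` repeats the training on a
degree-preserving edge shuffle of the same KG:

```
intact   KG: test AUC = 0.8714
shuffled KG: test AUC = 0.7765
AUC delta (intact - shuffled): 0.0948
```

The residual 0.78 under shuffling is what gene-embedding memorization of the
training labels achieves alone; the ~0.09 delta is the contribution of KG
*content* (the shuffle preserves all degree statistics). The other examples
build a corpus (`01`) and score individual candidate pairs (`04`).

## Command line

The same pipeline is scriptable via a thin CLI:

```
slkgnn simulate --out corpus/ --seed 0
slkgnn train    --kg corpus/kg_triplets.tsv --entities corpus/kg_entities.tsv \
                --pairs corpus/sl_pairs.csv --k 8 --d 32 --out run/ --seed 0
slkgnn evaluate --checkpoint run/ --kg ... --entities ... --pairs ...
slkgnn predict  --checkpoint run/ --kg ... --entities ... --pairs cand.csv --out preds.csv
slkgnn ablate   --kg ... --entities ... --pairs ... --k 8 --d 32 --out ablation/
```

File formats: KG triplets TSV (`head_id  relation  tail_id`), entities TSV
(`entity_id  entity_type`), pairs CSV (`gene_a,gene_b[,label]`; without a
label column all rows are positives and balanced negatives are sampled).
Every run directory gets a JSON manifest (config, seeds, input hashes,
metrics) and refuses overwrites without `--force`.

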