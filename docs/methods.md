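# Methods

## Problem and model

Given a heterogeneous knowledge graph G = (V_e, V_r) of typed entities and
typed directed triplets (h, r, t), and a set of labelled synthetic-lethality
(SL) gene pairs, the model learns a scoring function ŝ_ij estimating the
probability that genes i and j are an SL pair.

**Receptive fields.** Degrees in biomedical KGs are heavy-tailed, so each
entity contributes a fixed number k of neighbors per hop, sampled uniformly
*with replacement* from its incident edges; nodes with fewer than k
neighbors necessarily contribute duplicates. We use one code path (always
with replacement) rather than switching to without-replacement above degree
k: the expectation of the weighted average is unchanged and the variance
difference is immaterial at the k values used. Traversal is undirected with
relation types preserved — genes are predominantly tail entities in
biomedical schemas and a directed-only walk would orphan them; no inverse
relation types are introduced. Hop h of a field has exactly k^h entries and
cycles are permitted (a gene may resample itself two hops out).

**Partner-conditioned weighting.** The weight of edge (e, e′) inside gene
i's subgraph is the inner product between the *partner* gene j's embedding
and the relation-type embedding, softmax-normalized over the k children of
e. The conditioning vector is the partner's raw embedding-table row, not
its encoded output — conditioning on the encoded output would make each
encoding depend on the other and the definition circular. The same relation
type can therefore matter for one partner and be ignored for another, which
is the mechanism that lets the model down-weight uninformative relation
types (the synthetic decoy relations exercise exactly this).

**Aggregation.** One bottom-up sweep runs from hop H to hop 0. Each parent
aggregates its k children by the normalized weights and updates as
φ(W(e + e_P(e)) + b). Layer parameters (W, b) are per-sweep-step, not
shared: `layer_weights[0]` acts at the deepest level, `layer_weights[H-1]`
produces the final encoding. Leaf entities enter as raw embedding rows with
no frontier pre-aggregation. Hidden activations are ReLU; the final (hop-0)
update uses tanh by default. The tanh choice is deliberate: with ReLU
everywhere the two encodings are element-wise non-negative, every logit is
≥ 0, every probability ≥ 0.5, and the threshold-0.5 classifier can never
emit a negative — F1 becomes degenerate. `final_activation="relu"` restores
the all-ReLU reading for comparison.

**Scoring and loss.** The pair logit is ⟨ê_i, ê_j⟩, the probability its
sigmoid, the hard label thresholded at 0.5. The base loss is the
numerically stable cross-entropy *on logits*,
max(x,0) − x·s + log(1+e^(−|x|)); feeding the sigmoid output instead is
available behind `loss_on_logit=False`, but the stable algebraic form is
precisely the on-logits formulation, so logits are the default. The
regularizer is α times half the sum of squared entries of (a) the entity
embedding rows touched by the current batch's receptive fields and partner
genes, (b) the touched relation embedding rows, and (c) all layer weight
matrices; biases are not decayed. The mixed-norm shorthand ‖e‖+‖r‖+‖W‖² is
read uniformly as squared L2 norms — the unsquared reading is non-smooth at
zero and inconsistent with an L2 weight-decay regularizer; the ½ factor is
a convention that only rescales α. Decaying only touched rows keeps the
effective per-row decay rate independent of corpus size.

**Optimization.** Mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), summed
(not averaged) batch loss, defaults lr = 0.002, α = 0.0039, batch 256.
Training receptive fields are re-drawn fresh every epoch — a cheap
stochastic regularizer — while validation/test fields are drawn once under
a seed derived from the run seed, so per-epoch metrics move only because
parameters move. Early stopping tracks validation AUC with patience 10
(default) and restores the best-epoch parameters. All randomness (init,
field resampling, batch order, evaluation fields) derives from one
`TrainConfig.seed` through a `SeedSequence`, making runs bit-reproducible
single-threaded.

**Gradients.** No autodiff framework is used: the backward pass is written
by hand (softmax Jacobian, weighted-sum, linear layers, scatter-adds into
the embedding tables, the partner-conditioning path included). It is
checked two ways in the tests: central finite differences on random
coordinates (relative error ≤ 1e-4) and a pure-python nested-loop
implementation of the whole forward pass that must agree to 1e-9.

## Evaluation

AUC (average-rank tie handling), AUPR (step interpolation / average
precision) and F1 at threshold 0.5, computed via scikit-learn and
cross-checked in the tests against hand-rolled O(n²) rank and step-walk
references. Metrics require both classes present; single-class inputs
raise an explicit undefined-metric error rather than returning a number.
The `loss` reported per split is the mean per-pair cross-entropy without
the regularizer, so splits of different sizes are comparable.

## Synthetic corpus

The generator emulates the mechanism premise — shared latent factors
(process/pathway-like entities) underlie SL pairs — with the signal placed
*only* in the KG:

- 300 genes, each participating in 2 of 30 factor entities; factor
  popularity is Zipf-skewed (weight ∝ 1/rank) to mimic hub heterogeneity;
  any factor left unchosen is attached to one random gene so no node is
  isolated.
- 200 distractor entities of decoy types wired to genes through 5 decoy
  relation types at the same edge density as the factor edges; decoys carry
  no label information by construction.
- Unordered gene pairs are labelled SL with probability 0.9 when the genes
  share ≥ 1 factor and 0.02 otherwise, then balanced to 1500/1500 by
  rejection sampling and split 8:1:1.

With these rates ~95% of positives and ~3% of negatives share a factor, so
the trivial oracle "predict SL iff shared factor" reaches test AUC ≈ 0.96 —
an approximate ceiling certifying the planted signal. The ablation control
permutes tail endpoints within each relation type (repairing self-loops and
duplicates by pairwise swaps), which preserves entity/triplet counts,
per-relation edge counts and every node's degree sequence while destroying
the gene–factor semantics; the oracle drops to ≈ 0.5 on the shuffled graph.

What the generator does **not** emulate: real relation-type semantics and
their 24-type catalogue, realistic degree distributions beyond a one-knob
skew, correlated negatives (real "unknown" pairs are not uniformly random),
and gene–gene KG edges. Passing tests therefore demonstrate that the
architecture recovers relational signal routed through shared KG neighbors
under controlled conditions — not performance on any real SL corpus.

## Benchmark configuration and problem sizes

The reference defaults (k = 64, d = 256, H = 2) are sized for
million-edge KGs. The synthetic corpus has ~530 entities, 1200 edges and
gene degrees around 4–6, so the benchmark runs used by the test suite and
`scripts/acceptance.py` size the model to the fixture: **d = 32, k = 8,
H = 2, lr = 0.002, α = 0.0039, batch 256, ≤ 30 epochs, patience 6**. H = 2
is essential: genes reach other genes through shared factors in exactly two
hops. Under these conditions the model reaches mean held-out AUC ≈ 0.85
over three seeds on the intact KG versus ≈ 0.78 on the shuffled control —
the shuffled residual is pure label memorization through the embedding
table, and the gap is the KG-content contribution. The small-scale examples
in `examples/` use the same configuration.

## Numerical choices and edge cases

- float64 throughout; softmax is max-shifted; the loss uses log1p/abs forms.
- Glorot-style uniform init ±sqrt(6/(fan_in+fan_out)) per tensor shape,
  biases zero.
- Duplicate input triplets collapse to one (multiset edges would silently
  bias the sampler); self-loop triplets are rejected unless explicitly
  allowed (the layer update already has a self term).
- Negative sampling enumerates the unknown-pair population when it is small
  (≤ 2·10⁶ pairs) and falls back to rejection sampling above that.
- Split sizes follow floor(ratio·n) for train/valid with the remainder to
  test.
- AUC ties use the average-rank (Mann–Whitney) convention.

## Known limitations

- Pure-numpy training is CPU-bound and single-threaded by design
  (reproducibility); corpora at the scale of real SL databases would need
  hours, not the seconds the synthetic fixture takes.
- Negatives are sampled from unknown pairs, so some "negatives" may be
  undiscovered positives; metrics inherit that standard caveat.
- The relation weight depends only on (partner, relation type), not on the
  specific neighbor entity; attention over entities is deliberately out of
  scope.
- No k-fold cross-validation driver; the single 8:1:1 split with early
  stopping is the supported protocol.
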