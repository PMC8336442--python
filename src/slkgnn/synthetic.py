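"""Schema-faithful synthetic knowledge graphs with planted SL labels.

The generator emulates the premise that SL pairs arise from shared latent
mechanisms: genes participate in latent "factor" entities (biological-process
style), and an unordered gene pair is synthetic-lethal with high probability
when the genes share at least one factor and with low probability otherwise.
The signal lives ONLY in the knowledge graph (factor sharing), never in the
SL-pair topology itself, so a degree-preserving edge shuffle of the KG is a
clean ablation control: after shuffling, "shares a factor" carries no
information about the planted labels.

Besides the informative gene--factor ``participates`` edges, the graph has
distractor entities of decoy types wired to genes via decoy relation types at
comparable density; these carry no label information by construction and
exercise the relation-weighting mechanism.  Factor popularity is drawn from a
skewed (Zipf-like) distribution to reproduce the hub-degree heterogeneity of
real biomedical KGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .errors import CapacityError, ConfigError
from .kg_store import KnowledgeGraph, SLDataset, SLPair, split_dataset

log = logging.getLogger(__name__)

PARTICIPATES = "participates"
DECOY_RELATIONS = ("binds", "treats", "expresses", "resembles", "interacts")
DECOY_ETYPES = ("compound", "disease", "anatomy")


@dataclass
class SyntheticSpec:
    """Study conditions for the planted-factor corpus (defaults are the
    benchmark conditions: 300 genes, 30 factors, 3000 balanced pairs)."""

    n_genes: int = 300
    n_factors: int = 30
    n_distractor_entities: int = 200
    factors_per_gene: int = 2
    n_relation_types: int = 6
    p_pos_shared: float = 0.9
    p_pos_unshared: float = 0.02
    n_pairs: int = 3000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_pos_unshared < self.p_pos_shared <= 1):
            raise ConfigError(
                f"need 0 <= p_pos_unshared < p_pos_shared <= 1, got "
                f"{self.p_pos_unshared}, {self.p_pos_shared}"
            )
        if self.n_factors < 2 or self.factors_per_gene < 1:
            raise ConfigError("need n_factors >= 2 and factors_per_gene >= 1")
        if self.factors_per_gene > self.n_factors:
            raise ConfigError("factors_per_gene cannot exceed n_factors")
        if self.n_relation_types < 2 or self.n_relation_types > 1 + len(DECOY_RELATIONS):
            raise ConfigError(
                f"n_relation_types must be in [2, {1 + len(DECOY_RELATIONS)}]"
            )
        if self.n_pairs % 2:
            raise ConfigError("n_pairs must be even (balanced corpus)")

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _factor_id(i: int) -> str:
    return f"F{i:03d}"


def _distractor_id(i: int) -> str:
    return f"D{i:03d}"


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, dict[int, frozenset[int]]]:
    """Build the synthetic KG; returns the graph and the gene -> factor map.

    Every gene gets ``factors_per_gene`` distinct factors sampled with
    Zipf-skewed popularity; any factor left unused is attached to one random
    gene so no node is isolated.  Distractor edges (distractor, decoy
    relation, gene) are added at the same density as the factor edges.  The
    assignment map is keyed by the graph's internal gene index.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [_gene_id(i) for i in range(spec.n_genes)]
    factor_ids = [_factor_id(i) for i in range(spec.n_factors)]
    distractor_ids = [_distractor_id(i) for i in range(spec.n_distractor_entities)]

    weights = 1.0 / np.arange(1, spec.n_factors + 1)
    weights /= weights.sum()
    assignment_raw: dict[str, set[str]] = {}
    for g in gene_ids:
        picks = rng.choice(spec.n_factors, size=spec.factors_per_gene, replace=False, p=weights)
        assignment_raw[g] = {factor_ids[i] for i in picks}
    used = set().union(*assignment_raw.values()) if assignment_raw else set()
    for f in factor_ids:
        if f not in used:  # keep the factor connected; counts invariant
            g = gene_ids[int(rng.integers(0, spec.n_genes))]
            assignment_raw[g].add(f)

    triplets = [(g, PARTICIPATES, f) for g in gene_ids for f in sorted(assignment_raw[g])]

    decoy_rels = list(DECOY_RELATIONS[: spec.n_relation_types - 1])
    n_decoy_edges = spec.n_genes * spec.factors_per_gene
    decoy_edges: set[tuple[str, str, str]] = set()
    for d in distractor_ids:  # each distractor touches at least one gene
        g = gene_ids[int(rng.integers(0, spec.n_genes))]
        r = decoy_rels[int(rng.integers(0, len(decoy_rels)))]
        decoy_edges.add((d, r, g))
    guard = 0
    while len(decoy_edges) < max(n_decoy_edges, len(distractor_ids)) and guard < 100 * n_decoy_edges:
        d = distractor_ids[int(rng.integers(0, len(distractor_ids)))]
        g = gene_ids[int(rng.integers(0, spec.n_genes))]
        r = decoy_rels[int(rng.integers(0, len(decoy_rels)))]
        decoy_edges.add((d, r, g))
        guard += 1
    triplets += sorted(decoy_edges)

    entity_types = {g: "gene" for g in gene_ids}
    entity_types.update({f: "biological_process" for f in factor_ids})
    entity_types.update({d: DECOY_ETYPES[i % len(DECOY_ETYPES)] for i, d in enumerate(distractor_ids)})

    kg = KnowledgeGraph.from_raw(triplets, entity_types)
    assignment = {
        kg.entity_index[g]: frozenset(kg.entity_index[f] for f in facs)
        for g, facs in assignment_raw.items()
    }
    return kg, assignment


def plant_sl_labels(assignment: dict[int, frozenset[int]], spec: SyntheticSpec, seed: int) -> SLDataset:
    """Sample a balanced labelled pair corpus from the factor-sharing model.

    Candidate unordered pairs are drawn uniformly; a pair is labelled 1 with
    probability ``p_pos_shared`` when the genes share a factor and
    ``p_pos_unshared`` otherwise, and kept until ``n_pairs/2`` positives and
    negatives are banked (rejection sampling, capped at 100x oversampling).
    Returns an 8:1:1 split dataset.
    """
    genes = np.array(sorted(assignment), dtype=np.int64)
    n = len(genes)
    if n < 2:
        raise ConfigError("need at least two genes")
    ss = np.random.SeedSequence(seed).generate_state(2)
    rng = np.random.default_rng(int(ss[0]) % 2**31)
    quota = spec.n_pairs // 2
    pos: list[SLPair] = []
    neg: list[SLPair] = []
    seen: set[tuple[int, int]] = set()
    attempts, max_attempts = 0, 100 * spec.n_pairs
    while (len(pos) < quota or len(neg) < quota) and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = int(genes[min(i, j)]), int(genes[max(i, j)])
        if (a, b) in seen:
            continue
        shared = bool(assignment[a] & assignment[b])
        p = spec.p_pos_shared if shared else spec.p_pos_unshared
        label = int(rng.random() < p)
        if label and len(pos) < quota:
            seen.add((a, b))
            pos.append(SLPair(a, b, 1))
        elif not label and len(neg) < quota:
            seen.add((a, b))
            neg.append(SLPair(a, b, 0))
    if len(pos) < quota or len(neg) < quota:
        raise CapacityError(
            f"could not bank {quota}+{quota} labelled pairs within {max_attempts} draws; "
            "increase n_genes or relax n_pairs"
        )
    ds = split_dataset(pos + neg, ratio=(0.8, 0.1, 0.1), seed=int(ss[1]) % 2**31)
    ds.gene_universe = set(int(g) for g in genes)
    return ds


def shuffle_kg_edges(kg: KnowledgeGraph, seed: int) -> KnowledgeGraph:
    """Degree-preserving ablation control: permute tail endpoints within each
    relation type, destroying edge semantics while preserving graph size,
    per-relation edge counts and every node's degree sequence.

    Permutations that would create self-loops or duplicate triplets are
    repaired by pairwise tail swaps, so all graph invariants still hold.
    """
    rng = np.random.default_rng(seed)
    raw = kg.raw_triplets()
    by_rel: dict[str, list[tuple[str, str]]] = {}
    for h, r, t in raw:
        by_rel.setdefault(r, []).append((h, t))
    shuffled: list[tuple[str, str, str]] = []
    for r in sorted(by_rel):
        pairs = by_rel[r]
        heads = [h for h, _ in pairs]
        tails = [t for _, t in pairs]
        m = len(pairs)
        perm = rng.permutation(m)
        new_tails = [tails[i] for i in perm]
        _repair(heads, new_tails, rng)
        shuffled += [(heads[i], r, new_tails[i]) for i in range(m)]
    entity_types = {e.raw_id: e.etype for e in kg.entities}
    return KnowledgeGraph.from_raw(shuffled, entity_types)


def _repair(heads: list[str], tails: list[str], rng: np.random.Generator, max_rounds: int = 200) -> None:
    """Swap tails pairwise until no self-loops or duplicate edges remain."""
    m = len(heads)
    for _ in range(max_rounds):
        seen: dict[tuple[str, str], int] = {}
        bad: list[int] = []
        for i in range(m):
            e = (heads[i], tails[i])
            if heads[i] == tails[i] or e in seen:
                bad.append(i)
            else:
                seen[e] = i
        if not bad:
            return
        for i in bad:
            j = int(rng.integers(0, m))
            tails[i], tails[j] = tails[j], tails[i]
    raise CapacityError("could not de-duplicate shuffled edges; graph too dense to rewire")


def shares_factor(kg: KnowledgeGraph, gene_a: int, gene_b: int, relation: str = PARTICIPATES) -> bool:
    """Whether two genes touch a common entity via the given relation type.

    Recomputed from the graph itself (not the generator's assignment map) so
    it reflects shuffled graphs too.
    """
    r = kg.relation_index.get(relation)
    if r is None:
        return False
    na = kg.neighbors(gene_a)
    nb = kg.neighbors(gene_b)
    fa = set(na[na[:, 1] == r, 0].tolist())
    fb = set(nb[nb[:, 1] == r, 0].tolist())
    return bool(fa & fb)


def shared_factor_indicator(kg: KnowledgeGraph, pairs: list[SLPair]) -> np.ndarray:
    """0/1 oracle score per pair: 1 iff the genes share a participates-factor."""
    return np.array([float(shares_factor(kg, p.gene_a, p.gene_b)) for p in pairs])


def benchmark_config(seed: int = 0, **overrides):
    """Training configuration used with the synthetic corpus.

    The synthetic graph has ~530 entities and gene degrees around 4-6, so the
    model is sized to the fixture: d=32, k=8, H=2 (the reference-scale
    defaults k=64, d=256 target corpora three orders of magnitude larger).
    Optimizer settings keep the reference values (lr=0.002, alpha=0.0039).
    """
    from .training import TrainConfig

    base = dict(learning_rate=0.002, l2_alpha=0.0039, batch_size=256,
                max_epochs=30, patience=6, k=8, d=32, H=2, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)
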