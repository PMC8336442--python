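"""Gene-specific multi-hop receptive fields by fixed-size neighbor sampling.

Node degrees in biomedical KGs span orders of magnitude (anatomy hubs with
hundreds of thousands of edges, rarely studied genes with one).  To give every
gene a fixed-shape neighborhood, each entity contributes exactly ``k`` sampled
neighbors per hop, drawn uniformly *with replacement* from its incident edges
(a node with fewer than ``k`` neighbors therefore contributes duplicates).
Repeating for ``H`` hops yields hop arrays of size ``k**h``, aligned so that
the children of ``hop_entities[h][i]`` are
``hop_entities[h+1][i*k:(i+1)*k]`` with the connecting relation types in
``hop_relations[h]`` at the same positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EntityTypeError, InvariantError
from .kg_store import KnowledgeGraph


@dataclass(frozen=True)
class SamplerConfig:
    """Neighbor sample size ``k``, hop count ``H`` and base seed."""

    k: int = 64
    H: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.H < 1:
            raise ConfigError(f"sampler needs k >= 1 and H >= 1, got k={self.k}, H={self.H}")


@dataclass
class ReceptiveField:
    """Per-hop arrays of sampled entities and the relations reaching them.

    ``hop_entities[h]`` has length ``k**h`` (hop 0 is the seed gene alone);
    ``hop_relations[h]`` has length ``k**(h+1)`` and holds the relation type on
    the edge between ``hop_entities[h][i // k]`` and ``hop_entities[h+1][i]``.
    """

    hop_entities: list[np.ndarray]
    hop_relations: list[np.ndarray]

    @property
    def H(self) -> int:
        return len(self.hop_relations)


def sample_neighbors(kg: KnowledgeGraph, entity: int, k: int, rng: np.random.Generator):
    """Draw exactly ``k`` (neighbor, relation) pairs uniformly with replacement."""
    deg = kg.degree(entity)
    if deg == 0:
        raise InvariantError(
            f"entity {entity} has degree 0; isolated nodes must be removed at construction"
        )
    picks = kg.neighbors(entity)[rng.integers(0, deg, size=k)]
    return picks[:, 0].copy(), picks[:, 1].copy()


def build_receptive_field(
    kg: KnowledgeGraph, gene: int, cfg: SamplerConfig, rng: np.random.Generator | None = None
) -> ReceptiveField:
    """Sample the H-hop receptive field of one gene.

    Hop ``h+1`` is produced by one :func:`sample_neighbors` call per entry of
    hop ``h``, concatenated in order; deterministic given the rng state.
    """
    if not kg.is_gene(gene):
        raise EntityTypeError(f"entity {gene} has type {kg.etypes[gene]!r}, expected 'gene'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hop_entities = [np.array([gene], dtype=np.int64)]
    hop_relations: list[np.ndarray] = []
    for _ in range(cfg.H):
        parents = hop_entities[-1]
        ents = np.empty(len(parents) * cfg.k, dtype=np.int64)
        rels = np.empty(len(parents) * cfg.k, dtype=np.int64)
        for i, p in enumerate(parents):
            e, r = sample_neighbors(kg, int(p), cfg.k, rng)
            ents[i * cfg.k:(i + 1) * cfg.k] = e
            rels[i * cfg.k:(i + 1) * cfg.k] = r
        hop_entities.append(ents)
        hop_relations.append(rels)
    return ReceptiveField(hop_entities, hop_relations)


@dataclass
class StackedFields:
    """Receptive fields for a batch of genes, stacked into dense arrays.

    ``ent[h]`` has shape ``(batch, k**h)``; ``rel[h]`` has shape
    ``(batch, k**(h+1))`` and aligns with ``ent[h+1]``.
    """

    ent: list[np.ndarray]
    rel: list[np.ndarray]

    @property
    def H(self) -> int:
        return len(self.rel)

    @property
    def batch(self) -> int:
        return self.ent[0].shape[0]

    def take(self, idx) -> "StackedFields":
        """Row-subset view for mini-batching."""
        return StackedFields([e[idx] for e in self.ent], [r[idx] for r in self.rel])


def stack_fields(fields: list[ReceptiveField]) -> StackedFields:
    ent = [np.stack([f.hop_entities[h] for f in fields]) for h in range(fields[0].H + 1)]
    rel = [np.stack([f.hop_relations[h] for f in fields]) for h in range(fields[0].H)]
    return StackedFields(ent, rel)


def build_stacked_fields(
    kg: KnowledgeGraph, genes: np.ndarray, k: int, H: int, rng: np.random.Generator
) -> StackedFields:
    """Vectorized receptive-field sampling for a whole batch of seed genes.

    Semantically identical to stacking :func:`build_receptive_field` outputs
    (uniform with replacement per parent), but draws all of one hop's samples
    in a single vectorized pass for speed.
    """
    genes = np.asarray(genes, dtype=np.int64)
    B = genes.shape[0]
    offs = kg._nbr_offsets
    flat = kg._nbr_flat
    ent = [genes.reshape(B, 1)]
    rel: list[np.ndarray] = []
    for _ in range(H):
        parents = ent[-1].reshape(-1)
        deg = offs[parents + 1] - offs[parents]
        if np.any(deg == 0):
            bad = int(parents[np.argmax(deg == 0)])
            raise InvariantError(f"entity {bad} has degree 0 during sampling")
        # uniform integer in [0, deg) per parent, vectorized across ragged degrees
        draws = offs[parents, None] + (rng.random((parents.shape[0], k)) * deg[:, None]).astype(np.int64)
        picked = flat[draws]
        ent.append(picked[..., 0].reshape(B, -1))
        rel.append(picked[..., 1].reshape(B, -1))
    return StackedFields(ent, rel)


def dump_receptive_field(field: ReceptiveField, kg: KnowledgeGraph, path) -> None:
    """Debug dump: write the sampled subgraph as a TSV edge list."""
    ids = [e.raw_id for e in kg.entities]
    rels = [r.name for r in kg.relations]
    with open(path, "w") as fh:
        fh.write("hop\tparent_id\trelation\tchild_id\n")
        for h in range(field.H):
            parents = field.hop_entities[h]
            children = field.hop_entities[h + 1]
            k = len(children) // len(parents)
            for i, c in enumerate(children):
                p = parents[i // k]
                r = field.hop_relations[h][i]
                fh.write(f"{h + 1}\t{ids[p]}\t{rels[r]}\t{ids[c]}\n")
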