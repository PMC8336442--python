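"""Data model and I/O for the heterogeneous knowledge graph and the SL pair corpus.

The knowledge graph is a typed multi-relational graph: entities carry a type
(``gene``, ``biological_process``, ``compound``, ...) and edges are directed
triplets ``(head, relation, tail)``.  Neighbor *traversal* is undirected with
the relation type preserved — genes in biomedical KGs are predominantly tail
entities (e.g. ``(anatomy, expresses, gene)``) and a directed-only walk would
orphan them — so the neighbor index stores each triplet twice.

Synthetic-lethality (SL) pairs are unordered pairs of gene-type entities with
a binary label.  Balanced negative sets are drawn uniformly from the unknown
unordered pairs, once, globally, before splitting, so the train/valid/test
splits partition one fixed corpus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    ConfigError,
    EmptyInputError,
    EntityTypeError,
    FormatError,
    ReferentialIntegrityError,
)

log = logging.getLogger(__name__)

TRIPLET_COLUMNS = ("head_id", "relation", "tail_id")
ENTITY_COLUMNS = ("entity_id", "entity_type")


@dataclass(frozen=True)
class Entity:
    """A typed node with a stable external id and a contiguous internal index."""

    raw_id: str
    index: int
    etype: str


@dataclass(frozen=True)
class RelationType:
    name: str
    index: int


@dataclass(frozen=True)
class Triplet:
    """A directed edge ``head --relation--> tail`` in internal indices."""

    head: int
    relation: int
    tail: int


@dataclass(frozen=True)
class SLPair:
    """An unordered labelled gene pair, stored with ``gene_a < gene_b``."""

    gene_a: int
    gene_b: int
    label: int

    def key(self) -> tuple[int, int]:
        return (self.gene_a, self.gene_b) if self.gene_a < self.gene_b else (self.gene_b, self.gene_a)


def make_pair(a: int, b: int, label: int) -> SLPair:
    """Canonicalize an unordered pair so that ``gene_a < gene_b``."""
    if a == b:
        raise ValueError(f"self-pair ({a},{a}) is not a valid SL pair")
    lo, hi = (a, b) if a < b else (b, a)
    return SLPair(lo, hi, int(label))


class KnowledgeGraph:
    """Typed entities, typed directed triplets, and an undirected neighbor index.

    Construction removes isolated entities (those touching no triplet),
    collapses duplicate triplets, assigns contiguous indices sorted
    lexicographically by raw id (reproducible checkpoints), and builds a
    CSR-style symmetric neighbor index used by the fixed-size sampler.
    """

    def __init__(self, entities: list[Entity], relations: list[RelationType], triplets: list[Triplet]):
        self.entities = entities
        self.relations = relations
        self.triplets = triplets
        self.entity_index = {e.raw_id: e.index for e in entities}
        self.relation_index = {r.name: r.index for r in relations}
        self.etypes = [e.etype for e in entities]
        n = len(entities)
        heads = np.fromiter((t.head for t in triplets), dtype=np.int64, count=len(triplets))
        tails = np.fromiter((t.tail for t in triplets), dtype=np.int64, count=len(triplets))
        rels = np.fromiter((t.relation for t in triplets), dtype=np.int64, count=len(triplets))
        src = np.concatenate([heads, tails])
        dst = np.concatenate([tails, heads])
        rr = np.concatenate([rels, rels])
        order = np.argsort(src, kind="stable")
        self._nbr_flat = np.column_stack([dst[order], rr[order]])
        counts = np.bincount(src, minlength=n)
        self._nbr_offsets = np.concatenate([[0], np.cumsum(counts)])

    # -- basic accessors -------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def degree(self, e: int) -> int:
        return int(self._nbr_offsets[e + 1] - self._nbr_offsets[e])

    def neighbors(self, e: int) -> np.ndarray:
        """``(degree, 2)`` array of ``(neighbor index, relation index)`` pairs."""
        return self._nbr_flat[self._nbr_offsets[e]: self._nbr_offsets[e + 1]]

    @property
    def neighbor_index(self) -> list[np.ndarray]:
        """Per-entity neighbor lists (materialized view of the CSR index)."""
        return [self.neighbors(i) for i in range(self.n_entities)]

    def genes(self) -> np.ndarray:
        return np.array([e.index for e in self.entities if e.etype == "gene"], dtype=np.int64)

    def is_gene(self, idx: int) -> bool:
        return self.etypes[idx] == "gene"

    # -- construction ----------------------------------------------------
    @classmethod
    def from_raw(
        cls,
        raw_triplets: list[tuple[str, str, str]],
        entity_types: dict[str, str],
        allow_self_loops: bool = False,
    ) -> "KnowledgeGraph":
        """Build a graph from string triplets plus an id -> type map.

        Raises
        ------
        EmptyInputError
            if there are no triplets.
        ReferentialIntegrityError
            if a triplet references an id absent from ``entity_types``.
        FormatError
            if a self-loop triplet is present and not explicitly permitted.
        """
        if not raw_triplets:
            raise EmptyInputError("no triplets given; a knowledge graph needs at least one edge")
        for h, r, t in raw_triplets:
            if h not in entity_types:
                raise ReferentialIntegrityError(f"triplet head id {h!r} is not declared in the entity table")
            if t not in entity_types:
                raise ReferentialIntegrityError(f"triplet tail id {t!r} is not declared in the entity table")
            if h == t and not allow_self_loops:
                raise FormatError(f"self-loop triplet on {h!r}; pass allow_self_loops=True to permit")
        uniq = sorted(set(raw_triplets))
        n_dup = len(raw_triplets) - len(uniq)
        if n_dup:
            log.info("collapsed %d duplicate triplet(s)", n_dup)
        used = sorted({h for h, _, _ in uniq} | {t for _, _, t in uniq})
        n_isolated = len(entity_types) - len(used)
        if n_isolated:
            log.info("removed %d isolated entit(ies)", n_isolated)
        entities = [Entity(raw_id=i, index=j, etype=entity_types[i]) for j, i in enumerate(used)]
        rel_names = sorted({r for _, r, _ in uniq})
        relations = [RelationType(name=nm, index=j) for j, nm in enumerate(rel_names)]
        eidx = {e.raw_id: e.index for e in entities}
        ridx = {r.name: r.index for r in relations}
        triplets = [Triplet(eidx[h], ridx[r], eidx[t]) for h, r, t in uniq]
        return cls(entities, relations, triplets)

    def raw_triplets(self) -> list[tuple[str, str, str]]:
        ids = [e.raw_id for e in self.entities]
        rels = [r.name for r in self.relations]
        return [(ids[t.head], rels[t.relation], ids[t.tail]) for t in self.triplets]


def load_kg(triplet_path, entity_path, allow_self_loops: bool = False) -> KnowledgeGraph:
    """Load a knowledge graph from the two-file TSV layout.

    ``triplet_path``: TSV with header ``head_id  relation  tail_id``.
    ``entity_path``: TSV with header ``entity_id  entity_type``.
    Every id in the triplet file must appear in the entity file; entities that
    touch no triplet are removed; indices are assigned sorted by raw id.
    """
    tri = _read_tsv(triplet_path, TRIPLET_COLUMNS)
    ent = _read_tsv(entity_path, ENTITY_COLUMNS)
    dup_ids = ent[ent.duplicated("entity_id", keep=False)]
    if not dup_ids.empty and dup_ids.groupby("entity_id")["entity_type"].nunique().max() > 1:
        bad = dup_ids.groupby("entity_id")["entity_type"].nunique()
        raise FormatError(f"entity id(s) declared with conflicting types: {list(bad[bad > 1].index)}")
    entity_types = dict(zip(ent["entity_id"], ent["entity_type"]))
    raw = list(zip(tri["head_id"], tri["relation"], tri["tail_id"]))
    return KnowledgeGraph.from_raw(raw, entity_types, allow_self_loops=allow_self_loops)


def write_kg(kg: KnowledgeGraph, triplet_path, entity_path) -> None:
    """Write the canonical two-file layout (triplets sorted by head, relation, tail)."""
    rows = sorted(kg.raw_triplets())
    pd.DataFrame(rows, columns=list(TRIPLET_COLUMNS)).to_csv(triplet_path, sep="\t", index=False)
    ents = sorted((e.raw_id, e.etype) for e in kg.entities)
    pd.DataFrame(ents, columns=list(ENTITY_COLUMNS)).to_csv(entity_path, sep="\t", index=False)


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# SL pair corpus
# ---------------------------------------------------------------------------

def load_sl_pairs(path, kg: KnowledgeGraph) -> list[SLPair]:
    """Load labelled SL pairs from CSV with header ``gene_a,gene_b[,label]``.

    Rows without a label column are all positives.  Self-pairs are dropped
    (count logged); duplicate unordered pairs keep the first occurrence.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    has_label = "label" in df.columns
    pairs: list[SLPair] = []
    seen: set[tuple[int, int]] = set()
    n_self = n_dup = 0
    for row in df.itertuples(index=False):
        a_id, b_id = row.gene_a, row.gene_b
        for gid in (a_id, b_id):
            if gid not in kg.entity_index:
                raise ReferentialIntegrityError(f"{path}: gene id {gid!r} is not in the knowledge graph")
        a, b = kg.entity_index[a_id], kg.entity_index[b_id]
        for gid, idx in ((a_id, a), (b_id, b)):
            if not kg.is_gene(idx):
                raise EntityTypeError(f"{path}: id {gid!r} is a {kg.etypes[idx]!r} entity, not a gene")
        if a == b:
            n_self += 1
            continue
        label = int(row.label) if has_label else 1
        if label not in (0, 1):
            raise FormatError(f"{path}: label must be 0 or 1, got {label!r}")
        p = make_pair(a, b, label)
        if p.key() in seen:
            n_dup += 1
            continue
        seen.add(p.key())
        pairs.append(p)
    if n_self:
        log.warning("dropped %d self-pair(s)", n_self)
    if n_dup:
        log.info("dropped %d duplicate unordered pair(s)", n_dup)
    return pairs


def load_sl_positives(path, kg: KnowledgeGraph) -> list[SLPair]:
    """Load the positive (label 1) SL pairs from a pair CSV."""
    return [p for p in load_sl_pairs(path, kg) if p.label == 1]


def sample_negatives(positives: list[SLPair], universe: set[int] | np.ndarray, seed: int) -> list[SLPair]:
    """Draw ``len(positives)`` unknown unordered pairs uniformly, without replacement.

    Unknown means: not present among the positives.  Deterministic given
    ``seed``.  Raises :class:`CapacityError` when fewer unknown pairs exist
    than requested.
    """
    uni = np.array(sorted(universe), dtype=np.int64)
    u = len(uni)
    n = len(positives)
    pos_keys = {p.key() for p in positives}
    total = u * (u - 1) // 2
    # positives may involve genes outside `universe`; only pairs inside it shrink the pool
    uni_set = set(uni.tolist())
    inside = {k for k in pos_keys if k[0] in uni_set and k[1] in uni_set}
    available = total - len(inside)
    if available < n:
        raise CapacityError(
            f"need {n} negative pairs but only {available} unknown pairs exist over {u} genes"
        )
    rng = np.random.default_rng(seed)
    if total <= 2_000_000:
        ii, jj = np.triu_indices(u, k=1)
        cand = list(zip(uni[ii].tolist(), uni[jj].tolist()))
        mask = [k not in pos_keys for k in cand]
        avail = [k for k, m in zip(cand, mask) if m]
        pick = rng.choice(len(avail), size=n, replace=False)
        chosen = [avail[i] for i in sorted(pick.tolist())]
    else:  # rejection sampling for large universes
        chosen_set: set[tuple[int, int]] = set()
        chosen = []
        while len(chosen) < n:
            m = max(4 * (n - len(chosen)), 1024)
            a = uni[rng.integers(0, u, size=m)]
            b = uni[rng.integers(0, u, size=m)]
            for x, y in zip(a.tolist(), b.tolist()):
                if x == y:
                    continue
                k = (x, y) if x < y else (y, x)
                if k in pos_keys or k in chosen_set:
                    continue
                chosen_set.add(k)
                chosen.append(k)
                if len(chosen) == n:
                    break
    return [SLPair(a, b, 0) for a, b in chosen]


@dataclass
class SLDataset:
    """Labelled gene pairs with per-pair split tags in {train, valid, test}."""

    pairs: list[SLPair]
    split: list[str]
    gene_universe: set[int] = field(default_factory=set)

    def subset(self, tag: str) -> list[SLPair]:
        return [p for p, s in zip(self.pairs, self.split) if s == tag]

    def arrays(self, tag: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sub = self.subset(tag)
        a = np.array([p.gene_a for p in sub], dtype=np.int64)
        b = np.array([p.gene_b for p in sub], dtype=np.int64)
        y = np.array([p.label for p in sub], dtype=np.float64)
        return a, b, y


def split_dataset(pairs: list[SLPair], ratio=(0.8, 0.1, 0.1), seed: int = 0) -> SLDataset:
    """Randomly split pairs into train/valid/test by the given fractions.

    The permutation is seeded; split sizes are ``floor(ratio*n)`` for train and
    valid with the remainder assigned to test (so 101 pairs at 8:1:1 give
    80/10/11).  Per-split label balance is logged, not enforced.
    """
    if len(pairs) < 10:
        raise ValueError(f"need at least 10 pairs to split, got {len(pairs)}")
    r = tuple(float(x) for x in ratio)
    if len(r) != 3 or any(x <= 0 for x in r):
        raise ConfigError(f"split fractions must all be positive, got {r}")
    if abs(sum(r) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {r}")
    n = len(pairs)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(r[0] * n))
    n_valid = int(np.floor(r[1] * n))
    ordered = [pairs[i] for i in perm]
    tags = ["train"] * n_train + ["valid"] * n_valid + ["test"] * (n - n_train - n_valid)
    universe = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    ds = SLDataset(pairs=ordered, split=tags, gene_universe=universe)
    for tag in ("train", "valid", "test"):
        sub = ds.subset(tag)
        if sub:
            bal = sum(p.label for p in sub) / len(sub)
            log.info("split %s: %d pairs, positive fraction %.3f", tag, len(sub), bal)
    return ds
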