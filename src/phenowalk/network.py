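"""Heterogeneous gene/trait network model.

The central object is a block adjacency matrix over gene nodes and trait
nodes (human diseases or drugs as the *target* trait set, plus phenotype
sets of any number of model species)::

    A = [[ G ,  P ],
         [ Pᵀ,  Φ ]]

where ``G`` is a weighted gene-gene functional network, ``P`` is the
column-concatenation of per-species gene-trait bipartite association
matrices (target species first), and ``Φ`` is block-diagonal holding a
trait-trait similarity matrix for the target species only — similarity
information is unavailable for non-human phenotypes and for drugs, so
those blocks are zero.

Raw trait-trait similarities in [0, 1] are passed through an increasing
logistic squashing ``L(x) = 1 / (1 + exp(c·x + d))`` with ``c < 0`` before
assembly, so that weak text-mined similarities are strongly suppressed
while near-identical traits approach weight one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("phenowalk")

# Default logistic squashing constants: L(0) = 1e-4, L(1) ~= 0.9997.
DEFAULT_LOGISTIC_C = -15.0
DEFAULT_LOGISTIC_D = math.log(9999.0)


class NetworkError(ValueError):
    """Invalid network input (negative weight, unknown id, shape mismatch)."""


# ---------------------------------------------------------------------------
# Index types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneIndex:
    """Ordered universe of gene identifiers with a bijective position map."""

    ids: tuple[str, ...]
    positions: dict[str, int] = field(compare=False)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "GeneIndex":
        ids = tuple(ids)
        positions = {g: i for i, g in enumerate(ids)}
        if len(positions) != len(ids):
            raise NetworkError("gene ids are not unique")
        return cls(ids=ids, positions=positions)

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, gene: str) -> int:
        try:
            return self.positions[gene]
        except KeyError:
            raise NetworkError(f"unknown gene id: {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.positions


@dataclass(frozen=True)
class TraitIndex:
    """Ordered trait identifiers within one species namespace."""

    species: str
    ids: tuple[str, ...]
    positions: dict[str, int] = field(compare=False)

    @classmethod
    def from_ids(cls, species: str, ids: Iterable[str]) -> "TraitIndex":
        ids = tuple(ids)
        positions = {t: i for i, t in enumerate(ids)}
        if len(positions) != len(ids):
            raise NetworkError(f"trait ids not unique for species {species!r}")
        return cls(species=species, ids=ids, positions=positions)

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, trait: str) -> int:
        try:
            return self.positions[trait]
        except KeyError:
            raise NetworkError(
                f"unknown trait id {trait!r} for species {self.species!r}"
            ) from None

    def __contains__(self, trait: str) -> bool:
        return trait in self.positions


# ---------------------------------------------------------------------------
# Matrix-carrying types
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Symmetric weighted gene-gene network with zero diagonal."""

    genes: GeneIndex
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise NetworkError("gene network shape does not match gene index")
        if self.weights.nnz and self.weights.min() < 0:
            raise NetworkError("gene network has negative weights")
        asym = abs(self.weights - self.weights.T)
        if asym.nnz and asym.max() > 0:
            raise NetworkError("gene network is not symmetric")
        if self.weights.diagonal().any():
            raise NetworkError("gene network has self-loops")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def rescaled(self) -> "GeneNetwork":
        """Globally rescale weights to [0, 1] by the maximum edge weight."""
        m = self.weights.max() if self.weights.nnz else 0.0
        if m <= 0:
            return self
        return GeneNetwork(self.genes, (self.weights / m).tocsr())


@dataclass
class BipartiteAssociations:
    """Gene x trait association matrix for one species (binary by default)."""

    genes: GeneIndex
    traits: TraitIndex
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.traits)):
            raise NetworkError("association matrix shape mismatch")
        if self.matrix.nnz and self.matrix.min() < 0:
            raise NetworkError("association weights must be nonnegative")

    @property
    def species(self) -> str:
        return self.traits.species

    def pairs(self) -> list[tuple[str, str]]:
        """All stored (gene, trait) associations."""
        coo = self.matrix.tocoo()
        return [
            (self.genes.ids[i], self.traits.ids[j])
            for i, j in zip(coo.row, coo.col)
        ]

    def without_pairs(self, drop: Iterable[tuple[str, str]]) -> "BipartiteAssociations":
        """Copy with the given (gene, trait) entries zeroed (mask for CV)."""
        m = self.matrix.tolil(copy=True)
        for g, t in drop:
            m[self.genes[g], self.traits[t]] = 0
        out = m.tocsr()
        out.eliminate_zeros()
        return BipartiteAssociations(self.genes, self.traits, out)


@dataclass
class TraitSimilarity:
    """Symmetric trait-trait similarity for one species, entries in [0, 1]."""

    traits: TraitIndex
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.traits)
        if self.matrix.shape != (n, n):
            raise NetworkError("similarity matrix shape mismatch")
        asym = abs(self.matrix - self.matrix.T)
        if asym.nnz and asym.max() > 1e-12:
            raise NetworkError("similarity matrix is not symmetric")

    @classmethod
    def empty(cls, traits: TraitIndex) -> "TraitSimilarity":
        n = len(traits)
        return cls(traits, sp.csr_matrix((n, n)))

    def without_diagonal(self) -> "TraitSimilarity":
        m = self.matrix.tolil(copy=True)
        m.setdiag(0)
        out = m.tocsr()
        out.eliminate_zeros()
        return TraitSimilarity(self.traits, out)


@dataclass(frozen=True)
class LogisticParams:
    """Constants of the logistic similarity squashing L(x) = 1/(1+exp(cx+d))."""

    c: float = DEFAULT_LOGISTIC_C
    d: float = DEFAULT_LOGISTIC_D

    def __post_init__(self) -> None:
        if self.c >= 0:
            raise NetworkError("logistic slope c must be negative (increasing L)")

    def __call__(self, x):
        return 1.0 / (1.0 + np.exp(self.c * np.asarray(x, dtype=float) + self.d))


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_gene_network(
    edge_rows: Iterable[Sequence],
    genes: GeneIndex | None = None,
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (gene_a, gene_b[, weight]) rows.

    Rows without a weight column get weight 1. Duplicate undirected edges
    collapse to the maximum weight. Self-loops are dropped (counted in a
    warning); negative weights are rejected with the offending row.
    """
    cleaned: dict[tuple[str, str], float] = {}
    seen: list[str] = []
    seen_set: set[str] = set()
    n_loops = 0
    for row in edge_rows:
        a, b = str(row[0]), str(row[1])
        if not a or not b:
            raise NetworkError(f"empty gene id in edge row {row!r}")
        w = float(row[2]) if len(row) > 2 else 1.0
        if w < 0:
            raise NetworkError(f"negative edge weight in row {row!r}")
        for g in (a, b):
            if g not in seen_set:
                seen_set.add(g)
                seen.append(g)
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        prev = cleaned.get(key)
        cleaned[key] = w if prev is None else max(prev, w)
    if n_loops:
        logger.warning("dropped %d self-loop edge(s)", n_loops)
    if genes is None:
        genes = GeneIndex.from_ids(seen)
    n = len(genes)
    rows, cols, vals = [], [], []
    for (a, b), w in cleaned.items():
        i, j = genes[a], genes[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    weights = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return GeneNetwork(genes, weights)


def load_associations(
    assoc_rows: Iterable[Sequence],
    genes: GeneIndex,
    species: str,
    traits: TraitIndex | None = None,
) -> BipartiteAssociations:
    """Build per-species associations from (gene, trait_id[, weight]) rows.

    The gene universe is fixed by ``genes``: rows naming unknown genes are
    dropped with a logged count rather than silently extending the index.
    """
    kept: list[tuple[str, str, float]] = []
    trait_ids: list[str] = []
    trait_seen: set[str] = set()
    n_dropped = 0
    for row in assoc_rows:
        g, t = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) > 2 else 1.0
        if g not in genes:
            n_dropped += 1
            continue
        if traits is not None and t not in traits:
            raise NetworkError(f"unknown trait id {t!r} for species {species!r}")
        if t not in trait_seen:
            trait_seen.add(t)
            trait_ids.append(t)
        kept.append((g, t, w))
    if n_dropped:
        logger.warning(
            "species %s: dropped %d association(s) with genes absent from the network",
            species, n_dropped,
        )
    if traits is None:
        traits = TraitIndex.from_ids(species, trait_ids)
    dedup: dict[tuple[int, int], float] = {}
    for g, t, w in kept:
        key = (genes[g], traits[t])
        dedup[key] = max(dedup.get(key, 0.0), w)
    if dedup:
        rows, cols = zip(*dedup)
        vals = list(dedup.values())
    else:
        rows, cols, vals = [], [], []
    m = sp.csr_matrix((vals, (rows, cols)), shape=(len(genes), len(traits)))
    return BipartiteAssociations(genes, traits, m)


def load_trait_similarity(
    sim_rows: Iterable[Sequence],
    traits: TraitIndex,
) -> TraitSimilarity:
    """Build a raw (untransformed) trait similarity matrix from TSV rows."""
    dedup: dict[tuple[int, int], float] = {}
    for row in sim_rows:
        a, b, s = str(row[0]), str(row[1]), float(row[2])
        if not (0.0 <= s <= 1.0):
            raise NetworkError(f"similarity outside [0,1] in row {row!r}")
        if a not in traits or b not in traits:
            raise NetworkError(f"unknown trait in similarity row {row!r}")
        i, j = traits[a], traits[b]
        for key in {(i, j), (j, i)}:
            dedup[key] = max(dedup.get(key, 0.0), s)
    n = len(traits)
    if dedup:
        rows, cols = zip(*dedup)
        m = sp.csr_matrix((list(dedup.values()), (rows, cols)), shape=(n, n))
    else:
        m = sp.csr_matrix((n, n))
    return TraitSimilarity(traits, m)


def read_gene_network_tsv(path) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    return load_gene_network(df.itertuples(index=False, name=None))


def read_associations_tsv(path, genes: GeneIndex, species: str) -> BipartiteAssociations:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    return load_associations(df.itertuples(index=False, name=None), genes, species)


def read_trait_similarity_tsv(path, traits: TraitIndex) -> TraitSimilarity:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    return load_trait_similarity(df.itertuples(index=False, name=None), traits)


# ---------------------------------------------------------------------------
# Transform + assembly
# ---------------------------------------------------------------------------

def logistic_transform(
    raw_sim: TraitSimilarity, params: LogisticParams = LogisticParams()
) -> TraitSimilarity:
    """Apply the logistic squashing entrywise to stored similarities.

    Only stored (nonzero) entries are transformed; absent entries remain
    structural zeros, so sparsity is preserved even though L(0) > 0.
    """
    if raw_sim.matrix.nnz and (raw_sim.matrix.min() < 0 or raw_sim.matrix.max() > 1):
        raise NetworkError("raw similarities must lie in [0, 1]")
    out = raw_sim.matrix.copy().tocsr()
    out.data = params(out.data)
    return TraitSimilarity(raw_sim.traits, out)


@dataclass
class HeterogeneousNetwork:
    """The assembled gene/trait block network.

    ``bipartites`` is ordered with the target species (human diseases or
    drugs) first. ``trait_sim`` covers the target trait block; similarity
    blocks of the remaining species are zero. ``assembled`` is the full
    symmetric (n_genes + n_traits_total)^2 sparse matrix.
    """

    gene_net: GeneNetwork
    bipartites: list[BipartiteAssociations]
    trait_sim: TraitSimilarity
    assembled: sp.csr_matrix

    @property
    def genes(self) -> GeneIndex:
        return self.gene_net.genes

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def target(self) -> BipartiteAssociations:
        return self.bipartites[0]

    @property
    def target_traits(self) -> TraitIndex:
        return self.bipartites[0].traits

    @property
    def n_traits_total(self) -> int:
        return sum(len(b.traits) for b in self.bipartites)

    @property
    def species_order(self) -> list[str]:
        return [b.species for b in self.bipartites]

    def trait_offset(self, species: str) -> int:
        """Column offset of a species' trait block within the composite P."""
        off = 0
        for b in self.bipartites:
            if b.species == species:
                return off
            off += len(b.traits)
        raise NetworkError(f"unknown species {species!r}")

    def composite_p(self) -> sp.csr_matrix:
        return sp.hstack([b.matrix for b in self.bipartites]).tocsr()

    def with_target(self, target: BipartiteAssociations) -> "HeterogeneousNetwork":
        """Rebuild with a replacement target bipartite (used for CV masking)."""
        return assemble(self.gene_net, [target, *self.bipartites[1:]], self.trait_sim)


def assemble(
    gene_net: GeneNetwork,
    bipartites: Sequence[BipartiteAssociations],
    trait_sim: TraitSimilarity | None = None,
    zero_sim_diagonal: bool = True,
    row_normalize_sim: bool = False,
) -> HeterogeneousNetwork:
    """Assemble the block matrix ``[[G, P], [Pᵀ, Φ]]``.

    ``trait_sim`` must be indexed by the first (target) bipartite's traits
    and is expected to be already logistic-transformed. Its diagonal is
    zeroed by default so trivial self-similarity walks (d -> d) do not
    inflate every score uniformly. ``row_normalize_sim`` applies a
    symmetric degree normalization D^-1/2 Φ D^-1/2 before assembly (off
    by default: walk counting uses raw similarity weights; stochastic
    normalization belongs to the random-walk comparators).
    """
    if not bipartites:
        raise NetworkError("at least one (target) bipartite is required")
    genes = gene_net.genes
    for b in bipartites:
        if b.genes.ids != genes.ids:
            missing = sorted(set(genes.ids) ^ set(b.genes.ids))
            raise NetworkError(
                f"gene index mismatch for species {b.species!r}; differing ids: {missing[:10]}"
            )
    target = bipartites[0]
    if trait_sim is None:
        trait_sim = TraitSimilarity.empty(target.traits)
    if trait_sim.traits.ids != target.traits.ids or trait_sim.traits.species != target.species:
        raise NetworkError("trait similarity must be indexed by the target bipartite's traits")
    if zero_sim_diagonal:
        trait_sim = trait_sim.without_diagonal()
    if row_normalize_sim and trait_sim.matrix.nnz:
        sums = np.asarray(trait_sim.matrix.sum(axis=1)).ravel()
        inv = np.divide(1.0, np.sqrt(sums), out=np.zeros_like(sums),
                        where=sums > 0)
        d = sp.diags(inv)
        trait_sim = TraitSimilarity(trait_sim.traits,
                                    (d @ trait_sim.matrix @ d).tocsr())

    p = sp.hstack([b.matrix for b in bipartites]).tocsr()
    n_traits = p.shape[1]
    phi_blocks = [trait_sim.matrix] + [
        sp.csr_matrix((len(b.traits), len(b.traits))) for b in bipartites[1:]
    ]
    phi = sp.block_diag(phi_blocks, format="csr")
    assembled = sp.bmat(
        [[gene_net.weights, p], [p.T, phi]], format="csr"
    )
    assembled.eliminate_zeros()
    return HeterogeneousNetwork(
        gene_net=gene_net,
        bipartites=list(bipartites),
        trait_sim=trait_sim,
        assembled=assembled,
    )
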