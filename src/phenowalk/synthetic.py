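"""Synthetic heterogeneous worlds with planted gene-module/trait structure.

The generator emulates the statistical structure that guilt-by-association
methods exploit: genes belong to functional modules (a weighted stochastic
block model with within/between edge probabilities p_in > p_out), every
trait — target traits and each model species' phenotypes alike — is
anchored to a module and draws most of its genes from it, and trait-trait
similarity for the target species is the Jaccard overlap of the *module
composition* of trait gene sets — similarity reflects which functional
modules two traits draw on, never the identity of individual genes, so
held-out associations cannot leak through the similarity block (text-
mined similarity in the real pipeline is likewise gene-blind). A per-gene "study bias" weight (power-law with a configurable
exponent) skews which genes accumulate associations, mimicking the real
concentration of annotations on well-studied genes. Genomic coordinates
are placed uniformly on a small set of chromosomes so linkage-interval
evaluation is exercisable. A configurable fraction of true target
associations is moved to a hold-out list and masked from the network.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .evaluation import GeneCoordinates
from .network import (
    BipartiteAssociations,
    GeneIndex,
    GeneNetwork,
    HeterogeneousNetwork,
    LogisticParams,
    NetworkError,
    TraitIndex,
    TraitSimilarity,
    assemble,
    logistic_transform,
)

logger = logging.getLogger("phenowalk")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 300
    n_modules: int = 10
    n_traits_target: int = 40
    n_species: int = 4
    traits_per_species: int = 20
    genes_per_trait: int = 8
    genes_per_species_trait: int = 10
    p_in: float = 0.25
    p_out: float = 0.02
    assoc_signal: float = 0.8
    assoc_noise: float = 0.0
    degree_skew: float = 1.0
    holdout_fraction: float = 0.2
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    gene_length_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise NetworkError("require 0 <= p_out < p_in <= 1")
        for name in ("assoc_signal", "assoc_noise", "holdout_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise NetworkError(f"{name} must be in [0, 1]")
        if self.n_modules > self.n_genes:
            raise NetworkError("more modules than genes")
        if self.degree_skew < 0:
            raise NetworkError("degree_skew must be >= 0")


@dataclass
class SyntheticWorld:
    net: HeterogeneousNetwork
    truth: sp.csr_matrix          # full target associations before masking
    holdout: list[tuple[str, str]]
    coords: GeneCoordinates
    config: SyntheticConfig
    raw_trait_sim: TraitSimilarity = None  # pre-transform Jaccard similarities
    modules: np.ndarray = field(default=None)        # gene -> module id
    study_bias: np.ndarray = field(default=None)     # per-gene sampling weight
    study_rank: np.ndarray = field(default=None)     # per-gene study order (1 = most studied)
    target_anchors: np.ndarray = field(default=None)  # target trait -> module

    @property
    def truth_pairs(self) -> list[tuple[str, str]]:
        coo = self.truth.tocoo()
        genes, traits = self.net.genes, self.net.target_traits
        return [(genes.ids[i], traits.ids[j]) for i, j in zip(coo.row, coo.col)]


def _module_jaccard_similarity(assoc: sp.spmatrix, modules: np.ndarray,
                               traits) -> TraitSimilarity:
    """Jaccard overlap of the module sets spanned by each trait's genes.

    Gene-blind by construction: two traits are similar when their gene
    draws cover the same functional modules, so masking an individual
    association never changes what the similarity could reveal about it.
    """
    csc = assoc.tocsc()
    n_t = csc.shape[1]
    module_sets = [set(modules[csc[:, j].nonzero()[0]].tolist())
                   for j in range(n_t)]
    sim = np.zeros((n_t, n_t))
    for i in range(n_t):
        for j in range(i + 1, n_t):
            union = len(module_sets[i] | module_sets[j])
            if union:
                sim[i, j] = sim[j, i] = len(module_sets[i] & module_sets[j]) / union
    return TraitSimilarity(traits, sp.csr_matrix(sim))


def _draw_trait_genes(rng: np.random.Generator, module_members: np.ndarray,
                      all_genes: np.ndarray, bias: np.ndarray,
                      size: int, signal: float) -> np.ndarray:
    """Sample a trait's gene set: within-module w.p. ``signal``, else global.

    Sampling is without replacement, weighted by the study-bias factor.
    """
    chosen: set[int] = set()
    in_module = rng.random(size) < signal
    for use_module in in_module:
        pool = module_members if use_module else all_genes
        pool = np.array([g for g in pool if g not in chosen])
        if pool.size == 0:
            pool = np.array([g for g in all_genes if g not in chosen])
        if pool.size == 0:
            break
        w = bias[pool]
        chosen.add(int(rng.choice(pool, p=w / w.sum())))
    return np.array(sorted(chosen), dtype=int)


def generate(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a fully deterministic world from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = GeneIndex.from_ids([f"g{i:04d}" for i in range(n)])

    # --- gene network: weighted stochastic block model ---
    modules = np.sort(rng.integers(0, config.n_modules, size=n))
    same = modules[:, None] == modules[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    weights = np.triu(rng.uniform(0.0, 1.0, size=(n, n)), k=1) * upper
    # Uniform(0, 1]: resample zeros is overkill; nudge exact zeros on edges
    weights[upper & (weights == 0)] = 1e-9
    dense = weights + weights.T
    gene_net = GeneNetwork(genes, sp.csr_matrix(dense))

    # --- study bias: power-law weight over a random gene order ---
    order = rng.permutation(n)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    bias = ranks ** (-config.degree_skew / 2.0)
    bias /= bias.sum()

    all_gene_idx = np.arange(n)
    module_members = {m: np.where(modules == m)[0] for m in range(config.n_modules)}

    def make_bipartite(species: str, n_traits: int, per_trait: int
                       ) -> tuple[BipartiteAssociations, np.ndarray]:
        traits = TraitIndex.from_ids(species, [f"{species}:t{j:03d}" for j in range(n_traits)])
        anchors = rng.integers(0, config.n_modules, size=n_traits)
        rows, cols = [], []
        for j in range(n_traits):
            members = module_members[int(anchors[j])]
            size = per_trait
            if config.assoc_noise > 0:
                size += int(rng.binomial(n, config.assoc_noise))
            gene_ids = _draw_trait_genes(rng, members, all_gene_idx, bias,
                                         min(size, n), config.assoc_signal)
            rows.extend(gene_ids.tolist())
            cols.extend([j] * len(gene_ids))
        m = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(n, n_traits))
        return BipartiteAssociations(genes, traits, m), anchors

    target, anchors = make_bipartite("target", config.n_traits_target,
                                     config.genes_per_trait)
    others = [
        make_bipartite(f"sp{s}", config.traits_per_species,
                       config.genes_per_species_trait)[0]
        for s in range(config.n_species)
    ]

    # --- target trait similarity: module-composition Jaccard ---
    truth = target.matrix.copy().tocsr()
    raw_sim = _module_jaccard_similarity(truth, modules, target.traits)
    trait_sim = logistic_transform(raw_sim, LogisticParams())

    # --- hold-out: mask a fraction of true target associations ---
    coo = truth.tocoo()
    n_assoc = coo.nnz
    n_hold = int(round(config.holdout_fraction * n_assoc))
    pick = rng.choice(n_assoc, size=n_hold, replace=False)
    holdout = [
        (genes.ids[coo.row[i]], target.traits.ids[coo.col[i]]) for i in pick
    ]
    masked_target = target.without_pairs(holdout)

    # --- coordinates: genes placed uniformly on chromosomes ---
    chroms = rng.integers(0, config.n_chromosomes, size=n)
    starts = rng.integers(1, max(2, config.chrom_length_bp - config.gene_length_bp),
                          size=n)
    coords = GeneCoordinates({
        genes.ids[i]: (f"chr{chroms[i] + 1}", int(starts[i]),
                       int(starts[i] + config.gene_length_bp - 1))
        for i in range(n)
    })

    net = assemble(gene_net, [masked_target, *others], trait_sim)
    return SyntheticWorld(net=net, truth=truth, holdout=holdout,
                          coords=coords, config=config, raw_trait_sim=raw_sim,
                          modules=modules, study_bias=bias, study_rank=ranks,
                          target_anchors=anchors)


def unmasked_network(world: SyntheticWorld) -> HeterogeneousNetwork:
    """The world's network with every true target association visible."""
    full_target = BipartiteAssociations(
        world.net.genes, world.net.target_traits, world.truth.copy()
    )
    return world.net.with_target(full_target)


def degree_biased_variant(world: SyntheticWorld, skew: float) -> SyntheticWorld:
    """Re-draw target associations concentrating them on hub genes.

    Per-trait association totals and module anchors are conserved, but
    each re-drawn association comes from a *global* hub pool (gene
    weights study_rank^(-skew), i.e. the same well-studied genes that
    already dominate the model-species annotations) with probability
    skew/(skew+1), and uniformly from the trait's anchor module
    otherwise. Hubs therefore recur across unrelated
    traits — the multifunctionality regime — with a share that grows
    monotonically in ``skew``. ``skew = 0`` returns the world unchanged
    (identity).
    """
    if skew < 0:
        raise NetworkError("skew must be >= 0")
    if skew == 0:
        return copy.deepcopy(world)
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 977)
    n = cfg.n_genes
    genes = world.net.genes
    target_traits = world.net.target_traits
    bias = world.study_rank.astype(float) ** (-float(skew))
    bias /= bias.sum()
    all_gene_idx = np.arange(n)
    p_module = 1.0 / (1.0 + skew)
    module_members = {m: np.where(world.modules == m)[0]
                      for m in range(cfg.n_modules)}

    truth = world.truth.tocsc()
    uniform = np.full(n, 1.0 / n)
    rows, cols = [], []
    for j in range(truth.shape[1]):
        size = int(truth[:, j].nnz)
        if size == 0:
            continue
        members = module_members[int(world.target_anchors[j])]
        chosen: set[int] = set()
        for _ in range(min(size, n)):
            if rng.random() < p_module:
                pool = np.array([g for g in members if g not in chosen])
                w = uniform[pool] if pool.size else None
            else:
                pool = np.array([g for g in all_gene_idx if g not in chosen])
                w = bias[pool]
            if pool.size == 0:
                pool = np.array([g for g in all_gene_idx if g not in chosen])
                w = bias[pool]
            chosen.add(int(rng.choice(pool, p=w / w.sum())))
        rows.extend(sorted(chosen))
        cols.extend([j] * len(chosen))
    new_truth = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                              shape=truth.shape)

    coo = new_truth.tocoo()
    n_hold = int(round(cfg.holdout_fraction * coo.nnz))
    pick = rng.choice(coo.nnz, size=n_hold, replace=False)
    holdout = [(genes.ids[coo.row[i]], target_traits.ids[coo.col[i]])
               for i in pick]
    new_target = BipartiteAssociations(genes, target_traits, new_truth)
    masked = new_target.without_pairs(holdout)

    raw_sim = _module_jaccard_similarity(new_truth, world.modules, target_traits)
    trait_sim = logistic_transform(raw_sim, LogisticParams())
    net = assemble(world.net.gene_net, [masked, *world.net.bipartites[1:]],
                   trait_sim)
    return SyntheticWorld(net=net, truth=new_truth, holdout=holdout,
                          coords=world.coords, config=cfg, raw_trait_sim=raw_sim,
                          modules=world.modules, study_bias=world.study_bias,
                          target_anchors=world.target_anchors)


# ---------------------------------------------------------------------------
# TSV export (same formats the loaders read)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir) -> dict:
    """Write network/association/similarity/coordinate TSVs plus a manifest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = world.net
    genes = net.genes

    with open(out / "gene_network.tsv", "w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        coo = sp.triu(net.gene_net.weights, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{genes.ids[i]}\t{genes.ids[j]}\t{w:.6g}\n")

    assoc_files = {}
    for b in net.bipartites:
        fname = f"associations_{b.species}.tsv"
        with open(out / fname, "w") as fh:
            fh.write("# gene\ttrait_id\n")
            for g, t in b.pairs():
                fh.write(f"{g}\t{t}\n")
        assoc_files[b.species] = fname

    with open(out / "trait_similarity.tsv", "w") as fh:
        # raw (pre-transform) similarities — the format the loaders read
        fh.write("# trait_a\ttrait_b\tsimilarity\n")
        coo = sp.triu(world.raw_trait_sim.matrix, k=1).tocoo()
        for i, j, s in zip(coo.row, coo.col, coo.data):
            fh.write(f"{net.target_traits.ids[i]}\t{net.target_traits.ids[j]}\t{s:.6g}\n")

    with open(out / "gene_coords.tsv", "w") as fh:
        fh.write("# gene\tchrom\tstart_bp\tend_bp\n")
        for g in genes.ids:
            chrom, s, e = world.coords.of(g)
            fh.write(f"{g}\t{chrom}\t{s}\t{e}\n")

    manifest = {
        "species_order": net.species_order,
        "holdout": [list(p) for p in world.holdout],
        "truth": [list(p) for p in world.truth_pairs],
        "config": {k: getattr(world.config, k)
                   for k in SyntheticConfig.__dataclass_fields__},
        "files": {
            "gene_network": "gene_network.tsv",
            "associations": assoc_files,
            "trait_similarity": "trait_similarity.tsv",
            "gene_coords": "gene_coords.tsv",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
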