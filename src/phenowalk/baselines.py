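"""Comparator methods: RWRH, PRINCE, and the degree list.

RWRH (random walk with restart on the heterogeneous network) runs a
personalized-PageRank-style walk over the combined gene/trait graph:

    M = [[ (1-lam)·rownorm(G),  lam·rownorm(P)   ],
         [ lam·rownorm(Pᵀ),     (1-lam)·rownorm(Φ) ]]

with rows rescaled to remain stochastic when one block is empty, iterating
p <- (1-gamma)·Mᵀp + gamma·p0 from a restart vector over the trait's seed
nodes. PRINCE propagates a similarity-smoothed restart vector over the
degree-normalized gene network only; it never walks through gene-trait or
trait-trait edges. The degree list ranks genes by how many target traits
they are already associated with, regardless of the query trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .katz import ScoreMatrix
from .network import (
    BipartiteAssociations,
    GeneNetwork,
    HeterogeneousNetwork,
    LogisticParams,
    NetworkError,
    TraitSimilarity,
)

logger = logging.getLogger("phenowalk")


@dataclass(frozen=True)
class RWRHParams:
    """Walk parameters: cross-network jump lam, restart gamma, seed split eta."""

    jump_prob: float = 0.5
    restart_prob: float = 0.7
    eta: float = 0.5          # restart mass on the gene side of the seed set
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.jump_prob < 1 and 0 < self.restart_prob <= 1):
            raise NetworkError("require 0 < lambda < 1 and 0 < gamma <= 1")
        if not (0 <= self.eta <= 1):
            raise NetworkError("eta must be in [0, 1]")
        if self.tol <= 0:
            raise NetworkError("tol must be positive")


@dataclass(frozen=True)
class PRINCEParams:
    alpha: float = 0.9
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise NetworkError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# RWRH
# ---------------------------------------------------------------------------

def _rownorm(m: sp.spmatrix) -> sp.csr_matrix:
    m = m.tocsr()
    sums = np.asarray(m.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(inv) @ m


def rwrh_transition_matrix(net: HeterogeneousNetwork,
                           params: RWRHParams = RWRHParams(),
                           multi_species: bool = False) -> sp.csr_matrix:
    """Row-stochastic transition matrix of the heterogeneous walk.

    By default only the target bipartite enters (the configuration the
    method is usually compared in); ``multi_species=True`` swaps in the
    composite P over all species. Rows whose off-diagonal block is empty
    keep their full mass on the nonempty block; fully isolated nodes get
    a unit self-loop so the matrix stays stochastic.
    """
    lam = params.jump_prob
    g = net.gene_net.weights
    if multi_species:
        p = net.composite_p()
        n_tr = net.n_traits_total
        off = net.n_genes + net.trait_offset(net.target.species)
        phi = net.assembled[net.n_genes:, net.n_genes:]
    else:
        p = net.target.matrix
        n_tr = p.shape[1]
        phi = net.trait_sim.matrix
    n_g = net.n_genes

    g_norm, p_norm = _rownorm(g), _rownorm(p)
    pt_norm, phi_norm = _rownorm(p.T), _rownorm(phi)

    g_rows = np.asarray(g.sum(axis=1)).ravel() > 0
    p_rows = np.asarray(p.sum(axis=1)).ravel() > 0
    pt_rows = np.asarray(p.sum(axis=0)).ravel() > 0
    phi_rows = np.asarray(phi.sum(axis=1)).ravel() > 0

    # per-row weights so each row sums to 1
    w_g = np.where(p_rows, 1 - lam, 1.0) * g_rows
    w_p = np.where(g_rows, lam, 1.0) * p_rows
    w_pt = np.where(phi_rows, lam, 1.0) * pt_rows
    w_phi = np.where(pt_rows, 1 - lam, 1.0) * phi_rows

    top = sp.hstack([sp.diags(w_g) @ g_norm, sp.diags(w_p) @ p_norm])
    bottom = sp.hstack([sp.diags(w_pt) @ pt_norm, sp.diags(w_phi) @ phi_norm])
    m = sp.vstack([top, bottom]).tocsr()

    isolated = np.where(~np.concatenate([g_rows | p_rows, pt_rows | phi_rows]))[0]
    if isolated.size:
        m = (m + sp.csr_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=m.shape
        )).tocsr()
    return m


def rwrh_restart_vector(net: HeterogeneousNetwork, trait: str,
                        params: RWRHParams = RWRHParams(),
                        multi_species: bool = False) -> np.ndarray:
    """Restart distribution over the trait node and its known genes."""
    n_g = net.n_genes
    n_tr = net.n_traits_total if multi_species else len(net.target_traits)
    j = net.target_traits[trait]
    trait_node = n_g + (net.trait_offset(net.target.species) if multi_species else 0) + j
    seed_genes = net.target.matrix[:, j].nonzero()[0]
    p0 = np.zeros(n_g + n_tr)
    if seed_genes.size:
        p0[seed_genes] = params.eta / seed_genes.size
        p0[trait_node] = 1 - params.eta
    else:
        p0[trait_node] = 1.0
    return p0


def rwrh_stationary(m: sp.csr_matrix, p0: np.ndarray,
                    params: RWRHParams) -> np.ndarray:
    gamma = params.restart_prob
    mt = m.T.tocsr()
    p = p0.copy()
    for _ in range(params.max_iter):
        nxt = (1 - gamma) * (mt @ p) + gamma * p0
        if np.abs(nxt - p).sum() < params.tol:
            return nxt
        p = nxt
    residual = np.abs((1 - gamma) * (mt @ p) + gamma * p0 - p).sum()
    raise RuntimeError(
        f"RWRH failed to converge in {params.max_iter} iterations (residual {residual:.2e})"
    )


def rwrh_scores(net: HeterogeneousNetwork, trait: str,
                params: RWRHParams = RWRHParams(),
                multi_species: bool = False) -> np.ndarray:
    """Per-gene stationary probabilities for one query trait."""
    if trait not in net.target_traits:
        raise NetworkError(f"unknown target trait {trait!r}")
    m = rwrh_transition_matrix(net, params, multi_species)
    p0 = rwrh_restart_vector(net, trait, params, multi_species)
    if not p0.any():
        raise NetworkError(f"no seed nodes for trait {trait!r}")
    p = rwrh_stationary(m, p0, params)
    return p[: net.n_genes]


def rwrh_score_matrix(net: HeterogeneousNetwork,
                      params: RWRHParams = RWRHParams(),
                      multi_species: bool = False) -> ScoreMatrix:
    """Stationary gene scores for every target trait (shared transition matrix)."""
    m = rwrh_transition_matrix(net, params, multi_species)
    out = np.zeros((net.n_genes, len(net.target_traits)))
    for j, trait in enumerate(net.target_traits.ids):
        p0 = rwrh_restart_vector(net, trait, params, multi_species)
        out[:, j] = rwrh_stationary(m, p0, params)[: net.n_genes]
    return ScoreMatrix(net.genes, net.target_traits, out)


# ---------------------------------------------------------------------------
# PRINCE
# ---------------------------------------------------------------------------

def prince_normalized_adjacency(gene_net: GeneNetwork) -> sp.csr_matrix:
    """Symmetric degree normalization D^{-1/2} G D^{-1/2}; isolated genes -> 0."""
    g = gene_net.weights
    deg = np.asarray(g.sum(axis=1)).ravel()
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    d = sp.diags(inv_sqrt)
    return (d @ g @ d).tocsr()


def prince_restart_vector(target: BipartiteAssociations,
                          trait_sim: TraitSimilarity,
                          trait: str,
                          logistic: LogisticParams = LogisticParams()) -> np.ndarray:
    """Similarity-smoothed restart vector y for one query trait.

    y_g is the (transformed) similarity between the query and the most
    similar trait that gene g is known for; a gene known for the query
    itself gets the transform of raw similarity 1. ``trait_sim`` is
    expected to hold already-transformed values.
    """
    j = target.traits[trait]
    sim_row = np.asarray(trait_sim.matrix[j].todense()).ravel()
    sim_row = sim_row.copy()
    sim_row[j] = float(logistic(1.0))
    assoc = target.matrix.tocsc()
    y = np.zeros(len(target.genes))
    for d_prime in range(len(target.traits)):
        s = sim_row[d_prime]
        if s <= 0:
            continue
        genes_of = assoc[:, d_prime].nonzero()[0]
        if genes_of.size:
            y[genes_of] = np.maximum(y[genes_of], s)
    return y


def prince_scores(gene_net: GeneNetwork,
                  target: BipartiteAssociations,
                  trait_sim: TraitSimilarity,
                  trait: str,
                  params: PRINCEParams = PRINCEParams(),
                  logistic: LogisticParams = LogisticParams()) -> np.ndarray:
    """Propagated scores F = alpha·W'F + (1-alpha)·y iterated to tolerance."""
    if trait not in target.traits:
        raise NetworkError(f"unknown target trait {trait!r}")
    w = prince_normalized_adjacency(gene_net)
    y = prince_restart_vector(target, trait_sim, trait, logistic)
    f = y.copy()
    alpha = params.alpha
    for _ in range(params.max_iter):
        nxt = alpha * (w @ f) + (1 - alpha) * y
        if np.abs(nxt - f).max() < params.tol:
            return nxt
        f = nxt
    residual = np.abs(alpha * (w @ f) + (1 - alpha) * y - f).max()
    raise RuntimeError(
        f"PRINCE failed to converge in {params.max_iter} iterations (residual {residual:.2e})"
    )


def prince_score_matrix(gene_net: GeneNetwork,
                        target: BipartiteAssociations,
                        trait_sim: TraitSimilarity,
                        params: PRINCEParams = PRINCEParams(),
                        logistic: LogisticParams = LogisticParams()) -> ScoreMatrix:
    """All-trait PRINCE scores via one direct solve of (I - alpha·W')F = (1-alpha)·Y."""
    w = prince_normalized_adjacency(gene_net).toarray()
    n = len(gene_net.genes)
    y = np.column_stack([
        prince_restart_vector(target, trait_sim, t, logistic)
        for t in target.traits.ids
    ])
    f = np.linalg.solve(np.eye(n) - params.alpha * w, (1 - params.alpha) * y)
    return ScoreMatrix(gene_net.genes, target.traits, f)


# ---------------------------------------------------------------------------
# Degree baseline
# ---------------------------------------------------------------------------

def degree_rank(target: BipartiteAssociations) -> list[str]:
    """Genes by descending target-association count; one list for all traits."""
    counts = np.asarray((target.matrix > 0).sum(axis=1)).ravel()
    order = np.argsort(-counts, kind="stable")
    return [target.genes.ids[i] for i in order]


def degree_score_matrix(target: BipartiteAssociations) -> ScoreMatrix:
    """Association counts replicated across traits, as a score block."""
    counts = np.asarray((target.matrix > 0).sum(axis=1)).ravel().astype(float)
    block = np.tile(counts[:, None], (1, len(target.traits)))
    return ScoreMatrix(target.genes, target.traits, block)
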