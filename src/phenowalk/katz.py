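"""Truncated Katz scoring on the heterogeneous network.

The truncated Katz similarity between nodes i and j of a graph with
adjacency matrix A is

    S = sum_{l=1..k} beta^l A^l,

a damped count of walks of length at most k: [A^l]_ij is the number of
i-j walks of length l (the sum of edge-weight products, for weighted
graphs), and beta in (0, 1) downweights longer walks. Applied to the
assembled gene/trait block matrix, the gene x target-trait block of S
ranks candidate genes per trait. That block can be accumulated directly
by repeated sparse right-multiplication onto the target-trait columns,
without ever forming full matrix powers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import GeneIndex, HeterogeneousNetwork, NetworkError, TraitIndex

logger = logging.getLogger("phenowalk")

DEFAULT_BETA = 0.01
DEFAULT_MAX_LEN = 4


@dataclass(frozen=True)
class KatzParams:
    """Damping coefficient and truncation length of the walk sum."""

    beta: float = DEFAULT_BETA
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise NetworkError("beta must be positive")
        if self.max_len < 1:
            raise NetworkError("max_len must be >= 1")


@dataclass
class ScoreMatrix:
    """Dense gene x trait score block with its index labels."""

    genes: GeneIndex
    traits: TraitIndex
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.traits)):
            raise NetworkError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise NetworkError("score matrix has non-finite entries")

    def column(self, trait: str) -> np.ndarray:
        return self.scores[:, self.traits[trait]]

    def to_frame(self):
        """Long-format (gene, trait, score) table, per trait by descending score."""
        import pandas as pd

        records = []
        for j, t in enumerate(self.traits.ids):
            order = np.argsort(-self.scores[:, j], kind="stable")
            for i in order:
                records.append((self.genes.ids[i], t, self.scores[i, j]))
        return pd.DataFrame(records, columns=["gene", "trait", "score"])


def _check_finite(a: sp.spmatrix) -> None:
    if a.nnz and not np.all(np.isfinite(a.data)):
        raise NetworkError("adjacency matrix has non-finite entries")


def katz_full(net: HeterogeneousNetwork, params: KatzParams = KatzParams()) -> np.ndarray:
    """Full node x node truncated Katz matrix sum(beta^l A^l, l=1..k), dense."""
    a = net.assembled
    _check_finite(a)
    if params.max_len > 6:
        warnings.warn(
            "max_len > 6: matrix powers densify quickly; consider katz_block",
            stacklevel=2,
        )
    n = a.shape[0]
    power = sp.identity(n, format="csr")
    out = np.zeros((n, n))
    for length in range(1, params.max_len + 1):
        power = (power @ a).tocsr()
        out += (params.beta ** length) * power.toarray()
    return out


def katz_block(net: HeterogeneousNetwork, params: KatzParams = KatzParams(),
               include_direct: bool = True) -> ScoreMatrix:
    """Gene x target-trait block of the truncated Katz sum.

    Accumulates sum(beta^l A^l E) where E selects the target-trait columns,
    multiplying right-to-left so only (N x n_target) intermediates exist.
    ``include_direct=False`` drops the length-1 direct-association term
    beta * P_target (all longer walks are kept).
    """
    a = net.assembled
    _check_finite(a)
    n = a.shape[0]
    n_genes = net.n_genes
    n_target = len(net.target_traits)
    col0 = n_genes + net.trait_offset(net.target.species)
    selector = sp.csr_matrix(
        (np.ones(n_target), (np.arange(col0, col0 + n_target), np.arange(n_target))),
        shape=(n, n_target),
    )
    block = np.zeros((n_genes, n_target))
    cur = (a @ selector).tocsc()  # length-1 walks into the target traits
    for length in range(1, params.max_len + 1):
        if length > 1 or include_direct:
            block += (params.beta ** length) * cur[:n_genes].toarray()
        if length < params.max_len:
            cur = (a @ cur).tocsc()
    return ScoreMatrix(net.genes, net.target_traits, block)


def count_walks(net: HeterogeneousNetwork, source: int, target: int, length: int) -> float:
    """Exhaustively enumerate walks; test oracle for small instances only.

    ``source``/``target`` are node indices into the assembled matrix. For
    weighted graphs the return value is the sum over walks of the product
    of edge weights, i.e. exactly [A^length]_{source,target}.
    """
    a = net.assembled
    n = a.shape[0]
    if n > 50:
        raise NetworkError("count_walks is an enumeration oracle; instance too large")
    if length > 8:
        raise NetworkError("count_walks limited to length <= 8")
    dense = a.toarray()

    def recurse(node: int, remaining: int) -> float:
        if remaining == 0:
            return 1.0 if node == target else 0.0
        total = 0.0
        for nxt in np.nonzero(dense[node])[0]:
            total += dense[node, nxt] * recurse(int(nxt), remaining - 1)
        return total

    return recurse(source, length)
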