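"""Cross-validation protocols and ranking metrics.

Three schemes are provided, all built on the same rank machinery:

* **threefold** — known gene-trait pairs are partitioned into three
  near-equal groups; each group is hidden in turn, methods are re-run on
  the remaining associations, and the rank of every hidden gene within
  its trait's candidate list is recorded.
* **singleton** — restricted to genes with exactly one target-trait
  association; that single association is hidden (leaving the gene with
  no target associations at all), which probes how well a method finds
  traits for genes that look unstudied.
* **linkage** — each hidden gene is ranked only against the genes inside
  its simulated linkage interval (all genes within a fixed basepair
  window of either end of the gene).

Ranks use a conservative worst-rank-within-ties rule, so a scorer that
outputs a constant cannot look good. The headline summary is the rank
CDF, P(rank <= k), alongside macro-averaged precision/recall at k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .baselines import (
    PRINCEParams,
    RWRHParams,
    degree_score_matrix,
    prince_score_matrix,
    rwrh_score_matrix,
)
from .catapult import BiasedSVMParams, catapult_score_matrix, catapult_train
from .katz import KatzParams, ScoreMatrix, katz_block
from .network import HeterogeneousNetwork, LogisticParams, NetworkError

logger = logging.getLogger("phenowalk")

DEFAULT_WINDOW_BP = 10_000_000
DEFAULT_K_MAX = 100

#: A scorer maps a (already masked) network and a seed to a score block.
Scorer = Callable[[HeterogeneousNetwork, int], ScoreMatrix]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankResult:
    trait: str
    hidden_gene: str
    rank: int
    n_candidates: int

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.n_candidates):
            raise NetworkError("rank must lie in 1..n_candidates")


@dataclass
class EvaluationReport:
    scheme: str
    ranks: list[RankResult]
    cdf: np.ndarray                      # P(rank <= k), k = 1..k_max
    pr_curve: list[tuple[float, float]]  # (precision@k, recall@k), k = 1..k_max
    seed: int

    def cdf_at(self, k: int) -> float:
        return float(self.cdf[k - 1])

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "n_ranks": len(self.ranks),
            "cdf": [float(v) for v in self.cdf],
            "pr_curve": [[float(p), float(r)] for p, r in self.pr_curve],
            "ranks": [
                {
                    "trait": r.trait,
                    "hidden_gene": r.hidden_gene,
                    "rank": r.rank,
                    "n_candidates": r.n_candidates,
                }
                for r in self.ranks
            ],
        }


class GeneCoordinates:
    """1-based inclusive genomic intervals, one record per gene."""

    def __init__(self, records: Mapping[str, tuple[str, int, int]]):
        for gene, (_, start, end) in records.items():
            if start > end:
                raise NetworkError(f"start_bp > end_bp for gene {gene!r}")
        self._records = dict(records)

    def __contains__(self, gene: str) -> bool:
        return gene in self._records

    def __len__(self) -> int:
        return len(self._records)

    def of(self, gene: str) -> tuple[str, int, int]:
        return self._records[gene]

    def interval_members(self, gene: str, genes: Iterable[str],
                         window_bp: int = DEFAULT_WINDOW_BP) -> list[str]:
        """Genes on the same chromosome overlapping [start-window, end+window]."""
        chrom, start, end = self.of(gene)
        lo, hi = start - window_bp, end + window_bp
        members = []
        for g in genes:
            if g not in self._records:
                continue
            c, s, e = self._records[g]
            if c == chrom and s <= hi and e >= lo:
                members.append(g)
        return members

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence]) -> "GeneCoordinates":
        records = {}
        for gene, chrom, start, end in rows:
            gene = str(gene)
            if gene in records:
                raise NetworkError(f"duplicate coordinate record for {gene!r}")
            records[gene] = (str(chrom), int(start), int(end))
        return cls(records)

    @classmethod
    def read_tsv(cls, path) -> "GeneCoordinates":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene", "chrom", "start", "end"])
        return cls.from_rows(df.itertuples(index=False, name=None))

    @classmethod
    def from_bed_rows(cls, rows: Iterable[Sequence]) -> "GeneCoordinates":
        """Convert BED-style (chrom, start0, end_excl, gene) rows.

        BED is 0-based half-open; records are stored 1-based inclusive.
        """
        return cls.from_rows(
            (str(name), str(chrom), int(start0) + 1, int(end_excl))
            for chrom, start0, end_excl, name in rows
        )

    def to_bed_rows(self) -> list[tuple[str, int, int, str]]:
        """Export as BED-style 0-based half-open rows."""
        return [(chrom, start - 1, end, gene)
                for gene, (chrom, start, end) in sorted(self._records.items())]


# ---------------------------------------------------------------------------
# Rank machinery
# ---------------------------------------------------------------------------

def threefold_split(associations: Sequence[tuple[str, str]],
                    seed: int) -> list[list[tuple[str, str]]]:
    """Uniform random partition into 3 groups with sizes differing by <= 1."""
    associations = list(associations)
    if len(associations) < 3:
        raise NetworkError("need at least 3 associations for a 3-fold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(associations))
    return [
        [associations[i] for i in chunk]
        for chunk in np.array_split(order, 3)
    ]


def rank_of_hidden(scores: Mapping[str, float],
                   hidden_gene: str,
                   training_positives: Iterable[str],
                   candidate_set: Iterable[str]) -> RankResult:
    """Worst-rank-within-ties position of the hidden gene among candidates.

    rank = 1 + #{strictly better candidates} + #{ties, excluding itself}.
    Training positives are removed from the candidate set. Returns None
    only when callers pre-filtered the hidden gene away; a hidden gene
    missing from the candidate set is an error.
    """
    training = set(training_positives)
    candidates = [g for g in candidate_set if g not in training]
    if hidden_gene not in candidates:
        raise NetworkError(f"hidden gene {hidden_gene!r} absent from candidate set")
    s_hidden = scores[hidden_gene]
    greater = sum(1 for g in candidates if scores[g] > s_hidden)
    tied = sum(1 for g in candidates if scores[g] == s_hidden) - 1
    return RankResult(trait="", hidden_gene=hidden_gene,
                      rank=1 + greater + tied, n_candidates=len(candidates))


def rank_cdf(ranks: Sequence[int], k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """Empirical P(rank <= k) for k = 1..k_max."""
    if len(ranks) == 0:
        raise NetworkError("no ranks to summarize")
    arr = np.asarray(ranks)
    ks = np.arange(1, k_max + 1)
    return (arr[None, :] <= ks[:, None]).mean(axis=1)


def precision_recall_at_k(
    ordered_predictions: Mapping[str, Sequence[str]],
    hidden_sets: Mapping[str, set[str]],
    k_max: int = DEFAULT_K_MAX,
) -> list[tuple[float, float]]:
    """Macro-averaged (precision@k, recall@k) over traits with hidden genes."""
    curves = []
    for trait, hidden in hidden_sets.items():
        if not hidden:
            continue
        preds = list(ordered_predictions[trait])
        hits = np.cumsum([1 if g in hidden else 0 for g in preds[:k_max]])
        hits = np.pad(hits, (0, max(0, k_max - len(hits))), mode="edge") \
            if len(hits) else np.zeros(k_max)
        ks = np.arange(1, k_max + 1)
        curves.append((hits / ks, hits / len(hidden)))
    if not curves:
        raise NetworkError("no traits with nonempty hidden sets")
    precision = np.mean([c[0] for c in curves], axis=0)
    recall = np.mean([c[1] for c in curves], axis=0)
    return list(zip(precision.tolist(), recall.tolist()))


# ---------------------------------------------------------------------------
# Scorer factories
# ---------------------------------------------------------------------------

def katz_scorer(params: KatzParams = KatzParams()) -> Scorer:
    return lambda net, seed: katz_block(net, params)


def catapult_scorer(k: int = 30,
                    params: BiasedSVMParams = BiasedSVMParams(),
                    max_len: int = 4) -> Scorer:
    def score(net: HeterogeneousNetwork, seed: int) -> ScoreMatrix:
        model = catapult_train(net, k=k, params=params, seed=seed, max_len=max_len)
        return catapult_score_matrix(model, net)

    return score


def rwrh_scorer(params: RWRHParams = RWRHParams(),
                multi_species: bool = False) -> Scorer:
    return lambda net, seed: rwrh_score_matrix(net, params, multi_species)


def prince_scorer(params: PRINCEParams = PRINCEParams(),
                  logistic: LogisticParams = LogisticParams()) -> Scorer:
    return lambda net, seed: prince_score_matrix(
        net.gene_net, net.target, net.trait_sim, params, logistic
    )


def degree_scorer() -> Scorer:
    return lambda net, seed: degree_score_matrix(net.target)


def random_scorer() -> Scorer:
    """Uniform random scores — the calibration null for the rank machinery."""

    def score(net: HeterogeneousNetwork, seed: int) -> ScoreMatrix:
        rng = np.random.default_rng(seed)
        block = rng.random((net.n_genes, len(net.target_traits)))
        return ScoreMatrix(net.genes, net.target_traits, block)

    return score


def constant_scorer(value: float = 0.0) -> Scorer:
    def score(net: HeterogeneousNetwork, seed: int) -> ScoreMatrix:
        block = np.full((net.n_genes, len(net.target_traits)), value)
        return ScoreMatrix(net.genes, net.target_traits, block)

    return score


def external_scorer(score_frame) -> Scorer:
    """Scorer backed by a (gene, trait, score) table, e.g. a plug-in method.

    Pairs absent from the table score -inf is not used; they default to
    the table minimum minus one so they rank strictly last.
    """
    import pandas as pd

    df = pd.DataFrame(score_frame, columns=["gene", "trait", "score"]) \
        if not hasattr(score_frame, "columns") else score_frame

    def score(net: HeterogeneousNetwork, seed: int) -> ScoreMatrix:
        floor = float(df["score"].min()) - 1.0
        block = np.full((net.n_genes, len(net.target_traits)), floor)
        for gene, trait, s in df.itertuples(index=False):
            if gene in net.genes and trait in net.target_traits:
                block[net.genes[gene], net.target_traits[trait]] = float(s)
        return ScoreMatrix(net.genes, net.target_traits, block)

    return score


NAMED_SCORERS: dict[str, Callable[[], Scorer]] = {
    "katz": katz_scorer,
    "catapult": catapult_scorer,
    "rwrh": rwrh_scorer,
    "prince": prince_scorer,
    "degree": degree_scorer,
    "random": random_scorer,
}


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

def _assert_masked(net: HeterogeneousNetwork,
                   hidden: Iterable[tuple[str, str]]) -> None:
    # masking hygiene: the pair being scored must be invisible to the scorer
    m = net.target.matrix
    for g, t in hidden:
        if m[net.genes[g], net.target_traits[t]] != 0:
            raise NetworkError(f"hidden association {(g, t)} leaked into the network")


def _rank_batch(net_masked: HeterogeneousNetwork,
                score_block: ScoreMatrix,
                hidden: Sequence[tuple[str, str]],
                truth_pairs: set[tuple[str, str]],
                candidates_for: Callable[[str], Iterable[str]] | None = None,
                ) -> tuple[list[RankResult], dict[str, list[str]], dict[str, set[str]]]:
    """Rank every hidden pair against its trait's candidate list."""
    genes = list(net_masked.genes.ids)
    results: list[RankResult] = []
    ordered: dict[str, list[str]] = {}
    hidden_by_trait: dict[str, set[str]] = {}
    for g, t in hidden:
        hidden_by_trait.setdefault(t, set()).add(g)
    for t, hidden_genes in hidden_by_trait.items():
        training = {
            gg for (gg, tt) in truth_pairs
            if tt == t and (gg, tt) not in {(g, t) for g in hidden_genes}
        }
        col = score_block.column(t)
        scores = {g: float(col[net_masked.genes[g]]) for g in genes}
        # ordered predictions over the genome-wide candidate list (PR curves)
        genome_candidates = [g for g in genes if g not in training]
        order = sorted(genome_candidates, key=lambda g: (-scores[g], g))
        ordered[t] = order
        for g in sorted(hidden_genes):
            cand = genes if candidates_for is None else candidates_for(g)
            rr = rank_of_hidden(scores, g, training, cand)
            results.append(RankResult(trait=t, hidden_gene=g,
                                      rank=rr.rank, n_candidates=rr.n_candidates))
    return results, ordered, hidden_by_trait


def _finalize(scheme: str, all_ranks: list[RankResult],
              ordered: dict, hidden: dict, seed: int,
              k_max: int) -> EvaluationReport:
    cdf = rank_cdf([r.rank for r in all_ranks], k_max)
    pr = precision_recall_at_k(ordered, hidden, k_max)
    return EvaluationReport(scheme=scheme, ranks=all_ranks, cdf=cdf,
                            pr_curve=pr, seed=seed)


def threefold_cv(net: HeterogeneousNetwork, scorer: Scorer, seed: int,
                 k_max: int = DEFAULT_K_MAX) -> EvaluationReport:
    """Hide each third of the target associations in turn and rank them."""
    truth = net.target.pairs()
    folds = threefold_split(truth, seed)
    all_ranks: list[RankResult] = []
    ordered_all: dict[str, list[str]] = {}
    hidden_all: dict[str, set[str]] = {}
    for i, fold in enumerate(folds):
        masked = net.with_target(net.target.without_pairs(fold))
        _assert_masked(masked, fold)
        block = scorer(masked, seed * 31 + i)
        ranks, ordered, hidden = _rank_batch(masked, block, fold, set(truth))
        all_ranks.extend(ranks)
        for t, o in ordered.items():
            # a trait can have hidden genes in several folds; key by fold
            ordered_all[f"{t}#fold{i}"] = o
            hidden_all[f"{t}#fold{i}"] = hidden[t]
    return _finalize("threefold", all_ranks, ordered_all, hidden_all, seed, k_max)


def singleton_genes(net: HeterogeneousNetwork) -> list[str]:
    """Genes with exactly one target-trait association."""
    counts = np.asarray((net.target.matrix > 0).sum(axis=1)).ravel()
    return [net.genes.ids[i] for i in np.where(counts == 1)[0]]


def singleton_cv(net: HeterogeneousNetwork, scorer: Scorer, seed: int,
                 n_batches: int = 3,
                 k_max: int = DEFAULT_K_MAX) -> EvaluationReport:
    """Hide each singleton gene's sole target association and rank it.

    Only target-species associations are masked; the gene's model-species
    phenotype edges stay visible. Retraining is batched (``n_batches``
    groups of singletons masked together) to keep the cost workable.
    """
    truth = net.target.pairs()
    assoc_of = {g: t for g, t in truth}
    singles = singleton_genes(net)
    if not singles:
        raise NetworkError("no singleton genes to evaluate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(singles))
    batches = [b for b in np.array_split(order, min(n_batches, len(singles)))
               if len(b)]
    all_ranks: list[RankResult] = []
    ordered_all: dict[str, list[str]] = {}
    hidden_all: dict[str, set[str]] = {}
    for i, batch in enumerate(batches):
        fold = [(singles[j], assoc_of[singles[j]]) for j in batch]
        masked = net.with_target(net.target.without_pairs(fold))
        _assert_masked(masked, fold)
        block = scorer(masked, seed * 131 + i)
        ranks, ordered, hidden = _rank_batch(masked, block, fold, set(truth))
        all_ranks.extend(ranks)
        for t, o in ordered.items():
            ordered_all[f"{t}#batch{i}"] = o
            hidden_all[f"{t}#batch{i}"] = hidden[t]
    return _finalize("singleton", all_ranks, ordered_all, hidden_all, seed, k_max)


def linkage_interval_cv(net: HeterogeneousNetwork,
                        coords: GeneCoordinates,
                        scorer: Scorer, seed: int,
                        window_bp: int = DEFAULT_WINDOW_BP,
                        k_max: int = DEFAULT_K_MAX) -> EvaluationReport:
    """Rank hidden genes only within their simulated linkage interval."""
    truth = net.target.pairs()
    n_missing = sum(1 for g, _ in truth if g not in coords)
    if n_missing:
        logger.warning("linkage CV: %d hidden pair(s) lack coordinates; excluded",
                       n_missing)
    usable = [(g, t) for g, t in truth if g in coords]
    if not usable:
        raise NetworkError("no hidden pairs with coordinates")
    folds = threefold_split(usable, seed)
    genes = list(net.genes.ids)
    all_ranks: list[RankResult] = []
    ordered_all: dict[str, list[str]] = {}
    hidden_all: dict[str, set[str]] = {}
    for i, fold in enumerate(folds):
        masked = net.with_target(net.target.without_pairs(fold))
        _assert_masked(masked, fold)
        block = scorer(masked, seed * 31 + i)
        ranks, ordered, hidden = _rank_batch(
            masked, block, fold, set(truth),
            candidates_for=lambda g: coords.interval_members(g, genes, window_bp),
        )
        all_ranks.extend(ranks)
        for t, o in ordered.items():
            ordered_all[f"{t}#fold{i}"] = o
            hidden_all[f"{t}#fold{i}"] = hidden[t]
    return _finalize("linkage", all_ranks, ordered_all, hidden_all, seed, k_max)


def top_k_overlap(score_block: ScoreMatrix, k: int = 10) -> float:
    """Mean pairwise Jaccard similarity of per-trait top-k gene lists."""
    tops = []
    for j in range(len(score_block.traits)):
        col = score_block.scores[:, j]
        order = np.argsort(-col, kind="stable")[:k]
        tops.append(set(order.tolist()))
    if len(tops) < 2:
        return 0.0
    sims = []
    for i in range(len(tops)):
        for j in range(i + 1, len(tops)):
            inter = len(tops[i] & tops[j])
            union = len(tops[i] | tops[j])
            sims.append(inter / union if union else 0.0)
    return float(np.mean(sims))
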