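"""Catapult: positive-unlabeled learning over species-resolved walk features.

Each candidate (gene, target-trait) pair is described by the number of
walks of each *kind* connecting the gene to the trait through the
heterogeneous network: walks along the gene network (G), detours through
a particular species' phenotype set (P_s P_sᵀ), and steps through the
target trait-similarity network (Φ_t). The truncated Katz measure fixes
the weight of every length-l walk at beta^l; Catapult instead learns one
weight per walk kind — resolving species individually — with a linear
classifier, so that, e.g., mouse-phenotype detours may count for more
than yeast ones.

Because only positive associations are ever reported, training follows a
positive-unlabeled bagging scheme: repeatedly draw a random pseudo-negative
sample from the unlabeled pairs, train a biased soft-margin SVM (penalty
C+ on misclassified positives, smaller C- on the arbitrary "negatives"),
and aggregate each unlabeled pair's out-of-bag decision values across
bootstrap rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC, LinearSVC

from .katz import KatzParams, ScoreMatrix
from .network import HeterogeneousNetwork, NetworkError

logger = logging.getLogger("phenowalk")

DEFAULT_K = 30
DEFAULT_C_NEG = 1.0
DEFAULT_RATIO_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


# ---------------------------------------------------------------------------
# Walk-feature catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkFeature:
    """One walk kind: (gene-side atoms) · P_target · Φ_target^phi_power.

    ``atoms`` is a sequence over {"G"} ∪ {("PP", species)} composing a
    gene→gene map; "G" contributes walk length 1 and a species detour
    P_s P_sᵀ contributes length 2. Total walk length is
    len_atoms + 1 (for P_target) + phi_power.
    """

    atoms: tuple
    phi_power: int

    @property
    def length(self) -> int:
        return sum(1 if a == "G" else 2 for a in self.atoms) + 1 + self.phi_power

    @property
    def species(self) -> str | None:
        for a in self.atoms:
            if a != "G":
                return a[1]
        return None

    @property
    def name(self) -> str:
        parts = []
        for a in self.atoms:
            if a == "G":
                parts.append("G")
            else:
                parts.append(f"P[{a[1]}]*P[{a[1]}]^T")
        parts.append("P_t")
        parts.extend(["Phi_t"] * self.phi_power)
        return "*".join(parts)


@dataclass
class FeatureCatalogue:
    """Ordered walk kinds mapping genes to target traits, lengths <= max_len."""

    entries: list[WalkFeature]
    max_len: int
    species_order: list[str]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e.length for e in self.entries])


def build_catalogue(net: HeterogeneousNetwork, max_len: int = 4,
                    include_direct: bool = False) -> FeatureCatalogue:
    """Enumerate every distinct walk kind of length <= max_len.

    Gene-side compositions are built from atoms {G, P_s P_sᵀ for every
    species s, the target included}, followed by P_target and then powers
    of Φ_target. When the target similarity block is empty (drug mode),
    Φ-containing kinds are pruned. The length-1 direct term P_target is
    excluded by default: it restates the training label on positives and
    vanishes on every pair one would score.
    """
    if max_len not in (2, 3, 4):
        raise NetworkError("catalogue max_len must be in {2, 3, 4}")
    species = net.species_order
    has_phi = net.trait_sim.matrix.nnz > 0
    atom_choices: list = ["G"] + [("PP", s) for s in species]
    atom_len = {a: (1 if a == "G" else 2) for a in atom_choices}

    prefixes: list[tuple[tuple, int]] = []  # (atoms, atoms_length)

    def grow(atoms: tuple, used: int) -> None:
        prefixes.append((atoms, used))
        for a in atom_choices:
            if used + atom_len[a] + 1 <= max_len:
                grow(atoms + (a,), used + atom_len[a])

    grow((), 0)

    entries = []
    for atoms, used in prefixes:
        max_phi = (max_len - used - 1) if has_phi else 0
        for j in range(0, max_phi + 1):
            feat = WalkFeature(atoms=atoms, phi_power=j)
            if feat.length == 1 and not include_direct:
                continue
            entries.append(feat)
    entries.sort(key=lambda e: (e.length, _entry_sort_key(e, species)))
    return FeatureCatalogue(entries=entries, max_len=max_len, species_order=list(species))


def _entry_sort_key(e: WalkFeature, species: list[str]) -> tuple:
    def atom_key(a):
        return (0, -1) if a == "G" else (1, species.index(a[1]))

    return (tuple(atom_key(a) for a in e.atoms), e.phi_power)


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def feature_score_blocks(net: HeterogeneousNetwork,
                         catalogue: FeatureCatalogue) -> np.ndarray:
    """Walk counts for *all* (gene, target-trait) pairs.

    Returns an array of shape (n_genes, n_target_traits, n_features) where
    entry [g, d, f] is the weighted walk count of kind f from gene g to
    trait d. Each kind is evaluated right-to-left from P_target so all
    intermediates stay (n_genes x n_target) sparse.
    """
    g = net.gene_net.weights
    p_t = net.target.matrix
    phi = net.trait_sim.matrix
    p_by_species = {b.species: b.matrix for b in net.bipartites}

    n_genes, n_t = p_t.shape
    out = np.zeros((n_genes, n_t, len(catalogue)))
    # cache Φ powers applied to P_t
    phi_cache: dict[int, sp.csr_matrix] = {0: p_t.tocsr()}
    for f, feat in enumerate(catalogue.entries):
        j = feat.phi_power
        if j not in phi_cache:
            phi_cache[j] = (phi_cache[j - 1] @ phi).tocsr()
        r = phi_cache[j]
        for a in reversed(feat.atoms):
            if a == "G":
                r = (g @ r).tocsr()
            else:
                p_s = p_by_species[a[1]]
                r = (p_s @ (p_s.T @ r)).tocsr()
        out[:, :, f] = r.toarray()
    return out


@dataclass
class FeatureMatrix:
    """Feature rows for a list of (gene, trait) pairs.

    ``scaling`` holds the per-feature divisor that was applied to
    ``values`` (ones when the matrix is raw walk counts).
    """

    pairs: list[tuple[str, str]]
    catalogue: FeatureCatalogue
    values: np.ndarray
    scaling: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), len(self.catalogue)):
            raise NetworkError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise NetworkError("feature matrix has non-finite entries")
        self._index = {p: i for i, p in enumerate(self.pairs)}

    def rows_for(self, pairs: Iterable[tuple[str, str]]) -> np.ndarray:
        idx = [self._index[p] for p in pairs]
        return self.values[idx]


def compute_features(net: HeterogeneousNetwork,
                     pairs: Sequence[tuple[str, str]],
                     catalogue: FeatureCatalogue,
                     scale: np.ndarray | None = None) -> FeatureMatrix:
    """Walk-count feature rows for the given (gene, trait) pairs.

    Training positives that must not leak are expected to be already
    masked from the network's target bipartite. ``scale`` divides each
    feature column (e.g. the column maxima recorded at training time).
    """
    blocks = feature_score_blocks(net, catalogue)
    genes, traits = net.genes, net.target_traits
    rows = np.empty((len(pairs), len(catalogue)))
    for i, (gid, tid) in enumerate(pairs):
        rows[i] = blocks[genes[gid], traits[tid], :]
    if scale is None:
        scaling = np.ones(len(catalogue))
    else:
        scaling = np.asarray(scale, dtype=float)
        rows = rows / scaling
    return FeatureMatrix(pairs=list(pairs), catalogue=catalogue,
                         values=rows, scaling=scaling)


def all_pairs(net: HeterogeneousNetwork) -> list[tuple[str, str]]:
    """Every (gene, target-trait) pair in row-major gene order."""
    return [(g, t) for g in net.genes.ids for t in net.target_traits.ids]


def loo_feature_rows(net: HeterogeneousNetwork,
                     pairs: Sequence[tuple[str, str]],
                     catalogue: FeatureCatalogue) -> np.ndarray:
    """Leave-one-out walk counts: each pair's own target edge is removed.

    A pair that can be scored never has its own association in the
    network, but a visible positive does — and walk kinds touching the
    target bipartite more than once (e.g. P_t P_tᵀ P_t) then count
    walks through the pair's own edge, inflating exactly the training
    examples. Here every pair's feature row is evaluated with
    P_target[g, t] zeroed, so training positives look like what the
    model will score.

    Walk kinds linear in P_target are corrected in closed form
    (value - w · X[g,g] · Φ^j[t,t] for the kind X·P_t·Φ^j); the few
    kinds containing a target-species detour atom are re-evaluated
    exactly as a vector pipeline with the single entry zeroed in place.
    """
    g_mat = net.gene_net.weights.tocsr()
    p_t = net.target.matrix.tocsr()
    phi = net.trait_sim.matrix.tocsr()
    target_species = net.target.species
    p_by_species = {b.species: b.matrix.tocsr() for b in net.bipartites}
    genes, traits = net.genes, net.target_traits
    n_g, n_t = p_t.shape

    base = compute_features(net, pairs, catalogue).values

    # dense Φ powers (n_t is small) for the diagonal corrections
    max_phi = max((e.phi_power for e in catalogue.entries), default=0)
    phi_dense = phi.toarray()
    phi_pows = [np.eye(n_t)]
    for _ in range(max_phi):
        phi_pows.append(phi_pows[-1] @ phi_dense)

    # per-kind diagonal of the gene-side composition X (linear kinds only)
    def x_diag(atoms: tuple) -> np.ndarray:
        m = sp.identity(n_g, format="csr")
        for a in atoms:
            if a == "G":
                m = (m @ g_mat).tocsr()
            else:
                p_s = p_by_species[a[1]]
                m = (m @ (p_s @ p_s.T)).tocsr()
        return m.diagonal()

    linear = [f for f, e in enumerate(catalogue.entries)
              if all(a == "G" or a[1] != target_species for a in e.atoms)]
    quad = [f for f in range(len(catalogue)) if f not in linear]
    diags = {f: x_diag(catalogue.entries[f].atoms) for f in linear}

    p_mod = p_t.copy()
    out = base.copy()
    for i, (gid, tid) in enumerate(pairs):
        gi, ti = genes[gid], traits[tid]
        row = slice(p_mod.indptr[gi], p_mod.indptr[gi + 1])
        hits = np.where(p_mod.indices[row] == ti)[0]
        if hits.size == 0:
            continue  # pair not stored: base row already leak-free
        idx = p_mod.indptr[gi] + hits[0]
        w = p_mod.data[idx]
        p_mod.data[idx] = 0.0
        for f in linear:
            e = catalogue.entries[f]
            out[i, f] = base[i, f] - w * diags[f][gi] * phi_pows[e.phi_power][ti, ti]
        for f in quad:
            e = catalogue.entries[f]
            u = phi_pows[e.phi_power][:, ti]
            v = p_mod @ u
            a = np.zeros(n_g)
            a[gi] = 1.0
            for atom in e.atoms:  # all atoms symmetric; see note above
                if atom == "G":
                    a = g_mat @ a
                else:
                    p_s = p_mod if atom[1] == target_species \
                        else p_by_species[atom[1]]
                    a = p_s @ (p_s.T @ a)
            out[i, f] = float(a @ v)
        p_mod.data[idx] = w
    return out


# ---------------------------------------------------------------------------
# Biased soft-margin SVM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasedSVMParams:
    """Asymmetric misclassification penalties; C+ >= C- > 0."""

    c_pos: float = 10.0
    c_neg: float = DEFAULT_C_NEG
    intercept: bool = True

    def __post_init__(self) -> None:
        if not (self.c_pos >= self.c_neg > 0):
            raise NetworkError("require c_pos >= c_neg > 0")


def train_biased_svm(x: np.ndarray, labels: np.ndarray,
                     params: BiasedSVMParams = BiasedSVMParams()
                     ) -> tuple[np.ndarray, float]:
    """Solve min ½‖w‖² + C+·Σ_pos ξ_i + C-·Σ_neg ξ_i with hinge constraints.

    Returns (w, intercept). Implemented as a linear-kernel SVM with
    per-sample penalty weights, which optimizes exactly this objective.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NetworkError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise NetworkError("both classes must be present")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise NetworkError("labels must be in {+1, -1}")
    sw = np.where(y > 0, params.c_pos, params.c_neg)
    if params.intercept:
        clf = SVC(kernel="linear", C=1.0, tol=1e-6, cache_size=200,
                  max_iter=100_000)
        clf.fit(x, y, sample_weight=sw)
        return clf.coef_[0].copy(), float(clf.intercept_[0])
    clf = LinearSVC(loss="hinge", C=1.0, fit_intercept=False,
                    tol=1e-10, max_iter=200_000)
    clf.fit(x, y, sample_weight=sw)
    return clf.coef_[0].copy(), 0.0


def svm_objective(w: np.ndarray, b: float, x: np.ndarray, y: np.ndarray,
                  params: BiasedSVMParams) -> float:
    """Primal objective value at (w, b) — used for solver cross-checks."""
    margins = y * (x @ w + b)
    slack = np.maximum(0.0, 1.0 - margins)
    c = np.where(y > 0, params.c_pos, params.c_neg)
    return 0.5 * float(w @ w) + float(c @ slack)


# ---------------------------------------------------------------------------
# Bagging
# ---------------------------------------------------------------------------

@dataclass
class CatapultModel:
    """Aggregated hyperplanes and out-of-bag accumulators from bagging."""

    catalogue: FeatureCatalogue
    features: FeatureMatrix
    hyperplanes: np.ndarray          # (K, n_features)
    intercepts: np.ndarray           # (K,)
    score_sum: np.ndarray            # per pair in features.pairs
    score_count: np.ndarray
    positive_idx: np.ndarray
    unlabeled_idx: np.ndarray
    n_bootstraps: int
    seed: int
    params: BiasedSVMParams
    use_oob: bool = True

    @property
    def mean_hyperplane(self) -> np.ndarray:
        return self.hyperplanes.mean(axis=0)

    @property
    def mean_intercept(self) -> float:
        return float(self.intercepts.mean())


def catapult_fit(x_all: FeatureMatrix,
                 positives: Iterable[tuple[str, str]],
                 unlabeled: Iterable[tuple[str, str]],
                 k: int = DEFAULT_K,
                 params: BiasedSVMParams = BiasedSVMParams(),
                 seed: int = 0) -> CatapultModel:
    """Bagging of biased SVMs over bootstrap pseudo-negative draws.

    Each round draws |positives| unlabeled pairs (without replacement,
    independent across rounds), trains positives (+1) vs the draw (-1),
    and accumulates decision values for every out-of-bag unlabeled pair.
    Fully reproducible from ``seed``.
    """
    positives = list(positives)
    unlabeled = list(unlabeled)
    if set(positives) & set(unlabeled):
        raise NetworkError("positives and unlabeled sets overlap")
    if k < 1:
        raise NetworkError("need at least one bootstrap round")
    if len(unlabeled) < len(positives):
        raise NetworkError("unlabeled pool smaller than the positive set")

    pos_idx = np.array([x_all._index[p] for p in positives], dtype=int)
    unl_idx = np.array([x_all._index[p] for p in unlabeled], dtype=int)
    x = x_all.values
    n_pairs, n_feat = x.shape

    hyperplanes = np.zeros((k, n_feat))
    intercepts = np.zeros(k)
    score_sum = np.zeros(n_pairs)
    score_count = np.zeros(n_pairs, dtype=int)

    x_pos = x[pos_idx]
    streams = np.random.SeedSequence(seed).spawn(k)
    for t in range(k):
        rng = np.random.default_rng(streams[t])
        draw = rng.choice(len(unl_idx), size=len(pos_idx), replace=False)
        neg_rows = unl_idx[draw]
        x_train = np.vstack([x_pos, x[neg_rows]])
        y_train = np.concatenate([np.ones(len(pos_idx)), -np.ones(len(neg_rows))])
        w, b = train_biased_svm(x_train, y_train, params)
        hyperplanes[t] = w
        intercepts[t] = b
        oob = np.setdiff1d(unl_idx, neg_rows, assume_unique=False)
        score_sum[oob] += x[oob] @ w + b
        score_count[oob] += 1
        logger.debug("bootstrap %d: objective=%.4f", t,
                     svm_objective(w, b, x_train, y_train, params))
    return CatapultModel(
        catalogue=x_all.catalogue, features=x_all,
        hyperplanes=hyperplanes, intercepts=intercepts,
        score_sum=score_sum, score_count=score_count,
        positive_idx=pos_idx, unlabeled_idx=unl_idx,
        n_bootstraps=k, seed=seed, params=params,
    )


def catapult_score(model: CatapultModel,
                   pairs: Sequence[tuple[str, str]] | None = None) -> np.ndarray:
    """Aggregated score per pair.

    Out-of-bag accumulator mean where available (and ``use_oob``), else
    the mean decision value over all K hyperplanes.
    """
    if pairs is None:
        idx = np.arange(len(model.features.pairs))
    else:
        try:
            idx = np.array([model.features._index[p] for p in pairs], dtype=int)
        except KeyError as exc:
            raise NetworkError(f"pair not covered by the fitted model: {exc}") from None
    x = model.features.values[idx]
    mean_scores = x @ model.mean_hyperplane + model.mean_intercept
    counts = model.score_count[idx]
    sums = model.score_sum[idx]
    out = mean_scores.copy()
    if model.use_oob:
        mask = counts > 0
        out[mask] = sums[mask] / counts[mask]
    return out


def catapult_score_matrix(model: CatapultModel,
                          net: HeterogeneousNetwork) -> ScoreMatrix:
    """All-pairs scores reshaped to a gene x target-trait block."""
    pairs = all_pairs(net)
    scores = catapult_score(model, pairs)
    block = scores.reshape(len(net.genes), len(net.target_traits))
    return ScoreMatrix(net.genes, net.target_traits, block)


def catapult_train(net: HeterogeneousNetwork,
                   k: int = DEFAULT_K,
                   params: BiasedSVMParams | None = BiasedSVMParams(),
                   seed: int = 0,
                   max_len: int = 4) -> CatapultModel:
    """Convenience end-to-end fit on a network's target associations.

    Positives are the stored target associations; every other (gene,
    target-trait) pair is unlabeled. Feature columns are scaled by their
    maximum over all pairs. ``params=None`` selects the penalties by the
    5-fold recall-at-k tuning protocol before the bagging fit.
    """
    catalogue = build_catalogue(net, max_len=max_len)
    pairs = all_pairs(net)
    raw = compute_features(net, pairs, catalogue)
    positives = set(net.target.pairs())
    # visible positives get leave-one-out rows: their own edge removed
    pos_list = sorted(positives)
    raw_values = raw.values.copy()
    pos_rows = [i for i, p in enumerate(pairs) if p in positives]
    raw_values[pos_rows] = loo_feature_rows(net, [pairs[i] for i in pos_rows],
                                            catalogue)
    colmax = raw_values.max(axis=0)
    scale = np.where(colmax > 0, colmax, 1.0)
    x_all = FeatureMatrix(pairs=raw.pairs, catalogue=catalogue,
                          values=raw_values / scale, scaling=scale)
    unlabeled = [p for p in pairs if p not in positives]
    if params is None:
        c_pos, c_neg = tune_penalties(x_all, sorted(positives), unlabeled,
                                      seed=seed)
        params = BiasedSVMParams(c_pos=c_pos, c_neg=c_neg)
        logger.info("tuned penalties: C+=%g C-=%g", c_pos, c_neg)
    return catapult_fit(x_all, pos_list, unlabeled, k=k,
                        params=params, seed=seed)


def katz_reduction_scores(net: HeterogeneousNetwork,
                          kparams: KatzParams) -> ScoreMatrix:
    """Scores from a hyperplane pinned to the Katz damping weights.

    With every walk kind of length l weighted beta^l on *raw* walk counts,
    and the direct length-1 term beta*P_target added back, the dot-product
    score reproduces the truncated Katz gene x target-trait block exactly.
    """
    catalogue = build_catalogue(net, max_len=kparams.max_len)
    blocks = feature_score_blocks(net, catalogue)
    weights = kparams.beta ** catalogue.lengths
    scores = blocks @ weights
    scores = scores + kparams.beta * net.target.matrix.toarray()
    return ScoreMatrix(net.genes, net.target_traits, scores)


# ---------------------------------------------------------------------------
# Penalty tuning
# ---------------------------------------------------------------------------

def tune_penalties(x_all: FeatureMatrix,
                   positives: Sequence[tuple[str, str]],
                   unlabeled: Sequence[tuple[str, str]],
                   grid: Sequence[tuple[float, float]] | None = None,
                   k_eval: int = 100,
                   seed: int = 0) -> tuple[float, float]:
    """Select (C+, C-) by 5-fold recall-at-k on a 70% validation pool.

    70% of the positives form the validation pool, split into 5 folds.
    For each grid point and fold, a biased SVM is trained on the other 4
    folds' positives plus an equally sized random pseudo-negative sample;
    the held fold's recall within the top ``k_eval`` predictions (over the
    held fold plus all unlabeled pairs) is recorded. The grid point with
    the best mean recall wins; ties go to the smaller C+/C- ratio.
    """
    if grid is None:
        grid = [(r * DEFAULT_C_NEG, DEFAULT_C_NEG) for r in DEFAULT_RATIO_GRID]
    if not grid:
        raise NetworkError("empty penalty grid")
    positives = list(positives)
    if len(positives) < 5:
        raise NetworkError("need at least 5 positives for 5-fold tuning")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(len(positives))[: max(5, int(round(0.7 * len(positives))))]
    folds = np.array_split(pool, 5)
    unl_rows = x_all.rows_for(unlabeled)

    best: tuple[float, tuple[float, float]] | None = None
    for c_pos, c_neg in grid:
        params = BiasedSVMParams(c_pos=c_pos, c_neg=c_neg)
        recalls = []
        for i, held in enumerate(folds):
            if len(held) == 0:
                continue
            train_pos = np.concatenate([f for j, f in enumerate(folds) if j != i])
            neg_pick = rng.choice(len(unlabeled), size=len(train_pos), replace=False)
            x_train = np.vstack([
                x_all.values[[x_all._index[positives[p]] for p in train_pos]],
                unl_rows[neg_pick],
            ])
            y_train = np.concatenate([np.ones(len(train_pos)), -np.ones(len(neg_pick))])
            w, b = train_biased_svm(x_train, y_train, params)
            held_rows = x_all.values[[x_all._index[positives[p]] for p in held]]
            held_scores = held_rows @ w + b
            unl_scores = unl_rows @ w + b
            all_scores = np.concatenate([held_scores, unl_scores])
            cutoff_rank = min(k_eval, len(all_scores))
            threshold = np.sort(all_scores)[::-1][cutoff_rank - 1]
            hits = int(np.sum(held_scores >= threshold))
            recalls.append(hits / len(held))
        mean_recall = float(np.mean(recalls))
        key = (-mean_recall, c_pos / c_neg)
        if best is None or key < best[0]:
            best = (key, (c_pos, c_neg))
    return best[1]
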