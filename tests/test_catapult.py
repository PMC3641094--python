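"""Catapult: walk-feature catalogue, biased SVM, bagging, penalty tuning."""

import numpy as np
import pytest
from scipy.optimize import minimize

from phenowalk.catapult import (
    BiasedSVMParams,
    FeatureMatrix,
    all_pairs,
    build_catalogue,
    catapult_fit,
    catapult_score,
    catapult_train,
    compute_features,
    feature_score_blocks,
    katz_reduction_scores,
    loo_feature_rows,
    svm_objective,
    train_biased_svm,
    tune_penalties,
)
from phenowalk.katz import KatzParams, count_walks, katz_block
from phenowalk.network import NetworkError
from phenowalk.synthetic import SyntheticConfig, generate

from conftest import random_heterogeneous_net


def dual_qp_oracle(x, y, params):
    """Independent convex solve of the biased soft-margin problem.

    Solves the Wolfe dual (maximize sum(a) - 1/2 aᵀ Q a over the box
    0 <= a_i <= C_i with sum(a_i y_i) = 0); by strong duality its optimum
    equals the primal objective 1/2 ||w||^2 + sum_i C_i xi_i.
    """
    n, _ = x.shape
    q = (y[:, None] * x) @ (y[:, None] * x).T
    c = np.where(y > 0, params.c_pos, params.c_neg)

    def fun(a):
        return 0.5 * a @ q @ a - a.sum()

    def jac(a):
        return q @ a - 1.0

    from scipy.optimize import LinearConstraint

    res = minimize(
        fun, np.zeros(n), jac=jac, hess=lambda a: q, method="trust-constr",
        bounds=[(0.0, ci) for ci in c],
        constraints=[LinearConstraint(y, 0.0, 0.0)],
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    return -res.fun


class TestCatalogue:
    def test_nine_species_max_len_4_has_45_kinds(self):
        w = generate(SyntheticConfig(
            n_genes=40, n_modules=4, n_traits_target=4, n_species=8,
            traits_per_species=3, genes_per_trait=3, genes_per_species_trait=3,
            seed=5))
        cat = build_catalogue(w.net, max_len=4)
        assert len(cat) == 45  # 2 + (3 + 9) + (4 + 27)
        lengths = cat.lengths
        assert sorted(set(lengths)) == [2, 3, 4]
        assert (lengths == 2).sum() == 2
        assert (lengths == 3).sum() == 12
        assert (lengths == 4).sum() == 31

    def test_no_similarity_prunes_phi_kinds(self, rng):
        net = random_heterogeneous_net(rng, with_sim=False)
        cat = build_catalogue(net, max_len=4)
        assert all(e.phi_power == 0 for e in cat.entries)

    def test_names_deterministic(self, tiny_world):
        c1 = build_catalogue(tiny_world.net, max_len=4)
        c2 = build_catalogue(tiny_world.net, max_len=4)
        assert c1.names == c2.names

    def test_direct_term_excluded_by_default(self, tiny_world):
        cat = build_catalogue(tiny_world.net, max_len=3)
        assert all(e.length >= 2 for e in cat.entries)
        with_direct = build_catalogue(tiny_world.net, max_len=3, include_direct=True)
        assert len(with_direct) == len(cat) + 1

    def test_invalid_max_len_rejected(self, tiny_world):
        with pytest.raises(NetworkError):
            build_catalogue(tiny_world.net, max_len=5)


class TestFeatures:
    def test_features_equal_pattern_restricted_walk_counts(self, rng):
        # each feature must equal the (beta=1) walk count of its block pattern
        net = random_heterogeneous_net(rng, n_genes=6, n_target=2, n_other=1)
        cat = build_catalogue(net, max_len=3)
        blocks = feature_score_blocks(net, cat)
        g = net.gene_net.weights.toarray()
        p_t = net.target.matrix.toarray()
        phi = net.trait_sim.matrix.toarray()
        p_s = {b.species: b.matrix.toarray() for b in net.bipartites}
        for f, feat in enumerate(cat.entries):
            m = np.eye(net.n_genes)
            for atom in feat.atoms:
                m = m @ g if atom == "G" else m @ p_s[atom[1]] @ p_s[atom[1]].T
            m = m @ p_t
            for _ in range(feat.phi_power):
                m = m @ phi
            assert np.allclose(blocks[:, :, f], m, atol=1e-10), feat.name

    def test_all_zero_network_gives_zero_features(self):
        w = generate(SyntheticConfig(
            n_genes=20, n_modules=2, n_traits_target=3, n_species=1,
            traits_per_species=2, genes_per_trait=2, genes_per_species_trait=2,
            p_in=0.5, seed=3))
        net = w.net
        cat = build_catalogue(net, max_len=3)
        empty = net.with_target(net.target.without_pairs(net.target.pairs()))
        # zero the other blocks too by building on empty associations only
        vals = compute_features(empty, [(net.genes.ids[0], net.target_traits.ids[0])], cat)
        target_only = [f for f, e in enumerate(cat.entries)
                       if all(a == "G" or a[1] == "target" for a in e.atoms)]
        assert np.allclose(vals.values[0, target_only], 0)

    def test_shared_phenotype_walk_counted_once(self):
        # gene g2 shares one sp0 phenotype with g1; g1 is the known gene of d1:
        # the species-detour feature for (g2, d1) is exactly 1
        from phenowalk.network import (GeneIndex, assemble, load_associations,
                                       load_gene_network)
        genes = GeneIndex.from_ids(["g1", "g2"])
        gn = load_gene_network([], genes=genes)
        target = load_associations([("g1", "d1")], genes, "target")
        mouse = load_associations([("g1", "m1"), ("g2", "m1")], genes, "mouse")
        net = assemble(gn, [target, mouse])
        cat = build_catalogue(net, max_len=3)
        x = compute_features(net, [("g2", "d1")], cat)
        idx = cat.names.index("P[mouse]*P[mouse]^T*P_t")
        assert x.values[0, idx] == 1.0
        assert x.values[0, [i for i in range(len(cat)) if i != idx]].sum() == 0

    def test_unknown_pair_rejected(self, tiny_world):
        cat = build_catalogue(tiny_world.net, max_len=2)
        with pytest.raises(NetworkError):
            compute_features(tiny_world.net, [("nope", "target:t000")], cat)

    def test_loo_rows_match_per_pair_masked_network(self, rng):
        net = random_heterogeneous_net(rng, n_genes=10, n_target=3, n_other=2)
        cat = build_catalogue(net, max_len=4)
        positives = net.target.pairs()
        loo = loo_feature_rows(net, positives, cat)
        for i, pair in enumerate(positives):
            masked = net.with_target(net.target.without_pairs([pair]))
            ref = compute_features(masked, [pair], cat).values[0]
            assert np.allclose(loo[i], ref, atol=1e-10)


class TestBiasedSVM:
    def test_separable_points_zero_slack(self):
        x = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        w, b = train_biased_svm(x, y, BiasedSVMParams(c_pos=10, c_neg=1))
        margins = y * (x @ w + b)
        assert np.all(margins >= 1 - 1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_objective_matches_convex_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(8, 30))
        d = int(rng.integers(2, 10))
        x = rng.normal(size=(n, d))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if len(set(y)) < 2:
            y[0] = -y[0]
        params = BiasedSVMParams(c_pos=float(rng.choice([1, 2, 5, 10])), c_neg=1.0)
        w, b = train_biased_svm(x, y, params)
        obj = svm_objective(w, b, x, y, params)
        ref = dual_qp_oracle(x, y, params)
        assert obj == pytest.approx(ref, rel=1e-4, abs=1e-8)

    def test_label_swap_antisymmetry_with_equal_penalties(self, rng):
        x = rng.normal(size=(12, 3))
        y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        params = BiasedSVMParams(c_pos=2.0, c_neg=2.0)
        w1, b1 = train_biased_svm(x, y, params)
        w2, b2 = train_biased_svm(x, -y, params)
        assert np.allclose(w1, -w2, atol=1e-4)
        assert b1 == pytest.approx(-b2, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(NetworkError):
            train_biased_svm(np.ones((3, 2)), np.ones(3), BiasedSVMParams())

    def test_positive_slack_count_decreases_with_cpos(self, rng):
        # as C+ grows the classifier tolerates fewer positive-side mistakes
        x = rng.normal(size=(60, 4))
        y = np.where(rng.random(60) < 0.5, 1.0, -1.0)
        counts = []
        for c_pos in (1.0, 10.0, 100.0):
            w, b = train_biased_svm(x, y, BiasedSVMParams(c_pos=c_pos, c_neg=1.0))
            slack = np.maximum(0, 1 - y * (x @ w + b))
            counts.append(int(np.sum(slack[y > 0] > 1e-8)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_invalid_penalties_rejected(self):
        with pytest.raises(NetworkError):
            BiasedSVMParams(c_pos=1.0, c_neg=2.0)


class TestBagging:
    def _fixture(self, seed=0):
        w = generate(SyntheticConfig(
            n_genes=40, n_modules=4, n_traits_target=5, n_species=2,
            traits_per_species=3, genes_per_trait=3, genes_per_species_trait=3,
            seed=seed))
        net = w.net
        cat = build_catalogue(net, max_len=3)
        pairs = all_pairs(net)
        x = compute_features(net, pairs, cat)
        positives = sorted(set(net.target.pairs()))
        unlabeled = [p for p in pairs if p not in set(positives)]
        return x, positives, unlabeled

    def test_k1_scores_equal_single_hyperplane(self):
        x, pos, unl = self._fixture()
        model = catapult_fit(x, pos, unl, k=1, seed=3)
        scores = catapult_score(model, unl)
        w, b = model.hyperplanes[0], model.intercepts[0]
        expected = x.rows_for(unl) @ w + b
        oob = model.score_count[[x._index[p] for p in unl]] > 0
        assert np.allclose(scores[oob], expected[oob])

    def test_same_seed_bit_identical(self):
        x, pos, unl = self._fixture()
        m1 = catapult_fit(x, pos, unl, k=5, seed=9)
        m2 = catapult_fit(x, pos, unl, k=5, seed=9)
        assert np.array_equal(m1.score_sum, m2.score_sum)
        assert np.array_equal(m1.score_count, m2.score_count)
        assert np.array_equal(m1.hyperplanes, m2.hyperplanes)

    def test_never_sampled_pair_gets_mean_hyperplane_score(self):
        x, pos, unl = self._fixture()
        model = catapult_fit(x, pos, unl, k=3, seed=1)
        idx = [x._index[p] for p in unl]
        never = [p for p, i in zip(unl, idx) if model.score_count[i] == 3]
        assert never, "every-round-out-of-bag pairs should exist"
        s = catapult_score(model, never[:5])
        rows = x.rows_for(never[:5])
        expected = (rows @ model.hyperplanes.T + model.intercepts).mean(axis=1)
        assert np.allclose(s, expected)

    def test_scores_invariant_to_pair_order(self):
        x, pos, unl = self._fixture()
        model = catapult_fit(x, pos, unl, k=4, seed=2)
        sub = unl[:20]
        s1 = catapult_score(model, sub)
        s2 = catapult_score(model, sub[::-1])
        assert np.allclose(s1, s2[::-1])

    def test_overlapping_sets_rejected(self):
        x, pos, unl = self._fixture()
        with pytest.raises(NetworkError):
            catapult_fit(x, pos, pos, k=1, seed=0)

    def test_small_unlabeled_pool_rejected(self):
        x, pos, unl = self._fixture()
        with pytest.raises(NetworkError):
            catapult_fit(x, pos, unl[:2], k=1, seed=0)

    def test_holdout_recovery_on_default_world(self, default_world):
        # planted hold-outs must score above the unlabeled background
        model = catapult_train(default_world.net, k=30, seed=4)
        net = default_world.net
        scores = catapult_score(model)
        pair_index = {p: i for i, p in enumerate(model.features.pairs)}
        hold = [pair_index[p] for p in default_world.holdout]
        unl = [i for i in model.unlabeled_idx if i not in set(hold)]
        hold_s, unl_s = scores[hold], scores[unl]
        assert hold_s.mean() > unl_s.mean()
        # rank-sum AUC of holdout vs background
        from scipy.stats import mannwhitneyu
        auc = mannwhitneyu(hold_s, unl_s, alternative="greater").statistic \
            / (len(hold_s) * len(unl_s))
        assert auc > 0.8


class TestKatzReduction:
    @pytest.mark.parametrize("seed", range(10))
    def test_pinned_weights_reproduce_katz_block(self, seed):
        w = generate(SyntheticConfig(
            n_genes=30, n_modules=3, n_traits_target=4, n_species=2,
            traits_per_species=3, genes_per_trait=3, genes_per_species_trait=3,
            seed=seed))
        params = KatzParams(beta=0.2, max_len=3)
        pinned = katz_reduction_scores(w.net, params)
        reference = katz_block(w.net, params)
        assert np.abs(pinned.scores - reference.scores).max() < 1e-10


class TestTunePenalties:
    def test_single_point_grid_returned(self):
        x, pos, unl = TestBagging()._fixture()
        assert tune_penalties(x, pos, unl, grid=[(5.0, 1.0)], seed=0) == (5.0, 1.0)

    def test_dominant_grid_point_wins(self):
        # features equal the label for positives: any penalty separates, but a
        # grid point duplicated with itself must tie-break to the smaller ratio
        x, pos, unl = TestBagging()._fixture()
        best = tune_penalties(x, pos, unl, grid=[(20.0, 1.0), (1.0, 1.0)], seed=0)
        assert best in [(20.0, 1.0), (1.0, 1.0)]
        # reproducibility from seed
        again = tune_penalties(x, pos, unl, grid=[(20.0, 1.0), (1.0, 1.0)], seed=0)
        assert best == again

    def test_too_few_positives_rejected(self):
        x, pos, unl = TestBagging()._fixture()
        with pytest.raises(NetworkError):
            tune_penalties(x, pos[:3], unl, seed=0)
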