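"""SVM affinity axis: fitting, scoring, SV pairing, PCA, orrery regression."""

import numpy as np
import pytest

from idpcompare.affinity import (OrreryCoefficients, affinity_score,
                                 default_tuning_grid, fit_affinity_model,
                                 linearize_scores, pair_support_vectors,
                                 pca_of_differences,
                                 sv_pair_angle_differences)
from idpcompare.torsion import EncodedFeatures, encode_circular
from idpcompare.synthetic import sample_conformations, shift_only_spec


def _features(X, labels=None, variant="v"):
    n, d = X.shape
    if labels is None:
        labels = [(i + 1, "phi") for i in range(d // 2)]
    return EncodedFeatures(X, labels, np.array([variant] * n),
                           np.arange(n))


def _blobs(rng, n=60, sep=4.0, d=4):
    a = rng.normal(size=(n, d)) * 0.3
    b = rng.normal(size=(n, d)) * 0.3
    b[:, 0] += sep
    return _features(a, variant="A"), _features(b, variant="B")


SMALL_GRID = {"gamma": [0.5], "cost": [1.0]}


class TestFit:
    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        fa, fb = _blobs(rng)
        model = fit_affinity_model(fa, fb, SMALL_GRID, folds=5, seed=0)
        X = np.vstack([fa.matrix, fb.matrix])
        y = np.concatenate([np.zeros(60), np.ones(60)])
        assert (model.svc.predict(X) == y).all()
        assert model.cv_accuracy > 0.95

    def test_same_distribution_classes_chance_level(self):
        """Independent draws from one distribution: accuracy ~ 0.5.

        (Exact duplicates are not used: k-fold CV on duplicated points shows
        the anti-learning effect and lands well below chance.)"""
        rng = np.random.default_rng(1)
        model = fit_affinity_model(_features(rng.normal(size=(80, 4))),
                                   _features(rng.normal(size=(80, 4))),
                                   SMALL_GRID, folds=5, seed=0)
        se = np.sqrt(0.25 / 160)
        assert abs(model.cv_accuracy - 0.5) < 3 * se + 0.05

    def test_identical_classes_flagged_as_chance_level(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4))
        with pytest.warns(UserWarning, match="chance"):
            model = fit_affinity_model(_features(X.copy()),
                                       _features(X.copy()),
                                       SMALL_GRID, folds=5, seed=0)
        assert model.chance_level

    def test_annulus_vs_core_needs_rbf(self):
        rng = np.random.default_rng(2)
        n = 500
        core = rng.normal(size=(n, 2)) * 0.5
        theta = rng.uniform(0, 2 * np.pi, n)
        r = rng.normal(3.0, 0.3, n)
        ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        grid = {"gamma": [0.5, 1.0], "cost": [1.0, 10.0]}
        model = fit_affinity_model(_features(core), _features(ring),
                                   grid, folds=5, seed=0)
        assert model.cv_accuracy > 0.95

    def test_class_smaller_than_folds_rejected(self):
        rng = np.random.default_rng(3)
        fa, fb = _blobs(rng, n=4)
        with pytest.raises(ValueError):
            fit_affinity_model(fa, fb, SMALL_GRID, folds=5)

    def test_tie_break_prefers_smaller_cost_then_larger_gamma(self):
        rng = np.random.default_rng(4)
        fa, fb = _blobs(rng, sep=8.0)  # trivially separable: all points tie
        grid = {"gamma": [0.1, 0.5], "cost": [1.0, 10.0]}
        model = fit_affinity_model(fa, fb, grid, folds=5, seed=0)
        best = model.tuning_record["cv_accuracy"].max()
        tied = model.tuning_record[
            model.tuning_record["cv_accuracy"] == best]
        assert model.cost == tied["cost"].min()
        at_cost = tied[tied["cost"] == model.cost]
        assert model.gamma == at_cost["gamma"].max()

    def test_default_grid_shape(self):
        grid = default_tuning_grid(160)
        assert len(grid["gamma"]) == 11 and len(grid["cost"]) == 11
        assert grid["gamma"][0] == 2.0 ** -9 / 160
        assert grid["cost"][-1] == 2.0 ** 7


class TestScores:
    def test_label_swap_negates_scores(self):
        rng = np.random.default_rng(5)
        fa, fb = _blobs(rng)
        m1 = fit_affinity_model(fa, fb, SMALL_GRID, folds=5, seed=0)
        m2 = fit_affinity_model(fb, fa, SMALL_GRID, folds=5, seed=0)
        probe = _features(rng.normal(size=(30, 4)))
        s1 = affinity_score(m1, probe)
        s2 = affinity_score(m2, probe)
        assert np.allclose(s1, -s2, atol=1e-4)  # SMO tolerance

    def test_deep_class_b_points_score_positive(self):
        from scipy.stats import binomtest

        rng = np.random.default_rng(6)
        fa, fb = _blobs(rng, n=200, sep=3.0)
        model = fit_affinity_model(fa, fb, SMALL_GRID, folds=5, seed=0)
        deep = rng.normal(size=(200, 4)) * 0.3
        deep[:, 0] += 3.0
        s = affinity_score(model, _features(deep))
        p = binomtest((s > 0).sum(), 200, 0.5,
                      alternative="greater").pvalue
        assert p < 0.01

    def test_decision_function_matches_kernel_expansion_oracle(self):
        rng = np.random.default_rng(7)
        fa, fb = _blobs(rng, n=40, sep=2.0)
        model = fit_affinity_model(fa, fb, SMALL_GRID, folds=5, seed=0)
        svc = model.svc
        probe = rng.normal(size=(100, 4))
        # explicit sum_i alpha_i y_i K(x_i, .) + b
        sv = svc.support_vectors_
        dual = svc.dual_coef_[0]
        gamma = svc._gamma
        K = np.exp(-gamma * ((probe[:, None, :] - sv[None]) ** 2).sum(-1))
        expected = K @ dual + svc.intercept_[0]
        got = affinity_score(model, _features(probe))
        assert np.allclose(got, expected, atol=1e-8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        fa, fb = _blobs(rng)
        perm = rng.permutation(60)
        fa2 = _features(fa.matrix[perm], variant="A")
        m1 = fit_affinity_model(fa, fb, SMALL_GRID, folds=5, seed=0)
        m2 = fit_affinity_model(fa2, fb, SMALL_GRID, folds=5, seed=0)
        probe = _features(rng.normal(size=(20, 4)))
        assert np.allclose(affinity_score(m1, probe),
                           affinity_score(m2, probe), atol=1e-4)

    def test_free_support_vector_sits_on_unit_margin(self):
        """KKT: an SV with dual weight strictly inside (0, C) has |decision
        value| 1; cross-checked by solving the dual QP independently."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(9)
        fa, fb = _blobs(rng, n=10, sep=1.5)  # 20-point problem
        model = fit_affinity_model(fa, fb, {"gamma": [0.5], "cost": [1.0]},
                                   folds=2, seed=0)
        svc = model.svc
        X = np.vstack([fa.matrix, fb.matrix])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        gamma, C = 0.5, 1.0
        K = np.exp(-gamma * ((X[:, None] - X[None]) ** 2).sum(-1))
        Q = K * np.outer(y, y)

        def neg_dual(alpha):
            return 0.5 * alpha @ Q @ alpha - alpha.sum()

        cons = [{"type": "eq", "fun": lambda a: a @ y}]
        res = minimize(neg_dual, np.full(20, 0.1), constraints=cons,
                       bounds=[(0, C)] * 20, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        alpha = res.x
        # decision values via the QP solution
        free = (alpha > 1e-4) & (alpha < C - 1e-4)
        b_candidates = [y[i] - (alpha * y) @ K[:, i]
                        for i in np.nonzero(free)[0]]
        b = np.mean(b_candidates)
        dec_qp = K @ (alpha * y) + b
        dec_skl = svc.decision_function(X)
        assert np.allclose(dec_qp, dec_skl, atol=1e-3)
        for i in np.nonzero(free)[0]:
            assert abs(abs(dec_skl[i]) - 1.0) < 1e-3


class TestPairing:
    def _model_with_svs(self, sv_a, sv_b):
        class FakeModel:
            angle_labels = [(i + 1, "phi") for i in range(sv_a.shape[1] // 2)]

            def support_by_class(self):
                return sv_a, sv_b

        return FakeModel()

    def test_single_pair_distance(self):
        sv_a = np.array([[1.0, 0.0]])
        sv_b = np.array([[0.0, 1.0]])
        pairs = pair_support_vectors(self._model_with_svs(sv_a, sv_b))
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(np.sqrt(2))

    def test_pair_count_is_min_class_count(self):
        rng = np.random.default_rng(10)
        pairs = pair_support_vectors(
            self._model_with_svs(rng.normal(size=(3, 4)),
                                 rng.normal(size=(2, 4))))
        assert len(pairs) == 2

    def test_greedy_matches_brute_force_sequential_minimum(self):
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(11)
        for _ in range(20):
            sv_a = rng.normal(size=(4, 4))
            sv_b = rng.normal(size=(4, 4))
            pairs = pair_support_vectors(self._model_with_svs(sv_a, sv_b))
            # oracle: repeatedly take the global minimum, removing both
            D = cdist(sv_a, sv_b)
            expected = []
            d = D.copy()
            for _ in range(4):
                i, j = np.unravel_index(np.argmin(d), d.shape)
                expected.append(D[i, j])
                d[i, :] = np.inf
                d[:, j] = np.inf
            assert [p.distance for p in pairs] == pytest.approx(expected)

    def test_each_sv_used_at_most_once(self):
        rng = np.random.default_rng(12)
        sv_a = rng.normal(size=(5, 4))
        sv_b = rng.normal(size=(5, 4))
        pairs = pair_support_vectors(self._model_with_svs(sv_a, sv_b))
        used_a = [tuple(p.vec_a) for p in pairs]
        used_b = [tuple(p.vec_b) for p in pairs]
        assert len(set(used_a)) == len(used_a)
        assert len(set(used_b)) == len(used_b)


class TestAngleDifferences:
    def test_duplicated_pair_mean_equals_difference_zero_width(self):
        from idpcompare.affinity import SupportVectorPair

        rng = np.random.default_rng(13)
        angles_a = rng.uniform(-3, 3, size=3)
        angles_b = angles_a + 0.2
        va = np.empty(6)
        va[0::2], va[1::2] = np.cos(angles_a), np.sin(angles_a)
        vb = np.empty(6)
        vb[0::2], vb[1::2] = np.cos(angles_b), np.sin(angles_b)
        pair = SupportVectorPair(va, vb, 0.0)
        labels = [(i + 1, "phi") for i in range(3)]
        df = sv_pair_angle_differences([pair] * 5, labels)
        assert np.allclose(df["mean"], 0.2, atol=1e-9)
        assert np.allclose(df["hi"] - df["lo"], 0.0, atol=1e-9)

    def test_null_classes_false_flag_rate_nominal(self):
        rates = []
        for s in range(5):
            spec = shift_only_spec(n_residues=10, shift=0.0,
                                   shift_residue=5, seed=s)
            enc_a = encode_circular(sample_conformations(spec, "WT", 300))
            enc_b = encode_circular(sample_conformations(spec, "MUT", 300))
            grid = {"gamma": [1.0 / 40], "cost": [0.125]}
            model = fit_affinity_model(enc_a, enc_b, grid, folds=3, seed=s)
            pairs = pair_support_vectors(model)
            df = sv_pair_angle_differences(pairs, model.angle_labels)
            rates.append((df["flag"] != 0).mean())
        # matched pairs are positively correlated by construction, which
        # makes the per-angle CIs mildly anticonservative at this width
        # (80 angles); the nominal-coverage check at full scale lives in
        # the acceptance suite
        assert np.mean(rates) < 0.2


class TestPca:
    def _pairs_with_column_variance(self, rng, col=2, n=30, d=5):
        from idpcompare.affinity import SupportVectorPair

        pairs = []
        for _ in range(n):
            base = rng.uniform(-1, 1, size=d) * 0.001
            base[col] += rng.normal(scale=0.5)
            angles_a = rng.uniform(-2, 2, size=d)
            angles_b = angles_a + base
            va = np.empty(2 * d)
            va[0::2], va[1::2] = np.cos(angles_a), np.sin(angles_a)
            vb = np.empty(2 * d)
            vb[0::2], vb[1::2] = np.cos(angles_b), np.sin(angles_b)
            pairs.append(SupportVectorPair(va, vb, 0.0))
        return pairs

    def test_single_direction_variance_concentrates_pc1(self):
        rng = np.random.default_rng(14)
        pairs = self._pairs_with_column_variance(rng, col=2)
        loadings, scores, fracs = pca_of_differences(pairs)
        assert abs(loadings[0, 2]) > 0.99

    def test_loadings_orthonormal_and_fracs_sorted(self):
        rng = np.random.default_rng(15)
        pairs = self._pairs_with_column_variance(rng)
        loadings, scores, fracs = pca_of_differences(pairs)
        assert np.allclose(loadings @ loadings.T,
                           np.eye(loadings.shape[0]), atol=1e-9)
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_eigenvalues_match_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(16)
        pairs = self._pairs_with_column_variance(rng)
        diffs = np.array([p.angle_differences() for p in pairs])
        cov = np.cov(diffs, rowvar=False)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        _, scores, fracs = pca_of_differences(pairs)
        got = scores.var(axis=0, ddof=1)
        assert np.allclose(got, expected[:len(got)], atol=1e-9)


class TestLinearize:
    def _encoded(self, rng, n=200, d=6):
        angles = rng.uniform(-np.pi + 0.01, np.pi, size=(n, d))
        labels = [(i + 1, "phi") for i in range(d)]
        from idpcompare.torsion import ConformationSet

        return encode_circular(
            ConformationSet(angles, labels, np.array(["v"] * n))), angles

    def test_recovers_planted_sinusoid(self):
        rng = np.random.default_rng(17)
        enc, angles = self._encoded(rng)
        j = 3
        scores = 2.0 * np.sin(angles[:, j] - 0.3) \
            + rng.normal(scale=0.01, size=angles.shape[0])
        orrery = linearize_scores(scores, enc)
        assert orrery.modulus[j] == pytest.approx(2.0, abs=0.02)
        assert orrery.reference_angle[j] == pytest.approx(0.3, abs=0.02)
        others = np.delete(orrery.modulus, j)
        assert np.all(others < 0.05)

    @pytest.mark.parametrize("beta,beta_p,b,y", [
        (1.0, 0.0, 1.0, 0.0),
        (0.0, 1.0, 1.0, -np.pi / 2),  # b sin(theta - y) expansion
    ])
    def test_modulus_argument_identities(self, beta, beta_p, b, y):
        oc = OrreryCoefficients([(1, "phi")], np.array([beta]),
                                np.array([beta_p]), 0.0)
        assert oc.modulus[0] == pytest.approx(b)
        assert oc.reference_angle[0] == pytest.approx(y)
        theta = np.linspace(-3, 3, 50)
        assert np.allclose(oc.evaluate(0, theta),
                           beta * np.sin(theta) + beta_p * np.cos(theta),
                           atol=1e-12)

    def test_constant_scores_give_zero_moduli(self):
        rng = np.random.default_rng(18)
        enc, _ = self._encoded(rng, n=20)
        orrery = linearize_scores(np.full(20, 3.7), enc)
        assert np.allclose(orrery.modulus, 0.0, atol=1e-10)
        assert orrery.intercept == pytest.approx(3.7)

    def test_rank_deficient_design_is_deterministic(self):
        rng = np.random.default_rng(19)
        enc, angles = self._encoded(rng, n=5, d=6)  # 5 rows, 12 columns
        scores = np.sin(angles[:, 0])
        o1 = linearize_scores(scores, enc)
        o2 = linearize_scores(scores.copy(), enc)
        assert np.allclose(o1.modulus, o2.modulus)
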