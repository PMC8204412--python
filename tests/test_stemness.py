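import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.stats import rankdata

import splicestem as st
from splicestem.stemness import StemnessScores


def _rand_instance(rng, n, p):
    return rng.normal(0, 1, (n, p))


class TestOclrObjective:
    def test_value_and_gradient_at_origin(self):
        rng = np.random.default_rng(0)
        X = _rand_instance(rng, 10, 4)
        loss, grad = st.oclr_objective(np.zeros(4), X, lambda_=0.0)
        assert loss == pytest.approx(np.log(2))
        np.testing.assert_allclose(grad, -X.mean(axis=0) / 2, atol=1e-12)

    def test_single_sample_minimizer_matches_bisection_root(self):
        # d/dw [-log sigma(w) + w^2/2] = sigma(w) - 1 + w; root by bisection
        f = lambda w: 1 / (1 + np.exp(-w)) - 1 + w
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            lo, hi = (mid, hi) if f(mid) < 0 else (lo, mid)
        root = (lo + hi) / 2
        assert root == pytest.approx(0.4004, abs=1e-3)
        res = optimize.minimize(
            st.oclr_objective, [0.0], args=(np.array([[1.0]]), 1.0), jac=True,
            options={"gtol": 1e-10})
        assert res.x[0] == pytest.approx(root, abs=1e-6)

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = _rand_instance(rng, 10, 4)
            w = rng.normal(0, 1, 4)
            lam = rng.uniform(0.01, 1)
            _, grad = st.oclr_objective(w, X, lam)
            num = optimize.approx_fprime(
                w, lambda v: st.oclr_objective(v, X, lam)[0], 1e-7)
            np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            st.oclr_objective(np.zeros(3), np.zeros((5, 4)), 0.1)

    def test_convexity_along_random_segments(self):
        rng = np.random.default_rng(2)
        X = _rand_instance(rng, 15, 5)
        for _ in range(20):
            w1, w2 = rng.normal(0, 2, 5), rng.normal(0, 2, 5)
            t = rng.uniform()
            mid = st.oclr_objective(t * w1 + (1 - t) * w2, X, 0.1)[0]
            chord = t * st.oclr_objective(w1, X, 0.1)[0] + \
                (1 - t) * st.oclr_objective(w2, X, 0.1)[0]
            assert mid <= chord + 1e-12


def _toy_expr(rng, n_genes=12, n_samples=20):
    vals = pd.DataFrame(
        rng.lognormal(3, 1, (n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return st.ExpressionMatrix(vals)


class TestTrainOclr:
    def test_duplicating_training_samples_leaves_w_unchanged(self):
        rng = np.random.default_rng(3)
        expr = _toy_expr(rng)
        stem = list(expr.sample_ids[:8])
        m1 = st.train_oclr(expr, stem, lambda_=0.1)
        dup = st.ExpressionMatrix(
            pd.concat([expr.values, expr.values.add_suffix("_dup")], axis=1))
        m2 = st.train_oclr(dup, stem + [s + "_dup" for s in stem], lambda_=0.1)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-6)

    def test_large_ridge_shrinks_w_to_zero(self):
        rng = np.random.default_rng(4)
        expr = _toy_expr(rng)
        m = st.train_oclr(expr, list(expr.sample_ids[:8]), lambda_=1e6)
        assert np.linalg.norm(m.w) < 1e-4

    def test_matches_generic_optimizer_oracle(self):
        """Trained w agrees with a derivative-free minimizer of the same
        objective on small instances (convexity => unique optimum)."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            expr = _toy_expr(rng, n_genes=5, n_samples=25)
            stem = list(expr.sample_ids[:20])
            model = st.train_oclr(expr, stem, lambda_=0.5)
            log2x = expr.log2p()
            X = (log2x[stem].sub(log2x.mean(axis=1), axis=0)).to_numpy().T
            res = optimize.minimize(
                lambda w: st.oclr_objective(w, X, 0.5)[0],
                np.zeros(5), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
            np.testing.assert_allclose(model.w, res.x, atol=1e-5)

    def test_signature_genes_get_high_weights(self, default_run):
        model, truth = default_run["model"], default_run["truth"]
        expr_truth = st.simulate_training_cohort(st.SimulationConfig(seed=11))[2]
        sig = [g for g in expr_truth.signature_gene_ids if g in set(model.feature_ids)]
        pct = rankdata(model.w)[model.feature_ids.get_indexer(sig)].mean() / len(model.w)
        assert pct > 0.75

    def test_requires_two_stem_samples(self):
        expr = _toy_expr(np.random.default_rng(6))
        with pytest.raises(ValueError, match="2 stem"):
            st.train_oclr(expr, [expr.sample_ids[0]])

    def test_elastic_net_l1_sparsifies(self):
        rng = np.random.default_rng(7)
        expr = _toy_expr(rng)
        stem = list(expr.sample_ids[:8])
        dense = st.train_oclr(expr, stem, lambda_=0.01)
        sparse = st.train_oclr(expr, stem, lambda_=0.01, l1=0.05)
        assert (np.abs(sparse.w) < 1e-8).sum() > (np.abs(dense.w) < 1e-8).sum()


class TestScoreSamples:
    def test_profile_ranking_as_w_gives_raw_one(self):
        rng = np.random.default_rng(8)
        w = rng.normal(0, 1, 10)
        model = st.StemnessModel(pd.Index([f"G{i}" for i in range(10)]), w,
                                 0.1, np.zeros(10))
        vals = pd.DataFrame({"match": rankdata(w), "anti": -rankdata(w)},
                            index=model.feature_ids)
        scores = st.score_samples(model, st.ExpressionMatrix(vals, is_log=True))
        assert scores.raw[0] == pytest.approx(1.0)
        assert scores.raw[1] == pytest.approx(-1.0)

    def test_minmax_anchors_within_cohort(self, default_run):
        mrnasi = default_run["scores"].mrnasi
        assert np.nanmin(mrnasi) == pytest.approx(0.0)
        assert np.nanmax(mrnasi) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        w = rng.normal(0, 1, 20)
        model = st.StemnessModel(pd.Index([f"G{i}" for i in range(20)]), w,
                                 0.1, np.zeros(20))
        base = pd.DataFrame(rng.normal(5, 1, (20, 4)), index=model.feature_ids)
        s1 = st.score_samples(model, st.ExpressionMatrix(base, is_log=True))
        model2 = st.StemnessModel(model.feature_ids, w, 0.1, np.zeros(20))
        s2 = st.score_samples(
            model2, st.ExpressionMatrix(np.exp(base) + 3, is_log=True))
        np.testing.assert_allclose(s1.raw, s2.raw, atol=1e-12)

    def test_constant_profile_scores_missing(self):
        w = np.arange(5.0)
        model = st.StemnessModel(pd.Index(list("abcde")), w, 0.1, np.zeros(5))
        vals = pd.DataFrame({"flat": np.ones(5), "ok": [1, 2, 3, 4, 5.0],
                             "ok2": [5, 4, 3, 2, 1.0]}, index=model.feature_ids)
        with pytest.warns(UserWarning, match="constant"):
            scores = st.score_samples(model, st.ExpressionMatrix(vals, is_log=True))
        assert np.isnan(scores.raw[0]) and np.isfinite(scores.raw[1])

    def test_too_few_shared_features_rejected(self):
        model = st.StemnessModel(pd.Index(["x", "y", "z"]), np.ones(3), 0.1, np.zeros(3))
        vals = pd.DataFrame({"s": [1.0, 2.0]}, index=["x", "q"])
        with pytest.raises(ValueError, match="shared"):
            st.score_samples(model, st.ExpressionMatrix(vals, is_log=True))

    def test_anchors_frozen_for_later_cohorts(self):
        rng = np.random.default_rng(10)
        w = rng.normal(0, 1, 30)
        model = st.StemnessModel(pd.Index([f"G{i}" for i in range(30)]), w,
                                 0.1, np.zeros(30))
        first = pd.DataFrame(rng.normal(0, 1, (30, 6)), index=model.feature_ids)
        st.score_samples(model, st.ExpressionMatrix(first, is_log=True))
        lo, hi = model.scale_min, model.scale_max
        second = pd.DataFrame(rng.normal(0, 1, (30, 6)), index=model.feature_ids)
        st.score_samples(model, st.ExpressionMatrix(second, is_log=True))
        assert (model.scale_min, model.scale_max) == (lo, hi)


class TestEvaluateSeparation:
    def test_perfect_separation(self):
        assert st.evaluate_separation([3, 4, 1, 2], [True, True, False, False]) == 1.0

    @pytest.mark.parametrize(
        "pos,neg,expected",
        [((0.9, 0.8), (0.7, 0.9), 0.625),   # (1 + 0.5 + 1 + 0) / 4
         ((0.9, 0.8), (0.7, 0.8), 0.875)],  # (1 + 1 + 1 + 0.5) / 4
    )
    def test_worked_four_point_examples(self, pos, neg, expected):
        # expected values from brute force over all positive x negative pairs
        brute = sum(1.0 if p > n else (0.5 if p == n else 0.0)
                    for p in pos for n in neg) / (len(pos) * len(neg))
        assert brute == expected
        auc = st.evaluate_separation(list(pos) + list(neg),
                                     [True] * len(pos) + [False] * len(neg))
        assert auc == pytest.approx(expected)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0, 1, 4000)
        labels = rng.random(4000) < 0.5
        assert st.evaluate_separation(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            st.evaluate_separation([1, 2], [True, True])


class TestStratify:
    def _scores(self, values):
        n = len(values)
        return StemnessScores(pd.Index([f"S{i:03d}" for i in range(n)]),
                              np.asarray(values, float), np.asarray(values, float))

    def test_decile_split_counts(self):
        rng = np.random.default_rng(12)
        s = st.stratify_by_stemness(self._scores(rng.random(100)), frac=0.10)
        counts = s.stratum.value_counts()
        assert (counts["TSC"], counts["MID"], counts["USC"]) == (10, 80, 10)

    def test_half_split_boundary(self):
        s = st.stratify_by_stemness(self._scores(np.arange(10) / 10), frac=0.5)
        assert (s.stratum == "MID").sum() == 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            st.stratify_by_stemness(self._scores([0.1, 0.5, 0.9]), frac=0.75)

    def test_tsc_is_lowest_mrnasi_under_stem_low(self):
        s = st.stratify_by_stemness(self._scores(np.linspace(0, 1, 20)), frac=0.1)
        assert list(s.stratum[s.stratum == "TSC"].index) == ["S000", "S001"]
        assert list(s.stratum[s.stratum == "USC"].index) == ["S018", "S019"]

    def test_tsc_more_stem_like_than_usc(self, default_run):
        scores, truth = default_run["scores"], default_run["truth"]
        lat = truth.latent_stemness
        tsc = lat[scores.stratum[scores.stratum == "TSC"].index].mean()
        usc = lat[scores.stratum[scores.stratum == "USC"].index].mean()
        assert tsc > usc

    def test_tie_break_deterministic_by_sample_id(self):
        s = st.stratify_by_stemness(self._scores([0.5] * 9 + [0.4]), frac=0.1)
        assert list(s.stratum[s.stratum == "TSC"].index) == ["S009"]
        assert list(s.stratum[s.stratum == "USC"].index) == ["S008"]
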