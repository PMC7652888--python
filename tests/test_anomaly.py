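import numpy as np
import pytest

from deeplof.anomaly import (AnomalyScore, LOFModel, classify, fit, insample_lof,
                             k_distance_neighborhood, lof_score, lrd,
                             pairwise_distance, score)
from deeplof.network import FeatureDescriptor

from oracles import oracle_lof

LINE_REFS = np.array([[0.0], [10.0], [20.0], [30.0], [40.0]])


class TestPairwiseDistance:
    def test_hand_values(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert pairwise_distance(a, b, "squared_euclidean")[0, 0] == 25.0
        assert pairwise_distance(a, b, "euclidean")[0, 0] == 5.0

    def test_identical_vectors_zero(self, rng):
        x = rng.normal(size=(1, 6))
        assert pairwise_distance(x, x)[0, 0] == 0.0

    def test_matrix_matches_double_loop(self, rng):
        A = rng.normal(size=(20, 5))
        D = pairwise_distance(A, A, "squared_euclidean")
        for i in range(20):
            for j in range(20):
                assert D[i, j] == pytest.approx(np.sum((A[i] - A[j]) ** 2), abs=1e-12)
        np.testing.assert_allclose(D, D.T, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_distance(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))


class TestKDistanceNeighborhood:
    def test_line_example(self):
        nbrs = k_distance_neighborhood(np.array([20.0]),
                                       np.array([[0.0], [10.0], [30.0], [40.0]]), k=2)
        assert sorted(nbrs.tolist()) == [1, 2]  # refs 10 and 30

    def test_coincident_ref_included(self):
        refs = np.array([[0.0], [5.0], [9.0]])
        nbrs = k_distance_neighborhood(np.array([5.0]), refs, k=1)
        assert nbrs.tolist() == [1]

    def test_tie_inclusion_grows_neighborhood(self):
        refs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        nbrs = k_distance_neighborhood(np.zeros(2), refs, k=2)
        assert len(nbrs) == 3  # three equidistant nearest points

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            k_distance_neighborhood(np.array([0.0]), LINE_REFS, k=5)


class TestLrd:
    def test_interior_point(self):
        refs = np.array([[0.0], [10.0], [30.0], [40.0]])  # 20 excluded: query
        assert lrd(np.array([20.0]), refs, k=2) == pytest.approx(1.0 / 100.0)

    def test_exterior_point(self):
        assert lrd(np.array([100.0]), LINE_REFS, k=2) == pytest.approx(1.0 / 4250.0)

    def test_homogeneity_under_scaling(self, rng):
        refs = rng.normal(size=(15, 3))
        p = rng.normal(size=3) * 2
        base = lrd(p, refs, k=4, metric="squared_euclidean")
        scaled = lrd(3.0 * p, 3.0 * refs, k=4, metric="squared_euclidean")
        assert scaled == pytest.approx(base / 9.0, rel=1e-9)


class TestLofScore:
    def test_line_examples_leave_one_out(self):
        model = LOFModel(LINE_REFS, k=2, metric="squared_euclidean", variant="paper")
        scores = model.score(np.array([[20.0], [100.0]]))
        assert scores[0].lof == pytest.approx(1.0)
        assert scores[1].lof == pytest.approx(29.75)

    def test_external_query_hand_value(self):
        assert lof_score(np.array([100.0]), LINE_REFS, k=2,
                         metric="squared_euclidean", variant="paper") == pytest.approx(29.75)

    def test_interior_of_uniform_grid_scores_one(self):
        xx, yy = np.meshgrid(np.arange(20.0), np.arange(20.0))
        grid = np.column_stack([xx.ravel(), yy.ravel()])
        vals = insample_lof(grid, k=5, metric="squared_euclidean", variant="paper")
        interior = (xx.ravel() >= 3) & (xx.ravel() <= 16) & \
                   (yy.ravel() >= 3) & (yy.ravel() <= 16)
        np.testing.assert_allclose(vals[interior], 1.0, rtol=0.10)

    @pytest.mark.parametrize("variant", ["paper", "reachability"])
    @pytest.mark.parametrize("metric", ["squared_euclidean", "euclidean"])
    def test_matches_bruteforce_oracle(self, variant, metric, rng):
        for _ in range(15):
            n = int(rng.integers(8, 60))
            dim = int(rng.integers(1, 8))
            k = int(rng.integers(1, 6))
            refs = rng.normal(size=(n, dim))
            p = rng.normal(size=dim) * 1.5
            mine = lof_score(p, refs, k, metric, variant)
            expect = oracle_lof(p, refs, k, metric, variant)
            assert mine == pytest.approx(expect, rel=1e-10)

    def test_translation_and_rotation_invariance(self, rng):
        refs = rng.normal(size=(25, 3))
        p = rng.normal(size=3) * 2
        base = lof_score(p, refs, k=5)
        shift = rng.normal(size=3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        transformed = lof_score((p + shift) @ q, (refs + shift) @ q, k=5)
        assert transformed == pytest.approx(base, rel=1e-9)

    def test_monotone_in_escape_distance(self):
        rng = np.random.default_rng(3)
        refs = rng.normal(size=(30, 2))
        direction = np.array([1.0, 0.0])
        vals = [lof_score(direction * d, refs, k=5) for d in (5.0, 8.0, 12.0, 20.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_duplicate_of_dense_point_scores_one(self):
        refs = np.vstack([np.zeros((6, 2)), [[5.0, 5.0]]])
        assert lof_score(np.zeros(2), refs, k=3) == 1.0

    def test_reachability_variant_matches_sklearn(self, rng):
        from sklearn.neighbors import LocalOutlierFactor

        X = rng.normal(size=(40, 4))
        queries = rng.normal(size=(10, 4)) * 2
        sk = LocalOutlierFactor(n_neighbors=5, algorithm="brute",
                                metric="sqeuclidean", novelty=True).fit(X)
        mine = [lof_score(q, X, 5, "squared_euclidean", "reachability")
                for q in queries]
        np.testing.assert_allclose(mine, -sk.score_samples(queries), rtol=1e-7)
        np.testing.assert_allclose(insample_lof(X, 5, "squared_euclidean", "reachability"),
                                   -sk.negative_outlier_factor_, rtol=1e-7)


class TestFitScore:
    def _descriptors(self, rng, n=30):
        out = []
        for i in range(n):
            label = 0 if i < n - 8 else (1 if i < n - 3 else 2)
            centre = {0: 0.0, 1: 6.0, 2: -6.0}[label]
            out.append(FeatureDescriptor(rng.normal(centre, 1.0, size=4),
                                         f"d{i:03d}", label))
        return out

    def test_fit_scope_filters_labels(self, rng):
        descs = self._descriptors(rng)
        model = fit(descs, k=5, fit_scope="normal_only")
        assert len(model.refs) == 22
        model_all = fit(descs, k=5, fit_scope="all_cohort")
        assert len(model_all.refs) == 27
        model_tex = fit(descs, k=5, fit_scope="all_cohort", include_textures=True)
        assert len(model_tex.refs) == 30

    def test_training_refs_score_finite(self, rng):
        descs = self._descriptors(rng)
        model = fit(descs, k=5)
        results = score(model, [d for d in descs if d.label == 0])
        assert all(np.isfinite(r.lof) for r in results)

    def test_far_queries_score_higher_than_central(self, rng):
        refs = rng.normal(size=(40, 3))
        model = LOFModel(refs, k=5)
        near = np.mean([s.lof for s in model.score(rng.normal(size=(5, 3)) * 0.2)])
        far = np.mean([s.lof for s in model.score(rng.normal(size=(5, 3)) + 8.0)])
        assert far > near

    def test_ref_permutation_invariance(self, rng):
        refs = rng.normal(size=(20, 3))
        queries = rng.normal(size=(6, 3)) * 1.5
        a = [s.lof for s in LOFModel(refs, k=4).score(queries)]
        perm = rng.permutation(20)
        b = [s.lof for s in LOFModel(refs[perm], k=4).score(queries)]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_too_few_refs_rejected(self, rng):
        descs = self._descriptors(rng, n=6)
        with pytest.raises(ValueError):
            fit(descs, k=5, fit_scope="normal_only")


class TestClassify:
    def test_threshold_extremes(self):
        scores = np.array([0.5, 1.0, 29.75])
        assert classify(scores, np.inf).sum() == 0
        assert classify(scores, 0.0).sum() == 3

    def test_worked_example_decisions(self):
        scores = [AnomalyScore("p20", 1.0), AnomalyScore("p100", 29.75)]
        out = classify(scores, 2.0)
        assert [s.decision for s in out] == ["normal", "abnormal"]
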