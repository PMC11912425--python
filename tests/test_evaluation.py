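import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spose2afc as s
from spose2afc.evaluation import class_aggregate, repeated_triplet_counts

from conftest import random_embedding


def _repeat_table(counts, m):
    """Build a repeated-triplet table from per-triplet modal counts."""
    rows = []
    for t, c_lo in enumerate(counts):
        for r in range(m):
            choice = "A" if r < c_lo else "B"
            rows.append(dict(worker_id=f"w{r}", reference=f"r{t}",
                             option_a=f"a{t}", option_b=f"b{t}",
                             choice=choice, rt_ms=1000.0))
    return pd.DataFrame(rows)


class TestCeiling:
    def test_modal_fraction_direct(self):
        trials = _repeat_table([45], 60)
        assert s.consistency_ceiling(trials) == pytest.approx(75.0)

    def test_unanimous_is_hundred(self):
        assert s.consistency_ceiling(_repeat_table([20, 20], 20)) == 100.0

    def test_minimum_repeats_enforced(self):
        with pytest.raises(ValueError, match="2 responses"):
            repeated_triplet_counts(_repeat_table([1], 1))

    def test_ceiling_bounds_model_accuracy(self, truth_small, fit_small):
        reps = s.simulate_repeated_triplets(truth_small, n_triplets=250,
                                            m_repeats=30, seed=21)
        ceiling = s.consistency_ceiling(reps)
        assert 100 * fit_small.test_accuracy <= ceiling + 3.0


class TestChanceCorrection:
    def test_accuracy_at_ceiling_is_hundred(self):
        assert s.chance_corrected(73.84, 73.84) == 100.0

    def test_accuracy_at_chance_is_zero(self):
        assert s.chance_corrected(50.0, 73.84) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-20, 20), st.floats(51, 99), st.floats(55, 100))
    def test_shift_invariance(self, shift, acc, ceil):
        if ceil <= acc:
            acc, ceil = ceil - 2, acc + 2
        base = s.chance_corrected(acc, ceil, 50.0)
        shifted = s.chance_corrected(acc + shift, ceil + shift, 50.0 + shift)
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_ceiling_at_or_below_chance_rejected(self):
        with pytest.raises(ValueError):
            s.chance_corrected(60.0, 50.0)


class TestCompareMatrices:
    def test_identical_matrices_give_unit_r(self):
        A = s.marginal_similarity(random_embedding(10, 3, seed=1))
        res = s.compare_matrices(A, A, n_perm=99, n_boot=50, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] < 0.05

    def test_label_aware_alignment(self):
        A = s.marginal_similarity(random_embedding(10, 3, seed=2))
        perm = np.random.default_rng(0).permutation(10)
        B = s.SimilarityMatrix(A.values[np.ix_(perm, perm)],
                               [A.image_ids[i] for i in perm])
        res = s.compare_matrices(A, B, n_perm=99, n_boot=50, seed=0)
        assert res["r"] == pytest.approx(1.0)

    def test_null_p_values_not_degenerate(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(12):
            A = s.marginal_similarity(random_embedding(20, 3, seed=100 + rep))
            B = s.marginal_similarity(random_embedding(20, 3, seed=500 + rep))
            ps.append(s.compare_matrices(A, B, n_perm=99, n_boot=0,
                                         seed=rep)["p"])
        ps = np.asarray(ps)
        # under the null p should be spread out, not piled at either end
        assert 0.2 < ps.mean() < 0.8
        assert (ps <= 0.2).sum() <= 6


class TestReliability:
    @pytest.mark.parametrize("r_half,expected", [(1.0, 1.0), (0.0, 0.0),
                                                 (0.9417, 0.9700)])
    def test_spearman_brown(self, r_half, expected):
        assert s.spearman_brown(r_half) == pytest.approx(expected, abs=5e-4)

    def test_split_half_on_consistent_data(self, truth_small):
        big = s.GroundTruth(
            embedding=s.Embedding(truth_small.embedding.weights[:10] * 40,
                                  truth_small.embedding.image_ids[:10]),
            images=truth_small.images.iloc[:10], params={}, seed=0)
        sim = s.simulate_trials(big, design="full", n_repeats=2, lapse_rate=0.0,
                                seed=6)
        res = s.split_half_reliability(sim.trials, n_splits=2, seed=0)
        assert res["corrected"] > 0.95

    def test_explainable_variance_endpoints(self):
        assert s.explainable_variance(1.0, 1.0) == 100.0
        assert s.explainable_variance(0.0, 0.9) == 0.0
        assert s.explainable_variance(0.90, 0.97) == pytest.approx(83.5, abs=0.2)


class TestClassStructure:
    def test_block_matrix_means(self):
        V = np.full((6, 6), 0.4)
        for b in range(3):
            V[2 * b:2 * b + 2, 2 * b:2 * b + 2] = 0.9
        np.fill_diagonal(V, 1.0)
        mat = s.SimilarityMatrix(V, [f"i{i}" for i in range(6)])
        classes = pd.Series({f"i{i}": f"c{i // 2}" for i in range(6)})
        res = s.within_between_class(mat, classes)
        assert res["within_mean"] == pytest.approx(0.9)
        assert res["between_mean"] == pytest.approx(0.4)

    def test_degenerate_equal_entries_give_nan_t(self, caplog):
        V = np.full((6, 6), 0.5)
        np.fill_diagonal(V, 1.0)
        mat = s.SimilarityMatrix(V, [f"i{i}" for i in range(6)])
        classes = pd.Series({f"i{i}": f"c{i // 2}" for i in range(6)})
        res = s.within_between_class(mat, classes)
        assert np.isnan(res["t"])

    def test_generator_classes_are_cohesive(self, truth_small, classes_small):
        mat = s.marginal_similarity(truth_small.embedding)
        res = s.within_between_class(mat, classes_small)
        assert res["within_mean"] > res["between_mean"]
        assert res["t"] > 0


class TestDecoding:
    def test_orthogonal_classes_decode_perfectly(self):
        W = np.repeat(np.eye(5), 3, axis=0) * 2.0
        ids = [f"c{c}_e{e}" for c in range(5) for e in range(3)]
        emb = s.Embedding(W, ids)
        classes = pd.Series({i: i.split("_")[0] for i in ids})
        res = s.decode_classes(emb, classes)
        assert res["top1_pct"] == 100.0
        assert res["pairwise_accuracy_pct"] == 100.0
        assert res["median_rank"] == 1.0

    def test_shuffled_labels_fall_to_chance(self, truth_small, classes_small):
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(classes_small.to_numpy()),
                             index=classes_small.index)
        res = s.decode_classes(truth_small.embedding, shuffled)
        assert res["top1_pct"] < 4 * res["chance_top1_pct"] + 10
        assert abs(res["pairwise_accuracy_pct"] - 50.0) < 15.0

    def test_pairwise_matches_exhaustive_evaluation(self):
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(5)
        W = np.abs(rng.standard_normal((12, 3)))
        ids = [f"c{c}_e{e}" for c in range(4) for e in range(3)]
        emb = s.Embedding(W, ids)
        classes = pd.Series({i: i.split("_")[0] for i in ids})
        res = s.decode_classes(emb, classes)
        y = np.repeat(np.arange(4), 3)
        ex = np.tile(np.arange(3), 4)
        correct = total = 0
        for fold in range(3):
            for c1 in range(4):
                for c2 in range(c1 + 1, 4):
                    tr = (ex != fold) & np.isin(y, [c1, c2])
                    te = (ex == fold) & np.isin(y, [c1, c2])
                    clf = LinearSVC(C=1.0, random_state=0).fit(W[tr], y[tr])
                    correct += (clf.predict(W[te]) == y[te]).sum()
                    total += te.sum()
        assert res["pairwise_accuracy_pct"] == pytest.approx(100 * correct / total)


class TestSemanticComparison:
    def test_matched_matrices_give_unit_r_squared(self, rng):
        vecs = pd.DataFrame(rng.standard_normal((8, 30)),
                            index=[f"c{i}" for i in range(8)])
        C = np.corrcoef(vecs.to_numpy())
        # behavioral matrix whose class blocks equal an affine map of C
        V = np.repeat(np.repeat(0.5 + 0.4 * C, 3, axis=0), 3, axis=1)
        np.fill_diagonal(V, 1.0)
        ids = [f"c{c}_e{e}" for c in range(8) for e in range(3)]
        mat = s.SimilarityMatrix(0.5 * (V + V.T), ids)
        classes = pd.Series({i: i.split("_")[0] for i in ids})
        res = s.semantic_comparison(mat, vecs, classes)
        assert res["r_squared"] > 0.99

    def test_uncoupled_vectors_share_little_variance(self, truth_small,
                                                     classes_small):
        mat = s.marginal_similarity(truth_small.embedding)
        sem = s.make_semantic_vectors(truth_small, coupling=0.0, seed=9)
        res = s.semantic_comparison(mat, sem, classes_small)
        assert res["r_squared"] < 0.3

    def test_coupling_increases_shared_variance(self, truth_small, classes_small):
        mat = s.marginal_similarity(truth_small.embedding)
        r2 = {c: s.semantic_comparison(
            mat, s.make_semantic_vectors(truth_small, coupling=c, seed=9),
            classes_small)["r_squared"] for c in (0.0, 1.0)}
        assert r2[1.0] > r2[0.0]

    def test_class_aggregate_block_means(self):
        V = np.full((6, 6), 0.4)
        V[:3, :3] = 0.8
        V[3:, 3:] = 0.6
        np.fill_diagonal(V, 1.0)
        ids = [f"c{c}_e{e}" for c in range(2) for e in range(3)]
        agg = class_aggregate(s.SimilarityMatrix(V, ids),
                              pd.Series({i: i.split("_")[0] for i in ids}))
        assert agg.loc["c0", "c1"] == pytest.approx(0.4)
        assert agg.loc["c0", "c0"] == pytest.approx(0.8)


class TestPruningCurve:
    @staticmethod
    def _random_triplets(n, count, seed=0):
        rng = np.random.default_rng(seed)
        return np.array([rng.choice(n, 3, replace=False) for _ in range(count)])

    def test_one_sparse_embedding_is_flat(self):
        W = np.eye(6) * 1.5
        emb = s.Embedding(W, [f"i{i}" for i in range(6)])
        res = s.dimension_pruning_curve(emb, self._random_triplets(6, 200))
        assert (res["curve"]["r_squared"] == 1.0).all()

    def test_full_retention_is_perfect(self):
        emb = random_embedding(8, 4, seed=3)
        res = s.dimension_pruning_curve(emb, self._random_triplets(8, 200))
        assert res["curve"].iloc[-1]["r_squared"] == 1.0

    def test_dominant_dims_reached_quickly(self):
        rng = np.random.default_rng(4)
        n, k = 20, 10
        W = 0.01 * np.abs(rng.standard_normal((n, k)))
        for i in range(n):  # exactly 3 dominant dimensions per image
            W[i, rng.choice(k, 3, replace=False)] += 2.0
        emb = s.Embedding(W, [f"i{i}" for i in range(n)])
        res = s.dimension_pruning_curve(emb, self._random_triplets(n, 2000))
        assert res["dims_needed"][0.95] <= 4

    def test_curve_monotone_nonincreasing(self):
        emb = random_embedding(10, 6, seed=6)
        res = s.dimension_pruning_curve(emb, self._random_triplets(10, 1000))
        r2 = res["curve"].sort_values("dims_retained")["r_squared"].to_numpy()
        assert (np.diff(r2) >= -0.02).all()
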