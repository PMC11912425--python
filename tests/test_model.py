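import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spose2afc as s
from spose2afc.model import TripletEmbedding, trials_to_arrays

from conftest import random_embedding


class TestChoiceProbability:
    def test_all_zero_embedding_is_indifferent(self):
        emb = s.Embedding(np.zeros((4, 3)), ["a", "b", "c", "d"])
        assert s.choice_probability(emb, "a", "b", "c") == 0.5

    def test_log_odds_closed_form(self):
        # x_ref.x_a = ln 3, x_ref.x_b = 0  ->  p = 3/(3+1)
        W = np.array([[1.0, 0.0], [np.log(3.0), 0.0], [0.0, 0.0]])
        emb = s.Embedding(W, ["r", "a", "b"])
        assert s.choice_probability(emb, "r", "a", "b") == pytest.approx(0.75, abs=1e-12)

    def test_matches_scalar_loop_oracle(self):
        emb = random_embedding(5, 3, seed=42)
        W = emb.weights
        for r in range(5):
            for a in range(5):
                for b in range(5):
                    if len({r, a, b}) < 3:
                        continue
                    da = sum(W[r][d] * W[a][d] for d in range(3))
                    db = sum(W[r][d] * W[b][d] for d in range(3))
                    expect = np.exp(da) / (np.exp(da) + np.exp(db))
                    got = s.choice_probability(emb, f"im{r}", f"im{a}", f"im{b}")
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_probabilities_sum_to_one(self):
        emb = random_embedding(5, 3, seed=1)
        p_ab = s.choice_probability(emb, "im0", "im1", "im2")
        p_ba = s.choice_probability(emb, "im0", "im2", "im1")
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-12)
        assert 0 < p_ab < 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_invariant_to_appending_zero_dimensions(self, seed, extra):
        emb = random_embedding(4, 3, seed=seed)
        padded = s.Embedding(np.hstack([emb.weights, np.zeros((4, extra))]),
                             emb.image_ids)
        assert s.choice_probability(padded, "im0", "im1", "im2") == pytest.approx(
            s.choice_probability(emb, "im0", "im1", "im2"), abs=1e-15)

    def test_duplicate_ids_rejected(self):
        emb = random_embedding(4, 2)
        with pytest.raises(ValueError):
            s.choice_probability(emb, "im0", "im0", "im1")


class TestFit:
    def test_refit_same_seed_bit_identical(self, truth_small):
        sim = s.simulate_trials(truth_small, n_trials=5000, seed=9)
        X, y = trials_to_arrays(sim.trials, truth_small.embedding.image_ids)
        a = TripletEmbedding(n_dims=5, lam=0.1, max_epochs=5, random_state=4).fit(X, y)
        b = TripletEmbedding(n_dims=5, lam=0.1, max_epochs=5, random_state=4).fit(X, y)
        assert np.array_equal(a.embedding_, b.embedding_)

    def test_huge_lambda_collapses_to_chance(self, truth_small):
        sim = s.simulate_trials(truth_small, n_trials=8000, seed=10)
        cfg = s.FitConfig(n_init_dims=5, lam=50.0, max_epochs=80, patience=80, seed=1)
        res = s.fit_embedding(sim.trials, truth_small.images, cfg)
        assert res.embedding.n_dims == 0  # every dimension driven to zero
        assert res.test_accuracy == pytest.approx(0.5, abs=0.05)

    def test_weights_nonnegative_after_fit(self, fit_small):
        assert (fit_small.embedding.weights >= 0).all()

    def test_heldout_accuracy_approaches_bayes_bound(self, truth_small, sim_small,
                                                     fit_small):
        # accuracy cannot beat the generator's lapse-adjusted Bayes accuracy,
        # and with ample trials should come within a few points of it
        bayes_with_lapse = 0.9 * sim_small.bayes_accuracy + 0.05
        assert fit_small.test_accuracy <= bayes_with_lapse + 0.02
        assert fit_small.test_accuracy >= bayes_with_lapse - 0.05

    def test_training_objective_nonincreasing(self, fit_small):
        curve = np.asarray(fit_small.loss_curve)
        # allow optimizer noise but no sustained increase
        assert curve[-1] <= curve[0]
        assert np.min(curve) >= curve[-1] - 0.01


class TestSelectLambda:
    def test_single_value_grid_returned(self, truth_small):
        sim = s.simulate_trials(truth_small, n_trials=3000, seed=12)
        cfg = s.FitConfig(n_init_dims=4, lambda_grid=[0.2], max_epochs=3,
                          n_cv_folds=2, seed=0)
        lam, table = s.select_lambda(sim.trials, truth_small.images, cfg)
        assert lam == 0.2 and len(table) == 1

    def test_informative_data_rejects_huge_lambda(self, truth_small):
        sim = s.simulate_trials(truth_small, n_trials=12_000, seed=13)
        cfg = s.FitConfig(n_init_dims=5, lambda_grid=[0.1, 100.0], max_epochs=10,
                          n_cv_folds=2, seed=0)
        lam, table = s.select_lambda(sim.trials, truth_small.images, cfg)
        assert lam == 0.1
        accs = table.set_index("lam")["mean_val_accuracy"]
        assert accs[0.1] > accs[100.0]

    def test_accuracy_tie_breaks_to_larger_lambda(self, truth_small):
        # both lambdas collapse the model to all-zero weights -> identical
        # (chance) validation accuracy -> the larger, sparser one wins
        sim = s.simulate_trials(truth_small, n_trials=3000, seed=14)
        cfg = s.FitConfig(n_init_dims=4, lambda_grid=[50.0, 80.0], max_epochs=5,
                          n_cv_folds=2, seed=0)
        lam, _ = s.select_lambda(sim.trials, truth_small.images, cfg)
        assert lam == 80.0


class TestPruneAndOrder:
    def test_all_zero_column_removed(self):
        W = np.abs(np.random.default_rng(0).standard_normal((6, 3)))
        W[:, 1] = 0.0
        emb, n_pruned = s.prune_dimensions(s.Embedding(W, [f"i{i}" for i in range(6)]))
        assert n_pruned == 1 and emb.n_dims == 2

    def test_tiny_tolerance_keeps_strictly_positive_weights(self):
        W = np.full((4, 3), 0.2)
        emb, n_pruned = s.prune_dimensions(
            s.Embedding(W, list("abcd")), tol=1e-300)
        assert n_pruned == 0 and emb.n_dims == 3

    def test_order_by_descending_mean(self):
        W = np.column_stack([np.full(4, 0.4), np.full(4, 0.9)])
        emb = s.order_dimensions(s.Embedding(W, list("abcd")))
        assert emb.weights[0, 0] == 0.9 and emb.weights[0, 1] == 0.4

    def test_equal_means_keep_original_order(self):
        W = np.array([[0.2, 0.6], [0.6, 0.2]])
        emb = s.order_dimensions(s.Embedding(W, ["a", "b"]))
        assert np.array_equal(emb.weights, W)

    def test_ordering_preserves_column_multiset(self):
        emb = random_embedding(5, 4, seed=3)
        out = s.order_dimensions(emb)
        got = sorted(map(tuple, out.weights.T.round(12)))
        want = sorted(map(tuple, emb.weights.T.round(12)))
        assert got == want


class TestEmbeddingIO:
    def test_tsv_roundtrip(self, tmp_path):
        emb = random_embedding(5, 3, seed=8)
        emb.to_tsv(tmp_path / "e.tsv", sidecar={"lam": 0.3})
        back = s.Embedding.from_tsv(tmp_path / "e.tsv")
        assert back.image_ids == emb.image_ids
        assert np.allclose(back.weights, emb.weights)
        assert (tmp_path / "e.tsv.json").exists()

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            s.Embedding(np.array([[-0.1, 0.2]]), ["a"])
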