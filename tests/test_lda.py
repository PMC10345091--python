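import numpy as np
import pytest

from microtopics.datamodel import CountTable
from microtopics.lda import LdaError, fit_lda_gibbs, load_model, simulate_counts

from conftest import best_match_cosine, simulate_lda_table


class TestFitLdaGibbs:
    def test_k1_closed_form(self):
        # with one topic there is no sampling freedom: beta is exactly
        # (word totals + gamma) / (total tokens + V * gamma)
        table, _, _ = simulate_lda_table(D=10, V=8, K=2, depth=50, seed=3)
        gamma = 0.1
        model = fit_lda_gibbs(table, K=1, gamma=gamma, n_iterations=20,
                              burn_in=5, thin=1, seed=0)
        totals = table.values.sum(axis=1)
        expected = (totals + gamma) / (totals.sum() + table.n_features * gamma)
        np.testing.assert_allclose(model.beta[0], expected, rtol=1e-10)
        np.testing.assert_allclose(model.theta, 1.0)

    def test_disjoint_vocabulary_blocks(self):
        # two document groups on disjoint vocabulary halves force K=2 topics
        # to specialize
        rng = np.random.default_rng(8)
        V, D = 20, 40
        values = np.zeros((V, D), dtype=int)
        values[:10, :20] = rng.integers(5, 20, size=(10, 20))
        values[10:, 20:] = rng.integers(5, 20, size=(10, 20))
        table = CountTable("x", [f"f{v}" for v in range(V)],
                           [f"s{d}" for d in range(D)], values)
        model = fit_lda_gibbs(table, K=2, alpha=0.5, gamma=0.1,
                              n_iterations=200, burn_in=50, thin=5, seed=0)
        for k in range(2):
            half_mass = max(model.beta[k, :10].sum(), model.beta[k, 10:].sum())
            assert half_mass >= 0.95

    def test_deterministic_for_fixed_seed(self):
        table, _, _ = simulate_lda_table(D=15, V=12, K=2, depth=60, seed=4)
        m1 = fit_lda_gibbs(table, K=2, n_iterations=50, burn_in=10, thin=2, seed=9)
        m2 = fit_lda_gibbs(table, K=2, n_iterations=50, burn_in=10, thin=2, seed=9)
        np.testing.assert_array_equal(m1.theta, m2.theta)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_row_stochastic_outputs(self):
        table, _, _ = simulate_lda_table(D=12, V=10, K=3, depth=40, seed=5)
        model = fit_lda_gibbs(table, K=3, n_iterations=40, burn_in=10, thin=2, seed=1)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(model.beta.sum(axis=1), 1.0, atol=1e-8)
        assert model.theta.min() >= 0 and model.beta.min() >= 0

    def test_beats_k1_on_heldout_style_likelihood(self):
        # fitted K=3 model assigns higher in-sample token log-likelihood than
        # the K=1 model on K_true=3 data
        table, _, _ = simulate_lda_table(D=60, V=30, K=3, depth=200, seed=6)
        m3 = fit_lda_gibbs(table, K=3, alpha=0.5, gamma=0.1,
                           n_iterations=150, burn_in=50, thin=5, seed=0)
        m1 = fit_lda_gibbs(table, K=1, gamma=0.1, n_iterations=20,
                           burn_in=5, thin=1, seed=0)

        def loglik(model):
            probs = model.theta @ model.beta  # D x V token distributions
            return float((table.values.T * np.log(probs + 1e-300)).sum())

        assert loglik(m3) > loglik(m1)

    def test_empty_sample_errors_or_drops(self):
        values = np.array([[2, 0], [3, 0]])
        table = CountTable("x", ["f1", "f2"], ["s1", "s2"], values)
        with pytest.raises(LdaError, match="s2"):
            fit_lda_gibbs(table, K=1, n_iterations=10, burn_in=2, seed=0)
        model = fit_lda_gibbs(table, K=1, n_iterations=10, burn_in=2, seed=0,
                              drop_empty_samples=True)
        assert model.dropped_samples == ["s2"]
        assert model.sample_ids == ["s1"]

    def test_k_greater_than_v_rejected(self):
        table, _, _ = simulate_lda_table(D=5, V=4, K=2, depth=20, seed=7)
        with pytest.raises(LdaError, match="exceeds"):
            fit_lda_gibbs(table, K=5, n_iterations=10, burn_in=2, seed=0)

    def test_non_integer_counts_rejected(self):
        table = CountTable("x", ["f1"], ["s1"], np.array([[1.5]]))
        with pytest.raises(LdaError, match="integer"):
            fit_lda_gibbs(table, K=1, n_iterations=10, burn_in=2, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        table, _, _ = simulate_lda_table(D=8, V=6, K=2, depth=30, seed=9)
        model = fit_lda_gibbs(table, K=2, n_iterations=30, burn_in=10, thin=2, seed=2)
        model.save(tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(back.theta, model.theta, rtol=1e-9)
        np.testing.assert_allclose(back.beta, model.beta, rtol=1e-9)
        assert back.K == 2 and back.sample_ids == model.sample_ids


class TestSimulateCounts:
    def _model(self, theta, beta):
        from microtopics.lda import LdaModel

        D, K = theta.shape
        V = beta.shape[1]
        return LdaModel("x", K, 0.5, 0.1, theta, beta,
                        [f"f{v}" for v in range(V)], [f"s{d}" for d in range(D)])

    def test_one_hot_beta_degenerate(self):
        theta = np.full((3, 2), 0.5)
        beta = np.zeros((2, 4))
        beta[:, 2] = 1.0
        sim = simulate_counts(self._model(theta, beta), np.array([10, 10, 10]), seed=0)
        assert sim.values[2].sum() == 30
        assert sim.values.sum() == 30

    def test_column_sums_equal_depths(self):
        rng = np.random.default_rng(2)
        theta = rng.dirichlet([1, 1, 1], size=5)
        beta = rng.dirichlet(np.ones(8), size=3)
        depths = np.array([7, 20, 3, 50, 11])
        sim = simulate_counts(self._model(theta, beta), depths, seed=1)
        np.testing.assert_array_equal(sim.values.sum(axis=0), depths)

    def test_expectation_matches_analytic(self):
        # E[count_vd] = N_d * (theta beta)_dv, checked over 500 replicates
        rng = np.random.default_rng(3)
        theta = rng.dirichlet([0.5, 0.5], size=4)
        beta = rng.dirichlet(np.ones(6) * 0.5, size=2)
        model = self._model(theta, beta)
        depths = np.full(4, 200)
        acc = np.zeros((6, 4))
        n_rep = 500
        for i in range(n_rep):
            acc += simulate_counts(model, depths, seed=i).values
        mean = acc / n_rep
        expected = (theta @ beta).T * 200
        se = np.sqrt(np.maximum(expected * (1 - (theta @ beta).T), 1e-9) / n_rep)
        assert np.all(np.abs(mean - expected) <= 3 * se + 0.05)

    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(4)
        theta = rng.dirichlet([1, 1], size=3)
        beta = rng.dirichlet(np.ones(5), size=2)
        model = self._model(theta, beta)
        a = simulate_counts(model, np.array([9, 9, 9]), seed=5)
        b = simulate_counts(model, np.array([9, 9, 9]), seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_depth_length_mismatch(self):
        rng = np.random.default_rng(5)
        model = self._model(rng.dirichlet([1, 1], size=3), rng.dirichlet(np.ones(5), size=2))
        from microtopics.lda import LdaError

        with pytest.raises(LdaError, match="depth"):
            simulate_counts(model, np.array([5, 5]), seed=0)
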