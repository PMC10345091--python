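import numpy as np
import pytest

from microtopics.crossomic import (
    CrossOmicError,
    TopicVector,
    cluster_samples,
    cluster_topics,
    count_within_cluster_significant,
    flag_dominant_topic,
    multinomial_null_table,
    pool_topics,
    topic_correlation_matrix,
    within_between_ratio,
)
from microtopics.datamodel import CountTable
from microtopics.lda import LdaModel

from conftest import simulate_lda_table


def _tv(values, omic="a", k=0):
    return TopicVector(omic, k, np.asarray(values, dtype=float))


class TestTopicCorrelation:
    def test_self_correlation_one(self):
        t = _tv([0.1, 0.5, 0.3, 0.7, 0.2])
        rho, p = topic_correlation_matrix([t, t])
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        x = _tv([0.1, 0.2, 0.3, 0.4, 0.5])
        y = _tv([0.5, 0.4, 0.3, 0.2, 0.1], k=1)
        rho, p = topic_correlation_matrix([x, y])
        assert rho.iloc[0, 1] == pytest.approx(-1.0)
        assert p.iloc[0, 1] < 0.05

    def test_null_calibration(self):
        # fraction of independent pairs with p < .05 should be ~5%
        rng = np.random.default_rng(0)
        hits = 0
        n_pairs = 1000
        for _ in range(n_pairs):
            x = np.clip(rng.normal(0.5, 0.15, 80), 0, 1)
            y = np.clip(rng.normal(0.5, 0.15, 80), 0, 1)
            _, p = topic_correlation_matrix([_tv(x), _tv(y, k=1)])
            hits += p.iloc[0, 1] < 0.05
        assert abs(hits / n_pairs - 0.05) < 0.02

    def test_too_few_samples(self):
        with pytest.raises(CrossOmicError, match="4 samples"):
            topic_correlation_matrix([_tv([0.1, 0.2, 0.3])])


class TestClusterTopics:
    def test_duplicated_vectors_perfect_recovery(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 1, 10)
        topics = [_tv(a), _tv(a, k=1), _tv(b, omic="b"), _tv(b, omic="b", k=1)]
        out = cluster_topics(topics, n_clusters=2)
        labels = out.cluster_labels
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_1d_toy_ratio(self):
        # four topics at coordinates {0, 1, 10, 11}: clusters {0,1}, {10,11},
        # each with within/between ratio 1/10
        dist = np.abs(
            np.array([0.0, 1.0, 10.0, 11.0])[:, None]
            - np.array([0.0, 1.0, 10.0, 11.0])[None, :]
        )
        labels = np.array([1, 1, 2, 2])
        ratios = within_between_ratio(dist, labels)
        assert ratios == [pytest.approx(0.1), pytest.approx(0.1)]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        base = [_tv(rng.uniform(0, 1, 12), omic=f"o{i}") for i in range(6)]
        out1 = cluster_topics(base, n_clusters=3)
        order = [3, 0, 5, 1, 4, 2]
        out2 = cluster_topics([base[i] for i in order], n_clusters=3)
        from sklearn.metrics import adjusted_rand_score

        relabeled = np.empty(6, dtype=int)
        for new_pos, old_pos in enumerate(order):
            relabeled[old_pos] = out2.cluster_labels[new_pos]
        assert adjusted_rand_score(out1.cluster_labels, relabeled) == pytest.approx(1.0)

    def test_scale_invariant_argmin(self):
        rng = np.random.default_rng(3)
        topics = [_tv(rng.uniform(0, 0.5, 15), omic=f"o{i}") for i in range(6)]
        out1 = cluster_topics(topics, n_range=[2, 3, 4])
        scaled = [
            TopicVector(t.omic_name, t.topic_index, t.attribution * 2.0) for t in topics
        ]
        out2 = cluster_topics(scaled, n_range=[2, 3, 4])
        assert out1.n_clusters == out2.n_clusters
        np.testing.assert_allclose(
            out1.ratio_grid["inverse_correlation"], out2.ratio_grid["inverse_correlation"]
        )

    def test_bad_n_range(self):
        topics = [_tv(np.random.default_rng(4).uniform(0, 1, 8), omic=f"o{i}")
                  for i in range(4)]
        with pytest.raises(CrossOmicError, match="n_range"):
            cluster_topics(topics, n_range=[4])


class TestNullTable:
    def test_column_sums_preserved(self):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 30, size=(20, 10))
        values[0] += 1  # avoid an all-zero column
        table = CountTable("x", [f"f{i}" for i in range(20)],
                           [f"s{j}" for j in range(10)], values)
        null = multinomial_null_table(table, seed=0)
        np.testing.assert_array_equal(
            null.values.sum(axis=0), table.values.sum(axis=0)
        )

    def test_identity_resampling_preserves_frequencies(self):
        # resampling each sample from its own distribution keeps expected
        # feature frequencies (checked at depth 1e4 within 3 SE)
        rng = np.random.default_rng(6)
        probs = rng.dirichlet(np.ones(15))
        counts = rng.multinomial(10_000, probs, size=1).T
        table = CountTable("x", [f"f{i}" for i in range(15)], ["s0"],
                           counts.astype(float))
        acc = np.zeros(15)
        n_rep = 50
        for i in range(n_rep):
            acc += multinomial_null_table(table, seed=i, identity=True).values[:, 0]
        mean = acc / n_rep
        p_emp = table.values[:, 0] / 10_000
        se = np.sqrt(p_emp * (1 - p_emp) * 10_000 / n_rep)
        assert np.all(np.abs(mean - table.values[:, 0]) <= 3 * se + 1)


class TestFlagDominantTopic:
    def _model(self, theta):
        D, K = theta.shape
        beta = np.full((K, 10), 0.1)
        return LdaModel("x", K, 0.5, 0.1, theta, beta,
                        [f"f{v}" for v in range(10)], [f"s{d}" for d in range(D)])

    def test_uniform_theta_not_flagged(self):
        theta = np.full((6, 3), 1 / 3)
        assert flag_dominant_topic(self._model(theta), 10.0, [0, 0, 0]) == []

    def test_dominant_uninterpretable_topic_flagged(self):
        theta = np.column_stack([np.full(8, 0.99), np.full(8, 0.005), np.full(8, 0.005)])
        model = self._model(theta)
        assert flag_dominant_topic(model, 10.0, [0, 2, 1]) == [0]
        # with attributed features the same topic survives
        assert flag_dominant_topic(model, 10.0, [3, 2, 1]) == []

    def test_k1_returns_empty(self):
        theta = np.ones((5, 1))
        assert flag_dominant_topic(self._model(theta)) == []


class TestClusterSamples:
    def test_identical_profiles_co_cluster(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, 4)
        profiles = np.column_stack([a, a, rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)])
        topics = [_tv(profiles[i], k=i) for i in range(4)]
        out = cluster_samples(topics, ["s1", "s2", "s3", "s4"], n_clusters=2)
        assert out.cluster_labels[0] == out.cluster_labels[1]

    def test_disjoint_dominant_topics_exact_recovery(self):
        # construction oracle: two sample groups dominated by different topics
        rng = np.random.default_rng(8)
        n = 20
        theta = np.zeros((n, 4))
        theta[:10, 0] = 0.85
        theta[:10, 1:] = 0.05
        theta[10:, 1] = 0.85
        theta[10:, [0, 2, 3]] = 0.05
        theta += rng.uniform(0, 0.02, size=theta.shape)
        topics = [_tv(theta[:, k], k=k) for k in range(4)]
        out = cluster_samples(topics, [f"s{i}" for i in range(n)], n_clusters=2)
        from sklearn.metrics import adjusted_rand_score

        truth = np.array([0] * 10 + [1] * 10)
        assert adjusted_rand_score(truth, out.cluster_labels) == pytest.approx(1.0)

    def test_sibling_coclustering_high_at_strong_family_signal(self):
        from microtopics.synthetic import GeneratorConfig, OmicSpec, generate_cohort
        from microtopics.lda import fit_lda_gibbs
        from microtopics.normalization import rle_size_factors, normalize_log_discretize

        config = GeneratorConfig(
            n_families=20, omic_specs={"a": OmicSpec(60, 800)}, k_true=3,
            sibling_correlation=0.8, alpha_true=0.3, n_covariates=0, seed=13,
        )
        omics, metadata, truth = generate_cohort(config)
        table = omics["a"]
        norm = normalize_log_discretize(table, rle_size_factors(table))
        model = fit_lda_gibbs(norm.discretized_table(), K=3, alpha=0.5, gamma=0.1,
                              n_iterations=150, burn_in=50, thin=5, seed=0,
                              drop_empty_samples=True)
        topics = pool_topics({"a": model}, model.sample_ids)
        out = cluster_samples(topics, model.sample_ids, n_clusters=2,
                              metadata=metadata)
        assert out.sibling_coclustering_rate is not None
        assert out.sibling_coclustering_rate >= 0.85


class TestPoolAndCount:
    def test_pool_respects_exclusion(self):
        rng = np.random.default_rng(9)
        theta = rng.dirichlet([1, 1, 1], size=6)
        beta = rng.dirichlet(np.ones(8), size=3)
        model = LdaModel("a", 3, 0.5, 0.1, theta, beta,
                         [f"f{v}" for v in range(8)], [f"s{d}" for d in range(6)])
        topics = pool_topics({"a": model}, [f"s{d}" for d in range(6)],
                             exclude={("a", 1)})
        assert [t.topic_index for t in topics] == [0, 2]

    def test_within_cluster_significant_count(self):
        x = np.linspace(0, 1, 30)
        noise = np.random.default_rng(10).normal(0, 0.01, 30)
        topics = [_tv(x), _tv(np.clip(x + noise, 0, 1), k=1), _tv(x[::-1], omic="b")]
        labels = np.array([1, 1, 2])
        # the correlated pair shares cluster 1 => one significant pair
        assert count_within_cluster_significant(topics, labels) == 1
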