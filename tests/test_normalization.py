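import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microtopics.datamodel import CountTable
from microtopics.normalization import (
    NormalizationError,
    community_distance,
    distance_matrix,
    normalize_log_discretize,
    rle_size_factors,
    select_normalization,
)
from microtopics.synthetic import GeneratorConfig, OmicSpec, generate_cohort


class TestRleSizeFactors:
    def test_hand_example(self, hand_table):
        np.testing.assert_allclose(
            rle_size_factors(hand_table), [0.70710678, 1.41421356], atol=1e-4
        )

    def test_identical_samples_unit_factors(self):
        table = CountTable("x", ["f1", "f2"], ["s1", "s2"],
                           np.array([[3, 3], [7, 7]]))
        np.testing.assert_allclose(rle_size_factors(table), [1.0, 1.0])

    def test_column_scaling_moves_factors(self):
        # scaling one of two samples by c sends factors to (1/sqrt(c), sqrt(c))
        base = np.array([[2.0, 2.0], [8.0, 8.0], [5.0, 5.0]])
        for c in (2.0, 10.0):
            scaled = base.copy()
            scaled[:, 1] *= c
            table = CountTable("x", ["f1", "f2", "f3"], ["s1", "s2"], scaled)
            np.testing.assert_allclose(
                rle_size_factors(table), [1 / np.sqrt(c), np.sqrt(c)], rtol=1e-10
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.integers(1, 100, size=(6, 5)).astype(float)
        table = CountTable("x", [f"f{i}" for i in range(6)],
                           [f"s{j}" for j in range(5)], values)
        factors = rle_size_factors(table)
        fp = rng.permutation(6)
        sp = rng.permutation(5)
        shuffled = CountTable(
            "x", [f"f{i}" for i in fp], [f"s{j}" for j in sp], values[fp][:, sp]
        )
        np.testing.assert_allclose(rle_size_factors(shuffled), factors[sp])

    def test_sparse_fallback_prevalence_reference(self):
        rng = np.random.default_rng(1)
        values = rng.integers(1, 50, size=(10, 20)).astype(float)
        values[:, 0] = 0  # every feature has one zero -> no all-positive feature
        values[0:5, 0] = rng.integers(1, 50, size=5)
        table = CountTable("x", [f"f{i}" for i in range(10)],
                           [f"s{j}" for j in range(20)], values)
        factors = rle_size_factors(table)
        assert np.all(factors > 0)

    def test_no_reference_features_error(self):
        values = np.eye(4)
        table = CountTable("x", [f"f{i}" for i in range(4)],
                           [f"s{j}" for j in range(4)], values)
        with pytest.raises(NormalizationError, match="reference"):
            rle_size_factors(table)


class TestNormalizeLogDiscretize:
    def test_zero_preserved_and_arithmetic(self):
        table = CountTable("x", ["f1", "f2"], ["s1"], np.array([[0.0], [7.0]]))
        norm = normalize_log_discretize(table, np.array([1.0]))
        assert norm.log_values[0, 0] == 0 and norm.discretized[0, 0] == 0
        assert norm.log_values[1, 0] == pytest.approx(3.0)  # log2(8)
        assert norm.discretized[1, 0] == 3

    def test_monotone_in_raw_count(self):
        counts = np.arange(0, 200, dtype=float).reshape(-1, 1)
        table = CountTable("x", [f"f{i}" for i in range(200)], ["s1"], counts)
        norm = normalize_log_discretize(table, np.array([2.5]))
        assert np.all(np.diff(norm.discretized[:, 0]) >= 0)

    def test_nonpositive_factor_rejected(self, hand_table):
        with pytest.raises(NormalizationError):
            normalize_log_discretize(hand_table, np.array([1.0, 0.0]))


class TestCommunityDistance:
    @pytest.mark.parametrize(
        "metric",
        ["manhattan", "euclidean", "canberra", "clark", "bray_curtis",
         "kulczynski", "jaccard", "alt_gower", "inverse_correlation", "cosine"],
    )
    def test_identity_is_zero(self, metric):
        x = np.array([1.0, 2.0, 3.0, 0.5])
        assert community_distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "x, y, metric, expected",
        [
            ((1, 2), (2, 1), "bray_curtis", 1 / 3),
            ((1, 0), (0, 1), "canberra", 1.0),
            ((1, 2), (2, 1), "jaccard", 0.5),           # 2B/(1+B), B=1/3
            ((1, 0), (0, 1), "clark", 1.0),
            ((1, 2, 0), (2, 1, 0), "alt_gower", 1.0),   # double zero excluded
            ((1, 2), (2, 1), "kulczynski", 1 - 2 / 3),
            ((1, 0), (1, 1), "cosine", 1 - 1 / np.sqrt(2)),
            ((1, 2, 3), (3, 2, 1), "inverse_correlation", 2.0),
        ],
    )
    def test_hand_values(self, x, y, metric, expected):
        assert community_distance(x, y, metric) == pytest.approx(expected, abs=1e-10)

    def test_unknown_metric_and_length_mismatch(self):
        with pytest.raises(NormalizationError, match="unknown"):
            community_distance([1], [1], "chebyshev")
        with pytest.raises(NormalizationError, match="mismatch"):
            community_distance([1, 2], [1], "euclidean")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from(["euclidean", "manhattan"]))
    def test_triangle_inequality(self, seed, metric):
        rng = np.random.default_rng(seed)
        x, y, z = rng.uniform(0, 10, size=(3, 6))
        dxy = community_distance(x, y, metric)
        dyz = community_distance(y, z, metric)
        dxz = community_distance(x, z, metric)
        assert dxz <= dxy + dyz + 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_distance_matrix_structure(self, seed):
        rng = np.random.default_rng(seed)
        cols = rng.uniform(0, 5, size=(7, 4))
        dm = distance_matrix(cols, [f"s{j}" for j in range(4)], "bray_curtis")
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0)


class TestSelectNormalization:
    def test_single_candidate_degenerate_winner(self, small_cohort):
        omics, metadata, _ = small_cohort
        report = select_normalization(
            omics["a"], metadata, candidates=["rle"], metrics=["euclidean"]
        )
        assert report["winner"] == "rle"
        assert report["grid"].shape == (1, 1)

    def test_hand_ratio(self):
        # within-pair distances {1,1}, between distances {2,...} -> ratio 0.5
        values = np.array([[0.0, 1.0, 2.0, 3.0]])
        table = CountTable("x", ["f1"], ["F0S1", "F0S2", "F1S1", "F1S2"],
                           np.exp2(values) - 1)  # log2(x+1) recovers 0,1,2,3
        import pandas as pd

        from microtopics.datamodel import SampleMetadata

        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["F0S1", "F0S2", "F1S1", "F1S2"],
                    "individual_id": list("abcd"),
                    "family_id": ["F0", "F0", "F1", "F1"],
                    "phenotype": ["case", "control", "case", "control"],
                }
            ),
            [],
        )
        report = select_normalization(
            table, meta, candidates=["none"], metrics=["manhattan"]
        )
        # within: |0-1|, |2-3| -> 1; between: |0-2|,|0-3|,|1-2|,|1-3| -> 2
        assert report["grid"].loc["none", "manhattan"] == pytest.approx(0.5)

    def test_rle_beats_none_under_depth_noise(self):
        # seeded Monte-Carlo oracle: multiplicative depth noise is exactly
        # what median-of-ratios removes
        config = GeneratorConfig(
            n_families=20, omic_specs={"a": OmicSpec(80, 2000)}, k_true=3,
            sibling_correlation=0.9, n_covariates=0, seed=21,
        )
        omics, metadata, _ = generate_cohort(config)
        rng = np.random.default_rng(4)
        noisy_values = np.rint(
            omics["a"].values * np.exp(rng.normal(0, 0.8, size=omics["a"].n_samples))
        )
        table = CountTable("a", omics["a"].feature_ids, omics["a"].sample_ids,
                           noisy_values)
        report = select_normalization(table, metadata, candidates=["rle", "none"])
        grid = report["grid"]
        wins = sum(grid.loc["rle", m] < grid.loc["none", m] for m in grid.columns)
        assert wins >= 6
        assert report["winner"] == "rle"
        assert np.isfinite(grid.to_numpy(dtype=float)).all()
        assert (grid.to_numpy(dtype=float) > 0).all()

    def test_no_sibling_pairs_error(self, hand_table):
        import pandas as pd

        from microtopics.datamodel import SampleMetadata

        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "individual_id": ["i1", "i2"],
                    "family_id": ["f1", "f2"],
                    "phenotype": ["case", "control"],
                }
            ),
            [],
        )
        with pytest.raises(NormalizationError, match="sibling"):
            select_normalization(hand_table, meta, candidates=["none"])
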