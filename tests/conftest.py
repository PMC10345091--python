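import numpy as np
import pytest

from microtopics.datamodel import CountTable, SampleMetadata
from microtopics.synthetic import GeneratorConfig, OmicSpec, generate_cohort

import pandas as pd


@pytest.fixture
def hand_table():
    """3 features x 2 samples with a known median-of-ratios solution."""
    return CountTable(
        "hand", ["f1", "f2", "f3"], ["s1", "s2"], np.array([[2, 4], [8, 16], [2, 4]])
    )


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "sample_id": ["F0S1", "F0S2", "F1S1", "F1S2"],
            "individual_id": ["F0I1", "F0I2", "F1I1", "F1I2"],
            "family_id": ["F0", "F0", "F1", "F1"],
            "phenotype": ["case", "control", "case", "control"],
        }
    )
    return SampleMetadata(frame, [])


@pytest.fixture(scope="session")
def small_cohort():
    """Two-omic shared-theta cohort used by several integration tests."""
    config = GeneratorConfig(
        n_families=15,
        omic_specs={"a": OmicSpec(60, 500), "b": OmicSpec(50, 500)},
        k_true=3,
        n_covariates=2,
        seed=11,
    )
    return generate_cohort(config)


def simulate_lda_table(D, V, K, depth, alpha=0.5, gamma=0.1, seed=0, name="sim"):
    """Draw (table, theta, beta) from the LDA generative process."""
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    beta = rng.dirichlet(np.full(V, gamma), size=K)
    values = np.zeros((V, D), dtype=np.int64)
    for d in range(D):
        tc = rng.multinomial(depth, theta[d])
        for k in range(K):
            if tc[k]:
                values[:, d] += rng.multinomial(tc[k], beta[k])
    table = CountTable(
        name, [f"f{v}" for v in range(V)], [f"s{d:03d}" for d in range(D)], values
    )
    return table, theta, beta


def best_match_cosine(fitted_beta, true_beta):
    """Mean cosine similarity under the best bipartite topic matching."""
    from scipy.optimize import linear_sum_assignment

    a = fitted_beta / np.linalg.norm(fitted_beta, axis=1, keepdims=True)
    b = true_beta / np.linalg.norm(true_beta, axis=1, keepdims=True)
    sim = a @ b.T
    r, c = linear_sum_assignment(-sim)
    return float(sim[r, c].mean()), c
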