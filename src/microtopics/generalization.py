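"""Do topic-implied feature relationships replicate across datasets?

Two datasets profiled with comparable methods should, if topics reflect
real sub-communities, place the same features close together. Each fitted
model induces a feature-feature cosine distance matrix from its beta
columns (a feature's K topic weights); two such matrices, restricted to
their common features, are compared with a Mantel test whose null
distribution comes from jointly permuting one matrix's rows and columns
(permuting rows alone would break symmetry and is not a valid Mantel null).
The observed Pearson correlation of upper triangles is reported with an
add-one one-sided p-value (concordance alternative) and a z-score against
the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lda import LdaModel

__all__ = [
    "GeneralizationError",
    "FeatureDistanceMatrix",
    "MantelResult",
    "beta_cosine_distance",
    "mantel_test",
]


class GeneralizationError(ValueError):
    pass


@dataclass
class FeatureDistanceMatrix:
    feature_ids: list[str]
    K: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.feature_ids)
        if self.values.shape != (n, n):
            raise GeneralizationError("distance matrix shape does not match feature ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GeneralizationError("cosine distance matrix must be symmetric")
        if np.any(self.values < -1e-10) or np.any(self.values > 2 + 1e-10):
            raise GeneralizationError("cosine distances must lie in [0, 2]")
        np.fill_diagonal(self.values, 0.0)

    def restrict(self, feature_ids: list[str]) -> "FeatureDistanceMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return FeatureDistanceMatrix(
            list(feature_ids), self.K, self.values[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


def beta_cosine_distance(
    model: LdaModel, features: list[str] | None = None
) -> FeatureDistanceMatrix:
    """1 - cosine similarity between features' K-dimensional beta columns."""
    if features is None:
        features = list(model.feature_ids)
    pos = {f: i for i, f in enumerate(model.feature_ids)}
    missing = [f for f in features if f not in pos]
    if missing:
        raise GeneralizationError(f"features absent from model: {missing[:5]}")
    cols = model.beta[:, [pos[f] for f in features]]  # K x n
    norms = np.linalg.norm(cols, axis=0)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise GeneralizationError(
            f"all-zero beta column for feature {features[zero[0]]!r}"
        )
    unit = cols / norms[None, :]
    sim = np.clip(unit.T @ unit, -1.0, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return FeatureDistanceMatrix(list(features), model.K, dist)


@dataclass
class MantelResult:
    r: float
    n_permutations: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_features: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n_permutations": self.n_permutations,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p,
            "n_features": self.n_features,
            "seed": self.seed,
        }


def mantel_test(
    A: FeatureDistanceMatrix,
    B: FeatureDistanceMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """Mantel test on the common features of A and B.

    r is the Pearson correlation of upper-triangle entries. The null jointly
    permutes B's rows and columns ``n_permutations`` times;
    p = (1 + #{null r >= observed}) / (1 + n_permutations), one-sided for
    concordance, and z = (observed - null mean) / null SD.
    """
    common = sorted(set(A.feature_ids) & set(B.feature_ids))
    if len(common) < 5:
        raise GeneralizationError(
            f"need >= 5 common features, found {len(common)}"
        )
    a = A.restrict(common).values
    b = B.restrict(common).values
    n = len(common)
    iu = np.triu_indices(n, k=1)
    ta = a[iu]
    if ta.std() == 0:
        raise GeneralizationError("matrix A has a zero-variance upper triangle")
    tb = b[iu]
    if tb.std() == 0:
        raise GeneralizationError("matrix B has a zero-variance upper triangle")

    za = (ta - ta.mean()) / ta.std()

    def corr_with_a(mat: np.ndarray) -> float:
        t = mat[iu]
        sd = t.std()
        if sd == 0:
            return 0.0
        return float(np.mean(za * (t - t.mean()) / sd))

    observed = corr_with_a(b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        null[i] = corr_with_a(b[np.ix_(perm, perm)])
    null_mean = float(null.mean())
    null_sd = float(null.std())
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("inf")
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_permutations)
    return MantelResult(
        r=observed,
        n_permutations=n_permutations,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=float(p),
        n_features=n,
        seed=seed,
    )
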