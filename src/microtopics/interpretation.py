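"""Topic interpretation: which features define a topic, and which metadata
covariates track it.

A feature is attributed to a topic only when it passes two criteria on the
topic-feature weight matrix beta (K x V):

1. specificity — its maximum weight across topics exceeds the median weight
   by more than 1.5 sample standard deviations of its K weights, excluding
   features spread evenly ("ubiquitously") across topics;
2. driver — it loads heavily (above a configurable percentile of absolute
   loadings) on at least one of the top K-1 right-singular axes of the
   column-centered beta, the axes of maximal between-topic variation.

Surviving features are attributed to their argmax topic. Covariate links
are plain Spearman correlations between a topic's per-sample attribution
and each metadata covariate, starred at p < 0.05 (uncorrected, as a screen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datamodel import SampleMetadata
from .crossomic import TopicVector

__all__ = [
    "InterpretationError",
    "FeatureAttributionReport",
    "select_topic_features",
    "topic_metadata_correlation",
]


class InterpretationError(ValueError):
    pass


@dataclass
class FeatureAttributionReport:
    omic_name: str
    frame: pd.DataFrame  # feature_id, topic_index, weight, passed_sd, passed_svd
    percentile: float
    sd_multiplier: float

    def attributed(self) -> pd.DataFrame:
        """Features passing both criteria."""
        return self.frame[self.frame["passed_sd"] & self.frame["passed_svd"]]

    def counts_per_topic(self, K: int) -> list[int]:
        att = self.attributed()
        return [int((att["topic_index"] == k).sum()) for k in range(K)]


def select_topic_features(
    beta: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    percentile: float = 99.0,
    sd_multiplier: float = 1.5,
    omic_name: str = "",
) -> FeatureAttributionReport:
    """Dual-criterion feature selection on a K x V topic-feature matrix."""
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2:
        raise InterpretationError("beta must be K x V")
    K, V = beta.shape
    if K < 2:
        raise InterpretationError("need K >= 2 (SD across topics undefined for K = 1)")
    if not 0.0 < percentile < 100.0:
        raise InterpretationError("percentile must lie in (0, 100)")
    if feature_ids is None:
        feature_ids = [f"f{v}" for v in range(V)]
    if len(feature_ids) != V:
        raise InterpretationError("feature_ids length does not match beta columns")

    col_max = beta.max(axis=0)
    col_median = np.median(beta, axis=0)
    col_sd = beta.std(axis=0, ddof=1)
    passed_sd = col_max > col_median + sd_multiplier * col_sd

    centered = beta - beta.mean(axis=0, keepdims=True)
    # right-singular vectors of the centered matrix: axes of between-topic variation
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n_axes = min(K - 1, vt.shape[0])
    passed_svd = np.zeros(V, dtype=bool)
    for a in range(n_axes):
        loadings = np.abs(vt[a])
        cut = np.percentile(loadings, percentile)
        passed_svd |= loadings > cut

    frame = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "topic_index": beta.argmax(axis=0),
            "weight": col_max,
            "passed_sd": passed_sd,
            "passed_svd": passed_svd,
        }
    )
    return FeatureAttributionReport(omic_name, frame, percentile, sd_multiplier)


def topic_metadata_correlation(
    topics: Sequence[TopicVector],
    metadata: SampleMetadata,
    sample_ids: Sequence[str],
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each topic's attribution with each covariate.

    Missing covariate values are dropped pairwise; a covariate with fewer
    than 4 complete pairs for every topic is excluded with a warning column.
    Returns a long-format frame (topic, covariate, rho, p, significant).
    """
    names = list(covariates) if covariates is not None else list(metadata.covariate_names)
    cov = metadata.covariate_matrix(sample_ids, names)
    rows = []
    for name in names:
        values = cov[name].to_numpy(dtype=float)
        for t in topics:
            mask = np.isfinite(values)
            if mask.sum() < 4:
                continue
            rho, p = spearmanr(t.attribution[mask], values[mask])
            rows.append(
                {
                    "topic": t.label,
                    "covariate": name,
                    "rho": float(rho),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    if not rows:
        raise InterpretationError("no covariate had >= 4 complete pairs")
    return pd.DataFrame(rows)
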