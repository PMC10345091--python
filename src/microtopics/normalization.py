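"""Normalization, discretization and community-ecology distances.

Sequencing depth and instrument intensity differ across samples, so counts
are scaled by median-of-ratios (RLE-family) size factors before modeling:
the size factor of sample d is the median, over a reference feature set, of
that sample's count divided by the feature's geometric mean across samples.
Counts are then log2(x+1)-transformed (the topic model's Gibbs sampler works
on token counts, and the log transform both tames heteroskedasticity and
bounds the token load) and rounded half-to-even to integers.

The normalization method itself is selected by a data-driven criterion: the
sibling-pair cohort implies related samples should be closer than unrelated
ones, so the candidate minimizing the within-sibling / between-family mean
distance ratio across a panel of ecological metrics wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata

__all__ = [
    "NormalizationError",
    "NormalizedTable",
    "DistanceMatrix",
    "rle_size_factors",
    "total_sum_factors",
    "normalize_log_discretize",
    "community_distance",
    "distance_matrix",
    "select_normalization",
    "DISTANCE_METRICS",
]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedTable:
    source: CountTable
    size_factors: np.ndarray
    normalized: np.ndarray      # value / size_factor
    log_values: np.ndarray      # log2(normalized + 1)
    discretized: np.ndarray     # round-half-to-even of log_values, int
    transform_log: bool = True

    def discretized_table(self) -> CountTable:
        return CountTable(
            self.source.omic_name,
            list(self.source.feature_ids),
            list(self.source.sample_ids),
            self.discretized.astype(float),
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log_values, index=self.source.feature_ids, columns=self.source.sample_ids
        )


def rle_size_factors(table: CountTable, min_prevalence: float = 0.9) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    The reference set is the features with all-positive counts. When none
    exists (sparse omics), falls back to features positive in at least
    ``min_prevalence`` of samples, with geometric means over positive entries
    only and per-sample medians over the reference features positive in that
    sample.
    """
    x = table.values
    all_positive = np.all(x > 0, axis=1)
    if np.any(all_positive):
        ref = x[all_positive]
        log_gm = np.mean(np.log(ref), axis=1)
        ratios = np.exp(np.log(ref) - log_gm[:, None])
        return np.median(ratios, axis=0)
    prevalence = np.mean(x > 0, axis=1)
    ref_mask = prevalence >= min_prevalence
    if not np.any(ref_mask):
        raise NormalizationError(
            "no reference features: nothing all-positive and nothing with prevalence "
            f">= {min_prevalence:.0%}; consider total-sum scaling instead"
        )
    ref = x[ref_mask]
    with np.errstate(divide="ignore"):
        logs = np.where(ref > 0, np.log(np.where(ref > 0, ref, 1.0)), np.nan)
    log_gm = np.nanmean(logs, axis=1)
    factors = np.empty(table.n_samples)
    for d in range(table.n_samples):
        col = ref[:, d]
        pos = col > 0
        if not np.any(pos):
            raise NormalizationError(
                f"sample {table.sample_ids[d]!r} has no positive reference feature"
            )
        factors[d] = np.median(np.exp(np.log(col[pos]) - log_gm[pos]))
    return factors


def total_sum_factors(table: CountTable) -> np.ndarray:
    """Depth scaling: per-sample total divided by the mean total."""
    totals = table.sample_totals
    if np.any(totals <= 0):
        raise NormalizationError("sample with zero total count")
    return totals / totals.mean()


def normalize_log_discretize(table: CountTable, factors: np.ndarray) -> NormalizedTable:
    """Scale by size factors, log2(x+1), and round half-to-even to integers."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (table.n_samples,):
        raise NormalizationError("one size factor per sample required")
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise NormalizationError("size factors must be positive and finite")
    normalized = table.values / factors[None, :]
    log_values = np.log2(normalized + 1.0)
    discretized = np.rint(log_values).astype(np.int64)
    return NormalizedTable(table, factors, normalized, log_values, discretized)


# ---------------------------------------------------------------------------
# Community-ecology distances (vegan conventions: Canberra, Clark and
# alt-Gower average over the pairs that are not both zero; quantitative
# Jaccard is the Bray-Curtis transform 2B/(1+B)).

def _nonzero_pair_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (x != 0) | (y != 0)


def _manhattan(x, y):
    return float(np.sum(np.abs(x - y)))


def _euclidean(x, y):
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _canberra(x, y):
    m = _nonzero_pair_mask(x, y)
    if not np.any(m):
        return 0.0
    num = np.abs(x[m] - y[m])
    den = x[m] + y[m]
    return float(np.sum(num / den) / m.sum())


def _clark(x, y):
    m = _nonzero_pair_mask(x, y)
    if not np.any(m):
        return 0.0
    r = (x[m] - y[m]) / (x[m] + y[m])
    return float(np.sqrt(np.sum(r**2) / m.sum()))


def _bray_curtis(x, y):
    den = np.sum(x + y)
    if den == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / den)


def _kulczynski(x, y):
    sx, sy = np.sum(x), np.sum(y)
    if sx == 0 or sy == 0:
        return 1.0
    mins = np.sum(np.minimum(x, y))
    return float(1.0 - 0.5 * (mins / sx + mins / sy))


def _jaccard(x, y):
    b = _bray_curtis(x, y)
    return float(2.0 * b / (1.0 + b))


def _alt_gower(x, y):
    m = _nonzero_pair_mask(x, y)
    if not np.any(m):
        return 0.0
    return float(np.mean(np.abs(x[m] - y[m])))


def _inverse_correlation(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def _cosine(x, y):
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise NormalizationError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(x, y) / (nx * ny))


DISTANCE_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "manhattan": _manhattan,
    "euclidean": _euclidean,
    "canberra": _canberra,
    "clark": _clark,
    "bray_curtis": _bray_curtis,
    "kulczynski": _kulczynski,
    "jaccard": _jaccard,
    "alt_gower": _alt_gower,
    "inverse_correlation": _inverse_correlation,
    "cosine": _cosine,
}

ECOLOGICAL_METRICS = (
    "manhattan",
    "euclidean",
    "canberra",
    "clark",
    "bray_curtis",
    "kulczynski",
    "jaccard",
    "alt_gower",
)


def community_distance(x: Sequence[float], y: Sequence[float], metric: str) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise NormalizationError(f"length mismatch: {x.shape} vs {y.shape}")
    if metric not in DISTANCE_METRICS:
        raise NormalizationError(
            f"unknown metric {metric!r}; choose from {sorted(DISTANCE_METRICS)}"
        )
    if metric in ECOLOGICAL_METRICS and (np.any(x < 0) or np.any(y < 0)):
        raise NormalizationError(f"{metric} requires nonnegative entries")
    return DISTANCE_METRICS[metric](x, y)


@dataclass
class DistanceMatrix:
    ids: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise NormalizationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise NormalizationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise NormalizationError("distance matrix diagonal not zero")
        if np.any(self.values < -1e-12):
            raise NormalizationError("negative distance")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.maximum(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(columns: np.ndarray, ids: Sequence[str], metric: str) -> DistanceMatrix:
    """Pairwise distances between the columns of ``columns``."""
    n = columns.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = community_distance(columns[:, i], columns[:, j], metric)
    return DistanceMatrix(list(ids), metric, out)


NORMALIZATION_CANDIDATES: dict[str, Callable[[CountTable], np.ndarray]] = {
    "rle": rle_size_factors,
    "total_sum": total_sum_factors,
    "none": lambda t: np.ones(t.n_samples),
}


def select_normalization(
    table: CountTable,
    metadata: SampleMetadata,
    candidates: Sequence[str] = ("rle", "total_sum", "none"),
    metrics: Sequence[str] = ECOLOGICAL_METRICS,
) -> dict:
    """Score candidates by the within-sibling / between-family distance ratio.

    Distances are computed on log-normalized values. Returns the full
    (candidate x metric) ratio grid, the per-metric argmin candidate, and
    the overall winner (most metrics won; ties broken by candidate order).
    """
    pairs = metadata.sibling_pairs(table.sample_ids)
    if not pairs:
        raise NormalizationError("no sibling pairs available for normalization selection")
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    family = metadata.family_for(table.sample_ids)

    within_idx = [(sample_pos[a], sample_pos[b]) for a, b in pairs]
    n = table.n_samples
    between_idx = [
        (i, j) for i in range(n) for j in range(i + 1, n) if family[i] != family[j]
    ]
    if not between_idx:
        raise NormalizationError("no between-family sample pairs")

    grid = pd.DataFrame(index=list(candidates), columns=list(metrics), dtype=float)
    for cand in candidates:
        if cand not in NORMALIZATION_CANDIDATES:
            raise NormalizationError(f"unknown normalization candidate {cand!r}")
        norm = normalize_log_discretize(table, NORMALIZATION_CANDIDATES[cand](table))
        logs = norm.log_values
        for metric in metrics:
            within = np.mean(
                [community_distance(logs[:, i], logs[:, j], metric) for i, j in within_idx]
            )
            between = np.mean(
                [community_distance(logs[:, i], logs[:, j], metric) for i, j in between_idx]
            )
            grid.loc[cand, metric] = within / between if between > 0 else np.inf

    per_metric_winner = {m: grid[m].idxmin() for m in metrics}
    wins = {c: sum(1 for m in metrics if per_metric_winner[m] == c) for c in candidates}
    best = max(wins.values())
    winner = next(c for c in candidates if wins[c] == best)
    return {
        "grid": grid,
        "per_metric_winner": per_metric_winner,
        "winner": winner,
        "n_sibling_pairs": len(within_idx),
        "n_between_pairs": len(between_idx),
    }
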