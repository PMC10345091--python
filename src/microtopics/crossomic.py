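"""Cross-omic topic integration.

Because every omic layer is observed on the same underlying community, a
biological process should surface as one topic per omic whose per-sample
attributions (theta columns over the shared samples) co-vary. This module
pools topics across fitted per-omic models, clusters them on their
attribution vectors, selects the number of clusters by a within/between
distance ratio, and validates the claimed structure against an ensemble of
multinomial null tables in which cross-omic coupling is destroyed by
construction.

Samples themselves are clustered on their concatenated topic attributions
with inverse-correlation distance, the representation in which sibling
pairs are expected to co-cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .datamodel import OmicSet, SampleMetadata
from .lda import LdaModel, fit_lda_gibbs
from .datamodel import CountTable

__all__ = [
    "CrossOmicError",
    "TopicVector",
    "CrossOmicAssignment",
    "NullEnsembleReport",
    "SampleClustering",
    "pool_topics",
    "topic_correlation_matrix",
    "within_between_ratio",
    "cluster_topics",
    "multinomial_null_table",
    "null_validation",
    "flag_dominant_topic",
    "cluster_samples",
]

logger = logging.getLogger(__name__)

TOPIC_CLUSTER_METRICS = ("manhattan", "euclidean", "inverse_correlation")


class CrossOmicError(ValueError):
    pass


@dataclass
class TopicVector:
    """One topic's per-shared-sample attribution (a theta column)."""

    omic_name: str
    topic_index: int
    attribution: np.ndarray

    def __post_init__(self) -> None:
        self.attribution = np.asarray(self.attribution, dtype=float)
        if np.any(self.attribution < -1e-12) or np.any(self.attribution > 1 + 1e-12):
            raise CrossOmicError("attributions must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.omic_name}:topic{self.topic_index}"


def pool_topics(
    models: Mapping[str, LdaModel],
    shared_samples: Sequence[str],
    exclude: set[tuple[str, int]] | None = None,
) -> list[TopicVector]:
    """Theta columns of every model, restricted to the shared samples.

    ``exclude`` drops (omic, topic_index) pairs, e.g. flagged dominant
    topics.
    """
    exclude = exclude or set()
    out: list[TopicVector] = []
    for name, model in models.items():
        pos = {s: i for i, s in enumerate(model.sample_ids)}
        missing = [s for s in shared_samples if s not in pos]
        if missing:
            raise CrossOmicError(f"model {name!r} lacks shared samples {missing[:5]}")
        rows = [pos[s] for s in shared_samples]
        for k in range(model.K):
            if (name, k) in exclude:
                continue
            out.append(TopicVector(name, k, model.theta[rows, k]))
    return out


def _attribution_matrix(topics: Sequence[TopicVector]) -> np.ndarray:
    if not topics:
        raise CrossOmicError("no topics supplied")
    n = topics[0].attribution.shape[0]
    for t in topics:
        if t.attribution.shape[0] != n:
            raise CrossOmicError("topics do not share a sample order")
    return np.column_stack([t.attribution for t in topics])


def topic_correlation_matrix(
    topics: Sequence[TopicVector],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (average-rank ties) and t-approximation p-values."""
    x = _attribution_matrix(topics)
    if x.shape[0] < 4:
        raise CrossOmicError("need >= 4 samples for Spearman p-values")
    labels = [t.label for t in topics]
    if len(topics) == 1:
        rho = np.ones((1, 1))
        p = np.zeros((1, 1))
    elif len(topics) == 2:
        r, pv = spearmanr(x[:, 0], x[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho, p = spearmanr(x)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=labels, columns=labels),
        pd.DataFrame(p, index=labels, columns=labels),
    )


def _metric_distance(x: np.ndarray, metric: str) -> np.ndarray:
    """Square distance matrix between the columns of ``x``."""
    cols = x.T
    n = cols.shape[0]
    if metric == "manhattan":
        d = np.abs(cols[:, None, :] - cols[None, :, :]).sum(axis=2)
    elif metric == "euclidean":
        d = np.sqrt(((cols[:, None, :] - cols[None, :, :]) ** 2).sum(axis=2))
    elif metric == "inverse_correlation":
        sd = cols.std(axis=1)
        if np.any(sd == 0):
            logger.warning("constant attribution vector; its correlations set to 0")
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(cols)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        d = 1.0 - corr
    elif metric == "spearman":
        rho = spearmanr(x)[0] if n > 1 else np.ones((1, 1))
        rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
        np.fill_diagonal(rho, 1.0)
        d = 1.0 - rho
    else:
        raise CrossOmicError(f"unknown topic-cluster metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def within_between_ratio(dist: np.ndarray, labels: np.ndarray) -> list[float]:
    """Per-cluster mean within-pair distance over mean member-to-non-member
    distance; singleton clusters contribute within-distance 0."""
    ratios = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        others = np.where(labels != c)[0]
        if others.size == 0:
            raise CrossOmicError("a cluster covers all topics; shrink n_range")
        if members.size == 1:
            within = 0.0
        else:
            iu = np.triu_indices(members.size, k=1)
            within = float(dist[np.ix_(members, members)][iu].mean())
        between = float(dist[np.ix_(members, others)].mean())
        ratios.append(within / between if between > 0 else 0.0)
    return ratios


@dataclass
class CrossOmicAssignment:
    topics: list[TopicVector]
    correlation: pd.DataFrame
    pvalues: pd.DataFrame
    cluster_labels: np.ndarray
    n_clusters: int
    ratio_grid: pd.DataFrame  # index = candidate n, columns = metrics
    scores: pd.Series         # mean ratio per candidate n

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"topic": [t.label for t in self.topics], "cluster": self.cluster_labels}
        )


def cluster_topics(
    topics: Sequence[TopicVector],
    n_range: Sequence[int] | None = None,
    metrics: Sequence[str] = TOPIC_CLUSTER_METRICS,
    rel_tolerance: float = 0.05,
    n_clusters: int | None = None,
) -> CrossOmicAssignment:
    """Cluster pooled topics and select the cluster count.

    Topics are clustered hierarchically (average linkage). For each
    candidate n and metric the mean within/between ratio over that metric's
    own n-cluster cut is computed; the score of n averages the metrics, and
    the selected n is the smallest whose score is within ``rel_tolerance``
    (relative) of the minimum. Final labels come from an average-linkage cut
    of Spearman-correlation distance (1 - rho), the scale on which topic
    similarity is defined. Passing ``n_clusters`` skips selection.
    """
    topics = list(topics)
    if len(topics) < 2:
        raise CrossOmicError("need >= 2 topics to cluster")
    x = _attribution_matrix(topics)
    n_topics = len(topics)
    if n_range is None:
        n_range = range(2, n_topics)
    n_range = [int(n) for n in n_range]
    if not n_range and n_clusters is None:
        raise CrossOmicError("empty n_range")
    if any(n < 2 or n > n_topics - 1 for n in n_range):
        raise CrossOmicError(f"n_range must lie within [2, {n_topics - 1}]")

    grid = pd.DataFrame(index=n_range, columns=list(metrics), dtype=float)
    for metric in metrics:
        dist = _metric_distance(x, metric)
        tree = linkage(squareform(dist, checks=False), method="average")
        for n in n_range:
            labels = fcluster(tree, t=n, criterion="maxclust")
            grid.loc[n, metric] = float(np.mean(within_between_ratio(dist, labels)))
    scores = grid.mean(axis=1)

    if n_clusters is None:
        best = scores.min()
        ok = scores <= best + rel_tolerance * abs(best)
        n_clusters = int(scores.index[ok.to_numpy()][0])

    spearman_dist = _metric_distance(x, "spearman")
    tree = linkage(squareform(spearman_dist, checks=False), method="average")
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")

    corr, pvals = topic_correlation_matrix(topics)
    return CrossOmicAssignment(
        topics=topics,
        correlation=corr,
        pvalues=pvals,
        cluster_labels=np.asarray(labels),
        n_clusters=n_clusters,
        ratio_grid=grid,
        scores=scores,
    )


def count_within_cluster_significant(
    topics: Sequence[TopicVector], labels: np.ndarray, alpha: float = 0.05
) -> int:
    """Number of same-cluster topic pairs with Spearman p < alpha
    (uncorrected, matching the counting rule of the null comparison)."""
    _, pvals = topic_correlation_matrix(topics)
    p = pvals.to_numpy()
    count = 0
    for i in range(len(topics)):
        for j in range(i + 1, len(topics)):
            if labels[i] == labels[j] and p[i, j] < alpha:
                count += 1
    return count


def multinomial_null_table(
    table: CountTable, seed: int = 0, identity: bool = False
) -> CountTable:
    """Null table: each sample redrawn from a multinomial at its own total.

    Probabilities come from the empirical feature distribution of a
    uniformly chosen *other* sample (``identity=True`` uses the sample's own
    distribution — a resampling control that preserves expected feature
    frequencies). Column sums equal the original totals exactly.
    """
    rng = np.random.default_rng(seed)
    x = table.values
    V, D = x.shape
    out = np.zeros_like(x, dtype=np.int64)
    totals = x.sum(axis=0)
    for d in range(D):
        if identity:
            src = d
        else:
            src = int(rng.integers(0, D - 1))
            if src >= d:
                src += 1
        probs = x[:, src] / x[:, src].sum()
        out[:, d] = rng.multinomial(int(totals[d]), probs)
    return CountTable(table.omic_name, list(table.feature_ids), list(table.sample_ids), out)


@dataclass
class NullEnsembleReport:
    n_tables: int
    true_count: int
    null_counts: list[int]
    n_clusters: int
    alpha: float
    seeds: list[int] = field(default_factory=list)

    @property
    def exceeds_all_null(self) -> bool:
        return self.true_count > max(self.null_counts)


def null_validation(
    omics: OmicSet,
    fitted: Mapping[str, LdaModel],
    n_clusters: int,
    discretize=None,
    n_tables: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
    fit_kwargs: Mapping | None = None,
) -> NullEnsembleReport:
    """Compare the true within-cluster significant-correlation count with a
    multinomial null ensemble.

    Each of ``n_tables`` replicates redraws every omic's counts via
    :func:`multinomial_null_table`, reapplies the same discretization
    (``discretize``: CountTable -> CountTable, identity when None), refits
    LDA with each omic's own K/alpha/gamma/iteration settings and seed, and
    clusters the pooled null topics into ``n_clusters`` (the true data's
    count). The report holds the per-table counts of same-cluster topic
    pairs with Spearman p < alpha, against the true data's count.
    """
    if n_tables < 2:
        raise CrossOmicError("n_tables must be >= 2")
    fit_kwargs = dict(fit_kwargs or {})

    true_topics = pool_topics(fitted, omics.shared_samples)
    true_assign = cluster_topics(true_topics, n_clusters=n_clusters)
    true_count = count_within_cluster_significant(
        true_topics, true_assign.cluster_labels, alpha
    )

    null_counts: list[int] = []
    seeds: list[int] = []
    for t in range(n_tables):
        table_seed = seed + 7919 * t
        seeds.append(table_seed)
        null_models: dict[str, LdaModel] = {}
        for i, (name, table) in enumerate(sorted(omics.tables.items())):
            null = multinomial_null_table(table, seed=table_seed + i)
            if discretize is not None:
                null = discretize(null)
            model = fitted[name]
            kwargs = {
                "K": model.K,
                "alpha": model.alpha,
                "gamma": model.gamma,
                "n_iterations": model.n_iterations,
                "burn_in": model.burn_in,
                "seed": model.seed if model.seed is not None else 0,
                "drop_empty_samples": True,
            }
            kwargs.update(fit_kwargs)
            null_models[name] = fit_lda_gibbs(null, **kwargs)
        shared = sorted(
            set(omics.shared_samples)
            - {s for m in null_models.values() for s in m.dropped_samples}
        )
        null_topics = pool_topics(null_models, shared)
        assign = cluster_topics(null_topics, n_clusters=n_clusters)
        null_counts.append(
            count_within_cluster_significant(null_topics, assign.cluster_labels, alpha)
        )
    return NullEnsembleReport(n_tables, true_count, null_counts, n_clusters, alpha, seeds)


def flag_dominant_topic(
    model: LdaModel,
    attribution_ratio_threshold: float = 10.0,
    n_attributed_per_topic: Sequence[int] | None = None,
) -> list[int]:
    """Flag topics whose total attribution dwarfs the rest yet define no
    features.

    A topic is flagged when its theta column sum is at least
    ``attribution_ratio_threshold`` times the next-largest column sum AND it
    has zero features passing the interpretation criteria
    (``n_attributed_per_topic``, one count per topic). Such a topic absorbs
    probability mass without distinguishing samples and distorts downstream
    clustering; K = 1 models flag nothing (no comparison possible).
    """
    if model.K < 2:
        return []
    totals = model.theta.sum(axis=0)
    order = np.argsort(totals)[::-1]
    flagged = []
    top, second = order[0], order[1]
    if totals[top] >= attribution_ratio_threshold * totals[second]:
        n_attr = 0
        if n_attributed_per_topic is not None:
            n_attr = int(n_attributed_per_topic[top])
        if n_attr == 0:
            flagged.append(int(top))
    return flagged


@dataclass
class SampleClustering:
    sample_ids: list[str]
    linkage_method: str
    n_clusters: int
    cluster_labels: np.ndarray
    sibling_coclustering_rate: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.cluster_labels})


def cluster_samples(
    topics: Sequence[TopicVector],
    sample_ids: Sequence[str],
    n_clusters: int = 2,
    metadata: SampleMetadata | None = None,
    linkage_method: str = "complete",
) -> SampleClustering:
    """Hierarchically cluster samples on concatenated topic attributions.

    Pairwise distance is inverse correlation (1 - Pearson r) between sample
    topic profiles; pairs involving a constant profile get distance 1 with a
    warning. When metadata is given, the sibling co-clustering rate is the
    fraction of families whose members all land in one cluster.
    """
    x = _attribution_matrix(topics)  # samples x topics
    n = x.shape[0]
    if len(sample_ids) != n:
        raise CrossOmicError("sample_ids length does not match attributions")
    if n < n_clusters:
        raise CrossOmicError("fewer samples than requested clusters")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        logger.warning(
            "%d samples have constant topic profiles; their distances set to 1",
            int((sd == 0).sum()),
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    dist = np.maximum(1.0 - corr, 0.0)
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")

    rate = None
    if metadata is not None:
        fam = metadata.family_for(sample_ids)
        members: dict[str, list[int]] = {}
        for f, lab in zip(fam, labels):
            members.setdefault(str(f), []).append(int(lab))
        multi = {f: labs for f, labs in members.items() if len(labs) >= 2}
        if multi:
            together = sum(1 for labs in multi.values() if len(set(labs)) == 1)
            rate = together / len(multi)
    return SampleClustering(
        list(sample_ids), linkage_method, n_clusters, np.asarray(labels), rate
    )
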