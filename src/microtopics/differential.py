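"""Per-cluster differential-abundance testing.

Features separating case from control samples are found in two stages.

Stage 1 is a shadow-feature (Boruta-style) screen: the table is extended
with an independently permuted copy of every feature, a random-forest
classifier is fit on phenotype, and each column's importance is the mean
decrease in out-of-bag accuracy when that column is permuted (Breiman's
permutation importance, computed per tree on its own out-of-bag samples).
Over ``n_runs`` such forests each column gets a Z score (mean importance /
SD of importance across runs), and a feature is "important" only when its Z
exceeds the maximum shadow Z — under the null, real features and shadows
are exchangeable, so this is conservative by construction. The whole screen
is repeated ``n_repeats`` times and verdicts are tallied; features in the
top ``percentile_cut`` percentile of tallies survive.

Stage 2 applies a two-sided Wilcoxon rank-sum test to each survivor (exact
when both groups have <= 25 samples and no ties, normal approximation with
tie and continuity correction otherwise) with Benjamini-Hochberg correction
over the survivor set. Testing runs on normalized log-scale values, not on
the discretized LDA input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn import config_context
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialError",
    "BorutaTallyTable",
    "DifferentialReport",
    "boruta_trial",
    "tally_and_test",
    "wilcoxon_rank_sum",
    "bh_adjust",
]


class DifferentialError(ValueError):
    pass


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray([1 if l == "case" else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise DifferentialError("both phenotype groups must be present")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise DifferentialError("need >= 3 samples per phenotype group")
    return y


def _oob_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean decrease in out-of-bag accuracy per column (Breiman's
    permutation importance).

    The forest is a plain Breiman ensemble — one bootstrap and one
    random-feature (sqrt) decision tree per member — built as an explicit
    loop over sklearn trees so each tree's bag, and hence its out-of-bag
    samples, is available for the importance computation. For every tree,
    each column is permuted within the out-of-bag rows and the drop in that
    tree's out-of-bag accuracy is recorded; drops are averaged over trees.
    """
    n, n_cols = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y32 = np.ascontiguousarray(y, dtype=np.float64)
    tree_rng = np.random.default_rng(seed)
    drops = np.zeros(n_cols)
    n_used = 0
    stacked = np.empty(((n_cols + 1) * n, n_cols), dtype=np.float32)
    # Binary 0/1 targets: variance-reduction splits coincide with Gini splits,
    # so regression trees on the labels build the same forest while skipping
    # per-fit target-type inspection; predicted class = leaf mean > 1/2.
    with config_context(skip_parameter_validation=True):
        for _ in range(n_trees):
            idx = tree_rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            m = int(oob.sum())
            if m == 0:
                continue
            tree = DecisionTreeRegressor(
                max_features="sqrt", random_state=int(tree_rng.integers(0, 2**31 - 1))
            )
            tree.fit(X32[idx], y32[idx], check_input=False)
            X_oob = X32[oob]
            y_oob = y[oob]
            perm = rng.permutation(m)
            buf = stacked[: (n_cols + 1) * m]
            buf[:] = np.tile(X_oob, (n_cols + 1, 1))
            for j in range(n_cols):
                buf[(j + 1) * m : (j + 2) * m, j] = X_oob[perm, j]
            pred = tree.predict(buf, check_input=False).reshape(n_cols + 1, m) > 0.5
            acc = (pred == (y_oob[None, :] == 1)).mean(axis=1)
            drops += acc[0] - acc[1:]
            n_used += 1
    if n_used == 0:
        raise DifferentialError("no tree had out-of-bag samples")
    return drops / n_used


def boruta_trial(
    table: np.ndarray,
    labels: Sequence[str],
    n_runs: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """One shadow-feature screen; returns a boolean "important" flag per feature.

    ``table`` is feature x sample. The extended table — every feature plus
    an independently permuted shadow copy of each — is built once per trial;
    ``n_runs`` forests are then trained on it and Z = mean/SD of each
    column's importance over the runs. A feature is important iff its Z
    strictly exceeds the best shadow Z. Holding the shadow permutation fixed
    within a trial keeps real and shadow columns exchangeable under the
    null (both carry one fixed chance association with the labels), which
    is what makes the max-shadow rule conservative; repeated trials (see
    :func:`tally_and_test`) redraw the shadows. Constant features have
    importance identically 0 and are never flagged.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DifferentialError("table must be feature x sample")
    y = _check_labels(np.asarray(labels))
    if table.shape[1] != y.shape[0]:
        raise DifferentialError("one label per sample required")
    V, n = table.shape
    X_real = table.T
    rng = np.random.default_rng(seed)

    shadows = np.empty_like(X_real)
    for j in range(V):
        shadows[:, j] = X_real[rng.permutation(n), j]
    X = np.hstack([X_real, shadows])
    importances = np.empty((n_runs, 2 * V))
    for run in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        importances[run] = _oob_importance(X, y, n_trees, run_seed, rng)

    mean = importances.mean(axis=0)
    sd = importances.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(2 * V)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, np.where(mean > 0, np.inf, 0.0))
    z_real, z_shadow = z[:V], z[V:]
    return z_real > z_shadow.max()


@dataclass
class BorutaTallyTable:
    feature_ids: list[str]
    tallies: np.ndarray
    n_repeats: int
    seeds: list[int]
    n_runs: int
    n_trees: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids, "tally": self.tallies})


@dataclass
class DifferentialReport:
    cluster_id: str
    frame: pd.DataFrame  # survivors: feature_id, tally, tally_percentile, statistic, p, p_adj, direction
    tally_table: BorutaTallyTable
    alpha: float
    percentile_cut: float

    def reported(self) -> pd.DataFrame:
        """Features with BH-adjusted p below alpha."""
        return self.frame[self.frame["p_adj"] < self.alpha]


def wilcoxon_rank_sum(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact when both groups <= 25 and tie-free,
    otherwise normal approximation with tie and continuity correction."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    combined = np.concatenate([case, control])
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(case) <= 25 and len(control) <= 25 and tie_free) else "asymptotic"
    res = mannwhitneyu(
        case, control, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def tally_and_test(
    table: np.ndarray,
    labels: Sequence[str],
    feature_ids: Sequence[str] | None = None,
    cluster_id: str = "all",
    n_repeats: int = 100,
    n_runs: int = 100,
    n_trees: int = 500,
    percentile_cut: float = 90.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> DifferentialReport:
    """Repeat the shadow screen, tally verdicts, and rank-sum test the
    top-percentile features with BH correction.

    Survivors are features whose tally reaches the ``percentile_cut``
    percentile (linear interpolation) of all tallies, ties included; an
    all-zero tally vector yields an empty report rather than an error.
    """
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    y = _check_labels(labels)
    V = table.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{v}" for v in range(V)]
    feature_ids = [str(f) for f in feature_ids]

    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_repeats)]
    tallies = np.zeros(V, dtype=int)
    for s in seeds:
        tallies += boruta_trial(table, labels, n_runs=n_runs, n_trees=n_trees, seed=s)
    tally_table = BorutaTallyTable(feature_ids, tallies, n_repeats, seeds, n_runs, n_trees)

    columns = [
        "feature_id", "tally", "tally_percentile", "statistic", "p", "p_adj", "direction",
    ]
    if tallies.max() == 0:
        frame = pd.DataFrame(columns=columns)
        return DifferentialReport(cluster_id, frame, tally_table, alpha, percentile_cut)

    cut = np.percentile(tallies, percentile_cut)
    survivors = np.where(tallies >= cut)[0]
    # percentile rank of each tally among all tallies
    order = tallies.argsort(kind="stable")
    ranks = np.empty(V)
    ranks[order] = np.arange(V)
    case_mask = y == 1
    rows = []
    for v in survivors:
        stat, p = wilcoxon_rank_sum(table[v, case_mask], table[v, ~case_mask])
        diff = np.median(table[v, case_mask]) - np.median(table[v, ~case_mask])
        rows.append(
            {
                "feature_id": feature_ids[v],
                "tally": int(tallies[v]),
                "tally_percentile": 100.0 * (tallies < tallies[v]).mean(),
                "statistic": stat,
                "p": p,
                "direction": float(np.sign(diff)),
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
    frame = frame[columns].sort_values("p_adj", kind="stable").reset_index(drop=True)
    return DifferentialReport(cluster_id, frame, tally_table, alpha, percentile_cut)
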