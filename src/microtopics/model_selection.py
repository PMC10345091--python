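"""Choosing the number of topics by posterior-predictive checks.

A candidate model is judged by how well tables simulated from it reproduce
the observed table, summarized by three Pearson correlations:

* sample-quantile: percentiles (1..99) of each sample's feature-count
  vector, concatenated over samples, observed vs simulated;
* feature-quantile: the same with features and samples swapped;
* pairwise-marginal: correlation between the upper triangles of the
  feature-feature correlation matrices of the observed and simulated
  tables ("correlation of feature correlations") — the primary criterion,
  since a model that fits should capture feature co-occurrence.

K is then the smallest candidate whose pairwise-marginal score is within a
relative tolerance of the best achieved, provided its other two scores are
within twice that tolerance of their own maxima — a formalized elbow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable
from .lda import LdaModel, fit_lda_gibbs, simulate_counts

__all__ = ["SelectionError", "FitDiagnostics", "fit_metrics", "select_k", "evaluate_k_grid"]


class SelectionError(ValueError):
    pass


_PERCENTILES = np.arange(1, 100)


@dataclass
class FitDiagnostics:
    omic_name: str
    candidate_ks: list[int]
    sample_quantile_corr: list[float]
    feature_quantile_corr: list[float]
    pairwise_marginal_corr: list[float]
    n_simulations: int
    seed: int
    models: dict[int, LdaModel] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.candidate_ks,
                "sample_quantile_corr": self.sample_quantile_corr,
                "feature_quantile_corr": self.feature_quantile_corr,
                "pairwise_marginal_corr": self.pairwise_marginal_corr,
            }
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _quantile_vector(values: np.ndarray, axis: int) -> np.ndarray:
    """Percentiles 1..99 of each slice along ``axis``, concatenated."""
    return np.percentile(values, _PERCENTILES, axis=axis).T.ravel()


def _feature_correlation_triangle(values: np.ndarray) -> np.ndarray:
    """Upper triangle of the feature-feature Pearson matrix.

    Constant features (zero variance) produce undefined correlations; their
    entries are set to 0 so both tables are compared on the same support.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    iu = np.triu_indices(values.shape[0], k=1)
    return corr[iu]


def fit_metrics(
    true_table: CountTable,
    model: LdaModel,
    n_simulations: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(sample-quantile, feature-quantile, pairwise-marginal) correlations,
    each averaged over ``n_simulations`` simulated tables drawn at the true
    table's per-sample depths."""
    if set(model.sample_ids) != set(true_table.sample_ids) or len(
        model.feature_ids
    ) != true_table.n_features:
        raise SelectionError("model dimensions do not match the table")
    table = true_table.subset_samples(model.sample_ids)
    truth = table.values
    depths = np.maximum(table.sample_totals.astype(int), 1)

    true_sq = _quantile_vector(truth, axis=0)
    true_fq = _quantile_vector(truth, axis=1)
    true_tri = _feature_correlation_triangle(truth)

    sq, fq, pm = [], [], []
    for i in range(n_simulations):
        sim = simulate_counts(model, depths, seed=seed + i).values
        sq.append(_pearson(true_sq, _quantile_vector(sim, axis=0)))
        fq.append(_pearson(true_fq, _quantile_vector(sim, axis=1)))
        pm.append(_pearson(true_tri, _feature_correlation_triangle(sim)))
    return float(np.mean(sq)), float(np.mean(fq)), float(np.mean(pm))


def evaluate_k_grid(
    table: CountTable,
    candidate_ks: list[int],
    n_simulations: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> FitDiagnostics:
    """Fit one model per candidate K and score each with :func:`fit_metrics`."""
    if len(candidate_ks) < 1:
        raise SelectionError("need at least one candidate K")
    ks = sorted(candidate_ks)
    sq_all, fq_all, pm_all, models = [], [], [], {}
    for i, k in enumerate(ks):
        model = fit_lda_gibbs(table, K=k, seed=seed + 1000 * i, **fit_kwargs)
        sq, fq, pm = fit_metrics(table, model, n_simulations, seed=seed + 1000 * i + 500)
        sq_all.append(sq)
        fq_all.append(fq)
        pm_all.append(pm)
        models[k] = model
    return FitDiagnostics(
        table.omic_name, ks, sq_all, fq_all, pm_all, n_simulations, seed, models
    )


def select_k(diagnostics: FitDiagnostics, rel_tolerance: float = 0.02) -> dict:
    """Smallest K whose pairwise-marginal score is within ``rel_tolerance``
    (relative) of that metric's maximum, with the two quantile scores within
    2x the tolerance of their own maxima.

    Falls back to the pairwise-marginal argmax if no candidate satisfies all
    three clauses (possible when the metrics peak at different K).
    """
    ks = diagnostics.candidate_ks
    if len(ks) < 2:
        raise SelectionError("need >= 2 candidate Ks to select an elbow")
    pm = np.asarray(diagnostics.pairwise_marginal_corr)
    sq = np.asarray(diagnostics.sample_quantile_corr)
    fq = np.asarray(diagnostics.feature_quantile_corr)

    def within(values: np.ndarray, tol: float) -> np.ndarray:
        best = values.max()
        return values >= best - tol * abs(best)

    ok = within(pm, rel_tolerance) & within(sq, 2 * rel_tolerance) & within(fq, 2 * rel_tolerance)
    if np.any(ok):
        idx = int(np.argmax(ok))  # first (smallest K) satisfying all clauses
    else:
        idx = int(np.argmax(pm))
    gaps = {
        "pairwise_marginal": (pm.max() - pm).tolist(),
        "sample_quantile": (sq.max() - sq).tolist(),
        "feature_quantile": (fq.max() - fq).tolist(),
    }
    return {
        "selected_k": ks[idx],
        "rel_tolerance": rel_tolerance,
        "candidates": ks,
        "gaps": gaps,
        "satisfied_all_clauses": bool(np.any(ok)),
    }
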