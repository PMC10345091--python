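"""Collapsed Gibbs sampling for Latent Dirichlet Allocation on count tables.

Samples are documents, omic features are words. The generative model:

    theta_d ~ Dir(alpha)   per-sample topic probabilities (D x K)
    beta_k  ~ Dir(gamma)   per-topic feature probabilities (K x V)
    z_dn    ~ Mult(theta_d),  w_dn ~ Mult(beta_{z_dn})

The sampler integrates theta and beta out and resamples each token's topic
from the standard collapsed conditional

    p(z = k) propto (n_dk + alpha) * (n_kv + gamma) / (n_k + V * gamma)

theta and beta are posterior-mean estimates averaged over post-burn-in
sweeps. The per-sweep kernel consumes a pre-generated uniform stream, so the
numba-compiled path and the pure-Python fallback produce identical output
for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CountTable

__all__ = ["LdaError", "LdaModel", "fit_lda_gibbs", "simulate_counts", "load_model"]

logger = logging.getLogger(__name__)


class LdaError(ValueError):
    pass


def _sweep_py(doc_ids, word_ids, z, ndk, nkv, nk, alpha, gamma, uniforms):
    K = ndk.shape[1]
    V = nkv.shape[1]
    cum = np.empty(K)
    for t in range(doc_ids.shape[0]):
        d = doc_ids[t]
        w = word_ids[t]
        k_old = z[t]
        ndk[d, k_old] -= 1
        nkv[k_old, w] -= 1
        nk[k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (ndk[d, k] + alpha) * (nkv[k, w] + gamma) / (nk[k] + V * gamma)
            cum[k] = total
        u = uniforms[t] * total
        k_new = 0
        while cum[k_new] < u and k_new < K - 1:
            k_new += 1
        z[t] = k_new
        ndk[d, k_new] += 1
        nkv[k_new, w] += 1
        nk[k_new] += 1


try:  # compiled sweep; the Python fallback is arithmetic-identical
    from numba import njit

    _sweep = njit(cache=True)(_sweep_py)
except ImportError:  # pragma: no cover
    _sweep = _sweep_py


@dataclass
class LdaModel:
    """A fitted topic model for one omic layer."""

    omic_name: str
    K: int
    alpha: float
    gamma: float
    theta: np.ndarray  # D x K, rows sum to 1
    beta: np.ndarray   # K x V, rows sum to 1
    feature_ids: list[str]
    sample_ids: list[str]
    seed: int | None = None
    n_iterations: int = 0
    burn_in: int = 0
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta.shape != (len(self.sample_ids), self.K):
            raise LdaError("theta shape does not match sample_ids x K")
        if self.beta.shape != (self.K, len(self.feature_ids)):
            raise LdaError("beta shape does not match K x feature_ids")
        for name, m in (("theta", self.theta), ("beta", self.beta)):
            if np.any(m < 0):
                raise LdaError(f"{name} has negative entries")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                raise LdaError(f"{name} rows do not sum to 1")

    def theta_frame(self) -> pd.DataFrame:
        cols = [f"topic{k}" for k in range(self.K)]
        return pd.DataFrame(self.theta, index=self.sample_ids, columns=cols)

    def beta_frame(self) -> pd.DataFrame:
        idx = [f"topic{k}" for k in range(self.K)]
        return pd.DataFrame(self.beta, index=idx, columns=self.feature_ids)

    def save(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        theta_path = prefix.with_suffix(".theta.tsv")
        beta_path = prefix.with_suffix(".beta.tsv")
        meta_path = prefix.with_suffix(".model.json")
        self.theta_frame().to_csv(theta_path, sep="\t", index_label="sample_id")
        self.beta_frame().to_csv(beta_path, sep="\t", index_label="topic")
        meta = {
            "omic_name": self.omic_name,
            "K": self.K,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "dropped_samples": self.dropped_samples,
        }
        meta_path.write_text(json.dumps(meta, indent=2))
        return [theta_path, beta_path, meta_path]


def load_model(prefix: str | Path) -> LdaModel:
    prefix = Path(prefix)
    theta = pd.read_csv(prefix.with_suffix(".theta.tsv"), sep="\t", index_col=0)
    beta = pd.read_csv(prefix.with_suffix(".beta.tsv"), sep="\t", index_col=0)
    meta = json.loads(prefix.with_suffix(".model.json").read_text())
    return LdaModel(
        omic_name=meta["omic_name"],
        K=meta["K"],
        alpha=meta["alpha"],
        gamma=meta["gamma"],
        theta=theta.to_numpy(),
        beta=beta.to_numpy(),
        feature_ids=[str(c) for c in beta.columns],
        sample_ids=[str(i) for i in theta.index],
        seed=meta.get("seed"),
        n_iterations=meta.get("n_iterations", 0),
        burn_in=meta.get("burn_in", 0),
        dropped_samples=meta.get("dropped_samples", []),
    )


def _expand_tokens(counts: np.ndarray, max_tokens_per_doc: int, rng: np.random.Generator):
    """Expand a V x D integer table into (doc_ids, word_ids) token arrays.

    Documents exceeding ``max_tokens_per_doc`` are downsampled without
    replacement to bound memory; the log-discretized inputs used in practice
    stay far below the cap.
    """
    V, D = counts.shape
    doc_ids: list[np.ndarray] = []
    word_ids: list[np.ndarray] = []
    for d in range(D):
        col = counts[:, d]
        n = int(col.sum())
        words = np.repeat(np.arange(V, dtype=np.int64), col)
        if n > max_tokens_per_doc:
            words = rng.choice(words, size=max_tokens_per_doc, replace=False)
            n = max_tokens_per_doc
        doc_ids.append(np.full(n, d, dtype=np.int64))
        word_ids.append(words)
    return np.concatenate(doc_ids), np.concatenate(word_ids)


def fit_lda_gibbs(
    table: CountTable,
    K: int,
    alpha: float | None = None,
    gamma: float = 0.1,
    n_iterations: int = 2000,
    burn_in: int = 500,
    thin: int = 10,
    seed: int = 0,
    max_tokens_per_doc: int = 100_000,
    drop_empty_samples: bool = False,
) -> LdaModel:
    """Fit LDA by collapsed Gibbs sampling on a discretized count table.

    ``alpha`` defaults to 50/K. Samples that are all-zero after
    discretization have no tokens; they raise an error unless
    ``drop_empty_samples`` is set (pipeline mode), in which case they are
    dropped with a warning and recorded on the model.
    """
    if K < 1:
        raise LdaError("K must be >= 1")
    if K > table.n_features:
        raise LdaError(f"K={K} exceeds the number of features V={table.n_features}")
    if n_iterations <= burn_in:
        raise LdaError("n_iterations must exceed burn_in")
    counts = table.values
    if not np.allclose(counts, np.round(counts)):
        raise LdaError("fit_lda_gibbs requires integer (discretized) counts")
    counts = np.round(counts).astype(np.int64)

    empty = np.where(counts.sum(axis=0) == 0)[0]
    dropped: list[str] = []
    if empty.size:
        names = [table.sample_ids[i] for i in empty]
        if not drop_empty_samples:
            raise LdaError(f"samples with zero tokens after discretization: {names}")
        logger.warning("dropping %d all-zero samples: %s", len(names), names)
        dropped = names
        keep = [s for s in table.sample_ids if s not in set(names)]
        table = table.subset_samples(keep)
        counts = np.round(table.values).astype(np.int64)

    alpha = 50.0 / K if alpha is None else float(alpha)
    rng = np.random.default_rng(seed)
    doc_ids, word_ids = _expand_tokens(counts, max_tokens_per_doc, rng)
    n_tokens = doc_ids.shape[0]
    D, V = table.n_samples, table.n_features

    z = rng.integers(0, K, size=n_tokens).astype(np.int64)
    ndk = np.zeros((D, K), dtype=np.int64)
    nkv = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_ids, z), 1)
    np.add.at(nkv, (z, word_ids), 1)
    np.add.at(nk, z, 1)

    n_d = ndk.sum(axis=1).astype(float)
    theta_acc = np.zeros((D, K))
    beta_acc = np.zeros((K, V))
    n_kept = 0
    for sweep in range(n_iterations):
        uniforms = rng.random(n_tokens)
        _sweep(doc_ids, word_ids, z, ndk, nkv, nk, alpha, gamma, uniforms)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            theta_acc += (ndk + alpha) / (n_d[:, None] + K * alpha)
            beta_acc += (nkv + gamma) / (nk[:, None] + V * gamma)
            n_kept += 1
    theta = theta_acc / n_kept
    beta = beta_acc / n_kept
    # renormalize away accumulated floating-point drift
    theta /= theta.sum(axis=1, keepdims=True)
    beta /= beta.sum(axis=1, keepdims=True)

    return LdaModel(
        omic_name=table.omic_name,
        K=K,
        alpha=alpha,
        gamma=gamma,
        theta=theta,
        beta=beta,
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        seed=seed,
        n_iterations=n_iterations,
        burn_in=burn_in,
        dropped_samples=dropped,
    )


def simulate_counts(model: LdaModel, depths: np.ndarray, seed: int = 0) -> CountTable:
    """Draw a count table from a fitted model's generative process.

    For sample d, topic counts are Multinomial(N_d, theta_d) and each topic's
    tokens are Multinomial draws from its beta row, so column sums equal
    ``depths`` exactly.
    """
    depths = np.asarray(depths)
    D = len(model.sample_ids)
    if depths.shape != (D,):
        raise LdaError(f"need one depth per sample ({D}), got shape {depths.shape}")
    if np.any(depths <= 0):
        raise LdaError("depths must be positive")
    rng = np.random.default_rng(seed)
    V = len(model.feature_ids)
    values = np.zeros((V, D), dtype=np.int64)
    for d in range(D):
        topic_counts = rng.multinomial(int(depths[d]), model.theta[d])
        for k in range(model.K):
            if topic_counts[k]:
                values[:, d] += rng.multinomial(topic_counts[k], model.beta[k])
    return CountTable(model.omic_name, list(model.feature_ids), list(model.sample_ids), values)
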