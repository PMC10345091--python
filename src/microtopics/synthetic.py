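"""Synthetic multi-omic cohort generator.

Emulates the statistical structure the analysis assumes, without emulating
biology: a sibling-pair cohort (one case and one control child per family),
a per-sample topic distribution shared by every omic layer (the premise that
makes cross-omic topics discoverable), per-omic topic-feature distributions,
metadata covariates that load linearly on topics, and phenotype-differential
features planted by binomial thinning / Poisson inflation.

Each sibling's topic vector is a convex mixture of a family-level Dirichlet
draw and an individual draw, with the mixing weight ``sibling_correlation``:
1 makes siblings identical, 0 makes them exchangeable with strangers.
Setting ``shared_theta=False`` draws independent topic vectors per omic and
is the negative control for cross-omic clustering: it destroys exactly the
structure the cross-omic stage is meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CountTable, OmicSet, SampleMetadata

__all__ = [
    "ConfigError",
    "OmicSpec",
    "DifferentialSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohort",
    "plant_differentials",
]


class ConfigError(ValueError):
    pass


@dataclass
class OmicSpec:
    """Feature count and per-sample sequencing depth for one omic layer."""

    n_features: int
    depth: int

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")


@dataclass
class DifferentialSpec:
    """One planted phenotype effect: multiply a feature's expected counts in
    case samples by 2**log2_fc, optionally only within one topic-defined
    sample cluster."""

    omic: str
    feature: int | str = "random"
    log2_fc: float = 1.0
    cluster: int | str = "all"


@dataclass
class GeneratorConfig:
    """Study conditions for :func:`generate_cohort`.

    Defaults are the test-scale cohort: 40 sibling-pair families, four omic
    layers of 120-300 features at depth 2000, four true topics, Dirichlet
    concentrations alpha=0.5 (samples concentrate on a few topics) and
    gamma=0.1 (topics concentrate on a feature subset), and sibling
    topic-mixing weight 0.5.
    """

    n_families: int = 40
    omic_specs: dict[str, OmicSpec] = field(
        default_factory=lambda: {
            "16s": OmicSpec(200, 2000),
            "mtg": OmicSpec(300, 2000),
            "mtt": OmicSpec(300, 2000),
            "mbx": OmicSpec(120, 2000),
        }
    )
    k_true: int = 4
    alpha_true: float = 0.5
    gamma_true: float = 0.1
    sibling_correlation: float = 0.5
    shared_theta: bool = True
    n_covariates: int = 3
    covariate_topic_loadings: np.ndarray | None = None
    covariate_noise_sd: float = 0.1
    differential_spec: list[DifferentialSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.alpha_true <= 0 or self.gamma_true <= 0:
            raise ConfigError("Dirichlet concentrations must be positive")
        if not 0.0 <= self.sibling_correlation <= 1.0:
            raise ConfigError("sibling_correlation must lie in [0, 1]")
        if not self.omic_specs:
            raise ConfigError("at least one omic spec required")
        for name, spec in self.omic_specs.items():
            if self.k_true > spec.n_features:
                raise ConfigError(
                    f"k_true={self.k_true} exceeds n_features={spec.n_features} for omic {name!r}"
                )
        for d in self.differential_spec:
            if d.omic not in self.omic_specs:
                raise ConfigError(f"differential spec targets unknown omic {d.omic!r}")
            if isinstance(d.feature, int) and not (
                0 <= d.feature < self.omic_specs[d.omic].n_features
            ):
                raise ConfigError(
                    f"differential feature index {d.feature} out of range for omic {d.omic!r}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests.

    ``theta_true`` maps omic name to its D x K topic matrix (all entries are
    the same object when theta is shared); ``beta_true`` maps omic name to
    its K x V topic-feature matrix.
    """

    sample_ids: list[str]
    k_true: int
    shared_theta: bool
    theta_true: dict[str, np.ndarray]
    beta_true: dict[str, np.ndarray]
    family_ids: list[str]
    phenotypes: list[str]
    planted_features: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, th in self.theta_true.items():
            if not np.allclose(th.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"theta rows for {name!r} do not sum to 1")
        for name, b in self.beta_true.items():
            if not np.allclose(b.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"beta rows for {name!r} do not sum to 1")

    def dominant_topic(self, omic: str | None = None) -> np.ndarray:
        name = omic if omic is not None else next(iter(self.theta_true))
        return np.argmax(self.theta_true[name], axis=1)

    def save(self, path: str | Path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "k_true": self.k_true,
            "shared_theta": self.shared_theta,
            "theta_true": {k: v.tolist() for k, v in self.theta_true.items()},
            "beta_true": {k: v.tolist() for k, v in self.beta_true.items()},
            "family_ids": self.family_ids,
            "phenotypes": self.phenotypes,
            "planted_features": self.planted_features,
        }
        Path(path).write_text(json.dumps(payload))


def _draw_theta(
    rng: np.random.Generator, n_families: int, k: int, alpha: float, sibling_corr: float
) -> np.ndarray:
    """One topic vector per sibling: mix(family draw, individual draw)."""
    rows = []
    for _ in range(n_families):
        fam = rng.dirichlet(np.full(k, alpha))
        for _ in range(2):
            ind = rng.dirichlet(np.full(k, alpha))
            rows.append(sibling_corr * fam + (1.0 - sibling_corr) * ind)
    return np.asarray(rows)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[OmicSet, SampleMetadata, SyntheticTruth]:
    """Generate aligned omic count tables, metadata and ground truth.

    All randomness derives from ``config.seed``; repeated calls are
    bit-identical. Per-sample totals equal each omic's configured depth
    exactly (multinomial draws) before any differential planting.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_true
    n_samples = 2 * config.n_families

    sample_ids, individual_ids, family_ids, phenotypes = [], [], [], []
    for f in range(config.n_families):
        fam = f"F{f:03d}"
        for sib, pheno in ((1, "case"), (2, "control")):
            sample_ids.append(f"{fam}S{sib}")
            individual_ids.append(f"{fam}I{sib}")
            family_ids.append(fam)
            phenotypes.append(pheno)

    theta_shared = _draw_theta(
        rng, config.n_families, k, config.alpha_true, config.sibling_correlation
    )

    theta_true: dict[str, np.ndarray] = {}
    beta_true: dict[str, np.ndarray] = {}
    tables: list[CountTable] = []
    for name, spec in config.omic_specs.items():
        if config.shared_theta:
            theta = theta_shared
        else:
            theta = _draw_theta(
                rng, config.n_families, k, config.alpha_true, config.sibling_correlation
            )
        beta = rng.dirichlet(np.full(spec.n_features, config.gamma_true), size=k)
        values = np.zeros((spec.n_features, n_samples), dtype=np.int64)
        for d in range(n_samples):
            topic_counts = rng.multinomial(spec.depth, theta[d])
            for t in range(k):
                if topic_counts[t]:
                    values[:, d] += rng.multinomial(topic_counts[t], beta[t])
        theta_true[name] = theta
        beta_true[name] = beta
        feature_ids = [f"{name}_f{v:04d}" for v in range(spec.n_features)]
        tables.append(CountTable(name, feature_ids, list(sample_ids), values))

    frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "individual_id": individual_ids,
            "family_id": family_ids,
            "phenotype": phenotypes,
            "age": np.round(rng.uniform(2.0, 18.0, size=n_samples), 1),
        }
    )
    covariate_names = [f"diet_{i + 1}" for i in range(config.n_covariates)]
    if config.n_covariates:
        loadings = config.covariate_topic_loadings
        if loadings is None:
            loadings = rng.normal(0.0, 1.0, size=(config.n_covariates, k))
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (config.n_covariates, k):
            raise ConfigError(
                f"covariate_topic_loadings must be {config.n_covariates} x {k}"
            )
        cov = theta_shared @ loadings.T + rng.normal(
            0.0, config.covariate_noise_sd, size=(n_samples, config.n_covariates)
        )
        for j, cname in enumerate(covariate_names):
            frame[cname] = cov[:, j]
    metadata = SampleMetadata(frame, covariate_names)

    truth = SyntheticTruth(
        sample_ids=list(sample_ids),
        k_true=k,
        shared_theta=config.shared_theta,
        theta_true=theta_true,
        beta_true=beta_true,
        family_ids=list(family_ids),
        phenotypes=list(phenotypes),
    )
    omics = OmicSet({t.omic_name: t for t in tables}, sorted(sample_ids))
    omics = OmicSet(
        {name: t.subset_samples(omics.shared_samples) for name, t in omics.tables.items()},
        omics.shared_samples,
    )
    if config.differential_spec:
        omics = plant_differentials(
            omics, truth, config.differential_spec, metadata, seed=config.seed + 1
        )
    return omics, metadata, truth


def plant_differentials(
    omics: OmicSet,
    truth: SyntheticTruth,
    spec: Sequence[DifferentialSpec],
    metadata: SampleMetadata,
    seed: int = 0,
) -> OmicSet:
    """Multiply planted features' expected case-sample counts by 2**log2_fc.

    Negative fold changes thin counts binomially (each original count kept
    with probability 2**log2_fc); positive ones add Poisson(count *
    (2**log2_fc - 1)) extra counts, so the expectation is scaled exactly and
    log2_fc = 0 leaves the table untouched. Non-planted features and control
    samples are never modified.
    """
    rng = np.random.default_rng(seed)
    new_tables = {name: t.values.copy() for name, t in omics.tables.items()}
    seen: set[tuple[str, int]] = set()
    pheno = metadata.phenotype_for(omics.shared_samples)
    case_mask = pheno == "case"

    for entry in spec:
        if entry.omic not in omics.tables:
            raise ConfigError(f"cannot plant on omic {entry.omic!r}: not in the omic set")
        table = omics.tables[entry.omic]
        if entry.feature == "random":
            feat = int(rng.integers(0, table.n_features))
        else:
            feat = int(entry.feature)
            if not 0 <= feat < table.n_features:
                raise ConfigError(
                    f"feature index {feat} out of range for omic {entry.omic!r}"
                )
        key = (entry.omic, feat)
        if key in seen:
            raise ConfigError(f"feature {feat} of omic {entry.omic!r} planted twice")
        seen.add(key)

        affected = case_mask.copy()
        if entry.cluster != "all":
            dom = truth.dominant_topic(entry.omic)
            affected &= dom == int(entry.cluster)

        fc = 2.0 ** entry.log2_fc
        if entry.log2_fc != 0.0:
            counts = new_tables[entry.omic][feat, :]
            for d in np.where(affected)[0]:
                c = int(counts[d])
                if entry.log2_fc < 0:
                    counts[d] = rng.binomial(c, fc)
                else:
                    counts[d] = c + rng.poisson(c * (fc - 1.0))
        truth.planted_features.append(
            {
                "omic": entry.omic,
                "feature_index": feat,
                "feature_id": table.feature_ids[feat],
                "log2_fc": entry.log2_fc,
                "cluster": entry.cluster,
            }
        )

    rebuilt = {
        name: CountTable(name, list(t.feature_ids), list(t.sample_ids), new_tables[name])
        for name, t in omics.tables.items()
    }
    return OmicSet(rebuilt, list(omics.shared_samples))
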