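"""End-to-end orchestration: simulate/ingest -> normalize -> fit LDA per
omic -> select K -> cross-omic clustering -> interpretation -> sample
clustering -> per-cluster differential testing -> optional split-half
Mantel replication.

One global seed deterministically derives per-stage seeds (fixed offsets),
so a config re-run is byte-identical. Every emitted file lands in the
manifest with its checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .datamodel import (
    OmicSet,
    SampleMetadata,
    align_omics,
    read_count_table,
    read_metadata,
    write_count_table,
    write_metadata,
)
from .synthetic import DifferentialSpec, GeneratorConfig, OmicSpec, generate_cohort
from .normalization import (
    NORMALIZATION_CANDIDATES,
    normalize_log_discretize,
    select_normalization,
)
from .lda import fit_lda_gibbs
from .model_selection import evaluate_k_grid, select_k
from .crossomic import (
    cluster_samples,
    cluster_topics,
    flag_dominant_topic,
    null_validation,
    pool_topics,
)
from .interpretation import select_topic_features, topic_metadata_correlation
from .differential import tally_and_test
from .generalization import beta_cosine_distance, mantel_test

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated parameters for every stage; YAML-loadable.

    ``count_tables`` maps omic name to a TSV path; when empty, a synthetic
    cohort is generated from ``generator``.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    count_tables: dict[str, str] = field(default_factory=dict)
    metadata_path: str | None = None
    generator: dict[str, Any] = field(default_factory=dict)
    normalization: dict[str, Any] = field(
        default_factory=lambda: {"method": "rle", "select": False}
    )
    lda: dict[str, Any] = field(
        default_factory=lambda: {
            "alpha": None,
            "gamma": 0.1,
            "n_iterations": 2000,
            "burn_in": 500,
            "thin": 10,
        }
    )
    selection: dict[str, Any] = field(
        default_factory=lambda: {"k_grid": [2, 3, 4, 5, 6], "n_simulations": 5,
                                 "rel_tolerance": 0.02, "fixed_k": None}
    )
    crossomic: dict[str, Any] = field(
        default_factory=lambda: {
            "n_clusters": None,
            "null_tables": 15,
            "run_null": True,
            "drop_dominant": True,
            "dominant_threshold": 10.0,
        }
    )
    interpretation: dict[str, Any] = field(
        default_factory=lambda: {"percentile": 99.0, "sd_multiplier": 1.5}
    )
    sample_clustering: dict[str, Any] = field(default_factory=lambda: {"n_clusters": 2})
    differential: dict[str, Any] = field(
        default_factory=lambda: {
            "n_repeats": 100,
            "n_runs": 100,
            "n_trees": 500,
            "percentile_cut": 90.0,
            "alpha": 0.05,
        }
    )
    mantel: dict[str, Any] = field(
        default_factory=lambda: {"run": False, "n_permutations": 999}
    )

    def validate(self) -> list[str]:
        problems = []
        if self.seed < 0:
            problems.append("seed must be nonnegative")
        if not self.count_tables and not self.generator:
            problems.append("either count_tables or a generator block is required")
        if self.count_tables and self.metadata_path is None:
            problems.append("metadata_path required with count_tables")
        sel = self.selection
        if sel.get("fixed_k") is None and len(sel.get("k_grid", [])) < 2:
            problems.append("selection.k_grid needs >= 2 candidates (or set fixed_k)")
        if self.normalization.get("method") not in NORMALIZATION_CANDIDATES:
            problems.append(
                f"unknown normalization method {self.normalization.get('method')!r}"
            )
        if self.differential.get("alpha", 0.05) <= 0:
            problems.append("differential.alpha must be positive")
        return problems


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def _generator_from_dict(block: dict[str, Any], seed: int) -> GeneratorConfig:
    block = dict(block)
    omic_specs = {
        name: OmicSpec(**spec) if isinstance(spec, dict) else spec
        for name, spec in block.pop("omic_specs", {}).items()
    }
    diffs = [
        DifferentialSpec(**d) if isinstance(d, dict) else d
        for d in block.pop("differential_spec", [])
    ]
    kwargs = {"seed": seed, **block}
    if omic_specs:
        kwargs["omic_specs"] = omic_specs
    if diffs:
        kwargs["differential_spec"] = diffs
    return GeneratorConfig(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_timings: dict[str, float] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seeds: dict[str, int] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path)] = digest

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    problems = config.validate()
    if problems:
        raise ValueError("config validation failed: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(cfg_hash, __version__, config.seed)
    t_all = time.time()

    def timed(stage):
        manifest.stage_seeds[stage] = _stage_seed(config.seed, stage)
        return time.time()

    # --- ingest or simulate -------------------------------------------------
    t0 = timed("ingest")
    truth = None
    if config.count_tables:
        tables = [read_count_table(p, name) for name, p in config.count_tables.items()]
        metadata = read_metadata(config.metadata_path)
        omics = align_omics(tables)
    else:
        gen = _generator_from_dict(config.generator, _stage_seed(config.seed, "ingest"))
        omics, metadata, truth = generate_cohort(gen)
        for name, table in omics.tables.items():
            p = outdir / f"counts_{name}.tsv"
            write_count_table(table, p)
            manifest.register(p)
        p = outdir / "metadata.tsv"
        write_metadata(metadata, p)
        manifest.register(p)
        p = outdir / "truth.json"
        truth.save(p)
        manifest.register(p)
    metadata = metadata.subset(omics.shared_samples)
    manifest.stage_timings["ingest"] = time.time() - t0
    logger.info("ingest: %d omics, %d shared samples", len(omics.tables), len(omics.shared_samples))

    # --- normalization ------------------------------------------------------
    t0 = timed("normalize")
    method = config.normalization.get("method", "rle")
    normalized = {}
    for name, table in omics.tables.items():
        if config.normalization.get("select", False):
            report = select_normalization(table, metadata)
            method_used = report["winner"]
            grid_path = outdir / f"normalization_grid_{name}.tsv"
            report["grid"].to_csv(grid_path, sep="\t")
            manifest.register(grid_path)
        else:
            method_used = method
        factors = NORMALIZATION_CANDIDATES[method_used](table)
        norm = normalize_log_discretize(table, factors)
        normalized[name] = norm
        p = outdir / f"discretized_{name}.tsv"
        write_count_table(norm.discretized_table(), p)
        manifest.register(p)
    manifest.stage_timings["normalize"] = time.time() - t0

    # --- LDA fits with K selection ------------------------------------------
    t0 = timed("fit")
    lda_kwargs = {k: v for k, v in config.lda.items() if v is not None or k == "alpha"}
    models = {}
    selected = {}
    for i, (name, norm) in enumerate(sorted(normalized.items())):
        table = norm.discretized_table()
        fit_seed = _stage_seed(config.seed, f"fit:{name}")
        fixed_k = config.selection.get("fixed_k")
        if fixed_k is not None:
            model = fit_lda_gibbs(
                table, K=int(fixed_k), seed=fit_seed, drop_empty_samples=True, **lda_kwargs
            )
            selected[name] = int(fixed_k)
        else:
            diag = evaluate_k_grid(
                table,
                list(config.selection["k_grid"]),
                n_simulations=config.selection.get("n_simulations", 5),
                seed=fit_seed,
                drop_empty_samples=True,
                **lda_kwargs,
            )
            choice = select_k(diag, config.selection.get("rel_tolerance", 0.02))
            selected[name] = choice["selected_k"]
            model = diag.models[choice["selected_k"]]
            p = outdir / f"selection_{name}.tsv"
            diag.to_frame().to_csv(p, sep="\t", index=False)
            manifest.register(p)
        models[name] = model
        for p in model.save(outdir / f"model_{name}"):
            manifest.register(p)
    manifest.summary["selected_k"] = selected
    manifest.stage_timings["fit"] = time.time() - t0

    # --- cross-omic topics --------------------------------------------------
    t0 = timed("crossomic")
    shared = sorted(
        set(omics.shared_samples) - {s for m in models.values() for s in m.dropped_samples}
    )
    exclude: set[tuple[str, int]] = set()
    if config.crossomic.get("drop_dominant", True):
        for name, model in models.items():
            if model.K < 2:
                continue
            report = select_topic_features(
                model.beta,
                model.feature_ids,
                percentile=config.interpretation.get("percentile", 99.0),
                sd_multiplier=config.interpretation.get("sd_multiplier", 1.5),
                omic_name=name,
            )
            for k in flag_dominant_topic(
                model,
                config.crossomic.get("dominant_threshold", 10.0),
                report.counts_per_topic(model.K),
            ):
                exclude.add((name, k))
    topics = pool_topics(models, shared, exclude=exclude)
    assignment = cluster_topics(topics, n_clusters=config.crossomic.get("n_clusters"))
    p = outdir / "topic_clusters.tsv"
    assignment.labels_frame().to_csv(p, sep="\t", index=False)
    manifest.register(p)
    p = outdir / "topic_correlation.tsv"
    assignment.correlation.to_csv(p, sep="\t")
    manifest.register(p)
    manifest.summary["n_topic_clusters"] = assignment.n_clusters
    manifest.summary["excluded_dominant_topics"] = sorted(exclude)

    if config.crossomic.get("run_null", True):
        def discretize(table):
            factors = NORMALIZATION_CANDIDATES[method](table)
            return normalize_log_discretize(table, factors).discretized_table()

        null_report = null_validation(
            omics,
            models,
            n_clusters=assignment.n_clusters,
            discretize=discretize,
            n_tables=config.crossomic.get("null_tables", 15),
            seed=_stage_seed(config.seed, "null"),
        )
        p = outdir / "null_ensemble.json"
        p.write_text(
            json.dumps(
                {
                    "true_count": null_report.true_count,
                    "null_counts": null_report.null_counts,
                    "exceeds_all_null": null_report.exceeds_all_null,
                },
                indent=2,
            )
        )
        manifest.register(p)
        manifest.summary["null_true_count"] = null_report.true_count
        manifest.summary["null_max_count"] = max(null_report.null_counts)
    manifest.stage_timings["crossomic"] = time.time() - t0

    # --- interpretation -----------------------------------------------------
    t0 = timed("interpret")
    for name, model in models.items():
        if model.K < 2:
            continue
        report = select_topic_features(
            model.beta,
            model.feature_ids,
            percentile=config.interpretation.get("percentile", 99.0),
            sd_multiplier=config.interpretation.get("sd_multiplier", 1.5),
            omic_name=name,
        )
        p = outdir / f"topic_features_{name}.tsv"
        report.attributed().to_csv(p, sep="\t", index=False)
        manifest.register(p)
    if metadata.covariate_names:
        corr = topic_metadata_correlation(topics, metadata, shared)
        p = outdir / "topic_covariates.tsv"
        corr.to_csv(p, sep="\t", index=False)
        manifest.register(p)
    manifest.stage_timings["interpret"] = time.time() - t0

    # --- sample clustering --------------------------------------------------
    t0 = timed("cluster_samples")
    clustering = cluster_samples(
        topics, shared, n_clusters=config.sample_clustering.get("n_clusters", 2),
        metadata=metadata,
    )
    p = outdir / "sample_clusters.tsv"
    clustering.to_frame().to_csv(p, sep="\t", index=False)
    manifest.register(p)
    manifest.summary["sibling_coclustering_rate"] = clustering.sibling_coclustering_rate
    manifest.stage_timings["cluster_samples"] = time.time() - t0

    # --- differential testing per sample cluster per omic -------------------
    t0 = timed("differential")
    diff_cfg = config.differential
    pheno = metadata.phenotype_for(shared)
    reported_features: dict[str, list[str]] = {}
    for cluster in np.unique(clustering.cluster_labels):
        mask = clustering.cluster_labels == cluster
        labels = pheno[mask]
        if min((labels == "case").sum(), (labels == "control").sum()) < 3:
            logger.warning("cluster %s lacks 3 samples per group; skipped", cluster)
            continue
        for name, norm in normalized.items():
            pos = {s: i for i, s in enumerate(norm.source.sample_ids)}
            cols = [pos[s] for s, m in zip(shared, mask) if m]
            values = norm.log_values[:, cols]
            report = tally_and_test(
                values,
                labels,
                feature_ids=norm.source.feature_ids,
                cluster_id=f"cluster{cluster}",
                n_repeats=diff_cfg.get("n_repeats", 100),
                n_runs=diff_cfg.get("n_runs", 100),
                n_trees=diff_cfg.get("n_trees", 500),
                percentile_cut=diff_cfg.get("percentile_cut", 90.0),
                alpha=diff_cfg.get("alpha", 0.05),
                seed=_stage_seed(config.seed, f"diff:{cluster}:{name}"),
            )
            p = outdir / f"differential_cluster{cluster}_{name}.tsv"
            report.frame.to_csv(p, sep="\t", index=False)
            manifest.register(p)
            key = f"cluster{cluster}:{name}"
            reported_features[key] = report.reported()["feature_id"].tolist()
    manifest.summary["differential_reported"] = reported_features
    manifest.stage_timings["differential"] = time.time() - t0

    # --- optional split-half Mantel replication -----------------------------
    if config.mantel.get("run", False):
        t0 = timed("mantel")
        results = {}
        half = len(shared) // 2
        for name, norm in normalized.items():
            model = models[name]
            table = norm.discretized_table().subset_samples(shared)
            a = table.subset_samples(shared[:half])
            b = table.subset_samples(shared[half:])
            seed_m = _stage_seed(config.seed, f"mantel:{name}")
            kw = dict(K=model.K, alpha=model.alpha, gamma=model.gamma,
                      n_iterations=model.n_iterations, burn_in=model.burn_in,
                      drop_empty_samples=True)
            ma = fit_lda_gibbs(a, seed=seed_m, **kw)
            mb = fit_lda_gibbs(b, seed=seed_m + 1, **kw)
            res = mantel_test(
                beta_cosine_distance(ma),
                beta_cosine_distance(mb),
                n_permutations=config.mantel.get("n_permutations", 999),
                seed=seed_m + 2,
            )
            results[name] = res.to_dict()
        p = outdir / "mantel.json"
        p.write_text(json.dumps(results, indent=2))
        manifest.register(p)
        manifest.summary["mantel"] = {k: v["p"] for k, v in results.items()}
        manifest.stage_timings["mantel"] = time.time() - t0

    manifest.stage_timings["total"] = time.time() - t_all
    manifest.save(outdir / "manifest.json")
    return manifest
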