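"""End-to-end orchestration: generate → screen → cluster → tune → evaluate → interpret.

``run`` executes the whole origin-traceability workflow on one synthetic
table and persists every intermediate artifact (labelled table, per-component
screening table, dendrogram, per-model tuning traces and test metrics,
importance ranking) plus a JSON report whose manifest echoes every seed and
every default the published description leaves unstated (SVM C, swarm budget,
linkage, permutation repeats), so the report is regenerable bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import cluster as _cluster
from . import importance as _importance
from .group_stats import anova_table
from .metrics import confusion, metrics, stratified_split
from .pso import SEARCH_SPACES, PSOConfig, build_model, cv_fitness, optimize
from .registry import load_component_registry
from .synthesis import ChemTable, default_generator_config, generate_dataset

__all__ = ["PipelineConfig", "run", "read_chem_table", "write_chem_table"]

log = logging.getLogger("chemorigin")

ALL_PRESETS = tuple(SEARCH_SPACES)


def read_chem_table(path) -> ChemTable:
    return ChemTable.read_csv(path)


def write_chem_table(table: ChemTable, path) -> None:
    table.write_csv(path)


@dataclass
class PipelineConfig:
    """Flat configuration for one full pipeline run (YAML round-trippable)."""

    level: str = "region"                   # generator: 13 origins or 5 countries
    separation_scale: float = 1.0
    n_noise_features: int = 0
    samples_per_region: int | None = None   # cap per-origin n (None = published counts)
    generator_seed: int = 0
    models: tuple[str, ...] = ("svm-hybrid",)
    svm_C: float = 1.0
    swarm_size: int = 30
    max_iters: int = 50
    pso_seed: int = 0
    test_fraction: float = 0.2
    split_seed: int = 0
    cv_folds: int = 5
    cv_seed: int = 0
    linkage: str = "average"
    pfi_repeats: int = 10
    pfi_seed: int = 0
    group_by: str = "region"
    output_dir: str = "chemorigin_run"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model preset is required")
        unknown = [m for m in self.models if m not in SEARCH_SPACES]
        if unknown:
            raise ValueError(f"unknown model presets: {unknown}")
        self.models = tuple(self.models)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


def run(config: PipelineConfig) -> dict:
    """Execute all stages and return the (JSON-serialised) run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"manifest": config.to_dict()}
    timings: dict[str, float] = {}
    current = {"stage": "init"}

    def _stage(name: str) -> float:
        current["stage"] = name
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = _stage("generate")
        gen = default_generator_config(
            config.level, separation_scale=config.separation_scale,
            n_noise_features=config.n_noise_features, seed=config.generator_seed)
        if config.samples_per_region is not None:
            gen.region_counts = {r: (c, min(n, config.samples_per_region))
                                 for r, (c, n) in gen.region_counts.items()}
        table = generate_dataset(gen)
        write_chem_table(table, out / "chem_table.csv")
        report["table"] = {"n_samples": table.n_samples,
                           "n_components": table.n_components,
                           "path": str(out / "chem_table.csv")}
        timings["generate"] = time.perf_counter() - t0

        t0 = _stage("screen")
        registry = load_component_registry()
        screen = anova_table(table, group_by=config.group_by, registry=registry,
                             components=[c for c in table.component_names
                                         if not c.startswith("noise_")])
        screen.to_csv(out / "anova_summary.csv", index=False, encoding="utf-8")
        report["anova"] = {
            "n_components": int(len(screen)),
            "n_extremely_significant": int((screen["category"] == "***").sum()),
            "path": str(out / "anova_summary.csv")}
        timings["screen"] = time.perf_counter() - t0

        t0 = _stage("cluster")
        profiles = _cluster.mean_profiles(table, group_by=config.group_by)
        dist = _cluster.pearson_distance(profiles)
        dendro = _cluster.agglomerate(dist, list(profiles.index),
                                      linkage=config.linkage)
        (out / "dendrogram.nwk").write_text(_cluster.to_newick(dendro),
                                            encoding="utf-8")
        (out / "dendrogram.json").write_text(dendro.to_json(), encoding="utf-8")
        report["dendrogram"] = {"path": str(out / "dendrogram.nwk"),
                                "leaves": list(dendro.leaves)}
        timings["cluster"] = time.perf_counter() - t0

        t0 = _stage("split")
        plan = stratified_split(table, config.test_fraction, config.split_seed,
                                group_by=config.group_by)
        train, test = table.subset(plan.train), table.subset(plan.test)
        y_train = train.labels(config.group_by).astype(str)
        y_test = test.labels(config.group_by).astype(str)
        label_order = list(dict.fromkeys(table.labels(config.group_by).astype(str)))
        timings["split"] = time.perf_counter() - t0

        report["models"] = {}
        fitted: dict[str, object] = {}
        for preset in config.models:
            t0 = _stage(f"tune:{preset}")
            fitness = cv_fitness(preset, train, k=config.cv_folds,
                                 seed=config.cv_seed, group_by=config.group_by,
                                 C=config.svm_C, model_seed=config.pso_seed)
            pso_cfg = PSOConfig(swarm_size=config.swarm_size,
                                max_iters=config.max_iters, seed=config.pso_seed)
            result = optimize(fitness, SEARCH_SPACES[preset], pso_cfg)
            trace_path = out / f"pso_trace_{preset}.csv"
            with open(trace_path, "w", encoding="utf-8") as fh:
                fh.write("iteration,gbest_fitness,gbest_position\n")
                for it, fit, pos in result.trace:
                    fh.write(f"{it},{fit!r},\"{json.dumps(pos)}\"\n")
            timings[f"tune:{preset}"] = time.perf_counter() - t0

            t0 = _stage(f"evaluate:{preset}")
            model = build_model(preset, result.best_params, C=config.svm_C,
                                seed=config.pso_seed)
            model.fit(train.values, y_train)
            fitted[preset] = model
            train_acc = float(np.mean(model.predict(train.values) == y_train))
            pred = model.predict(test.values)
            cm = confusion(y_test, pred, labels=label_order)
            cm.write_csv(out / f"confusion_{preset}.csv")
            rep = metrics(cm)
            report["models"][preset] = {
                "best_params": result.best_params,
                "cv_fitness": result.best_fitness,
                "train_accuracy": train_acc,
                "test_accuracy": rep.accuracy,
                "macro_recall": rep.macro_recall,
                "macro_precision": rep.macro_precision,
                "macro_f1": rep.macro_f1,
                "confusion_path": str(out / f"confusion_{preset}.csv"),
                "pso_trace_path": str(trace_path)}
            timings[f"evaluate:{preset}"] = time.perf_counter() - t0

        t0 = _stage("interpret")
        best_preset = max(report["models"],
                          key=lambda m: report["models"][m]["test_accuracy"])
        records = _importance.permutation_importance(
            fitted[best_preset], test, repeats=config.pfi_repeats,
            seed=config.pfi_seed, group_by=config.group_by)
        _importance.rankings_frame(records).to_csv(out / "pfi_ranking.csv",
                                                   index=False, encoding="utf-8")
        _importance.plot_rankings(records, out / "pfi_ranking.png")
        report["pfi"] = {
            "model": best_preset,
            "top": [r.component for r in _importance.top_k(
                records, min(20, len(records)))],
            "path": str(out / "pfi_ranking.csv")}
        timings["interpret"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    log.info("stage timings (s): %s", {k: round(v, 2) for k, v in timings.items()})
    payload = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(payload, encoding="utf-8")
    return report
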