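"""Config-driven orchestration of the analysis stages.

A run config is a YAML document with a ``master_seed``, an ``output_dir``
and one block per requested stage (``simulate``, ``maturity``,
``reporter``, ``network``, ``diversity``). Only stages whose block is
present are executed, in dependency order. Per-stage seeds are derived
deterministically from the master seed, every output file is plain text
(TSV/JSON/GraphML), and the final ``run.json`` records the config hash and
the seeds, so identical configs produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import commstats, conet, maturity, reporter, simgen, tablesio

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("simulate", "maturity", "reporter", "network", "diversity")

__all__ = ["RunConfig", "load_config", "validate_config", "run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


class RunConfig:
    """Validated run configuration; thin wrapper over the YAML dict."""

    def __init__(self, raw: dict):
        self.raw = raw
        validate_config(raw)

    @property
    def master_seed(self) -> int:
        return int(self.raw.get("master_seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def stage(self, name: str) -> dict | None:
        return self.raw.get(name)

    def stage_seed(self, name: str) -> int:
        idx = STAGES.index(name)
        return int(np.random.SeedSequence([self.master_seed, idx]).generate_state(1)[0])

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(raw)


def validate_config(raw: dict) -> None:
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    if int(raw.get("version", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ValueError(f"unsupported config version {raw.get('version')}")
    if "output_dir" not in raw:
        raise ValueError("config requires output_dir")
    known = set(STAGES) | {"version", "master_seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if not any(s in raw for s in STAGES):
        raise ValueError("config declares no stages")


def _resolve_table(block: dict, key: str, outdir: Path, reader):
    """A stage input is either a path or the literal 'simulated'."""
    ref = block.get(key)
    if ref is None:
        raise ValueError(f"missing input {key!r}")
    if ref == "simulated":
        path = outdir / "simulate" / f"{key}.tsv"
        if not path.exists():
            raise ValueError(f"{key} = 'simulated' but simulate stage output {path} not found")
        return reader(path)
    return reader(ref)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_all(config: RunConfig | str | Path) -> dict:
    """Execute every configured stage; returns the run summary dict."""
    if not isinstance(config, RunConfig):
        config = load_config(config)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stages": {},
    }
    for stage in STAGES:
        block = config.stage(stage)
        if block is None:
            continue
        seed = config.stage_seed(stage)
        t0 = time.monotonic()
        logger.info("stage %s starting (seed %d)", stage, seed)
        try:
            runner = globals()[f"_run_{stage}"]
            info = runner(block, seed, outdir)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        logger.info("stage %s done in %.1fs", stage, time.monotonic() - t0)
        info["seed"] = seed
        summary["stages"][stage] = info
    _write_json(summary, outdir / "run.json")
    return summary


# -----------------------------------------------------------------------------
# stage runners
# -----------------------------------------------------------------------------

def _run_simulate(block: dict, seed: int, outdir: Path) -> dict:
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    info: dict = {}
    if "cohort" in block:
        params = dict(block["cohort"])
        params.setdefault("seed", seed)
        if "groups" in params:
            params["groups"] = tuple((str(g), float(w)) for g, w in params["groups"])
        if "sampling_days" in params:
            params["sampling_days"] = tuple(int(d) for d in params["sampling_days"])
        cfg = simgen.CohortConfig(**params)
        table, meta, truth = simgen.generate_cohort(cfg)
        tablesio.write_abundance_table(table, stage_dir / "table.tsv")
        tablesio.write_metadata(meta, stage_dir / "metadata.tsv")
        simgen.write_truth(truth, stage_dir / "cohort_truth.json")
        info["cohort"] = {"n_samples": table.n_samples, "n_taxa": table.n_taxa}
    if "kostudy" in block:
        cfg = simgen.KoStudyConfig(
            **{**block["kostudy"], "seed": block["kostudy"].get("seed", seed + 1)}
        )
        ko, meta, pathways, truth = simgen.generate_ko_study(cfg)
        tablesio.write_abundance_table(ko, stage_dir / "ko_table.tsv")
        tablesio.write_metadata(meta, stage_dir / "ko_metadata.tsv")
        tablesio.write_pathway_map(pathways, stage_dir / "pathways.tsv")
        simgen.write_truth(truth, stage_dir / "kostudy_truth.json")
        info["kostudy"] = {"n_kos": ko.n_taxa, "n_pathways": len(pathways)}
    if not info:
        raise ValueError("simulate block declares neither 'cohort' nor 'kostudy'")
    return info


def _run_maturity(block: dict, seed: int, outdir: Path) -> dict:
    stage_dir = outdir / "maturity"
    stage_dir.mkdir(parents=True, exist_ok=True)
    table = _resolve_table(block, "table", outdir, tablesio.read_abundance_table)
    meta = _resolve_table(block, "metadata", outdir, tablesio.read_metadata)
    cfg = maturity.AgeModelConfig(
        n_trees=int(block.get("n_trees", 5000)),
        n_importance_iters=int(block.get("n_importance_iters", 100)),
        cv_folds=int(block.get("cv_folds", 10)),
        cv_tolerance=float(block.get("cv_tolerance", 0.05)),
        seed=int(block.get("seed", seed)),
        cv_n_trees=block.get("cv_n_trees"),
    )
    res = maturity.run_maturity_analysis(
        table, meta, block["control_group"], cfg, delta=float(block.get("delta", 0.05))
    )
    res["predictions"].rename_axis("sample_id").to_frame().to_csv(
        stage_dir / "microbiota_age.tsv", sep="\t"
    )
    model = res["model"]
    out = {
        "control_group": block["control_group"],
        "k_star": res["k_star"],
        "train_r2": model.train_r2,
        "selected_taxa": model.selected_taxa,
        "cv_curve": {str(k): v for k, v in model.cv_curve.items()},
        "curves": {
            g: {
                "plateau_age": c.plateau_age,
                "plateau_value": c.plateau_value,
                "delta": c.delta,
            }
            for g, c in res["curves"].items()
        },
        "immi": {
            g: {"immi_days": r.immi_days, "censored": r.censored,
                "reference_value": r.reference_value}
            for g, r in res["immi"].items()
        },
    }
    _write_json(out, stage_dir / "summary.json")
    return {"k_star": res["k_star"], "train_r2": model.train_r2,
            "immi": {g: r.immi_days for g, r in res["immi"].items()}}


def _run_reporter(block: dict, seed: int, outdir: Path) -> dict:
    stage_dir = outdir / "reporter"
    stage_dir.mkdir(parents=True, exist_ok=True)
    ko = _resolve_table(block, "ko_table", outdir, tablesio.read_ko_table)
    meta = _resolve_table(block, "ko_metadata" if block.get("ko_metadata") else "metadata",
                          outdir, tablesio.read_metadata)
    pathways = _resolve_table(block, "pathways", outdir, tablesio.read_pathway_map)
    results = reporter.ko_differential_test(ko, meta)
    scores = reporter.score_pathways(
        results,
        pathways,
        n_sets=int(block.get("n_sets", 1000)),
        threshold=float(block.get("threshold", 1.6)),
        seed=int(block.get("seed", seed)),
    )
    reporter.results_to_frame(results).to_csv(stage_dir / "ko_tests.tsv", sep="\t", index=False)
    reporter.scores_to_frame(scores).to_csv(stage_dir / "reporter_scores.tsv", sep="\t", index=False)
    enriched = sorted(reporter.call_enriched_pathways(scores, float(block.get("threshold", 1.6))))
    _write_json({"enriched_pathways": enriched, "n_marker_kos":
                 int(sum(r.p_adj < 0.1 for r in results))}, stage_dir / "summary.json")
    return {"n_enriched": len(enriched)}


def _run_network(block: dict, seed: int, outdir: Path) -> dict:
    stage_dir = outdir / "network"
    stage_dir.mkdir(parents=True, exist_ok=True)
    table = _resolve_table(block, "table", outdir, tablesio.read_abundance_table)
    meta = _resolve_table(block, "metadata", outdir, tablesio.read_metadata)
    periods = [int(d) for d in block.get("periods", sorted(meta.data["age_days"].unique()))]
    res = conet.temporal_networks(
        table, meta, periods,
        group=block.get("group"),
        min_abs_rho=float(block.get("min_rho", 0.3)),
        max_q=float(block.get("max_q", 0.05)),
        n_permutations=int(block.get("permutations", 999)),
        seed=int(block.get("seed", seed)),
    )
    pooled = res["pooled"].pop("network")
    conet.write_edge_list(pooled, stage_dir / "pooled_edges.tsv")
    nx.write_graphml(pooled, stage_dir / "pooled.graphml")
    metrics = {"pooled": res["pooled"], "periods": {}}
    for day, info in res["periods"].items():
        net = info.pop("network")
        conet.write_edge_list(net, stage_dir / f"day{day}_edges.tsv")
        metrics["periods"][str(day)] = info
    _write_json(metrics, stage_dir / "metrics.json")
    return {"pooled_density": metrics["pooled"]["density"]}


def _run_diversity(block: dict, seed: int, outdir: Path) -> dict:
    stage_dir = outdir / "diversity"
    stage_dir.mkdir(parents=True, exist_ok=True)
    table = _resolve_table(block, "table", outdir, tablesio.read_abundance_table)
    meta = _resolve_table(block, "metadata", outdir, tablesio.read_metadata)
    alpha = commstats.alpha_diversity_table(table)
    alpha.to_csv(stage_dir / "alpha.tsv", sep="\t")
    dist = commstats.beta_distance(table, metric=block.get("metric", "braycurtis"))
    dist.to_csv(stage_dir / "beta_distance.tsv", sep="\t")
    labels = meta.groups_for(table.sample_ids)
    if len(set(labels)) < 2:
        logger.warning("single group; PERMANOVA/ANOSIM skipped")
        _write_json({"permanova": None, "anosim": None}, stage_dir / "tests.json")
        return {"permanova_p": None, "anosim_p": None}
    nperm = int(block.get("permutations", 999))
    perm = commstats.permanova(dist, labels, n_permutations=nperm, seed=seed)
    ano = commstats.anosim(dist, labels, n_permutations=nperm, seed=seed + 1)
    _write_json(
        {"permanova": vars(perm), "anosim": vars(ano)}, stage_dir / "tests.json"
    )
    return {"permanova_p": perm.p, "anosim_p": ano.p}
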