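"""Reproducible pipeline runner.

A YAML configuration names an ordered list of stages with their
parameters; the runner executes them in order (fail fast), derives one
deterministic random stream per stage from the global seed, writes a
resolved copy of the configuration next to the outputs, and records a run
manifest (tool version, config hash, input/output file hashes, per-stage
record counts).  Re-running with an identical configuration and inputs
reproduces byte-identical outputs, and stages whose recorded outputs are
already present and hash-identical are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, screen, cropseq, smlm, simulate

logger = logging.getLogger("perturbkit.pipeline")

TOP_LEVEL_KEYS = {"seed", "out_dir", "log_level", "stages"}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    stages: list[dict]
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - TOP_LEVEL_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" not in data or not data["stages"]:
            raise ValueError("configuration must list at least one stage")
        stages = []
        for st in data["stages"]:
            if "name" not in st:
                raise ValueError("every stage needs a 'name'")
            name = st["name"]
            if name not in STAGES:
                raise ValueError(
                    f"unknown stage {name!r}; available: {sorted(STAGES)}"
                )
            params = {k: v for k, v in st.items() if k != "name"}
            bad = set(params) - STAGES[name][1]
            if bad:
                raise ValueError(f"stage {name!r} has unknown parameters: {sorted(bad)}")
            stages.append({"name": name, **params})
        return cls(
            seed=int(data.get("seed", 0)),
            out_dir=Path(data.get("out_dir", "perturbkit_out")),
            stages=stages,
            log_level=str(data.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "log_level": self.log_level,
            "stages": self.stages,
        }

    def hash(self) -> str:
        # computational content only: where outputs land must not change them
        blob = json.dumps({"seed": self.seed, "stages": self.stages}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    started: str
    finished: str = ""
    stages: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "started": self.started,
            "finished": self.finished,
            "stages": self.stages,
        }


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % 2**31)


class _Ctx:
    """Shared state across stages: output dir, artifact paths, config hash."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.config_hash = config_hash
        self.paths: dict[str, Path] = {}

    def path(self, name: str) -> Path:
        return self.out_dir / name

    def need(self, key: str, override: str | None) -> Path:
        if override:
            return Path(override)
        if key not in self.paths:
            raise ValueError(f"stage requires {key!r} from an earlier stage or a path")
        return self.paths[key]


# ---------------------------------------------------------------------------
# stage runners; each returns (outputs: {key: Path}, record_counts: dict)


def _truth_to_json(truth: simulate.SimTruth) -> dict:
    out: dict = {}
    if truth.planted_effects is not None:
        out["planted_effects"] = [
            {"gene": g, "organ": o, "treatment": t, "multiplier": m}
            for g, eff in truth.planted_effects.items()
            for (o, t), m in eff.items()
        ]
        out["planted_directions"] = truth.planted_directions
    if truth.cell_guides is not None:
        out["cell_guides"] = truth.cell_guides
        out["cell_doublet"] = truth.cell_doublet
        out["gene_cluster_probs"] = {
            g: list(map(float, p)) for g, p in truth.gene_cluster_probs.items()
        }
    if truth.point_labels is not None:
        out["point_labels"] = truth.point_labels.tolist()
    return out


def _run_simulate_screen(ctx: _Ctx, params: dict, seed: int):
    planted: dict = {}
    for row in params.get("planted_effects", []):
        planted.setdefault(row["gene"], {})[(row["organ"], row["treatment"])] = float(
            row["multiplier"]
        )
    conditions = tuple(
        simulate.ScreenCondition(c["organ"], c["treatment"], c["batch"], int(c["n_replicates"]))
        for c in params["conditions"]
    ) if "conditions" in params else simulate.DEFAULT_SCREEN_CONDITIONS
    cfg = simulate.ScreenSimConfig(
        n_genes=int(params.get("n_genes", 200)),
        guides_per_gene=int(params.get("guides_per_gene", 5)),
        n_nontargeting=int(params.get("n_nontargeting", 25)),
        conditions=conditions,
        n_t0_replicates=int(params.get("n_t0_replicates", 3)),
        reads_per_sample=int(params.get("reads_per_sample", 1_000_000)),
        library_skew_sdlog=float(params.get("library_skew_sdlog", 0.5)),
        dispersion=float(params.get("dispersion", 0.2)),
        planted_effects=planted,
        seed=int(params.get("seed", seed)),
    )
    lib, counts, truth = simulate.simulate_screen(cfg)
    outputs = {
        "library": ctx.path("library.tsv"),
        "counts": ctx.path("counts.tsv"),
        "samples": ctx.path("samples.tsv"),
        "screen_truth": ctx.path("screen_truth.json"),
    }
    io.write_library(lib, outputs["library"], ctx.config_hash)
    io.write_count_table(counts, lib, outputs["counts"], ctx.config_hash)
    io.write_sample_metadata(counts, outputs["samples"], ctx.config_hash)
    io.write_json(_truth_to_json(truth), outputs["screen_truth"])
    return outputs, {"guides": len(lib.table), "samples": counts.counts.shape[1]}


def _run_screen_score(ctx: _Ctx, params: dict, seed: int):
    counts = io.read_count_table(
        ctx.need("counts", params.get("counts")), ctx.need("samples", params.get("meta"))
    )
    lib = io.read_library(ctx.need("library", params.get("library")))
    counts, _excluded = screen.sample_qc(
        counts, float(params.get("min_total_fraction", 0.1))
    )
    lfc = screen.normalize_counts(counts, lib, float(params.get("pseudocount", 0.5)))
    if bool(params.get("batch_adjust", True)):
        lfc = screen.adjust_batch(lfc)
    scores = screen.score_conditions(
        lfc,
        lib,
        top_fraction=float(params.get("top_fraction", 0.1)),
        n_perm=int(params.get("n_perm", 1000)),
        n_resample=int(params.get("n_resample", 10_000)),
        seed=int(params.get("seed", seed)),
    )
    outputs = {"scores": ctx.path("scores.tsv")}
    io._write_tsv(scores, outputs["scores"], ctx.config_hash)
    return outputs, {"gene_condition_rows": len(scores)}


def _run_screen_distill(ctx: _Ctx, params: dict, seed: int):
    scores = io._read_tsv(ctx.need("scores", params.get("scores")))
    hits = screen.distill_hits(
        scores,
        p_rank_max=float(params.get("p_rank", 0.05)),
        fdr_effect_max=float(params.get("fdr", 0.05)),
    )
    flat = hits.copy()
    flat["supporting_conditions"] = [
        ";".join(f"{o}:{t}" for o, t in conds) for conds in flat["supporting_conditions"]
    ]
    outputs = {"hits": ctx.path("hits.tsv"), "tissue": ctx.path("tissue.json")}
    io._write_tsv(flat, outputs["hits"], ctx.config_hash)
    io.write_json(screen.tissue_distribution(hits), outputs["tissue"])
    return outputs, {"hits": int(hits["hit"].sum())}


def _run_simulate_cropseq(ctx: _Ctx, params: dict, seed: int):
    shift = {g: list(map(float, v)) for g, v in params.get("cluster_shift", {}).items()}
    cfg = simulate.CropseqSimConfig(
        n_genes=int(params.get("n_genes", 20)),
        guides_per_gene=int(params.get("guides_per_gene", 3)),
        n_nontargeting_guides=int(params.get("n_nontargeting_guides", 10)),
        cells_per_guide=int(params.get("cells_per_guide", 50)),
        base_cluster_probs=tuple(params.get("base_cluster_probs", (1 / 6,) * 6)),
        cluster_shift=shift,
        ambient_rate=float(params.get("ambient_rate", 0.2)),
        true_guide_umi_mean=float(params.get("true_guide_umi_mean", 30.0)),
        doublet_rate=float(params.get("doublet_rate", 0.03)),
        seed=int(params.get("seed", seed)),
    )
    capture, cells, lib, truth = simulate.simulate_cropseq(cfg)
    outputs = {
        "capture_mtx": ctx.path("capture.mtx"),
        "barcodes": ctx.path("barcodes.tsv"),
        "features": ctx.path("features.tsv"),
        "cells": ctx.path("cells.tsv"),
        "cropseq_library": ctx.path("cropseq_library.tsv"),
        "cropseq_truth": ctx.path("cropseq_truth.json"),
    }
    io.write_capture_mtx(
        capture, outputs["capture_mtx"], outputs["barcodes"], outputs["features"]
    )
    io.write_cell_annotation(cells, outputs["cells"], ctx.config_hash)
    io.write_library(lib, outputs["cropseq_library"], ctx.config_hash)
    io.write_json(_truth_to_json(truth), outputs["cropseq_truth"])
    return outputs, {"cells": len(cells), "guides": len(lib.table)}


def _run_cropseq_assign(ctx: _Ctx, params: dict, seed: int):
    capture = io.read_capture_mtx(
        ctx.need("capture_mtx", params.get("mtx")),
        ctx.need("barcodes", params.get("barcodes")),
        ctx.need("features", params.get("features")),
    )
    assignment = cropseq.assign_guides(
        capture,
        min_umi=int(params.get("min_umi", 3)),
        dominance=float(params.get("dominance", 3.0)),
    )
    outputs = {"assignment": ctx.path("assignment.tsv")}
    io._write_tsv(assignment, outputs["assignment"], ctx.config_hash)
    n_ok = int((~assignment["assigned_guide"].isin([cropseq.NONE, cropseq.MULTIPLE])).sum())
    return outputs, {"cells": len(assignment), "assigned": n_ok}


def _run_cropseq_qc(ctx: _Ctx, params: dict, seed: int):
    cells = io.read_cell_annotation(ctx.need("cells", params.get("cells")))
    kept = cropseq.qc_filter(
        cells,
        umi_quantiles=(
            float(params.get("umi_quantile_low", 0.01)),
            float(params.get("umi_quantile_high", 0.99)),
        ),
        mito_max=float(params.get("mito_max", 0.10)),
    )
    outputs = {"cells_qc": ctx.path("cells_qc.tsv")}
    io.write_cell_annotation(kept, outputs["cells_qc"], ctx.config_hash)
    return outputs, {"cells_in": len(cells), "cells_kept": len(kept)}


def _run_cropseq_rank(ctx: _Ctx, params: dict, seed: int):
    assignment = io._read_tsv(ctx.need("assignment", params.get("assignment")))
    cells_key = "cells_qc" if ("cells_qc" in ctx.paths or params.get("cells") is None) else "cells"
    cells = io.read_cell_annotation(ctx.need(cells_key, params.get("cells")))
    lib = io.read_library(ctx.need("cropseq_library", params.get("library")))
    enrich = cropseq.phenotype_enrichment(assignment, cells, lib)
    table = cropseq.combined_rank(
        enrich,
        negative_clusters=[int(v) for v in params.get("negative_clusters", [0])],
        positive_clusters=[int(v) for v in params.get("positive_clusters", [1, 2, 3, 4, 5])],
        use_raw_ranks=bool(params.get("use_raw_ranks", False)),
    )
    outputs = {
        "enrichment": ctx.path("enrichment.tsv"),
        "combined_rank": ctx.path("combined_rank.tsv"),
    }
    io._write_tsv(enrich, outputs["enrichment"], ctx.config_hash)
    io._write_tsv(table, outputs["combined_rank"], ctx.config_hash)
    return outputs, {"genes": table.shape[0]}


def _run_simulate_smlm(ctx: _Ctx, params: dict, seed: int):
    clusters = tuple(
        simulate.PlantedCluster(tuple(c["center"]), float(c["radius"]), int(c["n_points"]))
        for c in params["clusters"]
    ) if "clusters" in params else simulate.DEFAULT_SMLM_CLUSTERS
    cfg = simulate.SmlmSimConfig(
        roi_width=float(params.get("roi_width", 10_000.0)),
        roi_height=float(params.get("roi_height", 10_000.0)),
        n_background=int(params.get("n_background", 2000)),
        clusters=clusters,
        seed=int(params.get("seed", seed)),
    )
    locs, truth = simulate.simulate_localizations(cfg)
    outputs = {
        "localizations": ctx.path("localizations.csv"),
        "smlm_truth": ctx.path("smlm_truth.json"),
        "roi": ctx.path("roi.json"),
    }
    io.write_localizations(locs, outputs["localizations"])
    io.write_json(_truth_to_json(truth), outputs["smlm_truth"])
    io.write_json({"bounds": list(locs.roi.bounds)}, outputs["roi"])
    return outputs, {"localizations": len(locs)}


def _run_smlm_cluster(ctx: _Ctx, params: dict, seed: int):
    from shapely.geometry import box

    if "roi" in params:
        roi = io.roi_from_spec(params["roi"])
    else:
        roi = box(*io.read_json(ctx.need("roi", None))["bounds"])
    locs = io.read_localizations(ctx.need("localizations", params.get("locs")), roi)
    summary = smlm.analyze_roi(
        locs,
        factor=float(params.get("factor", 3.0)),
        min_cluster_size=int(params.get("min_size", 10)),
    )
    table = summary.pop("cluster_table")
    outputs = {
        "smlm_summary": ctx.path("smlm_summary.json"),
        "smlm_clusters": ctx.path("smlm_clusters.tsv"),
    }
    io.write_json(summary, outputs["smlm_summary"])
    io._write_tsv(table, outputs["smlm_clusters"], ctx.config_hash)
    return outputs, {"clusters": summary["n_clusters"]}


STAGES: dict = {
    "simulate_screen": (
        _run_simulate_screen,
        {"n_genes", "guides_per_gene", "n_nontargeting", "conditions", "n_t0_replicates",
         "reads_per_sample", "library_skew_sdlog", "dispersion", "planted_effects", "seed"},
    ),
    "screen_score": (
        _run_screen_score,
        {"counts", "meta", "library", "min_total_fraction", "pseudocount", "batch_adjust",
         "top_fraction", "n_perm", "n_resample", "seed"},
    ),
    "screen_distill": (_run_screen_distill, {"scores", "p_rank", "fdr"}),
    "simulate_cropseq": (
        _run_simulate_cropseq,
        {"n_genes", "guides_per_gene", "n_nontargeting_guides", "cells_per_guide",
         "base_cluster_probs", "cluster_shift", "ambient_rate", "true_guide_umi_mean",
         "doublet_rate", "seed"},
    ),
    "cropseq_assign": (
        _run_cropseq_assign, {"mtx", "barcodes", "features", "min_umi", "dominance"}
    ),
    "cropseq_qc": (
        _run_cropseq_qc, {"cells", "umi_quantile_low", "umi_quantile_high", "mito_max"}
    ),
    "cropseq_rank": (
        _run_cropseq_rank,
        {"assignment", "cells", "library", "negative_clusters", "positive_clusters",
         "use_raw_ranks"},
    ),
    "simulate_smlm": (
        _run_simulate_smlm,
        {"roi_width", "roi_height", "n_background", "clusters", "seed"},
    ),
    "smlm_cluster": (_run_smlm_cluster, {"locs", "roi", "factor", "min_size"}),
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order and write the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = config.hash()
    with open(out_dir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    previous = None
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
    prev_stages = (
        {s["index"]: s for s in previous["stages"]}
        if previous and previous.get("config_hash") == config_hash
        else {}
    )

    manifest = RunManifest(
        version=__version__,
        config_hash=config_hash,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    ctx = _Ctx(out_dir, config_hash)
    for idx, stage in enumerate(config.stages):
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        runner, _allowed = STAGES[name]
        seed = _stage_seed(config.seed, idx)

        prev = prev_stages.get(idx)
        if prev and prev["name"] == name:
            paths = {k: Path(v) for k, v in prev["outputs"].items()}
            if all(p.exists() for p in paths.values()) and all(
                _file_hash(p) == prev["output_hashes"][k] for k, p in paths.items()
            ):
                logger.info("stage %d (%s): outputs up to date, skipping", idx, name)
                ctx.paths.update(paths)
                manifest.stages.append(dict(prev, resumed=True))
                continue

        logger.info("stage %d (%s): running", idx, name)
        input_hashes = {
            k: _file_hash(Path(v))
            for k, v in params.items()
            if isinstance(v, str) and Path(v).is_file()
        }
        outputs, counts = runner(ctx, params, seed)
        ctx.paths.update(outputs)
        manifest.stages.append(
            {
                "index": idx,
                "name": name,
                "seed": seed,
                "input_hashes": input_hashes,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "output_hashes": {k: _file_hash(v) for k, v in outputs.items()},
                "record_counts": counts,
                "resumed": False,
            }
        )
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json(manifest.to_dict(), manifest_path)
    return manifest
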