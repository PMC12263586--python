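"""Configuration-driven orchestration: simulate -> quantify -> stats, plus
affinity scanning, with structured logging and a reproducibility manifest.

A run is described by a YAML/JSON config validated against pydantic models
before any stage executes. Outputs land under ``output_root/run_id`` only;
the manifest records the config hash, the master seed, the package version
and a checksum for every file a stage reads or writes, so identical configs
reproduce identical checksums for deterministic stages. Manifests are
append-only: each run appends an entry rather than rewriting history.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .imaging import ImageBundle, QuantParams, load_annotation, load_bundle, \
    quantify_bundle
from .pbm import FULL_TABLE_SIZE, BindingSite, build_affinity_matrix, \
    load_pbm_table, render_heatmap
from .seqtools import GenomicInterval
from .stats import MeasurementTable, compare_groups, swarm_report
from .synthetic import SimulationConfig, annotation_from_truth, \
    simulate_cohort, simulate_pbm_table, write_bundle, write_truth, \
    write_pbm_table

__all__ = ["RunConfig", "PipelineConfigError", "PipelineStageFailure",
           "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "affinity", "stats")


class PipelineConfigError(ValueError):
    """Configuration invalid; raised before any stage runs."""


class PipelineStageFailure(RuntimeError):
    """A stage failed after the run started; manifest records the partial run."""


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

class GroupSpec(BaseModel):
    label: str
    n: int = Field(ge=1)
    config: dict[str, Any] = Field(default_factory=dict)  # per-group overrides


class SimulateBlock(BaseModel):
    groups: list[GroupSpec]
    image: dict[str, Any] = Field(default_factory=dict)  # shared overrides

    @field_validator("groups")
    @classmethod
    def _unique_labels(cls, v):
        labels = [g.label for g in v]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        return v


class QuantifyBlock(BaseModel):
    mask_choice: Literal["limb", "posterior", "zpa"] = "posterior"
    images: str | None = None       # needed when no simulate stage ran
    annotations: str | None = None
    params: dict[str, Any] = Field(default_factory=dict)


class SiteSpec(BaseModel):
    name: str
    start: int = Field(ge=1)  # 1-based inclusive within the query sequence
    end: int = Field(ge=1)


class PBMSpec(BaseModel):
    factor: str
    path: str | None = None          # UniProbe-style TSV
    consensus: str | None = None     # or a synthetic table
    decay: float = 0.5
    noise_cv: float = 0.0


class AffinityBlock(BaseModel):
    sequence: str | None = None
    fasta: str | None = None
    sites: list[SiteSpec]
    factors: list[PBMSpec]
    window_policy: str = "overlap6"


class StatsBlock(BaseModel):
    table: str | None = None         # CSV when no quantify stage ran
    group_order: list[str] | None = None
    comparisons: list[tuple[str, str]] | None = None
    star_scheme: str = "methods"


class RunConfig(BaseModel):
    run_id: str
    stages: list[Literal["simulate", "quantify", "affinity", "stats"]]
    master_seed: int = 0
    output_root: str = "runs"
    simulate: SimulateBlock | None = None
    quantify: QuantifyBlock | None = None
    affinity: AffinityBlock | None = None
    stats: StatsBlock | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise PipelineConfigError(str(exc)) from exc


def _check_config(config: RunConfig) -> None:
    """Cross-stage validation, before anything runs."""
    seen = set()
    for stage in config.stages:
        if stage in seen:
            raise PipelineConfigError(f"stage {stage!r} listed twice")
        seen.add(stage)
        if getattr(config, stage) is None:
            raise PipelineConfigError(
                f"stage {stage!r} requested but its parameter block is missing")
    if "quantify" in seen and "simulate" not in seen:
        q = config.quantify
        if not q.images or not q.annotations:
            raise PipelineConfigError(
                "quantify without simulate requires 'quantify.images' and "
                "'quantify.annotations' directories")
    if "stats" in seen and "quantify" not in seen and not config.stats.table:
        raise PipelineConfigError(
            "stats without quantify requires 'stats.table' (CSV path)")
    if "affinity" in seen:
        a = config.affinity
        if not a.sequence and not a.fasta:
            raise PipelineConfigError(
                "affinity requires 'affinity.sequence' or 'affinity.fasta'")
        for f in a.factors:
            if not f.path and not f.consensus:
                raise PipelineConfigError(
                    f"affinity factor {f.factor!r} needs 'path' or 'consensus'")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_tree(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _sha256(p)
            for p in sorted(root.rglob("*")) if p.is_file()}


class _JsonLog:
    """One JSON line per event, alongside the console log."""

    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def event(self, **fields) -> None:
        with self.path.open("a") as fh:
            fh.write(json.dumps(fields, default=str) + "\n")
        log.info("%s", fields)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, run_dir: Path, jlog: _JsonLog) -> dict:
    block = config.simulate
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    specs = []
    for g in block.groups:
        overrides = {**block.image, **g.config}
        cfg = SimulationConfig.default(**overrides) \
            if ("image_width" in overrides or "image_height" in overrides) \
            else SimulationConfig(**overrides)
        specs.append((g.label, cfg, g.n))
    cohort = simulate_cohort(specs, seed=config.master_seed)
    for bundle, truth, label in cohort:
        stem = out / bundle.embryo_id
        write_bundle(bundle, stem.with_suffix(".tif"))
        write_truth(truth, out / (bundle.embryo_id + "_truth"))
        ann = annotation_from_truth(truth, bundle.embryo_id, label)
        with stem.with_suffix(".annotation.json").open("w") as fh:
            json.dump({"embryo_id": ann.embryo_id, "group": ann.group,
                       "boundary_polyline": [list(v) for v in
                                             ann.boundary_polyline],
                       "orientation": {"anterior": ann.orientation.anterior,
                                       "distal": ann.orientation.distal},
                       "limb_side_point": list(ann.limb_side_point)}, fh)
    jlog.event(stage="simulate", bundles=len(cohort),
               seed=config.master_seed)
    return {"bundles": len(cohort), "dir": str(out)}


def _stage_quantify(config: RunConfig, run_dir: Path, jlog: _JsonLog) -> dict:
    block = config.quantify
    out = run_dir / "quantify"
    out.mkdir(parents=True, exist_ok=True)
    images = Path(block.images) if block.images else run_dir / "simulate"
    annotations = Path(block.annotations) if block.annotations else images
    params = QuantParams(**block.params)
    rows = []
    for tif in sorted(images.glob("*.tif")):
        ann_path = annotations / (tif.stem + ".annotation.json")
        if not ann_path.exists():
            raise PipelineStageFailure(f"missing annotation for {tif.name}")
        annotation = load_annotation(ann_path)
        bundle = load_bundle(tif, embryo_id=annotation.embryo_id,
                             group=annotation.group)
        record = quantify_bundle(bundle, annotation, block.mask_choice, params)
        rows.append(record.to_row())
        jlog.event(stage="quantify", embryo=record.embryo_id,
                   relative_activity=record.relative_activity,
                   thresholds={k: record.metadata.get(k) for k in
                               ("rfp_threshold", "gfp_threshold")},
                   mask_choice=block.mask_choice, excluded=record.excluded)
    if not rows:
        raise PipelineStageFailure(f"no image bundles found under {images}")
    import pandas as pd
    table = pd.DataFrame(rows)
    csv_path = out / "activity.csv"
    table.to_csv(csv_path, index=False)
    return {"csv": str(csv_path), "n": len(rows),
            "excluded": int(table["excluded"].sum())}


def _stage_affinity(config: RunConfig, run_dir: Path, jlog: _JsonLog) -> dict:
    block = config.affinity
    out = run_dir / "affinity"
    out.mkdir(parents=True, exist_ok=True)
    if block.sequence:
        sequence = block.sequence.upper()
    else:
        from Bio import SeqIO
        sequence = str(next(SeqIO.parse(block.fasta, "fasta")).seq).upper()
    sites = [BindingSite(s.name, GenomicInterval("query", s.start, s.end))
             for s in block.sites]
    tables = {}
    for spec in block.factors:
        if spec.path:
            tables[spec.factor] = load_pbm_table(spec.path, spec.factor)
        else:
            tables[spec.factor] = simulate_pbm_table(
                spec.consensus, decay_per_mismatch=spec.decay,
                noise_cv=spec.noise_cv, seed=config.master_seed,
                factor_name=spec.factor)
    matrix = build_affinity_matrix(tables, sequence, sites,
                                   block.window_policy)
    matrix.to_frame().to_csv(out / "affinity_matrix.tsv", sep="\t")
    with (out / "provenance.json").open("w") as fh:
        json.dump({f"{f}|{s}": {"status": matrix.provenance.get((f, s)),
                                "window": matrix.window_choice.get((f, s))}
                   for f in matrix.factors for s in matrix.sites},
                  fh, indent=2)
    render_heatmap(matrix, out / "heatmap.png")
    jlog.event(stage="affinity", factors=matrix.factors, sites=matrix.sites)
    return {"matrix": str(out / "affinity_matrix.tsv")}


def _stage_stats(config: RunConfig, run_dir: Path, jlog: _JsonLog) -> dict:
    block = config.stats
    out = run_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    source = Path(block.table) if block.table else \
        run_dir / "quantify" / "activity.csv"
    import pandas as pd
    frame = pd.read_csv(source)
    if "excluded" in frame.columns:
        frame = frame[~frame["excluded"].astype(bool)]
    table = MeasurementTable(
        frame[["embryo_id", "group", "relative_activity"]],
        group_order=block.group_order)
    results = compare_groups(table, block.comparisons, block.star_scheme)
    with (out / "results.json").open("w") as fh:
        json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=2)
    swarm_report(table, results, out / "swarm")
    jlog.event(stage="stats",
               tests={k: v.p_value for k, v in results.items()})
    return {"results": str(out / "results.json")}


_STAGE_FNS = {"simulate": _stage_simulate, "quantify": _stage_quantify,
              "affinity": _stage_affinity, "stats": _stage_stats}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest entry.

    The manifest (``manifest.json`` under the run directory) is a list of
    run entries, appended to on each invocation. A stage failure records a
    partial entry before PipelineStageFailure propagates.
    """
    _check_config(config)
    run_dir = Path(config.output_root) / config.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    jlog = _JsonLog(run_dir / "run.log.jsonl")

    resolved = config.model_dump()
    config_text = yaml.safe_dump(resolved, sort_keys=True)
    (run_dir / "config_resolved.yaml").write_text(config_text)

    entry: dict = {
        "run_id": config.run_id,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "version": __version__,
        "stages": {},
        "status": "running",
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    jlog.event(event="run_start", run_id=config.run_id,
               seed=config.master_seed)
    try:
        for stage in config.stages:
            info = _STAGE_FNS[stage](config, run_dir, jlog)
            stage_dir = run_dir / stage
            info["checksums"] = _checksum_tree(stage_dir) \
                if stage_dir.exists() else {}
            entry["stages"][stage] = info
        entry["status"] = "complete"
    except PipelineConfigError:
        raise
    except Exception as exc:
        entry["status"] = f"failed: {exc}"
        _append_manifest(run_dir, entry)
        raise PipelineStageFailure(str(exc)) from exc
    _append_manifest(run_dir, entry)
    jlog.event(event="run_end", run_id=config.run_id, status=entry["status"])
    return entry


def _append_manifest(run_dir: Path, entry: dict) -> None:
    path = run_dir / "manifest.json"
    history = json.loads(path.read_text()) if path.exists() else []
    history.append(entry)
    path.write_text(json.dumps(history, indent=2))


# ---------------------------------------------------------------------------
# Input validation (reporting only; mutates nothing)
# ---------------------------------------------------------------------------

def validate_inputs(images_dir: str | Path | None = None,
                    annotations_dir: str | Path | None = None,
                    pbm_paths: list[str | Path] | None = None) -> list[str]:
    """Report problems with run inputs without mutating anything.

    Checks: per-bundle channel dimensions agree; every image has a complete
    annotation; PBM tables carry the full 65,536 8-mers.
    """
    issues: list[str] = []
    if images_dir is not None:
        images_dir = Path(images_dir)
        annotations_dir = Path(annotations_dir or images_dir)
        for tif in sorted(images_dir.glob("*.tif")):
            try:
                load_bundle(tif)
            except Exception as exc:
                issues.append(f"{tif.name}: {exc}")
            ann = annotations_dir / (tif.stem + ".annotation.json")
            if not ann.exists():
                issues.append(f"{tif.name}: missing annotation sidecar")
            else:
                try:
                    load_annotation(ann)
                except Exception as exc:
                    issues.append(f"{ann.name}: {exc}")
    for path in pbm_paths or []:
        try:
            table = load_pbm_table(path)
        except Exception as exc:
            issues.append(f"{Path(path).name}: {exc}")
            continue
        if not table.is_complete:
            issues.append(
                f"{Path(path).name}: incomplete PBM table "
                f"({len(table.intensities)} of {FULL_TABLE_SIZE} 8-mers)")
    return issues
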