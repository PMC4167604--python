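"""End-to-end orchestration: floor -> filter -> SOM -> partition -> planes -> enrichment.

A run is a pure function of (input files, configuration, seed): repeated
runs write byte-identical output bundles.  All randomness flows from the
single configured seed (SOM fallback initialization and sequential-mode
sample ordering are the only stochastic stages; batch training with the
deterministic principal-plane initialization uses no randomness at all).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import enrichment as _enrichment
from . import io as _io
from . import planes as _planes
from . import preprocess as _preprocess
from . import som as _som

logger = logging.getLogger("edisom")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the full accumulated list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; mirrored 1:1 by CLI flags."""

    expression_path: str
    control_label: str
    out_dir: str
    gene_sets: list[tuple[str, str]] = field(default_factory=list)  # (path, namespace)
    log2_input: bool = False
    floor: float = 200.0
    min_fold: float = 2.0
    min_stages: int = 4
    rings: int | None = None
    max_clusters: int | None = None
    train_mode: str = "batch"
    epochs_scale: float = 1.0
    min_overlap: int = 3
    fdr: float = 0.05
    background: str = "prefilter"  # or "filtered"
    seed: int = 0
    plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError([f"unknown config key: {k}" for k in sorted(unknown)])
        if "gene_sets" in raw:
            raw["gene_sets"] = [tuple(entry) for entry in raw["gene_sets"]]
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Check every parameter domain; return ALL violations (empty list = valid)."""
    errors: list[str] = []
    if not Path(config.expression_path).is_file():
        errors.append(f"expression_path does not exist: {config.expression_path}")
    for path, _namespace in config.gene_sets:
        if not Path(path).is_file():
            errors.append(f"gene-set file does not exist: {path}")
    if not config.control_label:
        errors.append("control_label must be non-empty")
    if not config.floor > 0:
        errors.append(f"floor must be > 0, got {config.floor}")
    if not config.min_fold > 1:
        errors.append(f"min_fold must be > 1, got {config.min_fold}")
    if config.min_stages < 1:
        errors.append(f"min_stages must be >= 1, got {config.min_stages}")
    if config.rings is not None and config.rings < 1:
        errors.append(f"rings must be >= 1, got {config.rings}")
    if config.max_clusters is not None and config.max_clusters < 1:
        errors.append(f"max_clusters must be >= 1, got {config.max_clusters}")
    if config.train_mode not in ("batch", "sequential"):
        errors.append(f"train_mode must be 'batch' or 'sequential', got {config.train_mode!r}")
    if config.epochs_scale <= 0:
        errors.append(f"epochs_scale must be > 0, got {config.epochs_scale}")
    if config.min_overlap < 0:
        errors.append(f"min_overlap must be >= 0, got {config.min_overlap}")
    if not 0 < config.fdr <= 1:
        errors.append(f"fdr must lie in (0, 1], got {config.fdr}")
    if config.background not in ("prefilter", "filtered"):
        errors.append(f"background must be 'prefilter' or 'filtered', got {config.background!r}")
    if config.seed < 0:
        errors.append(f"seed must be >= 0, got {config.seed}")
    return errors


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the output manifest.

    Stages: read -> apply_floor -> fold_change -> regulation_filter ->
    build_grid -> train -> map_bmu -> neighbor_distance -> find_seeds ->
    partition -> component_planes -> enrich_clusters -> write_results.
    The manifest records every written file with its content hash plus the
    per-stage counts logged along the way.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError(errors)

    def _stage(name: str):
        logger.info("stage: %s", name)

    _stage("read_expression_table")
    matrix = _io.read_expression_table(
        config.expression_path, config.control_label, log2_input=config.log2_input
    )
    logger.info("  %d transcripts x %d conditions", matrix.n_transcripts, matrix.n_conditions)

    _stage("apply_floor")
    matrix = _preprocess.apply_floor(matrix, config.floor)

    _stage("fold_change")
    fc_full = _preprocess.fold_change(matrix)

    _stage("regulation_filter")
    if config.min_stages > fc_full.n_stages:
        raise ConfigError(
            [f"min_stages={config.min_stages} exceeds the {fc_full.n_stages} available stages"]
        )
    rule = _preprocess.FilterRule(
        min_fold=config.min_fold, min_stages=config.min_stages, floor=config.floor
    )
    fc, report = _preprocess.regulation_filter(fc_full, rule)
    n_kept = fc.n_transcripts
    n_dropped = fc_full.n_transcripts - n_kept
    logger.info("  kept %d, dropped %d (kept + dropped = %d input rows)",
                n_kept, n_dropped, fc_full.n_transcripts)
    if n_kept == 0:
        raise ValueError(
            "regulation filter kept no transcripts; relax --min-fold or --min-stages "
            "(or check that the table is linear-scale intensities)"
        )

    _stage("build_grid")
    grid = _som.build_grid(fc, rings_override=config.rings, seed=config.seed)
    logger.info("  %d rings, %d units", grid.rings, grid.n_units)

    _stage("train")
    schedule = _som.default_schedule(
        grid, fc.n_transcripts, mode=config.train_mode, seed=config.seed,
        epochs_scale=config.epochs_scale,
    )
    grid = _som.train(grid, fc, schedule)

    _stage("map_bmu")
    bmu = _som.map_bmu(grid, fc)
    logger.info("  quantization error %.4f", bmu.quantization_error)

    _stage("find_seeds")
    heights = _cluster.neighbor_distance(grid)
    seeds = _cluster.find_seeds(grid, heights)
    if config.max_clusters is not None and len(seeds) > config.max_clusters:
        seeds = _cluster.merge_closest_seeds(grid, seeds, config.max_clusters)
    logger.info("  %d seed units", len(seeds))

    _stage("partition")
    part = _cluster.partition(grid, seeds, bmu)
    sizes = _cluster.cluster_sizes(part)
    logger.info("  %d clusters, sizes %s", part.n_clusters, sizes)

    _stage("component_planes")
    planes = _planes.component_planes(grid)
    plane_frames = {
        plane.stage_label: _planes.plane_frame(plane, grid) for plane in planes
    }

    _stage("enrich_clusters")
    enrichment_frames = []
    for path, namespace in config.gene_sets:
        ann = _io.read_gene_sets(path, namespace)
        annotated = set().union(*(m for _, m in ann.terms.values()))
        if config.background == "prefilter":
            universe = set(fc_full.transcript_ids) & annotated
        else:
            universe = set(fc.transcript_ids) & annotated
        enrichment_frames.append(
            _enrichment.enrich_clusters(
                part, ann, universe, min_overlap=config.min_overlap, fdr=config.fdr
            )
        )
    if enrichment_frames:
        enrichment = pd.concat(enrichment_frames, ignore_index=True)
    else:
        enrichment = pd.DataFrame(columns=_enrichment.ENRICHMENT_COLUMNS)

    _stage("write_results")
    bundle = _io.ResultBundle(
        cluster_table=part.cluster_table(bmu),
        seed_profiles=part.seed_profile_table(fc.stage_labels),
        enrichment=enrichment,
        planes=plane_frames,
        filter_report=report,
    )
    out_dir = Path(config.out_dir)
    files = _io.write_results(bundle, out_dir)
    if config.plot:
        png = _planes.render_planes(grid, out_dir / "component_planes.png")
        files[png.name] = "binary"

    manifest = {
        "files": files,
        "counts": {
            "input_transcripts": matrix.n_transcripts,
            "kept": n_kept,
            "dropped": n_dropped,
            "units": grid.n_units,
            "rings": grid.rings,
            "clusters": part.n_clusters,
            "cluster_sizes": {str(k): v for k, v in sizes.items()},
            "enrichment_rows": int(len(enrichment)),
            "reported_terms": int(enrichment["reported"].sum()) if len(enrichment) else 0,
        },
        "quantization_error": bmu.quantization_error,
        "config": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        },
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
    return manifest
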