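"""End-to-end pipeline: normalise -> collapse -> select -> cluster -> annotate.

Optionally runs over-representation analysis (given a GMT file) and stained-
section quantification (given images).  Each run writes its stage outputs
plus a manifest (package version, seeds, parameters, input checksums, output
checksums) into a run directory; re-running with the same inputs and seed
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation import MarkerTable, assign_cell_types, map_markers
from .clustering import cluster_transcripts
from .enrichment import cluster_ora, read_gmt
from .histology import QuantConfig, quantify_image, read_image
from .matrix import ExpressionMatrix, ProbeAnnotation, collapse_probes_median, \
    quantile_normalize, read_expression_table
from .selection import SelectionConfig, select_transcripts

_log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and the global seed for one pipeline run.

    Stage seeds derive deterministically from ``rng_seed``.
    """

    expression_tsv: str
    annotation_tsv: str
    marker_table_tsv: str | None = None   # None -> packaged marker table
    gmt_path: str | None = None
    image_paths: list = dataclasses.field(default_factory=list)
    um2_per_pixel: float = 1.0
    scale: str = "log2"
    n_permutations: int = 10
    fdr_threshold: float = 30.0
    sd_threshold: float = 15.0
    k: object = "auto"
    k_range: tuple = (2, 10)
    rho_max: float = 0.8
    rng_seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "gapwave_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "inputs": {},
        "outputs": {},
        "results": {},
    }

    @_stage("load")
    def load():
        m = read_expression_table(cfg.expression_tsv)
        ann = ProbeAnnotation.read_tsv(cfg.annotation_tsv)
        manifest["inputs"]["expression_tsv"] = _sha256(cfg.expression_tsv)
        manifest["inputs"]["annotation_tsv"] = _sha256(cfg.annotation_tsv)
        return m, ann

    @_stage("normalize")
    def normalize(m):
        return quantile_normalize(m)

    @_stage("collapse")
    def collapse(m, ann):
        return collapse_probes_median(m, ann)

    @_stage("select")
    def select(collapsed):
        sel_cfg = SelectionConfig(
            n_permutations=cfg.n_permutations,
            fdr_threshold=cfg.fdr_threshold,
            sd_threshold=cfg.sd_threshold,
            rng_seed=cfg.rng_seed,
        )
        res = select_transcripts(collapsed, sel_cfg, scale=cfg.scale)
        res.write_tsv(out / "selection.tsv")
        manifest["results"]["n_selected"] = res.n_selected
        return res

    @_stage("cluster")
    def cluster(collapsed, selection):
        ids = selection.selected_ids
        if not ids:
            raise ValueError("no transcripts selected; nothing to cluster")
        idx = [collapsed.matrix.row_ids.index(t) for t in ids]
        sub = ExpressionMatrix(
            collapsed.matrix.values[idx], ids, collapsed.matrix.col_days,
            collapsed.matrix.scale,
        )
        work = sub.to_log2() if cfg.scale == "log2" else sub
        res = cluster_transcripts(work, k=cfg.k, k_range=cfg.k_range,
                                  rho_max=cfg.rho_max, rng_seed=cfg.rng_seed)
        res.write_tsv(out / "clusters.tsv")
        res.median_z_profiles.to_csv(out / "cluster_profiles.tsv", sep="\t",
                                     float_format="%.6g")
        manifest["results"]["k"] = res.k
        manifest["results"]["cluster_sizes"] = {
            str(k): int(v) for k, v in res.cluster_sizes().items()
        }
        return res

    @_stage("annotate")
    def annotate(clusters):
        if cfg.marker_table_tsv is not None:
            markers = MarkerTable.read_tsv(cfg.marker_table_tsv)
            manifest["inputs"]["marker_table_tsv"] = _sha256(cfg.marker_table_tsv)
        else:
            markers = MarkerTable.load_packaged()
        evidence, missing = map_markers(markers, clusters.labels)
        assignment = assign_cell_types(clusters.median_z_profiles, evidence)
        assignment.to_json(out / "cell_types.json")
        manifest["results"]["cell_types"] = {
            str(k): v for k, v in assignment.labels.items()
        }
        manifest["results"]["markers_missing"] = len(missing)
        return assignment

    @_stage("enrich")
    def enrich(collapsed, clusters):
        collection = read_gmt(cfg.gmt_path, universe=collapsed.matrix.row_ids)
        manifest["inputs"]["gmt_path"] = _sha256(cfg.gmt_path)
        members = {int(c): clusters.labels[clusters.labels == c].index.tolist()
                   for c in sorted(clusters.labels.unique())}
        df = cluster_ora(members, collection)
        df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        return df

    @_stage("quantify_images")
    def quantify():
        qcfg = QuantConfig(um2_per_pixel=cfg.um2_per_pixel)
        rows = []
        for path in cfg.image_paths:
            res = quantify_image(read_image(path), qcfg)
            res["image"] = Path(path).name
            manifest["inputs"][f"image:{Path(path).name}"] = _sha256(path)
            rows.append(res)
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "leydig_areas.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        return rows

    m, ann = load()
    norm = normalize(m)
    collapsed = collapse(norm, ann)
    selection = select(collapsed)
    clusters = cluster(collapsed, selection)
    annotate(clusters)
    if cfg.gmt_path:
        enrich(collapsed, clusters)
    if cfg.image_paths:
        quantify()

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
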