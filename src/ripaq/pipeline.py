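"""End-to-end orchestration: simulate -> preprocess -> segment -> classify
-> validate -> score (-> report), with a reproducible run manifest.

Configuration lives in a single YAML file; defaults follow the published
workflow (segmentation scale 25, shape 0.1, compactness 0.1, 50-m stream
buffer, 15 stations per bank, 200 validation objects).  All stage outputs
are persisted under ``outdir`` and hashed into ``manifest.json`` so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import preprocess as pre
from . import scene as scn
from . import scoring, stats
from .geo import read_geojson, read_raster, write_geojson_features, write_raster
from .segmentation import SegmentationParams, multiresolution_segment, segment_stats

log = logging.getLogger("ripaq")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "ripaq_out"
    simulate: bool = True
    scene: scn.SceneSpec = field(default_factory=scn.SceneSpec)
    ms_path: str | None = None
    pan_path: str | None = None
    stream_path: str | None = None
    qbr_path: str | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classifier: cls.ClassifierConfig = field(default_factory=cls.ClassifierConfig)
    weights: dict[str, float] = field(
        default_factory=lambda: dict(scoring.DEFAULT_WEIGHTS)
    )
    buffer_width_m: float = 50.0
    n_stations: int = 15
    validation_n: int = 200
    validation_seed: int = 0
    sharpen: bool = True
    n_pcs: int = 3

    def validate(self) -> None:
        if self.buffer_width_m <= 0:
            raise ValueError("buffer_width_m must be positive")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.validation_n < 1:
            raise ValueError("validation_n must be >= 1")
        if not 1 <= self.n_pcs <= 8:
            raise ValueError("n_pcs must be in 1..8")
        scoring.check_weights(self.weights)
        self.scene.validate()
        self.classifier.validate()
        if not self.simulate:
            for name in ("ms_path", "pan_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or not found in run mode")


_TOP_KEYS = {
    "outdir", "simulate", "scene", "paths", "segmentation", "classifier",
    "weights", "buffer_width_m", "n_stations", "validation_n",
    "validation_seed", "sharpen", "n_pcs",
}
_PATH_KEYS = {"ms", "pan", "stream", "qbr"}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; absent keys take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kw: dict = {}
    for key in ("outdir", "simulate", "buffer_width_m", "n_stations",
                "validation_n", "validation_seed", "sharpen", "n_pcs",
                "weights"):
        if key in raw:
            kw[key] = raw[key]
    if "scene" in raw:
        scene_kw = dict(raw["scene"])
        if "class_spectra" in scene_kw:
            scene_kw["class_spectra"] = {
                k: tuple(v) for k, v in scene_kw["class_spectra"].items()
            }
        kw["scene"] = scn.SceneSpec(**scene_kw)
    if "segmentation" in raw:
        kw["segmentation"] = SegmentationParams(**raw["segmentation"])
    if "classifier" in raw:
        kw["classifier"] = cls.ClassifierConfig(**raw["classifier"])
    if "paths" in raw:
        paths = raw["paths"]
        unknown = set(paths) - _PATH_KEYS
        if unknown:
            raise ValueError(f"unknown path keys: {sorted(unknown)}")
        for short, attr in (("ms", "ms_path"), ("pan", "pan_path"),
                            ("stream", "stream_path"), ("qbr", "qbr_path")):
            if short in paths:
                kw[attr] = paths[short]
    cfg = PipelineConfig(**kw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "stages": [],
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate) if config.simulate else ("load", _stage_load),
        ("preprocess", _stage_preprocess),
        ("segment", _stage_segment),
        ("classify", _stage_classify),
        ("validate", _stage_validate),
        ("score", _stage_score),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(config, outdir, state)
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage '{name}' failed: {e}") from e
        if outputs is None:
            continue
        manifest["stages"].append(
            {"name": name, "outputs": {k: _sha256(p) for k, p in outputs.items()}}
        )
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scene"]["class_spectra"] = {
        k: list(v) for k, v in d["scene"]["class_spectra"].items()
    }
    return d


def _stage_simulate(config, outdir, state):
    ms, pan, truth = scn.generate_scene(config.scene)
    state.update(ms=ms, pan=pan, truth=truth, centerline=truth.centerline)
    return scn.write_scene(outdir, ms, pan, truth)


def _stage_load(config, outdir, state):
    bands, t, meta = read_raster(config.ms_path)
    state["ms"] = scn.MultispectralImage(
        bands=bands.astype(float), resolution=t.px, transform=t
    )
    pv, tp, _ = read_raster(config.pan_path)
    state["pan"] = scn.PanImage(values=pv.astype(float), resolution=tp.px,
                                transform=tp)
    state["truth"] = None
    state["centerline"] = (
        read_geojson(config.stream_path) if config.stream_path else None
    )
    return None


def _stage_preprocess(config, outdir, state):
    composite, src = pre.make_composite(
        state["ms"], state["pan"], n_pcs=config.n_pcs, sharpen=config.sharpen
    )
    state["composite"] = composite
    state["src"] = src
    state["rendvi"] = pre.re_ndvi(src)
    path = outdir / "composite.tif"
    write_raster(path, composite.bands, composite.transform,
                 band_names=list(composite.band_names), nodata=float("nan"))
    ev = outdir / "explained_variance.json"
    ev.write_text(json.dumps({"explained_variance": composite.explained_variance}))
    return {"composite": path, "explained_variance": ev}


def _stage_segment(config, outdir, state):
    composite = state["composite"]
    centerline = state["centerline"]
    mask = None
    if centerline is not None:
        region = scoring.buffer_stream(
            centerline, composite.transform, composite.bands.shape[:2],
            config.buffer_width_m,
        )
        mask = region.mask
        state["buffer"] = region
    segmap = multiresolution_segment(composite, config.segmentation, mask)
    state["segmap"] = segmap
    raster_path = outdir / "segments.tif"
    write_raster(raster_path, segmap.segment_ids, composite.transform,
                 band_names=["segment_id"], nodata=0)
    stats_path = outdir / "segment_stats.csv"
    segment_stats(segmap, composite).to_csv(stats_path)
    return {"segments": raster_path, "segment_stats": stats_path}


def _stage_classify(config, outdir, state):
    feats = cls.object_features(
        state["segmap"], state["composite"], state["rendvi"], state["src"]
    )
    objects = cls.classify_objects(feats, config.classifier)
    state["objects"] = objects
    class_raster = cls.paint_classes(state["segmap"], objects["predicted_class"])
    state["class_raster"] = class_raster
    raster_path = outdir / "classes.tif"
    write_raster(raster_path, class_raster, state["composite"].transform,
                 band_names=["class"], nodata=0)
    table_path = outdir / "objects.csv"
    objects.to_csv(table_path)
    return {"classes": raster_path, "objects": table_path}


def _stage_validate(config, outdir, state):
    truth = state.get("truth")
    if truth is None:
        log.info("no ground truth available; skipping validation")
        return None
    objects = state["objects"]
    labels = truth.labels
    ratio = truth.transform.px / state["composite"].transform.px
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError("truth and composite grids are not integer-related")
    if r > 1:  # segmentation ran on the sharpened grid
        labels = np.kron(labels, np.ones((r, r), dtype=labels.dtype))
    ref = cls.majority_reference(state["segmap"], labels)
    objects = objects.join(ref)
    n = min(config.validation_n, len(objects))
    sample = cls.sample_validation_objects(objects, n, config.validation_seed)
    cm = cls.confusion_matrix(
        sample["predicted_class"], sample["reference_class"]
    )
    metrics = {
        "n_objects": len(objects),
        "n_validation": n,
        "labels": list(cm.labels),
        "confusion_matrix": cm.counts.tolist(),
        "overall_accuracy": cls.overall_accuracy(cm),
        "cohens_kappa": cls.cohens_kappa(cm),
    }
    path = outdir / "validation.json"
    path.write_text(json.dumps(metrics, indent=2))
    state["validation"] = metrics
    return {"validation": path}


def _stage_score(config, outdir, state):
    centerline = state.get("centerline")
    if centerline is None:
        raise FileNotFoundError("no stream centerline available for scoring")
    stations = scoring.make_stations(
        centerline, config.n_stations, config.buffer_width_m
    )
    qbr_blocks = None
    if config.qbr_path:
        qbr_blocks = pd.read_csv(config.qbr_path)
    table = scoring.score_stations(
        state["class_raster"], state["composite"].transform, stations,
        config.weights, qbr_blocks,
    )
    state["stations"] = table
    csv_path = outdir / "stations.csv"
    table.to_csv(csv_path, index=False)
    geo_path = outdir / "stations.geojson"
    write_geojson_features(
        geo_path,
        [
            (st.footprint, row)
            for st, (_, row_s) in zip(stations, table.iterrows())
            for row in [row_s.to_dict()]
        ],
    )
    return {"stations": csv_path, "stations_geojson": geo_path}


def _stage_report(config, outdir, state):
    table = state.get("stations")
    if table is None or "qbr" not in table.columns or table["qbr"].isna().any():
        return None
    scores = stats.PairedScores(
        station_ids=tuple(table["station_id"]),
        rsqi=table["rsqi"].to_numpy(float),
        qbr=table["qbr"].to_numpy(float),
    )
    report = stats.agreement_report(scores)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2))
    return {"report": path}
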