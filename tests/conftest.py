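"""Shared fixtures: small synthetic scenes and the 5-seed recovery runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ripaq

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from ripaq import classify as cls
from ripaq.preprocess import CompositeRaster
from ripaq.geo import GridTransform


def make_composite_from_array(values: np.ndarray) -> CompositeRaster:
    """Wrap a plain (H, W) or (H, W, B) array as a composite raster."""
    if values.ndim == 2:
        values = values[:, :, None]
    nb = values.shape[2]
    return CompositeRaster(
        bands=values.astype(float),
        band_names=tuple(f"b{i + 1}" for i in range(nb)),
        explained_variance=tuple(1.0 for _ in range(nb)),
        transform=GridTransform(0.0, float(values.shape[0]), 1.0),
    )


@pytest.fixture(scope="session")
def small_scene():
    """A compact default-conditions scene used by several unit tests."""
    spec = ripaq.SceneSpec(width_px=128, height_px=256, seed=7)
    ms, pan, truth = ripaq.generate_scene(spec)
    return spec, ms, pan, truth


def run_recovery(seed: int, n_stations: int = 3) -> dict:
    """One full recovery experiment: simulate, process, classify, score.

    Default study conditions (noise, spectra, river geometry, segmentation
    scale 25 / shape 0.1 / compactness 0.1, 50-m buffer) on a 320 x 640 m
    corridor; segmentation runs on the pansharpened 0.5-m composite as in
    the published workflow.
    """
    spec = ripaq.SceneSpec(width_px=160, height_px=320, seed=seed)
    ms, pan, truth = ripaq.generate_scene(spec)
    composite, src = ripaq.make_composite(ms, pan, sharpen=True)
    region = ripaq.buffer_stream(
        truth.centerline, composite.transform, composite.bands.shape[:2], 50.0
    )
    segmap = ripaq.multiresolution_segment(
        composite, ripaq.SegmentationParams(), region.mask
    )
    rendvi = ripaq.re_ndvi(src)
    objects = cls.classify_objects(
        cls.object_features(segmap, composite, rendvi, src)
    )
    fine_truth = np.kron(
        truth.labels, np.ones((spec.pan_ratio, spec.pan_ratio), dtype=np.int32)
    )
    objects = objects.join(cls.majority_reference(segmap, fine_truth))
    cm = cls.confusion_matrix(
        objects["predicted_class"], objects["reference_class"]
    )
    class_raster = cls.paint_classes(segmap, objects["predicted_class"])
    stations = ripaq.make_stations(truth.centerline, n_stations)
    predicted = ripaq.score_stations(class_raster, composite.transform, stations)
    reference = ripaq.truth_station_scores(truth, stations)
    return {
        "seed": seed,
        "segmap": segmap,
        "objects": objects,
        "kappa": cls.cohens_kappa(cm),
        "accuracy": cls.overall_accuracy(cm),
        "predicted_scores": predicted,
        "reference_scores": reference,
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Recovery experiments for five seeds (shared: these are expensive)."""
    return [run_recovery(seed) for seed in (1, 2, 3, 4, 5)]
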