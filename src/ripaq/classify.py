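"""Object-based classification and accuracy assessment.

Segments become image objects carrying spectral and shape features; a
transparent hierarchical rule cascade assigns each object to water,
forest, crops or urban; a stratified random sample of objects is compared
against reference labels through a confusion matrix, overall accuracy and
Cohen's kappa.

The cascade mirrors how a photo-interpreter separates the classes:

1. water   — mean red-edge NDVI below ``t_water`` (no vegetation, dark NIR);
2. urban   — remaining objects that are bright (mean reflectance above
             ``t_urban_brightness``) yet weakly vegetated (RE-NDVI below
             ``t_urban_rendvi``);
3. forest vs crops — RE-NDVI at or above ``t_forest`` is forest, else crops.

Thresholds can be supplied directly or fitted as midpoints between class
centroids of labelled seed objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import CompositeRaster
from .scene import CLASS_CODES, CODE_NAMES, MultispectralImage
from .segmentation import SegmentMap, segment_stats

CLASS_SET = ("water", "forest", "crops", "urban", "bare_soil")


@dataclass(frozen=True)
class ClassifierConfig:
    t_water: float = 0.05
    t_urban_brightness: float = 0.20
    t_urban_rendvi: float = 0.15
    t_forest: float = 0.35
    fallback: str = "crops"

    def validate(self) -> None:
        if self.fallback not in CLASS_SET:
            raise ValueError(f"unknown fallback class {self.fallback!r}")


def object_features(
    segmap: SegmentMap,
    composite: CompositeRaster,
    rendvi: np.ndarray,
    ms: MultispectralImage,
) -> pd.DataFrame:
    """Feature table per image object.

    Composite band means/sds come from :func:`segment_stats`; mean raw
    RE-NDVI and brightness (mean reflectance across the 8 bands) are added
    because the rule cascade thresholds physical quantities, not the
    standardised composite.
    """
    df = segment_stats(segmap, composite)
    ids = segmap.segment_ids
    valid = ids > 0
    flat = ids[valid]
    k = segmap.n_segments
    counts = np.bincount(flat, minlength=k + 1)[1:]
    nd = np.bincount(flat, weights=rendvi[valid], minlength=k + 1)[1:]
    bright_px = ms.bands.mean(axis=2)
    br = np.bincount(flat, weights=bright_px[valid], minlength=k + 1)[1:]
    df["rendvi_mean"] = nd / counts
    df["brightness"] = br / counts
    return df


def classify_objects(
    features: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Apply the hierarchical rule cascade; adds a ``predicted_class`` column.

    Objects whose features are not finite fall through every rule and get
    the fallback class; their number is recorded in
    ``DataFrame.attrs['n_fallback']``.
    """
    config.validate()
    nd = features["rendvi_mean"].to_numpy(dtype=float)
    br = features["brightness"].to_numpy(dtype=float)
    pred = np.empty(len(features), dtype=object)
    ok = np.isfinite(nd) & np.isfinite(br)
    pred[~ok] = config.fallback
    water = ok & (nd < config.t_water)
    urban = ok & ~water & (br > config.t_urban_brightness) & (
        nd < config.t_urban_rendvi
    )
    forest = ok & ~water & ~urban & (nd >= config.t_forest)
    crops = ok & ~water & ~urban & ~forest
    pred[water] = "water"
    pred[urban] = "urban"
    pred[forest] = "forest"
    pred[crops] = "crops"
    out = features.copy()
    out["predicted_class"] = pred
    out.attrs["n_fallback"] = int(np.count_nonzero(~ok))
    return out


def fit_thresholds(
    features: pd.DataFrame, labels: pd.Series, config: ClassifierConfig | None = None
) -> ClassifierConfig:
    """Set cascade thresholds from labelled seed objects.

    Each threshold becomes the midpoint between the relevant class
    centroids (water vs rest on RE-NDVI, urban vs vegetated on brightness
    and RE-NDVI, forest vs crops on RE-NDVI).  Classes absent from the
    seeds keep the incoming default.
    """
    base = config or ClassifierConfig()
    nd = features["rendvi_mean"].groupby(labels).mean()
    br = features["brightness"].groupby(labels).mean()
    kw = {}
    veg = [c for c in ("forest", "crops") if c in nd.index]
    if "water" in nd.index and len(nd.index) > 1:
        others = nd.drop("water").min()
        kw["t_water"] = float((nd["water"] + others) / 2)
    if "urban" in br.index and veg:
        kw["t_urban_brightness"] = float((br["urban"] + br[veg].max()) / 2)
        kw["t_urban_rendvi"] = float((nd["urban"] + nd[veg].min()) / 2)
    if "forest" in nd.index and "crops" in nd.index:
        kw["t_forest"] = float((nd["forest"] + nd["crops"]) / 2)
    return replace(base, **kw)


def paint_classes(segmap: SegmentMap, predicted: pd.Series) -> np.ndarray:
    """Rasterise predicted object classes back to the pixel grid."""
    lut = np.zeros(segmap.n_segments + 1, dtype=np.int32)
    for sid, name in predicted.items():
        lut[sid] = CLASS_CODES[name]
    return lut[segmap.segment_ids]


def majority_reference(segmap: SegmentMap, truth_labels: np.ndarray) -> pd.Series:
    """Reference class per object: majority ground-truth label of its pixels."""
    ids = segmap.segment_ids
    valid = (ids > 0) & (truth_labels > 0)
    k = segmap.n_segments
    ncls = max(CLASS_CODES.values())
    joint = np.bincount(
        (ids[valid].astype(np.int64) * (ncls + 1)) + truth_labels[valid],
        minlength=(k + 1) * (ncls + 1),
    ).reshape(k + 1, ncls + 1)
    maj = joint[1:, 1:].argmax(axis=1) + 1
    return pd.Series(
        [CODE_NAMES[c] for c in maj], index=np.arange(1, k + 1), name="reference_class"
    )


def sample_validation_objects(
    objects: pd.DataFrame, n: int, seed: int
) -> pd.DataFrame:
    """Stratified random validation sample of ``n`` objects.

    Per-class allocation is proportional to predicted-class object counts
    with largest-remainder rounding; sampling within a class is uniform
    without replacement.
    """
    counts = objects["predicted_class"].value_counts().sort_index()
    if n < len(counts):
        raise ValueError("n is smaller than the number of classes present")
    if n > len(objects):
        raise ValueError("n exceeds the number of objects")
    alloc = allocate_proportional(counts.to_dict(), n)
    rng = np.random.default_rng(seed)
    picks = []
    for cls in counts.index:
        take = min(alloc[cls], counts[cls])
        pool = objects.index[objects["predicted_class"] == cls].to_numpy()
        picks.append(rng.choice(pool, size=take, replace=False))
    chosen = np.concatenate(picks)
    return objects.loc[np.sort(chosen)]


def allocate_proportional(counts: dict[str, int], n: int) -> dict[str, int]:
    """Largest-remainder integer split of ``n`` proportional to ``counts``."""
    names = sorted(counts)
    weights = np.array([counts[c] for c in names], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no objects to allocate")
    quota = weights / total * n
    base = np.floor(quota).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return dict(zip(names, base.tolist()))


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts, rows = predicted class, columns = reference class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be square and match the labels")
        if np.any(c < 0) or c.sum() == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(pred, ref, labels: tuple[str, ...] | None = None) -> ConfusionMatrix:
    pred = list(pred)
    ref = list(ref)
    if len(pred) != len(ref):
        raise ValueError("predicted and reference labels differ in length")
    if not pred:
        raise ValueError("empty label lists")
    if labels is None:
        labels = tuple(sorted(set(pred) | set(ref)))
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, r in zip(pred, ref):
        if p not in index or r not in index:
            raise ValueError(f"label outside the class set: {p!r}/{r!r}")
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of agreeing pairs: trace over total."""
    return float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    p_e = float(rows @ cols) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
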