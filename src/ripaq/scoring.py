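"""Riparian strip scoring: buffers, stations, land-cover composition,
RSQI, QBR categorisation and restoration triage.

The riparian strip quality index is a weighted average of land-cover
percentages inside the strip,

    RSQI = sum_i(%LU_i * W_i) / 10

with the standard weight table forest 10.0, crops 1.9, bare soil 1.7 and
infrastructure (built-up) 1.9, giving a 17-100 range.  Water is excluded
from the denominator: the strip is the land beside the channel, and the
weight table carries no water entry.

Stations are 100-m stretches of channel (50 m up- and downstream of the
station centre) evaluated separately per bank, each clipped to a 50-m
bank-side buffer.  QBR is the field counterpart: four 0-25 blocks scored
in steps of 5, summed to 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import substring

from .geo import GridTransform, line_side
from .scene import CODE_NAMES

#: Land-cover class weights W_i of the quality index.
DEFAULT_WEIGHTS: dict[str, float] = {
    "forest": 10.0,
    "crops": 1.9,
    "bare_soil": 1.7,
    "urban": 1.9,  # the infrastructure weight
}

STATION_LENGTH_M = 100.0


def check_weights(weights: dict[str, float]) -> None:
    for name, w in weights.items():
        if not 0 < w <= 10:
            raise ValueError(f"weight for {name!r} outside (0, 10]")


@dataclass(frozen=True)
class BufferRegion:
    """50-m stream buffer split into banks on the raster grid."""

    mask: np.ndarray  # bool, either bank
    left: np.ndarray
    right: np.ndarray


@dataclass(frozen=True)
class SamplingStation:
    id: str
    bank: str  # "left" | "right"
    chainage_m: float
    footprint: Polygon

    def __post_init__(self):
        if self.bank not in ("left", "right"):
            raise ValueError("bank must be 'left' or 'right'")
        if self.footprint.is_empty:
            raise ValueError("station footprint is empty")


def buffer_stream(
    centerline: LineString,
    transform: GridTransform,
    shape_hw: tuple[int, int],
    width_m: float = 50.0,
) -> BufferRegion:
    """Pixels whose centre lies within ``width_m`` of the centerline,
    split into left/right banks by the signed side of the local direction
    of travel."""
    if centerline.length <= 0 or len(centerline.coords) < 2:
        raise ValueError("degenerate centerline")
    xs, ys = transform.pixel_centres(shape_hw)
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = shapely.distance(centerline, pts).reshape(shape_hw)
    inside = dist <= width_m
    side = line_side(centerline, xs.ravel(), ys.ravel()).reshape(shape_hw)
    return BufferRegion(
        mask=inside, left=inside & (side > 0), right=inside & (side <= 0)
    )


def make_stations(
    centerline: LineString,
    n_stations: int,
    buffer_width_m: float = 50.0,
    banks: tuple[str, ...] = ("left", "right"),
) -> list[SamplingStation]:
    """Equally spaced 100-m stations along the channel, one per bank.

    Station centres sit at the midpoints of ``n_stations`` equal chainage
    intervals; each footprint is the 100-m sub-line buffered one-sided by
    the buffer width.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    length = centerline.length
    if length < n_stations * STATION_LENGTH_M:
        raise ValueError(
            f"centerline of {length:.0f} m too short for "
            f"{n_stations} stations of {STATION_LENGTH_M:.0f} m"
        )
    spacing = length / n_stations
    stations = []
    for k in range(n_stations):
        centre = (k + 0.5) * spacing
        sub = substring(centerline, centre - STATION_LENGTH_M / 2,
                        centre + STATION_LENGTH_M / 2)
        for bank in banks:
            sign = 1.0 if bank == "left" else -1.0
            poly = sub.buffer(
                sign * buffer_width_m, single_sided=True, quad_segs=8
            )
            poly = shapely.make_valid(poly)
            stations.append(
                SamplingStation(
                    id=f"S{k + 1:02d}{bank[0].upper()}",
                    bank=bank,
                    chainage_m=centre,
                    footprint=poly,
                )
            )
    return stations


def composition(
    class_raster: np.ndarray,
    transform: GridTransform,
    station: SamplingStation,
    exclude: frozenset[str] = frozenset({"water"}),
) -> dict[str, float]:
    """Land-cover percentages inside the station footprint.

    Pixel-centre inclusion; excluded classes (and nodata) are dropped and
    the remainder renormalised to 100%.
    """
    h, w = class_raster.shape
    minx, miny, maxx, maxy = station.footprint.bounds
    c0 = max(int((minx - transform.x0) / transform.px) - 1, 0)
    c1 = min(int(np.ceil((maxx - transform.x0) / transform.px)) + 1, w)
    r0 = max(int((transform.y0 - maxy) / transform.px) - 1, 0)
    r1 = min(int(np.ceil((transform.y0 - miny) / transform.px)) + 1, h)
    if c1 <= c0 or r1 <= r0:
        raise ValueError(f"station {station.id} does not intersect the raster")
    xs = transform.x0 + (np.arange(c0, c1) + 0.5) * transform.px
    ys = transform.y0 - (np.arange(r0, r1) + 0.5) * transform.px
    gx, gy = np.meshgrid(xs, ys)
    hit = shapely.contains_xy(station.footprint, gx.ravel(), gy.ravel())
    codes = class_raster[r0:r1, c0:c1].ravel()[hit]
    counts: dict[str, int] = {}
    for code in np.unique(codes):
        if code <= 0:
            continue
        name = CODE_NAMES[int(code)]
        if name in exclude:
            continue
        counts[name] = int(np.count_nonzero(codes == code))
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"station {station.id} has no scorable land pixels")
    return {name: 100.0 * cnt / total for name, cnt in counts.items()}


def rsqi(comp: dict[str, float], weights: dict[str, float] = DEFAULT_WEIGHTS) -> float:
    """Quality index sum_i(%LU_i * W_i) / 10 for one composition."""
    check_weights(weights)
    total = sum(comp.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"composition sums to {total}, not 100")
    score = 0.0
    for name, pct in comp.items():
        if pct < 0:
            raise ValueError("negative land-cover percentage")
        if name not in weights:
            raise ValueError(f"class {name!r} has no weight")
        score += pct * weights[name]
    return score / 10.0


def rsqi_category(score: float) -> str:
    if score < 0:
        raise ValueError("RSQI cannot be negative")
    if score < 40:
        return "very_low"
    if score < 60:
        return "low"
    if score < 80:
        return "moderate"
    return "high"


def qbr_total(blocks: tuple[int, int, int, int]) -> int:
    """Sum of the four QBR blocks (each 0-25 in steps of 5)."""
    if len(blocks) != 4:
        raise ValueError("QBR needs exactly four block scores")
    for b in blocks:
        if b not in (0, 5, 10, 15, 20, 25):
            raise ValueError(f"block score {b} not in {{0, 5, ..., 25}}")
    return int(sum(blocks))


def _check_qbr(total: int) -> None:
    if not (0 <= total <= 100) or total % 5 != 0:
        raise ValueError(f"QBR total {total} must be a multiple of 5 in [0, 100]")


def qbr_category(total: int) -> str:
    _check_qbr(total)
    if total >= 95:
        return "very_good"
    if total >= 75:
        return "good"
    if total >= 55:
        return "moderate"
    if total >= 30:
        return "poor"
    return "bad"


def restoration_action(total: int) -> str:
    """Triage: conservation above 90, recovery 55-90, restoration below 55."""
    _check_qbr(total)
    if total >= 95:
        return "conservation"
    if total >= 55:
        return "recovery"
    return "restoration"


def score_stations(
    class_raster: np.ndarray,
    transform: GridTransform,
    stations: list[SamplingStation],
    weights: dict[str, float] = DEFAULT_WEIGHTS,
    qbr_blocks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every station; optionally join field QBR block scores.

    ``qbr_blocks`` columns: station_id, block1..block4.
    """
    rows = []
    qbr_map = {}
    if qbr_blocks is not None:
        for _, rec in qbr_blocks.iterrows():
            blocks = tuple(int(rec[f"block{i}"]) for i in range(1, 5))
            qbr_map[str(rec["station_id"])] = qbr_total(blocks)
    for st in stations:
        comp = composition(class_raster, transform, st)
        score = rsqi(comp, weights)
        row = {
            "station_id": st.id,
            "bank": st.bank,
            "chainage_m": st.chainage_m,
            "rsqi": score,
            "rsqi_category": rsqi_category(score),
        }
        for name in weights:
            row[f"pct_{name}"] = comp.get(name, 0.0)
        if st.id in qbr_map:
            q = qbr_map[st.id]
            row["qbr"] = q
            row["qbr_category"] = qbr_category(q)
            row["action"] = restoration_action(q)
        rows.append(row)
    return pd.DataFrame(rows)
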