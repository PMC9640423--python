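"""Stream buffers, stations, land-cover composition, RSQI and QBR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Polygon

import ripaq
from ripaq.geo import GridTransform
from ripaq.scene import CLASS_CODES
from ripaq.scoring import (
    DEFAULT_WEIGHTS,
    SamplingStation,
    buffer_stream,
    composition,
    make_stations,
    qbr_category,
    qbr_total,
    restoration_action,
    rsqi,
    rsqi_category,
)


# --------------------------------------------------------------- buffers

def test_straight_centerline_buffer_is_a_band_split_by_bank():
    # horizontal west-to-east line through the middle of a 100 x 40 px grid
    t = GridTransform(0.0, 80.0, 2.0)
    line = LineString([(0.0, 40.0), (200.0, 40.0)])
    region = buffer_stream(line, t, (40, 100), width_m=50.0)
    # 50-m half-width at 2-m pixels: rows 15..24 above and below the line
    dist_rows = np.abs(80.0 - (np.arange(40) + 0.5) * 2.0 - 40.0)
    expected = dist_rows <= 50.0
    assert np.array_equal(region.mask[:, 50], expected)
    # travelling east, the left bank is the north (upper) half
    assert region.left[:20].any() and not region.left[20:].any()
    assert region.right[20:].any() and not region.right[:20].any()


def test_zero_width_keeps_only_pixels_on_the_line():
    t = GridTransform(0.0, 8.0, 2.0)
    line = LineString([(0.0, 5.0), (8.0, 5.0)])  # passes through row-1 centres
    region = buffer_stream(line, t, (4, 4), width_m=0.0)
    assert np.array_equal(np.nonzero(region.mask.any(axis=1))[0], [1])


def test_meander_buffer_area_matches_band_estimate():
    # gentle sine meander spanning the full grid, so end caps are clipped
    xs = np.linspace(0.0, 2000.0, 400)
    ys = 100.0 + 30.0 * np.sin(2 * np.pi * xs / 1000.0)
    line = LineString(np.column_stack([xs, ys]))
    t = GridTransform(0.0, 200.0, 4.0)
    region = buffer_stream(line, t, (50, 500), width_m=50.0)
    area = region.mask.sum() * 16.0
    assert area == pytest.approx(2 * 50.0 * line.length, rel=0.05)


def test_degenerate_centerline_rejected():
    t = GridTransform(0.0, 8.0, 2.0)
    with pytest.raises(ValueError):
        buffer_stream(LineString([(1.0, 1.0), (1.0, 1.0)]), t, (4, 4))


# -------------------------------------------------------------- stations

def _straight_line(length_m: float) -> LineString:
    return LineString([(0.0, 100.0), (length_m, 100.0)])


def test_fifteen_centres_give_thirty_stations():
    stations = make_stations(_straight_line(2000.0), 15)
    assert len(stations) == 30
    assert sum(s.bank == "left" for s in stations) == 15
    assert sum(s.bank == "right" for s in stations) == 15
    assert len({s.id for s in stations}) == 30


def test_single_centre_gives_left_and_right_station():
    stations = make_stations(_straight_line(150.0), 1)
    assert [s.bank for s in stations] == ["left", "right"]


def test_adjacent_footprints_do_not_overlap_when_spacing_exceeds_100m():
    stations = make_stations(_straight_line(2000.0), 10)  # 200-m spacing
    left = [s for s in stations if s.bank == "left"]
    for a, b in zip(left, left[1:]):
        assert a.footprint.intersection(b.footprint).area < 1e-6


def test_too_short_centerline_rejected():
    with pytest.raises(ValueError):
        make_stations(_straight_line(900.0), 15)


# ----------------------------------------------------------- composition

def _square_station(x0, y0, size) -> SamplingStation:
    poly = Polygon(
        [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]
    )
    return SamplingStation(id="T01L", bank="left", chainage_m=0.0, footprint=poly)


def test_composition_counts_and_percentages():
    t = GridTransform(0.0, 20.0, 2.0)
    raster = np.zeros((10, 10), dtype=np.int32)
    raster[:6, :] = CLASS_CODES["forest"]  # 60 px
    raster[6:, :] = CLASS_CODES["crops"]  # 40 px
    comp = composition(raster, t, _square_station(0, 0, 20))
    assert comp == pytest.approx({"forest": 60.0, "crops": 40.0})


def test_composition_excludes_water_and_renormalises():
    t = GridTransform(0.0, 20.0, 2.0)
    raster = np.zeros((10, 10), dtype=np.int32)
    raster[:5, :] = CLASS_CODES["water"]  # 50 px dropped
    raster[5:8, :] = CLASS_CODES["forest"]  # 30 px -> 60 %
    raster[8:, :] = CLASS_CODES["crops"]  # 20 px -> 40 %
    comp = composition(raster, t, _square_station(0, 0, 20))
    assert comp == pytest.approx({"forest": 60.0, "crops": 40.0})


def test_all_water_station_rejected():
    t = GridTransform(0.0, 20.0, 2.0)
    raster = np.full((10, 10), CLASS_CODES["water"], dtype=np.int32)
    with pytest.raises(ValueError):
        composition(raster, t, _square_station(0, 0, 20))


# ------------------------------------------------------------------ RSQI

@pytest.mark.parametrize(
    "comp,expected",
    [
        ({"forest": 100.0}, 100.0),
        ({"bare_soil": 100.0}, 17.0),
        ({"forest": 60.0, "crops": 40.0}, 67.6),
        ({"forest": 50.0, "crops": 30.0, "urban": 20.0}, 59.5),
    ],
)
def test_rsqi_hand_computed_values(comp, expected):
    assert rsqi(comp) == pytest.approx(expected)


def test_rsqi_rejects_unknown_class_and_bad_totals():
    with pytest.raises(ValueError):
        rsqi({"wetland": 100.0})
    with pytest.raises(ValueError):
        rsqi({"forest": 70.0})


@given(
    forest=st.floats(0, 100),
    shift=st.floats(0, 100),
    other=st.sampled_from(["crops", "bare_soil", "urban"]),
)
@settings(max_examples=100, deadline=None)
def test_rsqi_monotone_in_forest_share(forest, shift, other):
    """Moving share from any other class to forest never lowers the score."""
    rest = 100.0 - forest
    shift = min(shift, rest)
    base = rsqi({"forest": forest, other: rest})
    better = rsqi({"forest": forest + shift, other: rest - shift})
    assert better >= base - 1e-9


def test_rsqi_bounds_under_default_weights():
    lo = min(rsqi({c: 100.0}) for c in DEFAULT_WEIGHTS)
    hi = max(rsqi({c: 100.0}) for c in DEFAULT_WEIGHTS)
    assert lo == pytest.approx(17.0)
    assert hi == pytest.approx(100.0)


# ------------------------------------------------------------- categories

@pytest.mark.parametrize(
    "score,category",
    [(37.0, "very_low"), (94.0, "high"), (71.57, "moderate"),
     (39.99, "very_low"), (40.0, "low"), (60.0, "moderate"), (80.0, "high")],
)
def test_rsqi_categories(score, category):
    assert rsqi_category(score) == category


def test_qbr_total_examples():
    assert qbr_total((25, 25, 25, 25)) == 100
    assert qbr_total((0, 0, 0, 0)) == 0
    assert qbr_total((15, 15, 15, 10)) == 55
    with pytest.raises(ValueError):
        qbr_total((12, 10, 10, 10))
    with pytest.raises(ValueError):
        qbr_total((30, 10, 10, 10))


@pytest.mark.parametrize(
    "total,category",
    [(100, "very_good"), (95, "very_good"), (90, "good"), (75, "good"),
     (70, "moderate"), (55, "moderate"), (50, "poor"), (30, "poor"),
     (25, "bad"), (0, "bad")],
)
def test_qbr_categories(total, category):
    assert qbr_category(total) == category


@pytest.mark.parametrize(
    "total,action",
    [(95, "conservation"), (100, "conservation"), (90, "recovery"),
     (60, "recovery"), (55, "recovery"), (50, "restoration"),
     (40, "restoration"), (0, "restoration")],
)
def test_restoration_triage(total, action):
    assert restoration_action(total) == action


def test_category_functions_total_on_their_domains():
    for total in range(0, 101, 5):
        assert qbr_category(total) in {
            "very_good", "good", "moderate", "poor", "bad"
        }
        assert restoration_action(total) in {
            "conservation", "recovery", "restoration"
        }
    for score in np.linspace(0, 100, 2001):
        assert rsqi_category(score) in {"very_low", "low", "moderate", "high"}


def test_score_stations_joins_field_qbr(small_scene):
    import pandas as pd

    _, _, _, truth = small_scene
    stations = make_stations(truth.centerline, 2)
    qbr = pd.DataFrame(
        {
            "station_id": [s.id for s in stations],
            "block1": 15, "block2": 15, "block3": 15, "block4": 10,
        }
    )
    table = ripaq.score_stations(
        truth.labels, truth.transform, stations, qbr_blocks=qbr
    )
    assert len(table) == 4
    assert (table["qbr"] == 55).all()
    assert (table["qbr_category"] == "moderate").all()
    assert (table["action"] == "recovery").all()
    assert table["rsqi"].between(17, 100).all()
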