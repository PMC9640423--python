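"""Pansharpening, RE-NDVI, PCA and composite assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ripaq
from ripaq.geo import GridTransform
from ripaq.preprocess import (
    NIR_BAND,
    RE_BAND,
    build_composite,
    pansharpen,
    pca_reduce,
    re_ndvi,
)
from ripaq.scene import MultispectralImage, PanImage


def _ms_from(bands: np.ndarray, px: float = 2.0) -> MultispectralImage:
    h = bands.shape[0]
    return MultispectralImage(
        bands=bands, resolution=px, transform=GridTransform(0.0, h * px, px)
    )


def _stack(nir: float, re: float, shape=(2, 2)) -> MultispectralImage:
    bands = np.full(shape + (8,), 0.1)
    bands[:, :, NIR_BAND] = nir
    bands[:, :, RE_BAND] = re
    return _ms_from(bands)


# ---------------------------------------------------------------- RE-NDVI

@pytest.mark.parametrize(
    "nir,re,expected",
    [(0.30, 0.10, 0.5), (0.25, 0.25, 0.0), (0.6, 0.2, 0.5), (0.1, 0.3, -0.5)],
)
def test_re_ndvi_point_values(nir, re, expected):
    out = re_ndvi(_stack(nir, re))
    assert np.allclose(out, expected)


def test_re_ndvi_undefined_where_both_bands_zero():
    out = re_ndvi(_stack(0.0, 0.0))
    assert np.all(np.isnan(out))


def test_re_ndvi_propagates_nodata():
    ms = _stack(0.3, 0.1)
    bands = ms.bands.copy()
    bands[0, 0, NIR_BAND] = np.nan
    out = re_ndvi(_ms_from(bands))
    assert np.isnan(out[0, 0]) and np.isfinite(out[1, 1])


@given(
    nir=st.floats(0.01, 1.0, allow_nan=False),
    re=st.floats(0.01, 1.0, allow_nan=False),
)
@settings(max_examples=50, deadline=None)
def test_re_ndvi_antisymmetric_and_bounded(nir, re):
    fwd = re_ndvi(_stack(nir, re))[0, 0]
    rev = re_ndvi(_stack(re, nir))[0, 0]
    assert fwd == pytest.approx(-rev, abs=1e-12)
    assert -1.0 <= fwd <= 1.0


# ------------------------------------------------------------ pansharpen

def test_constant_inputs_pass_through():
    ms = _stack(0.3, 0.1, shape=(4, 4))
    pan = PanImage(
        values=np.full((16, 16), 0.25),
        resolution=0.5,
        transform=ms.transform.refine(4),
    )
    sharp = pansharpen(ms, pan)
    assert sharp.bands.shape == (16, 16, 8)
    assert np.allclose(sharp.bands[:, :, NIR_BAND], 0.3)
    assert np.allclose(sharp.bands[:, :, RE_BAND], 0.1)


def test_unit_ratio_is_identity():
    rng = np.random.default_rng(0)
    ms = _ms_from(rng.uniform(0.05, 0.6, (8, 8, 8)))
    pan = PanImage(
        values=rng.uniform(0, 1, (8, 8)), resolution=2.0, transform=ms.transform
    )
    sharp = pansharpen(ms, pan)
    assert np.allclose(sharp.bands, ms.bands)


def test_downsampled_sharp_product_recovers_band_means():
    """Wald-style spectral consistency on a seeded synthetic scene."""
    spec = ripaq.SceneSpec(width_px=64, height_px=96, seed=7)
    ms, pan, _ = ripaq.generate_scene(spec)
    sharp = pansharpen(ms, pan)
    down = _block(sharp.bands, spec.pan_ratio)
    rel = np.abs(down.mean(axis=(0, 1)) - ms.bands.mean(axis=(0, 1)))
    rel /= ms.bands.mean(axis=(0, 1))
    assert np.all(rel < 0.01)


def _block(a, r):
    h, w = a.shape[:2]
    return a.reshape(h // r, r, w // r, r, -1).mean(axis=(1, 3))


def test_mismatched_extent_rejected():
    ms = _stack(0.3, 0.1, shape=(4, 4))
    pan = PanImage(
        values=np.zeros((12, 16)), resolution=0.5,
        transform=ms.transform.refine(4),
    )
    with pytest.raises(ValueError):
        pansharpen(ms, pan)


def test_non_integer_ratio_rejected():
    ms = _stack(0.3, 0.1, shape=(4, 4))
    pan = PanImage(
        values=np.zeros((10, 10)), resolution=0.8,
        transform=GridTransform(0.0, 8.0, 0.8),
    )
    with pytest.raises(ValueError):
        pansharpen(ms, pan)


# ------------------------------------------------------------------- PCA

def test_single_varying_band_concentrates_variance():
    rng = np.random.default_rng(1)
    bands = np.full((10, 10, 8), 0.2)
    bands[:, :, 3] = rng.uniform(0, 1, (10, 10))
    _, explained = pca_reduce(_ms_from(bands), 1)
    assert explained[0] == pytest.approx(1.0)


def test_explained_variance_fractions_sum_to_one():
    rng = np.random.default_rng(2)
    ms = _ms_from(rng.uniform(0, 1, (12, 9, 8)))
    _, explained = pca_reduce(ms, 3)
    assert sum(explained) == pytest.approx(1.0, abs=1e-9)
    assert all(explained[i] >= explained[i + 1] for i in range(7))


def test_collinear_two_band_toy_recovers_the_diagonal_axis():
    """Pixels (0,0),(1,1),(2,2) on two active bands: PC1 along (1,1)/sqrt(2)."""
    bands = np.full((1, 3, 8), 0.5)
    bands[0, :, 0] = [0.0, 1.0, 2.0]
    bands[0, :, 1] = [0.0, 1.0, 2.0]
    scores, explained, comps, mean = pca_reduce(
        _ms_from(bands), 1, return_model=True
    )
    assert explained[0] == pytest.approx(1.0)
    assert abs(comps[0, 0]) == pytest.approx(1 / np.sqrt(2))
    assert abs(comps[1, 0]) == pytest.approx(1 / np.sqrt(2))
    assert np.allclose(
        np.sort(scores.ravel()), [-np.sqrt(2), 0.0, np.sqrt(2)]
    )


def test_full_rank_projection_reconstructs_centred_data():
    rng = np.random.default_rng(3)
    ms = _ms_from(rng.uniform(0, 1, (15, 11, 8)))
    scores, _, comps, mean = pca_reduce(ms, 8, return_model=True)
    recon = scores.reshape(-1, 8) @ comps.T + mean
    err = np.abs(recon - ms.bands.reshape(-1, 8)).max()
    assert err < 1e-6 * np.abs(ms.bands).max()


def test_pca_rejects_bad_inputs():
    with pytest.raises(ValueError):
        pca_reduce(_stack(0.3, 0.1), 9)
    bands = np.full((3, 3, 8), np.nan)
    with pytest.raises(ValueError):
        pca_reduce(_ms_from(bands), 2)


def test_pca_matches_reference_implementation():
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(4)
    ms = _ms_from(rng.uniform(0, 1, (20, 20, 8)))
    scores, explained = pca_reduce(ms, 3)
    ref = sklearn.PCA(n_components=8).fit(ms.bands.reshape(-1, 8))
    assert np.allclose(explained, ref.explained_variance_ratio_, atol=1e-9)
    ref_scores = ref.transform(ms.bands.reshape(-1, 8))[:, :3]
    # same subspace up to per-component sign
    assert np.allclose(
        np.abs(scores.reshape(-1, 3)), np.abs(ref_scores), atol=1e-8
    )


# ------------------------------------------------------------- composite

def test_composite_has_four_standardised_bands():
    rng = np.random.default_rng(5)
    ms = _ms_from(rng.uniform(0, 1, (16, 16, 8)))
    pcs, explained = pca_reduce(ms, 3)
    comp = build_composite(pcs, explained, re_ndvi(ms), ms.transform)
    assert comp.bands.shape[2] == 4
    assert comp.band_names == ("pc1", "pc2", "pc3", "re_ndvi")
    mu = np.nanmean(comp.bands, axis=(0, 1))
    sd = np.nanstd(comp.bands, axis=(0, 1))
    assert np.all(np.abs(mu) < 1e-9)
    assert np.allclose(sd, 1.0)


def test_composite_propagates_nodata_across_bands():
    rng = np.random.default_rng(6)
    ms = _ms_from(rng.uniform(0.1, 0.9, (8, 8, 8)))
    pcs, explained = pca_reduce(ms, 3)
    ndvi = re_ndvi(ms)
    ndvi[2, 3] = np.nan
    comp = build_composite(pcs, explained, ndvi, ms.transform)
    assert np.all(np.isnan(comp.bands[2, 3, :]))
    assert np.all(np.isfinite(comp.bands[0, 0, :]))


def test_composite_rejects_grid_mismatch():
    rng = np.random.default_rng(7)
    ms = _ms_from(rng.uniform(0, 1, (8, 8, 8)))
    pcs, explained = pca_reduce(ms, 3)
    with pytest.raises(ValueError):
        build_composite(pcs, explained, np.zeros((4, 4)), ms.transform)
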