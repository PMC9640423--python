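"""Image preprocessing: pansharpening, RE-NDVI, PCA and the analysis composite.

The analysis composite is the 4-band stack [PC1, PC2, PC3, RE-NDVI] (each
band standardised over valid pixels) that feeds segmentation.  The red-edge
NDVI uses the NIR1 (band 7) and red-edge (band 6) reflectances:

    RE-NDVI = (NIR - RE) / (NIR + RE)

Pansharpening follows a least-squares component-substitution scheme: the
panchromatic band, block-averaged to the multispectral grid, is regressed
on the 8 MS bands to obtain a synthetic low-resolution intensity; the
high-frequency detail (PAN minus upsampled intensity) is injected into
each upsampled band with a per-band gain cov(band, intensity)/var(intensity).
By construction, block-averaging the sharpened product back to the MS grid
recovers the original band values up to the regression residual, which is
zero on noiseless scenes (Wald-style spectral consistency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import GridTransform
from .scene import BAND_NAMES, N_BANDS, MultispectralImage, PanImage

RE_BAND = BAND_NAMES.index("red_edge")  # band 6 (0-based 5)
NIR_BAND = BAND_NAMES.index("nir1")  # band 7 (0-based 6)


@dataclass(frozen=True)
class CompositeRaster:
    """4-band analysis stack: three principal components plus RE-NDVI."""

    bands: np.ndarray  # H x W x 4, NaN = nodata
    band_names: tuple[str, ...]
    explained_variance: tuple[float, ...]
    transform: GridTransform

    def __post_init__(self):
        ev = self.explained_variance
        if any(e < -1e-12 or e > 1 + 1e-12 for e in ev):
            raise ValueError("explained variance fractions must lie in [0, 1]")
        if any(ev[i] < ev[i + 1] - 1e-12 for i in range(len(ev) - 1)):
            raise ValueError("explained variance must be non-increasing")


def _block_mean(a: np.ndarray, r: int) -> np.ndarray:
    h, w = a.shape[:2]
    return a.reshape(h // r, r, w // r, r, *a.shape[2:]).mean(axis=(1, 3))


def _upsample(a: np.ndarray, r: int) -> np.ndarray:
    return np.repeat(np.repeat(a, r, axis=0), r, axis=1)


def pansharpen(ms: MultispectralImage, pan: PanImage) -> MultispectralImage:
    """Fuse the PAN band into the MS stack at PAN resolution."""
    ratio = ms.resolution / pan.resolution
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9 or r < 1:
        raise ValueError(f"PAN/MS resolution ratio {ratio} is not an integer")
    h, w = ms.bands.shape[:2]
    if pan.values.shape != (h * r, w * r):
        raise ValueError("PAN extent does not match the MS extent")
    if (
        abs(ms.transform.x0 - pan.transform.x0) > 1e-6
        or abs(ms.transform.y0 - pan.transform.y0) > 1e-6
    ):
        raise ValueError("PAN and MS rasters are not co-registered")
    if r == 1:
        return MultispectralImage(
            bands=ms.bands.copy(), resolution=pan.resolution, transform=pan.transform
        )

    pan_low = _block_mean(pan.values, r)
    X = ms.bands.reshape(-1, N_BANDS)
    design = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(design, pan_low.ravel(), rcond=None)
    intensity = (design @ coef).reshape(h, w)

    var_i = intensity.var()
    if var_i < 1e-15:
        gains = np.zeros(N_BANDS)
    else:
        centred_i = (intensity - intensity.mean()).ravel()
        gains = (X - X.mean(axis=0)).T @ centred_i / (len(centred_i) * var_i)

    detail = pan.values - _upsample(intensity, r)
    sharp = _upsample(ms.bands, r) + detail[:, :, None] * gains[None, None, :]
    return MultispectralImage(
        bands=sharp, resolution=pan.resolution, transform=pan.transform
    )


def re_ndvi(ms: MultispectralImage) -> np.ndarray:
    """Red-edge NDVI raster in [-1, 1]; NaN where undefined or nodata."""
    nir = ms.bands[:, :, NIR_BAND].astype(float)
    re = ms.bands[:, :, RE_BAND].astype(float)
    denom = nir + re
    out = np.full(denom.shape, np.nan)
    ok = np.isfinite(denom) & (denom != 0)
    out[ok] = (nir[ok] - re[ok]) / denom[ok]
    return out


def pca_reduce(ms: MultispectralImage, n_components: int = 3, *,
               return_model: bool = False):
    """Project the band stack onto the leading principal components.

    The eigendecomposition is of the band covariance matrix over valid
    (finite) pixels.  Returns ``(scores, explained)`` where ``scores`` is
    H x W x n_components (NaN outside the valid mask) and ``explained``
    holds all 8 variance fractions in descending order.  With
    ``return_model`` the orthonormal loading matrix (bands x components)
    and the band mean vector are appended.
    """
    if not 1 <= n_components <= N_BANDS:
        raise ValueError("n_components must be in 1..8")
    X = ms.bands.reshape(-1, N_BANDS).astype(float)
    valid = np.all(np.isfinite(X), axis=1)
    if not np.any(valid):
        raise ValueError("image has no valid pixels")
    Xv = X[valid]
    mean = Xv.mean(axis=0)
    cov = np.cov(Xv - mean, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(N_BANDS)])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    total = eigval.sum()
    explained = (
        tuple(float(v) for v in eigval / total)
        if total > 0
        else (0.0,) * N_BANDS
    )

    h, w = ms.bands.shape[:2]
    scores = np.full((h * w, n_components), np.nan)
    scores[valid] = (Xv - mean) @ eigvec[:, :n_components]
    scores = scores.reshape(h, w, n_components)
    if return_model:
        return scores, explained, eigvec[:, :n_components], mean
    return scores, explained


def build_composite(
    pcs: np.ndarray,
    explained: tuple[float, ...],
    rendvi: np.ndarray,
    transform: GridTransform,
) -> CompositeRaster:
    """Stack principal components and RE-NDVI, standardised band-wise.

    Each band is scaled to zero mean and unit variance over valid pixels
    so colour heterogeneity in segmentation weighs the bands comparably;
    NaN in any input band propagates to all composite bands of that pixel.
    """
    if pcs.shape[:2] != rendvi.shape:
        raise ValueError("principal-component and RE-NDVI grids do not match")
    stack = np.dstack([pcs, rendvi[:, :, None]]).astype(float)
    valid = np.all(np.isfinite(stack), axis=2)
    stack[~valid] = np.nan
    for b in range(stack.shape[2]):
        band = stack[:, :, b]
        mu = np.nanmean(band[valid]) if np.any(valid) else np.nan
        sd = np.nanstd(band[valid]) if np.any(valid) else np.nan
        if not np.isfinite(sd) or sd == 0:
            band[valid] = 0.0
        else:
            band[valid] = (band[valid] - mu) / sd
    names = tuple(f"pc{i + 1}" for i in range(pcs.shape[2])) + ("re_ndvi",)
    return CompositeRaster(
        bands=stack,
        band_names=names,
        explained_variance=tuple(explained[: pcs.shape[2]]),
        transform=transform,
    )


def make_composite(
    ms: MultispectralImage,
    pan: PanImage | None = None,
    *,
    n_pcs: int = 3,
    sharpen: bool = True,
) -> tuple[CompositeRaster, MultispectralImage]:
    """Run the preprocessing chain and return (composite, source image).

    With ``sharpen`` the chain operates on the pansharpened stack at PAN
    resolution; otherwise on the native MS grid.
    """
    src = pansharpen(ms, pan) if (sharpen and pan is not None) else ms
    pcs, explained = pca_reduce(src, n_components=n_pcs)
    ndvi = re_ndvi(src)
    return build_composite(pcs, explained, ndvi, src.transform), src


def mean_composites(composites: list[CompositeRaster]) -> CompositeRaster:
    """Band-wise mean of per-date composites (multi-date unification)."""
    if not composites:
        raise ValueError("no composites to merge")
    ref = composites[0]
    stack = np.stack([c.bands for c in composites])
    return CompositeRaster(
        bands=np.nanmean(stack, axis=0),
        band_names=ref.band_names,
        explained_variance=ref.explained_variance,
        transform=ref.transform,
    )
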