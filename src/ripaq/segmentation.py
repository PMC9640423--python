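"""Multiresolution region-merging segmentation of the analysis composite.

Bottom-up pairwise merging in the Baatz-Schäpe style: every valid pixel
starts as its own segment and adjacent segments merge while the fusion
cost stays below ``scale**2``.  The cost blends colour heterogeneity
(growth of size-weighted per-band standard deviation) with shape
heterogeneity (compactness and smoothness, both perimeter-based):

    f       = shape_w * h_shape + (1 - shape_w) * h_colour
    h_colour = sum_b [ n_m sd_m,b - (n_1 sd_1,b + n_2 sd_2,b) ]
    h_shape = compact_w * h_cmpct + (1 - compact_w) * h_smooth
    h_cmpct = n_m P_m / sqrt(n_m) - (n_1 P_1 / sqrt(n_1) + n_2 P_2 / sqrt(n_2))
    h_smooth = n_m P_m / b_m - (n_1 P_1 / b_1 + n_2 P_2 / b_2)

with P the segment perimeter in pixel edges, b the bounding-box perimeter
and sd the population standard deviation.  Merging uses local mutual
best fitting: in deterministic sweeps (ascending segment id, ids being the
row-major index of the segment's first pixel) a segment merges with its
cheapest neighbour only if it is that neighbour's cheapest partner too;
ties go to the lowest neighbour id, and sweeps repeat to a fixed point.
Pixels are 4-connected; band weights are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .preprocess import CompositeRaster


@dataclass(frozen=True)
class SegmentationParams:
    scale: float = 25.0
    shape_weight: float = 0.1
    compactness_weight: float = 0.1

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0 <= self.shape_weight <= 1:
            raise ValueError("shape_weight must lie in [0, 1]")
        if not 0 <= self.compactness_weight <= 1:
            raise ValueError("compactness_weight must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentMap:
    """Pixel partition: ids 1..n_segments, 0 outside the segmented region."""

    segment_ids: np.ndarray  # H x W int32
    n_segments: int
    adjacency: frozenset  # of (i, j) pairs, i < j


def multiresolution_segment(
    composite: CompositeRaster,
    params: SegmentationParams = SegmentationParams(),
    mask: np.ndarray | None = None,
) -> SegmentMap:
    """Segment the composite within ``mask`` (default: all pixels)."""
    bands = composite.bands
    h, w, nb = bands.shape
    if mask is None:
        region = np.ones((h, w), dtype=bool)
    else:
        region = np.asarray(mask, dtype=bool)
        if region.shape != (h, w):
            raise ValueError("mask shape does not match the composite")
    if not region.any():
        raise ValueError("segmentation mask is empty")
    if not np.all(np.isfinite(bands[region])):
        raise ValueError("non-finite composite values inside the mask")

    scale2 = params.scale * params.scale
    sw = params.shape_weight
    cw = params.compactness_weight

    lin = np.full((h, w), -1, dtype=np.int64)
    rr, cc = np.nonzero(region)
    lin[rr, cc] = rr * w + cc

    # per-segment state, keyed by the row-major index of the first pixel
    n: dict[int, int] = {}
    sm: dict[int, list[float]] = {}
    sq: dict[int, list[float]] = {}
    per: dict[int, int] = {}
    bbox: dict[int, tuple[int, int, int, int]] = {}
    nbr: dict[int, dict[int, int]] = {}

    for r, c in zip(rr.tolist(), cc.tolist()):
        sid = r * w + c
        vals = bands[r, c]
        n[sid] = 1
        sm[sid] = [float(v) for v in vals]
        sq[sid] = [float(v) * float(v) for v in vals]
        per[sid] = 4
        bbox[sid] = (r, r, c, c)
        d: dict[int, int] = {}
        if c + 1 < w and lin[r, c + 1] >= 0:
            d[sid + 1] = 1
        if c > 0 and lin[r, c - 1] >= 0:
            d[sid - 1] = 1
        if r + 1 < h and lin[r + 1, c] >= 0:
            d[sid + w] = 1
        if r > 0 and lin[r - 1, c] >= 0:
            d[sid - w] = 1
        nbr[sid] = d

    memo: dict[tuple[int, int], float] = {}
    parent: dict[int, int] = {}  # merged-away id -> absorbing id

    def cost(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        f = memo.get(key)
        if f is not None:
            return f
        n1 = n[a]
        n2 = n[b]
        nm = n1 + n2
        sma, sqa, smb, sqb = sm[a], sq[a], sm[b], sq[b]
        h_col = 0.0
        for i in range(nb):
            s1 = sma[i]
            q1 = sqa[i]
            s2 = smb[i]
            q2 = sqb[i]
            v1 = q1 / n1 - (s1 / n1) ** 2
            v2 = q2 / n2 - (s2 / n2) ** 2
            vm = (q1 + q2) / nm - ((s1 + s2) / nm) ** 2
            h_col += (
                nm * (sqrt(vm) if vm > 0 else 0.0)
                - n1 * (sqrt(v1) if v1 > 0 else 0.0)
                - n2 * (sqrt(v2) if v2 > 0 else 0.0)
            )
        if sw > 0:
            p1, p2 = per[a], per[b]
            pm = p1 + p2 - 2 * nbr[a][b]
            h_cmp = sqrt(nm) * pm - (sqrt(n1) * p1 + sqrt(n2) * p2)
            r0a, r1a, c0a, c1a = bbox[a]
            r0b, r1b, c0b, c1b = bbox[b]
            bm = 2 * (
                (max(r1a, r1b) - min(r0a, r0b) + 1)
                + (max(c1a, c1b) - min(c0a, c0b) + 1)
            )
            b1 = 2 * ((r1a - r0a + 1) + (c1a - c0a + 1))
            b2 = 2 * ((r1b - r0b + 1) + (c1b - c0b + 1))
            h_smo = nm * pm / bm - (n1 * p1 / b1 + n2 * p2 / b2)
            h_shape = cw * h_cmp + (1 - cw) * h_smo
        else:
            h_shape = 0.0
        f = sw * h_shape + (1 - sw) * h_col
        memo[key] = f
        return f

    def best(a: int) -> tuple[int, float] | None:
        out_t = -1
        out_f = float("inf")
        for t in nbr[a]:
            f = cost(a, t)
            if f < out_f or (f == out_f and t < out_t):
                out_f = f
                out_t = t
        return None if out_t < 0 else (out_t, out_f)

    def merge(a: int, b: int) -> None:
        u, v = (a, b) if a < b else (b, a)
        # invalidate cached costs touching either side
        for x in nbr[u]:
            memo.pop((u, x) if u < x else (x, u), None)
        for x in nbr[v]:
            memo.pop((v, x) if v < x else (x, v), None)
        n[u] += n[v]
        smu, smv, squ, sqv = sm[u], sm[v], sq[u], sq[v]
        for i in range(nb):
            smu[i] += smv[i]
            squ[i] += sqv[i]
        per[u] = per[u] + per[v] - 2 * nbr[u][v]
        r0a, r1a, c0a, c1a = bbox[u]
        r0b, r1b, c0b, c1b = bbox[v]
        bbox[u] = (min(r0a, r0b), max(r1a, r1b), min(c0a, c0b), max(c1a, c1b))
        du = nbr[u]
        del du[v]
        for x, cnt in nbr[v].items():
            if x == u:
                continue
            du[x] = du.get(x, 0) + cnt
            dx = nbr[x]
            del dx[v]
            dx[u] = dx.get(u, 0) + cnt
        del n[v], sm[v], sq[v], per[v], bbox[v], nbr[v]
        parent[v] = u

    while True:
        merged_any = False
        for s in sorted(n):
            if s not in n:
                continue
            found = best(s)
            if found is None:
                continue
            t, f = found
            if not f < scale2:
                continue
            back = best(t)
            if back is not None and back[0] == s:
                merge(s, t)
                merged_any = True
        if not merged_any:
            break

    return _finalise(lin, nbr, parent, h, w)


def _finalise(lin, nbr, parent, h, w) -> SegmentMap:
    """Relabel surviving segments 1..k in row-major order of first pixel."""

    def resolve(x: int) -> int:
        path = []
        while x in parent:
            path.append(x)
            x = parent[x]
        for p in path:
            parent[p] = x
        return x

    seg_ids = np.zeros((h, w), dtype=np.int32)
    new_id: dict[int, int] = {}
    rr, cc = np.nonzero(lin >= 0)
    for r, c in zip(rr.tolist(), cc.tolist()):
        root = resolve(int(lin[r, c]))
        sid = new_id.get(root)
        if sid is None:
            sid = len(new_id) + 1
            new_id[root] = sid
        seg_ids[r, c] = sid
    pairs = set()
    for a, d in nbr.items():
        ia = new_id[a]
        for b in d:
            ib = new_id[b]
            pairs.add((ia, ib) if ia < ib else (ib, ia))
    return SegmentMap(
        segment_ids=seg_ids, n_segments=len(new_id), adjacency=frozenset(pairs)
    )


def segment_stats(segmap: SegmentMap, composite: CompositeRaster) -> pd.DataFrame:
    """Per-segment band means/sds (population), pixel areas and perimeters."""
    ids = segmap.segment_ids
    bands = composite.bands
    if ids.shape != bands.shape[:2]:
        raise ValueError("segment map and composite grids do not match")
    k = segmap.n_segments
    valid = ids > 0
    flat = ids[valid]
    counts = np.bincount(flat, minlength=k + 1)[1:]
    rows = {"segment_id": np.arange(1, k + 1), "area_px": counts}
    for b, name in enumerate(composite.band_names):
        vals = bands[:, :, b][valid]
        s = np.bincount(flat, weights=vals, minlength=k + 1)[1:]
        q = np.bincount(flat, weights=vals * vals, minlength=k + 1)[1:]
        mean = s / counts
        var = np.maximum(q / counts - mean**2, 0.0)
        rows[f"mean_{name}"] = mean
        rows[f"sd_{name}"] = np.sqrt(var)
    rows["perimeter_px"] = _perimeters(ids, k)
    df = pd.DataFrame(rows).set_index("segment_id")
    df["compactness"] = df["perimeter_px"] / np.sqrt(df["area_px"])
    return df


def _perimeters(ids: np.ndarray, k: int) -> np.ndarray:
    """Boundary edge count per segment (image border and nodata included)."""
    h, w = ids.shape
    padded = np.zeros((h + 2, w + 2), dtype=ids.dtype)
    padded[1:-1, 1:-1] = ids
    perim = np.zeros(k + 1, dtype=np.int64)
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nb = padded[1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc]
        edge = (ids > 0) & (nb != ids)
        perim += np.bincount(ids[edge], minlength=k + 1)
    return perim[1:]
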