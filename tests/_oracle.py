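"""Brute-force region-merging oracle for tiny images.

Independent of the production implementation: segments are explicit pixel
sets and every statistic (mean, sd, perimeter, bounding box) is recomputed
from scratch at each cost evaluation.  Applies the same fusion criterion,
threshold and tie-breaking rules so partitions are directly comparable on
instances small enough to afford the quadratic recomputation.
"""

from __future__ import annotations

from math import sqrt

import numpy as np


def _stats(pixels: frozenset, values: np.ndarray):
    arr = np.array(sorted(pixels))
    vals = values[arr[:, 0], arr[:, 1], :]
    n = len(pixels)
    sds = vals.std(axis=0)  # population sd
    perim = 0
    for r, c in pixels:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            if (r + dr, c + dc) not in pixels:
                perim += 1
    r0, c0 = arr.min(axis=0)
    r1, c1 = arr.max(axis=0)
    return n, sds, perim, 2 * ((r1 - r0 + 1) + (c1 - c0 + 1))


def _merged_bbox_perim(a: frozenset, b: frozenset):
    arr = np.array(sorted(a | b))
    r0, c0 = arr.min(axis=0)
    r1, c1 = arr.max(axis=0)
    return 2 * ((r1 - r0 + 1) + (c1 - c0 + 1))


def oracle_segment(
    values: np.ndarray,
    scale: float,
    shape_weight: float = 0.1,
    compactness_weight: float = 0.1,
) -> np.ndarray:
    """Return a label array (1..k, row-major first-pixel order)."""
    if values.ndim == 2:
        values = values[:, :, None]
    h, w, _ = values.shape
    segs: dict[int, frozenset] = {
        r * w + c: frozenset({(r, c)}) for r in range(h) for c in range(w)
    }

    def cost(a: int, b: int) -> float:
        pa, pb = segs[a], segs[b]
        n1, sd1, per1, bb1 = _stats(pa, values)
        n2, sd2, per2, bb2 = _stats(pb, values)
        nm, sdm, perm, _ = _stats(pa | pb, values)
        h_col = float(np.sum(nm * sdm - n1 * sd1 - n2 * sd2))
        bbm = _merged_bbox_perim(pa, pb)
        h_cmp = sqrt(nm) * perm - (sqrt(n1) * per1 + sqrt(n2) * per2)
        h_smo = nm * perm / bbm - (n1 * per1 / bb1 + n2 * per2 / bb2)
        h_shape = compactness_weight * h_cmp + (1 - compactness_weight) * h_smo
        return shape_weight * h_shape + (1 - shape_weight) * h_col

    def neighbours(a: int) -> list[int]:
        out = set()
        pa = segs[a]
        for r, c in pa:
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                q = (r + dr, c + dc)
                if 0 <= q[0] < h and 0 <= q[1] < w and q not in pa:
                    for b, pb in segs.items():
                        if q in pb:
                            out.add(b)
                            break
        return sorted(out)

    def best(a: int):
        out = None
        for b in neighbours(a):
            f = cost(a, b)
            if out is None or f < out[1] or (f == out[1] and b < out[0]):
                out = (b, f)
        return out

    scale2 = scale * scale
    while True:
        merged = False
        for a in sorted(segs):
            if a not in segs:
                continue
            fa = best(a)
            if fa is None or not fa[1] < scale2:
                continue
            b, _ = fa
            fb = best(b)
            if fb is not None and fb[0] == a:
                u, v = min(a, b), max(a, b)
                segs[u] = segs[u] | segs[v]
                del segs[v]
                merged = True
        if not merged:
            break

    labels = np.zeros((h, w), dtype=np.int32)
    new_id: dict[int, int] = {}
    for r in range(h):
        for c in range(w):
            root = next(s for s, p in segs.items() if (r, c) in p)
            if root not in new_id:
                new_id[root] = len(new_id) + 1
            labels[r, c] = new_id[root]
    return labels
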