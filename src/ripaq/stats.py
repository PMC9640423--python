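"""Descriptive statistics and index-agreement analysis.

The remote-sensing index (RSQI) is compared against the field index (QBR)
per station: descriptives, Shapiro-Wilk normality, Levene variance
homogeneity (parametric gate at p > 0.05 for both), and Pearson
correlation with a two-sided t-test p-value.  Reports mark correlations
significant at alpha = 0.01 with two stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedScores:
    station_ids: tuple[str, ...]
    rsqi: np.ndarray
    qbr: np.ndarray

    def __post_init__(self):
        if len(self.rsqi) != len(self.qbr) or len(self.rsqi) != len(self.station_ids):
            raise ValueError("station ids and score vectors differ in length")
        if len(self.rsqi) < 3:
            raise ValueError("need at least 3 paired stations")
        if not (np.all(np.isfinite(self.rsqi)) and np.all(np.isfinite(self.qbr))):
            raise ValueError("scores must be finite")


def descriptives(values) -> dict[str, float]:
    """Mean, sample standard deviation (n-1), min and max.

    A single observation has undefined spread; it is reported as 0 with a
    degenerate-n flag.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    out = {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "degenerate_n": v.size == 1,
    }
    return out


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def variance_check(*groups) -> tuple[float, float]:
    """Levene statistic and p-value across two or more groups."""
    if len(groups) < 2:
        raise ValueError("Levene needs at least 2 groups")
    res = sps.levene(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def agreement_report(scores: PairedScores, alpha: float = 0.01) -> dict:
    """Full RSQI-vs-QBR comparison for one station table."""
    sw_r = normality_check(scores.rsqi)
    sw_q = normality_check(scores.qbr)
    lev = variance_check(scores.rsqi, scores.qbr)
    parametric = sw_r[1] > 0.05 and sw_q[1] > 0.05 and lev[1] > 0.05
    r, p = pearson(scores.rsqi, scores.qbr)
    return {
        "n": len(scores.rsqi),
        "rsqi": descriptives(scores.rsqi),
        "qbr": descriptives(scores.qbr),
        "shapiro_rsqi": {"statistic": sw_r[0], "p": sw_r[1]},
        "shapiro_qbr": {"statistic": sw_q[0], "p": sw_q[1]},
        "levene": {"statistic": lev[0], "p": lev[1]},
        "parametric": parametric,
        "pearson_r": r,
        "pearson_p": p,
        "significance": "**" if p < alpha else "",
    }
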