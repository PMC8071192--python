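"""Compression stiffening rate and test-retest repeatability.

The compression stiffening rate is the ordinary least-squares slope of ROI
elasticity (kPa) on applied compression (kPa) — dimensionless because both
axes share a unit — fitted per subject on ROI means, with the intercept
estimating the basal elasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CompressionSeries", "StiffeningFit",
           "stiffening_rate", "repeatability_index"]


@dataclass
class CompressionSeries:
    """Ordered (applied compression kPa, elasticity kPa) pairs of one subject."""

    points: Sequence[tuple[float, float]]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need at least 2 points")
        comps = [p[0] for p in self.points]
        if len(set(comps)) < 2:
            raise ValueError("need at least 2 distinct compression values")
        if any(p[1] <= 0 for p in self.points):
            raise ValueError("elasticities must be positive")


@dataclass
class StiffeningFit:
    slope: float           # adimensional
    intercept_kpa: float   # basal-elasticity estimate
    r_squared: float


def stiffening_rate(series: CompressionSeries) -> StiffeningFit:
    """OLS slope of elasticity on compression ("compression stiffening rate")."""
    x = np.array([p[0] for p in series.points], dtype=float)
    y = np.array([p[1] for p in series.points], dtype=float)
    fit = stats.linregress(x, y)
    r2 = 1.0 if len(x) == 2 else float(fit.rvalue) ** 2
    return StiffeningFit(slope=float(fit.slope),
                         intercept_kpa=float(fit.intercept),
                         r_squared=r2)


def repeatability_index(replicate_pairs: Sequence[tuple[float, float]],
                        method: str = "relative_sd") -> float:
    """Test-retest repeatability index, percent.

    ``relative_sd`` (default): per pair, the relative difference
    ``d_i = 100 * (m1 - m2) / mean(m1, m2)``; the index is ``1.96 * SD(d_i)``
    (sample SD across pairs).  ``within_subject_cv``: the within-subject
    coefficient of variation convention, ``1.96 * 100 * sqrt(mean(d_i^2)) /
    ... `` computed as 1.96 times the RMS of ``d_i / sqrt(2)``.
    """
    if len(replicate_pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    d = []
    for m1, m2 in replicate_pairs:
        mean = 0.5 * (m1 + m2)
        if mean <= 0:
            raise ValueError("pair means must be positive")
        d.append(100.0 * (m1 - m2) / mean)
    d = np.asarray(d)
    if method == "relative_sd":
        return float(1.96 * np.std(d, ddof=1))
    if method == "within_subject_cv":
        return float(1.96 * math.sqrt(float(np.mean((d / math.sqrt(2.0)) ** 2))))
    raise ValueError(f"unknown method {method!r}")
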