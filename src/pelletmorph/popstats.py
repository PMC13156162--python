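"""Population-level statistics for pellet size distributions.

Distribution comparison (Mann–Whitney U), replicate similarity via the
histogram-intersection overlap coefficient on common 50 µm bins, the
surface-to-volume ratio of a pellet population under the sphere assumption,
and its monotone (Spearman) association with substrate uptake rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image2d import SizeDistribution

__all__ = [
    "mann_whitney_u",
    "significance_stars",
    "overlap_coefficient",
    "surface_to_volume",
    "SurfaceVolumeResult",
    "correlate_sv_uptake",
    "SVUptakeCorrelation",
]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between two diameter samples.

    Returns (U, p) where U is the statistic of the first sample, computed
    from rank sums with midranks for ties.  The p-value is exact (full
    enumeration of labelings) when both samples have at most 12 observations
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and a.size <= 12 and b.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Conventional significance marks: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def overlap_coefficient(qa, qb, bin_width: float = 50.0) -> float:
    """Histogram-intersection overlap of two size distributions, in [0, 1].

    Both inputs (raw diameters or :class:`SizeDistribution` objects carrying
    their raw diameters) are rebinned onto common ``bin_width`` edges from 0
    to the joint maximum, then Σ_bins min(q0_a, q0_b) is returned.  Symmetric;
    1 iff the binned distributions coincide, 0 for disjoint supports.
    """
    da = qa.diameters if isinstance(qa, SizeDistribution) else np.asarray(qa, float)
    db = qb.diameters if isinstance(qb, SizeDistribution) else np.asarray(qb, float)
    if da is None or db is None:
        raise ValueError("distributions must carry their raw diameters for rebinning")
    top = bin_width * (np.ceil(max(da.max(), db.max()) / bin_width) + 1)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    ha, _ = np.histogram(da, bins=edges)
    hb, _ = np.histogram(db, bins=edges)
    return float(np.minimum(ha / ha.sum(), hb / hb.sum()).sum())


@dataclass
class SurfaceVolumeResult:
    """Surface-to-volume ratio of a pellet population (spheres assumed)."""

    sv_ratio: float  # µm⁻¹
    surface_per_ml: float | None  # µm² mL⁻¹
    volume_per_ml: float | None  # µm³ mL⁻¹
    n: int


def surface_to_volume(
    diameters, concentration: float | None = None
) -> SurfaceVolumeResult:
    """S/V of a population of spheres: 6·Σd² / Σd³ (µm⁻¹).

    The pellet number concentration cancels in the ratio but scales the
    absolute surface and volume per mL, which are also reported when a
    concentration (mL⁻¹) is supplied.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("diameters must be non-empty")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    s2, s3 = (d**2).sum(), (d**3).sum()
    ratio = 6.0 * s2 / s3
    surface = volume = None
    if concentration is not None:
        surface = concentration * np.pi * s2 / d.size
        volume = concentration * np.pi / 6.0 * s3 / d.size
    return SurfaceVolumeResult(float(ratio), surface, volume, int(d.size))


@dataclass
class SVUptakeCorrelation:
    rho: float  # Spearman rank correlation (NaN when undefined)
    pvalue: float
    n: int
    positive: bool | None  # sign report; None when no direction


def correlate_sv_uptake(sv_ratios, uptake_rates) -> SVUptakeCorrelation:
    """Spearman rank correlation between per-condition S/V and uptake rate.

    With fewer than 3 paired conditions the correlation is undefined and
    only the sign of the pairwise trend is reported.
    """
    sv = np.asarray(sv_ratios, dtype=float)
    up = np.asarray(uptake_rates, dtype=float)
    if sv.shape != up.shape:
        raise ValueError("paired inputs must have equal length")
    n = sv.size
    if n < 3:
        sign = None
        if n == 2:
            prod = (sv[1] - sv[0]) * (up[1] - up[0])
            sign = bool(prod > 0) if prod != 0 else None
        return SVUptakeCorrelation(float("nan"), float("nan"), n, sign)
    rho, p = stats.spearmanr(sv, up)
    positive = bool(rho > 0) if rho == rho and rho != 0 else None
    return SVUptakeCorrelation(float(rho), float(p), n, positive)
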