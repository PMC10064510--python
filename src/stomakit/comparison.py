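"""Automated-vs-manual agreement and contrasting-phenotype screening.

:func:`fit_regression` quantifies agreement between automated and
manual/reference measurements of the same units (typically per-image stomatal
counts or per-image mean sizes) by ordinary least squares of automated (y)
on manual (x), reporting slope, intercept and the coefficient of
determination R^2 = 1 - SS_res / SS_tot. Slope and intercept are reported
alongside R^2 so a calibration bias remains visible even when correlation
is high.

:func:`screen_contrasts` ranks image summaries by stomatal density and
returns the extreme-quantile groups together with the rank correlation
between density and mean complex size, surfacing the density–size
trade-off (high density with smaller stomata vs low density with larger
stomata) that rapid phenotypic screening looks for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measure import ImageSummary

__all__ = [
    "PairedMeasurements",
    "RegressionResult",
    "ContrastReport",
    "fit_regression",
    "screen_contrasts",
    "rank_correlation",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Manual/reference (x) vs automated (y) values for the same units."""

    unit_ids: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    trait: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        if not (len(self.unit_ids) == len(self.x) == len(self.y)):
            raise ValueError("unit_ids, x and y must have equal lengths")
        if len(self.x) < 2:
            raise ValueError("need at least 2 paired measurements")
        if not all(np.isfinite(self.x)) or not all(np.isfinite(self.y)):
            raise ValueError("paired measurements must be finite")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class ContrastReport:
    """Extreme-density groups and the density–size rank correlation."""

    high_group: list[ImageSummary]
    low_group: list[ImageSummary]
    high_mean_density: float
    low_mean_density: float
    high_mean_area_um2: float | None
    low_mean_area_um2: float | None
    density_size_rank_correlation: float | None


def fit_regression(pairs: PairedMeasurements) -> RegressionResult:
    """Ordinary least squares of automated (y) on manual (x), with intercept.

    Raises on constant x (the fit is undefined).
    """
    x = np.asarray(pairs.x, dtype=float)
    y = np.asarray(pairs.y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to fit a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(slope, intercept, r2, len(x))


def _ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties sharing their mean rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_correlation(a: np.ndarray, b: np.ndarray) -> float | None:
    """Spearman-type correlation via explicit rank transform.

    Returns None when either variable is constant (correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    ra, rb = _ranks(a), _ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt(np.sum(ra**2) * np.sum(rb**2))
    return float(np.sum(ra * rb) / denom)


def screen_contrasts(
    summaries: list[ImageSummary], quantile: float = 0.2
) -> ContrastReport:
    """Extract extreme stomatal-density groups from a cohort of images.

    Units are ranked by density (ties broken by image id for determinism);
    the top and bottom quantile groups together hold ``ceil(2*quantile*n)``
    units. Also reports the rank correlation between density and mean
    complex area across the whole cohort.
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    n = len(summaries)
    total = int(np.ceil(2 * quantile * n))
    k_high = total // 2 + total % 2
    k_low = total - k_high
    if k_high < 2 or k_low < 2:
        raise ValueError(
            f"quantile {quantile} of {n} units gives groups smaller than 2"
        )
    ranked = sorted(summaries, key=lambda s: (-s.density_mm2, s.image_id))
    high = ranked[:k_high]
    low = list(reversed(ranked[-k_low:]))  # lowest density first

    def mean_area(group: list[ImageSummary]) -> float | None:
        vals = [s.mean_complex_area_um2 for s in group if s.mean_complex_area_um2 is not None]
        return float(np.mean(vals)) if vals else None

    with_area = [s for s in summaries if s.mean_complex_area_um2 is not None]
    corr = None
    if len(with_area) >= 3:
        corr = rank_correlation(
            np.array([s.density_mm2 for s in with_area]),
            np.array([s.mean_complex_area_um2 for s in with_area]),
        )
    return ContrastReport(
        high_group=high,
        low_group=low,
        high_mean_density=float(np.mean([s.density_mm2 for s in high])),
        low_mean_density=float(np.mean([s.density_mm2 for s in low])),
        high_mean_area_um2=mean_area(high),
        low_mean_area_um2=mean_area(low),
        density_size_rank_correlation=corr,
    )
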