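"""Bait-normalized iBAQ ratio series and windowed trend regression.

For each protein, the per-fraction iBAQ value is divided by the bait's iBAQ
value in the same fraction; an ordinary least-squares line of ratio against
fraction index is fitted inside a configurable fraction window (default
[26, 36], the bait peak region), and the slope's two-sided t-test decides
between a flat, ascending or descending trend. A flat trend indicates the
protein tracks the bait at constant relative amount across both assemblies;
an ascending slope indicates over-representation in the higher-mass
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .io_tables import QuantTable

__all__ = [
    "RatioSeries",
    "SlopeResult",
    "DEFAULT_WINDOW",
    "DEFAULT_ALPHA",
    "ratio_series",
    "shift_series",
    "pool_series",
    "fit_slope",
    "classify_trend",
]

DEFAULT_WINDOW: tuple[int, int] = (26, 36)
DEFAULT_ALPHA: float = 0.05

TREND_FLAT = "flat"
TREND_ASCENDING = "ascending"
TREND_DESCENDING = "descending"


@dataclass
class RatioSeries:
    """Per-fraction iBAQ(protein)/iBAQ(bait) values over usable fractions.

    Only fractions where the bait iBAQ is positive appear; ``n_skipped``
    counts window fractions dropped because the bait was unobserved there.
    """

    protein_id: str
    fractions: list[int]
    ratios: list[float]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.ratios):
            raise ValueError("fractions and ratios must have equal length")
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.fractions)


@dataclass
class SlopeResult:
    protein_id: str
    slope: float
    intercept: float
    stderr_slope: float
    p_value: float
    n_used: int
    trend: str


def ratio_series(
    table: QuantTable,
    protein_id: str,
    bait_id: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> RatioSeries:
    """Bait-normalized iBAQ ratios for *protein_id* inside *window* (inclusive,
    1-based). Fractions with bait iBAQ = 0 are skipped and counted."""
    try:
        bait_row = table.ibaq[table.index_of(bait_id)]
    except KeyError:
        raise ValueError(f"bait {bait_id!r} absent from table") from None
    prot_row = table.ibaq[table.index_of(protein_id)]

    lo, hi = int(window[0]), int(window[1])
    if not 1 <= lo <= hi <= table.n_fractions:
        raise ValueError(f"window {window} outside [1, {table.n_fractions}]")

    fractions, ratios, skipped = [], [], 0
    for f in range(lo, hi + 1):
        bait_val = bait_row[f - 1]
        if bait_val > 0:
            fractions.append(f)
            ratios.append(float(prot_row[f - 1] / bait_val))
        else:
            skipped += 1
    if not fractions:
        raise ValueError(f"no usable fractions in window {window} (bait all zero)")
    return RatioSeries(protein_id=protein_id, fractions=fractions, ratios=ratios, n_skipped=skipped)


def shift_series(series: RatioSeries, offset: int) -> RatioSeries:
    """Relabel fractions by adding *offset* (used to place an aligned replicate
    on the reference replicate's fraction axis)."""
    return replace(series, fractions=[f + offset for f in series.fractions])


def pool_series(series_list: list[RatioSeries]) -> RatioSeries:
    """Concatenate ratio series (e.g. the two replicates) into one fit input."""
    if not series_list:
        raise ValueError("nothing to pool")
    pids = {s.protein_id for s in series_list}
    if len(pids) != 1:
        raise ValueError(f"cannot pool series of different proteins: {sorted(pids)}")
    return RatioSeries(
        protein_id=series_list[0].protein_id,
        fractions=[f for s in series_list for f in s.fractions],
        ratios=[r for s in series_list for r in s.ratios],
        n_skipped=sum(s.n_skipped for s in series_list),
    )


def fit_slope(
    series: RatioSeries,
    alpha: float = DEFAULT_ALPHA,
    log_ratios: bool = False,
    min_fold: float | None = None,
) -> SlopeResult:
    """OLS of ratio on fraction index with a two-sided t-test on the slope
    (t distribution, ``n_used - 2`` degrees of freedom).

    Options (both off by default, matching the plain normalized-iBAQ
    regression):

    * ``log_ratios`` fits ``ln(ratio)`` instead of the raw ratio; zero
      ratios (unobserved protein cells) are excluded from the fit. Slope
      units become log-ratio per fraction; the trend rule is unchanged.
    * ``min_fold`` downgrades a significant trend to ``flat`` unless the
      fitted line implies at least that fold change across the fitted
      fraction span — an effect-size floor separating visually "steep"
      trends from statistically detectable but shallow ones.

    A series that is constant to within floating-point noise is reported as
    slope 0, p-value 1 (exact-arithmetic degenerate case).
    """
    xs, ys = list(series.fractions), list(series.ratios)
    if log_ratios:
        pairs = [(x, np.log(y)) for x, y in zip(xs, ys) if y > 0]
        xs, ys = [p[0] for p in pairs], [p[1] for p in pairs]
    n = len(xs)
    if n < 3:
        raise InsufficientDataError(
            f"{series.protein_id}: need >= 3 usable points, have {n}"
        )
    if len(set(xs)) < 2:
        raise ValueError(f"{series.protein_id}: zero variance in fraction indices")

    ys_arr = np.asarray(ys, dtype=float)
    if np.ptp(ys_arr) <= 1e-9 * max(float(np.abs(ys_arr).max()), 1e-300):
        # constant up to floating-point jitter
        result = SlopeResult(
            protein_id=series.protein_id,
            slope=0.0,
            intercept=float(ys_arr.mean()),
            stderr_slope=0.0,
            p_value=1.0,
            n_used=n,
            trend=TREND_FLAT,
        )
        return result

    fit = stats.linregress(xs, ys_arr)
    result = SlopeResult(
        protein_id=series.protein_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr_slope=float(fit.stderr),
        p_value=_slope_p_value(fit, n),
        n_used=n,
        trend="",
    )
    result.trend = classify_trend(result, alpha)
    if min_fold is not None and result.trend != TREND_FLAT:
        if _fitted_fold(result, min(xs), max(xs), log_ratios) < min_fold:
            result.trend = TREND_FLAT
    return result


def _fitted_fold(result: SlopeResult, x_min: float, x_max: float, log_ratios: bool) -> float:
    """Fold change implied by the fitted line across the fitted span (>= 1)."""
    if log_ratios:
        return float(np.exp(abs(result.slope) * (x_max - x_min)))
    lo = result.intercept + result.slope * x_min
    hi = result.intercept + result.slope * x_max
    lo, hi = sorted((lo, hi))
    if lo <= 0:
        return float("inf")  # line crosses zero within the span: maximal change
    return hi / lo


def _slope_p_value(fit, n: int) -> float:
    # linregress returns p = 1 (t = 0/0 handled as 0) for an exactly constant
    # series; guard against nan from zero residual variance with zero slope.
    p = float(fit.pvalue)
    if p != p:  # nan: zero residual variance
        p = 0.0 if fit.slope != 0 else 1.0
    return p


def classify_trend(result: SlopeResult, alpha: float = DEFAULT_ALPHA) -> str:
    """``flat`` when the slope is not significant at *alpha*; otherwise the
    slope's sign decides ``ascending``/``descending``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if result.p_value >= alpha:
        return TREND_FLAT
    return TREND_ASCENDING if result.slope > 0 else TREND_DESCENDING
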