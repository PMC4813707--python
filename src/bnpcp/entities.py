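"""Bait peak detection, complex-entity definition and membership assignment.

The bait's migration profile is smoothed with a short moving average and its
local maxima of sufficient prominence become entity apexes. Each apex is
given a fraction region bounded by the flanking minima (midpoint rule for
tied minima between adjacent apexes); the outer flanks stop where the
smoothed signal falls below 1% of the apex height. Regions are labeled
"I", "II", ... from low to high fraction index (fraction 1 = gel bottom =
low mass). Every other protein is then assigned the share of its profile
mass falling inside each region, and a boolean per-entity call at a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .profiles import MigrationProfile, MwCalibration
from .stoichiometry import SlopeResult

__all__ = [
    "PeakRegion",
    "EntityMembership",
    "detect_peaks",
    "assign_entity",
    "entity_report",
    "DEFAULT_MIN_PROMINENCE",
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_CALL_THRESHOLD",
    "OUTSIDE_SHARE",
]

DEFAULT_MIN_PROMINENCE = 0.25
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_CALL_THRESHOLD = 0.2
#: profile-mass share outside all regions beyond which a protein is "outside"
OUTSIDE_SHARE = 0.8
_FLANK_FLOOR = 0.01  # outer region bounds stop below this fraction of apex height

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class PeakRegion:
    """One bait-defined entity: apex fraction with inclusive bounds (1-based)."""

    label: str
    apex: int
    left: int
    right: int
    apex_mass_kda: float | None = None

    def __post_init__(self) -> None:
        if not self.left <= self.apex <= self.right:
            raise ValueError(f"region {self.label}: need left <= apex <= right")

    def fractions(self) -> range:
        return range(self.left, self.right + 1)


@dataclass
class EntityMembership:
    """Per-entity profile-mass shares and threshold calls for one protein."""

    protein_id: str
    shares: dict[str, float]
    calls: dict[str, bool]
    outside: bool


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (partial windows at ends)."""
    if window == 1:
        return values.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def detect_peaks(
    profile: MigrationProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    calibration: MwCalibration | None = None,
) -> list[PeakRegion]:
    """Detect entity regions on a (typically bait) migration profile.

    ``min_prominence`` is relative: a local maximum qualifies when its
    prominence is at least ``min_prominence * max(smoothed profile)``.
    Adjacent equal maxima (plateaus) merge into one peak whose apex is the
    plateau's lowest fraction index. Supplying *calibration* annotates each
    region with the apparent mass at its apex where the ladder covers it.
    """
    if profile.is_zero():
        raise ValueError(f"cannot detect peaks on zero profile {profile.protein_id!r}")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")

    y = _smooth(profile.values, smooth_window)
    threshold = min_prominence * float(y.max())
    # pad so peaks at the first/last fraction are eligible
    padded = np.concatenate([[-np.inf], y, [-np.inf]])
    idx, props = find_peaks(padded, prominence=threshold, plateau_size=(1, None))
    apexes = sorted(int(le) - 1 for le in props["left_edges"])  # plateau low edge, 0-based

    if not apexes:
        # degenerate fallback: the global maximum is always one region
        apexes = [int(np.argmax(y))]

    # boundaries between adjacent apexes: position of the minimum between them
    # (middle of a tied-minimum plateau)
    cuts = []
    for a, b in zip(apexes[:-1], apexes[1:]):
        inner = y[a + 1 : b]
        lows = np.flatnonzero(inner == inner.min()) + a + 1
        cuts.append(int(lows[(len(lows) - 1) // 2]))

    regions = []
    for k, apex in enumerate(apexes):
        floor = _FLANK_FLOOR * y[apex]
        if k == 0:
            left = apex
            while left - 1 >= 0 and y[left - 1] <= y[left] and y[left - 1] >= floor:
                left -= 1
        else:
            left = cuts[k - 1] + 1
        if k == len(apexes) - 1:
            right = apex
            while right + 1 < y.size and y[right + 1] <= y[right] and y[right + 1] >= floor:
                right += 1
        else:
            right = cuts[k]
        label = _ROMAN[k] if k < len(_ROMAN) else str(k + 1)
        mass = None
        if calibration is not None:
            lo, hi = calibration.span
            if lo <= apex + 1 <= hi:
                mass = calibration.mass_at(apex + 1)
        regions.append(
            PeakRegion(label=label, apex=apex + 1, left=left + 1, right=right + 1, apex_mass_kda=mass)
        )
    return regions


def assign_entity(
    profile: MigrationProfile,
    regions: list[PeakRegion],
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
) -> EntityMembership:
    """Share of *profile*'s mass inside each region, with threshold calls.

    A protein whose profile mass lies at least 80% outside all regions is
    flagged ``outside`` (e.g. a monomer band below the complex region).
    """
    if not 0 < call_threshold < 1:
        raise ValueError("call_threshold must be in (0, 1)")
    spans = sorted((r.left, r.right, r.label) for r in regions)
    for (l1, r1, lab1), (l2, r2, lab2) in zip(spans[:-1], spans[1:]):
        if l2 <= r1:
            raise ValueError(f"regions {lab1} and {lab2} overlap")
    shares = {
        r.label: float(profile.values[r.left - 1 : r.right].sum()) for r in regions
    }
    calls = {label: share >= call_threshold for label, share in shares.items()}
    total_inside = sum(shares.values())
    outside = (1.0 - total_inside) >= OUTSIDE_SHARE
    return EntityMembership(
        protein_id=profile.protein_id, shares=shares, calls=calls, outside=outside
    )


def entity_report(
    memberships: list[EntityMembership],
    slopes: list[SlopeResult] | None = None,
    co_cluster_ids: set[str] | None = None,
):
    """Summary table joining entity calls, shares, trend and co-cluster flag.

    Returns a pandas DataFrame with one row per membership, columns:
    ``protein_id``, ``share_<label>`` and ``call_<label>`` per entity,
    ``outside``, ``trend`` and ``in_bait_cluster``.
    """
    import pandas as pd

    labels = sorted({label for m in memberships for label in m.shares})
    trend_by_id = {s.protein_id: s.trend for s in slopes or []}
    rows = []
    for m in memberships:
        row: dict[str, object] = {"protein_id": m.protein_id}
        for label in labels:
            row[f"share_{label}"] = m.shares.get(label, 0.0)
            row[f"call_{label}"] = m.calls.get(label, False)
        row["outside"] = m.outside
        row["trend"] = trend_by_id.get(m.protein_id, "")
        row["in_bait_cluster"] = (
            m.protein_id in co_cluster_ids if co_cluster_ids is not None else False
        )
        rows.append(row)
    columns = (
        ["protein_id"]
        + [f"share_{l}" for l in labels]
        + [f"call_{l}" for l in labels]
        + ["outside", "trend", "in_bait_cluster"]
    )
    return pd.DataFrame(rows, columns=columns)
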