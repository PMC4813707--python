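"""Migration profiles: normalization, MW annotation and replicate alignment.

A migration profile is a protein's per-fraction intensity vector divided by
the protein's total intensity across the whole separation, so that every
nonzero profile sums to 1. Fractions are 1-based; fraction 1 is the gel
bottom (lowest apparent mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationRangeError
from .io_tables import QuantTable

__all__ = [
    "MigrationProfile",
    "MwCalibration",
    "build_profiles",
    "calibrate_mw",
    "apex_fraction",
    "align_replicates",
    "shift_profile",
]


@dataclass
class MigrationProfile:
    """Normalized per-fraction intensity vector for one protein.

    ``values`` sums to 1 when ``total_intensity > 0`` and is all-zero when
    the protein was not observed at all. Profiles produced by replicate
    alignment may lose edge mass to truncation and then sum to < 1.
    """

    protein_id: str
    values: np.ndarray
    total_intensity: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.total_intensity = float(self.total_intensity)

    @property
    def n_fractions(self) -> int:
        return self.values.size

    def is_zero(self) -> bool:
        return self.total_intensity == 0.0


def build_profiles(table: QuantTable) -> list[MigrationProfile]:
    """One profile per table record, in table order.

    Normalization uses the intensity vectors (iBAQ is reserved for
    stoichiometry); proteins with zero total intensity yield all-zero
    profiles flagged via ``total_intensity = 0``.
    """
    profiles = []
    for i, pid in enumerate(table.protein_ids):
        row = table.intensity[i]
        total = float(row.sum())
        values = row / total if total > 0 else np.zeros_like(row)
        profiles.append(MigrationProfile(protein_id=pid, values=values, total_intensity=total))
    return profiles


@dataclass
class MwCalibration:
    """Piecewise log-linear map from fraction index to apparent mass (kDa).

    Interpolates log10(mass) against fraction index between ladder anchors;
    exact at anchors. Queries outside the ladder span raise
    :class:`~bnpcp.errors.CalibrationRangeError`.
    """

    fractions: np.ndarray
    log10_mass: np.ndarray

    def mass_at(self, fraction: float) -> float:
        lo, hi = self.fractions[0], self.fractions[-1]
        if not lo <= fraction <= hi:
            raise CalibrationRangeError(
                f"fraction {fraction} outside calibrated span [{lo}, {hi}]"
            )
        return float(10.0 ** np.interp(fraction, self.fractions, self.log10_mass))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.fractions[0]), float(self.fractions[-1])


def calibrate_mw(ladder: list[tuple[int, float]]) -> MwCalibration:
    """Build an :class:`MwCalibration` from a validated (fraction, kDa) ladder."""
    from .io_tables import validate_ladder

    rows = validate_ladder(ladder)
    fracs = np.array([f for f, _ in rows], dtype=float)
    logm = np.log10([m for _, m in rows])
    return MwCalibration(fractions=fracs, log10_mass=logm)


def apex_fraction(profile: MigrationProfile) -> int:
    """1-based index of the profile maximum; ties break toward the lowest index."""
    if profile.is_zero():
        raise ValueError(f"apex undefined for zero profile {profile.protein_id!r}")
    return int(np.argmax(profile.values)) + 1


def shift_profile(profile: MigrationProfile, offset: int) -> MigrationProfile:
    """Shift a profile by *offset* fractions (positive = toward higher index),
    zero-padding and truncating at the edges."""
    values = np.zeros_like(profile.values)
    n = values.size
    if offset >= 0:
        values[offset:] = profile.values[: n - offset]
    else:
        values[: n + offset] = profile.values[-offset:]
    return MigrationProfile(
        protein_id=profile.protein_id, values=values, total_intensity=profile.total_intensity
    )


def _find(profiles: list[MigrationProfile], protein_id: str) -> MigrationProfile:
    for p in profiles:
        if p.protein_id == protein_id:
            return p
    raise ValueError(f"bait {protein_id!r} not found in replicate")


def align_replicates(
    profiles_a: list[MigrationProfile],
    profiles_b: list[MigrationProfile],
    bait_id: str,
) -> tuple[int, list[MigrationProfile]]:
    """Align replicate *b* onto replicate *a* by the bait's apex fraction.

    Returns ``(offset, aligned_b)`` where ``offset = apex_a - apex_b`` and
    ``aligned_b`` is every profile of *b* shifted by ``offset`` (zero-padded
    and truncated at the gel edges), so the bait apexes coincide.
    """
    bait_a, bait_b = _find(profiles_a, bait_id), _find(profiles_b, bait_id)
    if bait_a.is_zero() or bait_b.is_zero():
        raise ValueError(f"bait {bait_id!r} has a zero profile in one replicate")
    offset = apex_fraction(bait_a) - apex_fraction(bait_b)
    return offset, [shift_profile(p, offset) for p in profiles_b]
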