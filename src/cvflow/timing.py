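"""Venous-phase timing scores per hemisphere and relative (rCVF) scores.

Three cortical veins drain the MCA territory into the superior sagittal
sinus: the superficial middle cerebral vein (SMCV), the vein of Trolard
(VOT) and the vein of Labbe (VOL).  Per hemisphere three venous time points
are read off the acquisition grid:

* CVF1 — first time any (present) cortical vein becomes visible,
* CVF2 — first time most veins are at their maximum opacification,
* CVF3 — first time after CVF2 when every vein has cleared.

CVF21 = CVF2 - CVF1 is the early-to-peak interval; CVF31 = CVF3 - CVF1 the
whole venous phase.  rCVF scores are affected-minus-contralateral
differences (positive = delayed filling on the affected side), and a
patient's filling is "fast" on an rCVF index when their value is at or
below the cohort median for that index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tac import Tac

__all__ = [
    "VEINS",
    "VeinEnhancement",
    "HemisphereCvfTimes",
    "RelativeCvf",
    "VelocityLabel",
    "CensoredOnsetError",
    "CensoredClearanceError",
    "detect_cvf1",
    "detect_cvf2",
    "detect_cvf3",
    "derive_intervals",
    "relative_cvf",
    "classify_velocity",
    "DEFAULT_VISIBILITY_THRESHOLD",
]

VEINS = ("SMCV", "VOT", "VOL")

#: enhancement (HU above baseline) at which a vein counts as visible; shared
#: by onset (CVF1), clearance (CVF3) and presence scoring.
DEFAULT_VISIBILITY_THRESHOLD = 50.0


class CensoredOnsetError(ValueError):
    """No present vein ever reaches the visibility threshold on the grid."""


class CensoredClearanceError(ValueError):
    """Some vein is still opacified at the last acquired volume."""


@dataclass
class VeinEnhancement:
    """One cortical vein's TAC, with its presence flag (set by extent scoring)."""

    vein: str
    hemisphere: str
    tac: Tac
    present: bool = True

    def __post_init__(self) -> None:
        if self.vein not in VEINS:
            raise ValueError(f"unknown vein label {self.vein!r}; expected one of {VEINS}")


@dataclass(frozen=True)
class HemisphereCvfTimes:
    """CVF1/2/3 plus the derived CVF21/CVF31 intervals for one hemisphere."""

    cvf1: float
    cvf2: float
    cvf3: float

    def __post_init__(self) -> None:
        if not (self.cvf1 <= self.cvf2 <= self.cvf3):
            raise ValueError("require cvf1 <= cvf2 <= cvf3")

    @property
    def cvf21(self) -> float:
        return self.cvf2 - self.cvf1

    @property
    def cvf31(self) -> float:
        return self.cvf3 - self.cvf1


@dataclass(frozen=True)
class RelativeCvf:
    """Affected-minus-contralateral CVF time differences (seconds, signed)."""

    rcvf1: float
    rcvf2: float
    rcvf3: float
    rcvf21: float
    rcvf31: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rcvf1": self.rcvf1,
            "rcvf2": self.rcvf2,
            "rcvf3": self.rcvf3,
            "rcvf21": self.rcvf21,
            "rcvf31": self.rcvf31,
        }


@dataclass(frozen=True)
class VelocityLabel:
    """Fast/slow label for one rCVF index relative to a cohort median."""

    index: str
    value: float
    threshold: float

    @property
    def label(self) -> str:
        return "fast" if self.value <= self.threshold else "slow"

    @property
    def fast(self) -> bool:
        return self.value <= self.threshold


def _present(veins: Iterable[VeinEnhancement]) -> list[VeinEnhancement]:
    out = [v for v in veins if v.present]
    if not out:
        raise ValueError("need at least one present vein")
    if len({v.tac.grid for v in out}) > 1:
        raise ValueError("all vein TACs must share one grid")
    return out


def detect_cvf1(
    veins: Iterable[VeinEnhancement],
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> float:
    """Earliest grid time at which any present vein's enhancement reaches threshold."""
    present = _present(veins)
    times = present[0].tac.grid.array
    any_visible = np.zeros(len(times), dtype=bool)
    for v in present:
        any_visible |= v.tac.enhancement >= visibility_threshold
    idx = np.flatnonzero(any_visible)
    if idx.size == 0:
        raise CensoredOnsetError(
            "no present vein reaches the visibility threshold within the acquisition"
        )
    return float(times[idx[0]])


def detect_cvf2(
    veins: Iterable[VeinEnhancement],
    peak_tolerance: float = 0.05,
    majority_fraction: float = 0.5,
) -> float:
    """Earliest grid time when "most" present veins are at maximum opacification.

    A vein counts as at-maximum at time t when its enhancement is within
    ``peak_tolerance`` (fractional) of its own maximum enhancement; "most"
    means at least ``ceil(majority_fraction * m)`` of the m present veins.
    Such a time always exists because every vein attains its own maximum.
    """
    present = _present(veins)
    times = present[0].tac.grid.array
    m = len(present)
    need = max(1, math.ceil(majority_fraction * m))
    at_peak = np.zeros((m, len(times)), dtype=bool)
    for i, v in enumerate(present):
        enh = v.tac.enhancement
        at_peak[i] = enh >= (1.0 - peak_tolerance) * enh.max()
    counts = at_peak.sum(axis=0)
    idx = np.flatnonzero(counts >= need)
    if idx.size == 0:
        # distinct peaks can make a strict majority unattainable at any single
        # time; fall back to the earliest time with the best attainable count
        return float(times[int(np.argmax(counts))])
    return float(times[idx[0]])


def detect_cvf3(
    veins: Iterable[VeinEnhancement],
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    after: float | None = None,
) -> float:
    """Earliest grid time after ``after`` (the hemisphere's CVF2) when every
    present vein has cleared below the visibility threshold."""
    present = _present(veins)
    times = present[0].tac.grid.array
    all_clear = np.ones(len(times), dtype=bool)
    for v in present:
        all_clear &= v.tac.enhancement < visibility_threshold
    mask = all_clear if after is None else all_clear & (times > after)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise CensoredClearanceError(
            "some vein is still opacified at the last acquired volume"
        )
    return float(times[idx[0]])


def derive_intervals(cvf1: float, cvf2: float, cvf3: float) -> tuple[float, float]:
    """(CVF21, CVF31) = (CVF2 - CVF1, CVF3 - CVF1); ordering is enforced."""
    if not (cvf1 <= cvf2 <= cvf3):
        raise ValueError(f"require cvf1 <= cvf2 <= cvf3, got {(cvf1, cvf2, cvf3)}")
    return cvf2 - cvf1, cvf3 - cvf1


def relative_cvf(affected: HemisphereCvfTimes, contralateral: HemisphereCvfTimes) -> RelativeCvf:
    """Componentwise affected-minus-contralateral differences (rCVF scores)."""
    return RelativeCvf(
        rcvf1=affected.cvf1 - contralateral.cvf1,
        rcvf2=affected.cvf2 - contralateral.cvf2,
        rcvf3=affected.cvf3 - contralateral.cvf3,
        rcvf21=affected.cvf21 - contralateral.cvf21,
        rcvf31=affected.cvf31 - contralateral.cvf31,
    )


def classify_velocity(
    cohort_values: Sequence[float], index: str = "rcvf21"
) -> list[VelocityLabel]:
    """Median-split fast/slow labels for one rCVF index across a cohort.

    The threshold is the sample median (mean of the two central order
    statistics for even n); a patient is "fast" when their value is less
    than or equal to the median, so at least half the cohort is fast.
    """
    vals = np.asarray(cohort_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty cohort")
    if not np.all(np.isfinite(vals)):
        raise ValueError("cohort values must be finite")
    threshold = float(np.median(vals))
    return [VelocityLabel(index=index, value=float(v), threshold=threshold) for v in vals]
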