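"""Per-vein presence (CVF+/CVF-) and the ipsilateral CVF- set and count.

A vein is CVF+ when it opacifies at any grid time inside the venous window
and CVF- when it never does.  Because a vein can be congenitally absent,
only *ipsilateral* CVF- — absent on the affected side while present on the
contralateral side — is attributed to the stenosis; bilateral absence is
treated as anatomical variation and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tac import Tac
from .timing import DEFAULT_VISIBILITY_THRESHOLD, VEINS

__all__ = ["VeinPresence", "ExtentResult", "assess_presence", "ipsilateral_absence"]


@dataclass(frozen=True)
class VeinPresence:
    """CVF+/CVF- flags for the three scored veins of one hemisphere."""

    smcv: bool
    vot: bool
    vol: bool

    def flag(self, vein: str) -> bool:
        return {"SMCV": self.smcv, "VOT": self.vot, "VOL": self.vol}[vein]


@dataclass(frozen=True)
class ExtentResult:
    """Ipsilateral CVF- set, its count, and the count category."""

    ipsilateral_absent: frozenset[str]
    n_ipsilateral_absent: int

    def __post_init__(self) -> None:
        if self.n_ipsilateral_absent != len(self.ipsilateral_absent):
            raise ValueError("count inconsistent with the absent set")

    @property
    def category(self) -> str:
        return "none" if self.n_ipsilateral_absent == 0 else f"CVF-={self.n_ipsilateral_absent}"


def assess_presence(
    vein_tac: Tac,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    venous_window: tuple[float, float] | None = None,
) -> bool:
    """True (CVF+) when the vein's peak enhancement inside the venous window
    reaches the visibility threshold, using a >= boundary convention.

    With no window the whole acquisition is used.
    """
    times = vein_tac.grid.array
    if venous_window is None:
        in_window = np.ones(len(times), dtype=bool)
    else:
        start, end = venous_window
        in_window = (times >= start) & (times <= end)
        if not in_window.any():
            raise ValueError(
                f"venous window ({start:g}, {end:g}) s does not intersect the grid"
            )
    return bool(vein_tac.enhancement[in_window].max() >= visibility_threshold)


def ipsilateral_absence(affected: VeinPresence, contralateral: VeinPresence) -> ExtentResult:
    """Veins absent on the affected side but present contralaterally."""
    absent = frozenset(
        v for v in VEINS if (not affected.flag(v)) and contralateral.flag(v)
    )
    return ExtentResult(ipsilateral_absent=absent, n_ipsilateral_absent=len(absent))
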