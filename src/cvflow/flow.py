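"""Antegrade-flow and collateral-status decision rules.

The underlying gradings are visual reads of the dynamic CTA (or synthetic
stand-ins): the fraction of the contralateral MCA territory filled by the
affected MCA at the arterial phase, and a three-level collateral contrast
grade at each selected phase.  This module implements only the published
decision rules on top of those inputs.
"""

from __future__ import annotations

__all__ = ["COLLATERAL_GRADES", "classify_antegrade", "classify_collateral"]

#: ordered none < peripheral < complete
COLLATERAL_GRADES = ("none", "peripheral", "complete")


def classify_antegrade(filling_ratio: float) -> str:
    """"preserved" when the affected MCA fills strictly more than two-thirds
    of the contralateral territory at A-TAC, else "compromised"."""
    if not 0.0 <= filling_ratio <= 1.0:
        raise ValueError(f"filling_ratio must be in [0, 1], got {filling_ratio!r}")
    return "preserved" if filling_ratio > 2.0 / 3.0 else "compromised"


def classify_collateral(grade_at_a: str, grade_at_v: str) -> str:
    """"good" when collaterals show complete contrast enhancement at either
    A-TAC or V-TAC; "poor" for no or only peripheral enhancement at both."""
    for g in (grade_at_a, grade_at_v):
        if g not in COLLATERAL_GRADES:
            raise ValueError(f"unknown collateral grade {g!r}; expected one of {COLLATERAL_GRADES}")
    return "good" if "complete" in (grade_at_a, grade_at_v) else "poor"
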