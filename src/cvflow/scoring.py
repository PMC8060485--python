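"""Per-patient scoring: TAC table -> phase selection, CVF times, extent.

Reads the long-format TAC table (patient_id, group, hemisphere, structure,
time_s, attenuation_hu), selects A-TAC/V-TAC from the MCA and SSS curves,
then scores each hemisphere's three cortical veins for presence and for the
CVF1/CVF2/CVF3 time points.

Presence and timing are mutually dependent (the venous window is anchored
at CVF1, while timing uses only present veins), so scoring is two-pass:
a provisional presence read over the fallback window [V-TAC - 2 grid
intervals, last volume] feeds a provisional CVF1, the definitive presence
read uses [CVF1 - 1 interval, last volume], and CVF1/2/3 are then detected
on the definitively present veins.  Censored onsets/clearances are reported
as missing values with explicit flags, never silently imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import extent as ext
from . import timing as tim
from .flow import classify_antegrade, classify_collateral
from .tac import AcquisitionGrid, PhaseSelectionError, Tac, select_phases
from .timing import (
    DEFAULT_VISIBILITY_THRESHOLD,
    CensoredClearanceError,
    CensoredOnsetError,
    VeinEnhancement,
)

__all__ = ["score_patient", "score_cohort", "add_velocity_labels", "RCVF_INDICES"]

RCVF_INDICES = ("rcvf1", "rcvf2", "rcvf3", "rcvf21", "rcvf31")


def _patient_tacs(df: pd.DataFrame) -> tuple[AcquisitionGrid, dict[tuple[str, str], Tac]]:
    times = np.sort(df["time_s"].unique())
    grid = AcquisitionGrid(tuple(times))
    tacs: dict[tuple[str, str], Tac] = {}
    for (hemi, structure), sub in df.groupby(["hemisphere", "structure"]):
        sub = sub.sort_values("time_s")
        if len(sub) != len(grid):
            raise ValueError(
                f"{structure}/{hemi}: {len(sub)} samples but grid has {len(grid)}"
            )
        tacs[(hemi, structure)] = Tac(grid, tuple(sub["attenuation_hu"].to_numpy()))
    return grid, tacs


def _score_hemisphere(
    hemi: str,
    tacs: dict[tuple[str, str], Tac],
    grid: AcquisitionGrid,
    v_tac: float,
    threshold: float,
) -> dict:
    """Presence flags, CVF1/2/3 (NaN when censored) and censoring flags."""
    dt = grid.spacing
    out: dict = {}
    vein_tacs = {v: tacs[(hemi, v)] for v in tim.VEINS if (hemi, v) in tacs}

    fallback = (v_tac - 2 * dt, grid.end)
    provisional = {
        v: ext.assess_presence(t, threshold, fallback) for v, t in vein_tacs.items()
    }
    cvf1 = cvf2 = cvf3 = np.nan
    censored_onset = censored_clearance = False
    presence = provisional
    if any(provisional.values()):
        veins = [
            VeinEnhancement(v, hemi, t, present=provisional[v]) for v, t in vein_tacs.items()
        ]
        try:
            cvf1_prov = tim.detect_cvf1(veins, threshold)
            window = (cvf1_prov - dt, grid.end)
            presence = {v: ext.assess_presence(t, threshold, window) for v, t in vein_tacs.items()}
            veins = [
                VeinEnhancement(v, hemi, t, present=presence[v]) for v, t in vein_tacs.items()
            ]
            cvf1 = tim.detect_cvf1(veins, threshold)
            cvf2 = tim.detect_cvf2(veins)
            try:
                cvf3 = tim.detect_cvf3(veins, threshold, after=cvf2)
            except CensoredClearanceError:
                censored_clearance = True
        except CensoredOnsetError:
            censored_onset = True
    else:
        censored_onset = True

    side = "aff" if hemi == "affected" else "contra"
    for v in tim.VEINS:
        out[f"{v.lower()}_{side}"] = "CVF+" if presence.get(v, False) else "CVF-"
    out[f"cvf1_{side}"] = cvf1
    out[f"cvf2_{side}"] = cvf2
    out[f"cvf3_{side}"] = cvf3
    out[f"cvf21_{side}"] = cvf2 - cvf1
    out[f"cvf31_{side}"] = cvf3 - cvf1
    out[f"censored_onset_{side}"] = int(censored_onset)
    out[f"censored_clearance_{side}"] = int(censored_clearance)
    out[f"_presence_{side}"] = presence
    return out


def score_patient(
    patient_df: pd.DataFrame,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> dict:
    """Score one patient's TAC set; returns a flat dict of score columns."""
    grid, tacs = _patient_tacs(patient_df)
    required = [("affected", "MCA"), ("contralateral", "MCA"), ("affected", "SSS")]
    for key in required:
        if key not in tacs:
            raise ValueError(f"missing TAC for {key[1]} ({key[0]} hemisphere)")
    phases = select_phases(
        tacs[("affected", "MCA")], tacs[("contralateral", "MCA")], tacs[("affected", "SSS")]
    )
    row: dict = {
        "patient_id": patient_df["patient_id"].iloc[0],
        "group": patient_df["group"].iloc[0],
        "a_tac": phases.a_tac,
        "v_tac": phases.v_tac,
    }
    for hemi in ("affected", "contralateral"):
        row.update(_score_hemisphere(hemi, tacs, grid, phases.v_tac, visibility_threshold))

    # relative scores (NaN-propagating, so censoring never fabricates a value)
    row["rcvf1"] = row["cvf1_aff"] - row["cvf1_contra"]
    row["rcvf2"] = row["cvf2_aff"] - row["cvf2_contra"]
    row["rcvf3"] = row["cvf3_aff"] - row["cvf3_contra"]
    row["rcvf21"] = row["cvf21_aff"] - row["cvf21_contra"]
    row["rcvf31"] = row["cvf31_aff"] - row["cvf31_contra"]

    pres_aff = row.pop("_presence_aff")
    pres_contra = row.pop("_presence_contra")
    result = ext.ipsilateral_absence(
        ext.VeinPresence(*(pres_aff.get(v, False) for v in tim.VEINS)),
        ext.VeinPresence(*(pres_contra.get(v, False) for v in tim.VEINS)),
    )
    row["ipsilateral_cvf_minus_n"] = result.n_ipsilateral_absent
    row["ipsilateral_cvf_minus"] = ",".join(sorted(result.ipsilateral_absent))
    return row


def score_cohort(
    tac_df: pd.DataFrame,
    clinical_df: pd.DataFrame | None = None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> pd.DataFrame:
    """Score every patient in a long-format TAC table; optionally merge the
    clinical table and derive antegrade/collateral/outcome labels."""
    rows = []
    for pid, sub in tac_df.groupby("patient_id", sort=True):
        try:
            rows.append(score_patient(sub, visibility_threshold))
        except (PhaseSelectionError, ValueError) as exc:
            raise type(exc)(f"patient {pid}: {exc}") from exc
    scores = pd.DataFrame(rows)
    if clinical_df is not None:
        scores = scores.merge(
            clinical_df.drop(columns=["group"], errors="ignore"), on="patient_id", how="left"
        )
        if "antegrade_filling_ratio" in scores.columns:
            scores["antegrade_label"] = scores["antegrade_filling_ratio"].map(
                lambda r: classify_antegrade(r) if pd.notna(r) else np.nan
            )
        if {"collateral_grade_atac", "collateral_grade_vtac"} <= set(scores.columns):
            scores["collateral_status"] = [
                classify_collateral(a, v) if isinstance(a, str) and isinstance(v, str) else np.nan
                for a, v in zip(scores["collateral_grade_atac"], scores["collateral_grade_vtac"])
            ]
        if "mrs_3month" in scores.columns:
            scores["poor_outcome"] = scores["mrs_3month"].map(
                lambda m: float(m > 2) if pd.notna(m) else np.nan
            )
    return scores


def add_velocity_labels(scores: pd.DataFrame, analysis_group: str = "symptomatic") -> pd.DataFrame:
    """Median-split fast/slow flags per rCVF index, thresholds computed
    within the analysis cohort (the symptomatic group by default).

    Adds velocity_fast_<index> (1 = fast, 0 = slow, NaN outside the analysis
    cohort or when the score is missing) and velocity_threshold_<index>.
    """
    scores = scores.copy()
    mask = scores["group"] == analysis_group
    for idx in RCVF_INDICES:
        vals = scores.loc[mask, idx].dropna()
        if vals.empty:
            raise ValueError(f"no finite {idx} values in the {analysis_group} group")
        labels = tim.classify_velocity(vals.to_numpy(), index=idx)
        threshold = labels[0].threshold
        scores[f"velocity_threshold_{idx}"] = threshold
        scores[f"velocity_fast_{idx}"] = np.where(
            mask & scores[idx].notna(), (scores[idx] <= threshold).astype(float), np.nan
        )
    return scores
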