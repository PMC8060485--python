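"""Cohort summary tables in the style of a clinical imaging study.

Five summaries are produced from the scored cohort:

* baseline        — demographics and risk factors by group;
* hemispheres     — per-group vein absence and CVF times, affected vs
                    contralateral hemisphere;
* imaging         — between-group imaging findings (ipsilateral CVF-,
                    rCVF medians, collateral status, antegrade flow);
* velocity        — fast/slow rCVF velocity vs collateral status in the
                    symptomatic group, with the Woolf OR per index;
* outcome         — 3-month outcome associations in the symptomatic group,
                    with univariate and NIHSS-adjusted odds ratios for the
                    two-vein ipsilateral CVF- category.

Counts print as "k (pct%)" with percentages rounded half-away-from-zero;
continuous variables as mean ± sd or median (q1–q3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import RCVF_INDICES
from .stats import (
    Contingency2x2,
    DegenerateSampleError,
    SeparationError,
    association_test_2x2,
    fmt_count_pct,
    fmt_mean_sd,
    fmt_median_iqr,
    group_compare_continuous,
    logistic_regression,
    odds_ratio_woolf,
)

__all__ = ["summarize_cohort", "velocity_collateral_table", "outcome_table"]

VEIN_COLS = ("smcv", "vot", "vol")


def _count_row(label: str, flags_a, flags_b, mode: str = "auto") -> dict:
    a, b = np.asarray(flags_a, dtype=float), np.asarray(flags_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    ka, kb = int(a.sum()), int(b.sum())
    table = Contingency2x2(ka, len(a) - ka, kb, len(b) - kb)
    test = association_test_2x2(table, mode=mode)
    return {
        "variable": label,
        "group_a": fmt_count_pct(ka, len(a)),
        "group_b": fmt_count_pct(kb, len(b)),
        "p": round(test.p_value, 4),
        "test": test.method,
    }


def _continuous_row(label: str, x, y, mode: str) -> dict:
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    fmt = fmt_mean_sd if mode == "t" else fmt_median_iqr
    try:
        p = round(group_compare_continuous(x, y, mode=mode).p_value, 4)
    except (ValueError, DegenerateSampleError):
        p = np.nan
    return {"variable": label, "group_a": fmt(x), "group_b": fmt(y), "p": p, "test": mode}


def baseline_table(scores: pd.DataFrame) -> pd.DataFrame:
    sym = scores[scores["group"] == "symptomatic"]
    asy = scores[scores["group"] == "asymptomatic"]
    rows = [_continuous_row("Age, years", sym["age"], asy["age"], "t")]
    for col, label in [
        ("female", "Female"),
        ("hypertension", "Hypertension"),
        ("diabetes", "Diabetes mellitus"),
        ("smoking", "Smoking history"),
        ("drinking", "Drinking"),
        ("lipid_disorder", "Lipid disorder"),
    ]:
        rows.append(_count_row(label, sym[col], asy[col]))
    rows.append(
        _count_row(
            "Occlusion (100%)",
            sym["stenosis_class"] == "occlusion",
            asy["stenosis_class"] == "occlusion",
        )
    )
    return pd.DataFrame(rows)


def hemisphere_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per group: vein absence and CVF times, affected vs contralateral."""
    rows = []
    for group in ("symptomatic", "asymptomatic"):
        g = scores[scores["group"] == group]
        any_aff = g[[f"{v}_aff" for v in VEIN_COLS]].eq("CVF-").any(axis=1)
        any_con = g[[f"{v}_contra" for v in VEIN_COLS]].eq("CVF-").any(axis=1)
        row = _count_row("Any CVF-", any_aff, any_con)
        rows.append({"group": group, **row})
        for v in VEIN_COLS:
            row = _count_row(f"{v.upper()}-", g[f"{v}_aff"] == "CVF-", g[f"{v}_contra"] == "CVF-")
            rows.append({"group": group, **row})
        for t in ("cvf1", "cvf2", "cvf3", "cvf21", "cvf31"):
            row = _continuous_row(
                f"{t.upper()}, s", g[f"{t}_aff"], g[f"{t}_contra"], "mann_whitney"
            )
            rows.append({"group": group, **row})
    df = pd.DataFrame(rows)
    return df.rename(columns={"group_a": "affected", "group_b": "contralateral"})


def imaging_table(scores: pd.DataFrame) -> pd.DataFrame:
    sym = scores[scores["group"] == "symptomatic"]
    asy = scores[scores["group"] == "asymptomatic"]
    rows = [
        _count_row(
            "Ipsilateral CVF-",
            sym["ipsilateral_cvf_minus_n"] >= 1,
            asy["ipsilateral_cvf_minus_n"] >= 1,
        )
    ]
    for v in VEIN_COLS:
        rows.append(
            _count_row(
                f"Ipsilateral {v.upper()}-",
                sym["ipsilateral_cvf_minus"].str.contains(v.upper()),
                asy["ipsilateral_cvf_minus"].str.contains(v.upper()),
            )
        )
    for n in (1, 2):
        rows.append(
            _count_row(
                f"CVF- = {n}",
                sym["ipsilateral_cvf_minus_n"] == n,
                asy["ipsilateral_cvf_minus_n"] == n,
            )
        )
    for idx in RCVF_INDICES:
        rows.append(_continuous_row(f"{idx}, s", sym[idx], asy[idx], "mann_whitney"))
    rows.append(_count_row("Poor collateral status", sym["collateral_status"] == "poor",
                           asy["collateral_status"] == "poor"))
    rows.append(_count_row("Compromised antegrade flow", sym["antegrade_label"] == "compromised",
                           asy["antegrade_label"] == "compromised"))
    return pd.DataFrame(rows)


def velocity_collateral_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Fast/slow velocity vs collateral status, symptomatic patients.

    One row per rCVF index with the fast counts in each collateral group and
    the Woolf OR for "fast" (exposure) vs poor collateral status (case):
    cells (poor&fast, poor&slow, good&fast, good&slow).
    """
    sym = scores[(scores["group"] == "symptomatic") & scores["collateral_status"].notna()]
    rows = []
    for idx in RCVF_INDICES:
        sub = sym[sym[f"velocity_fast_{idx}"].notna()]
        fast = sub[f"velocity_fast_{idx}"] == 1
        poor = sub["collateral_status"] == "poor"
        table = Contingency2x2(
            int((poor & fast).sum()),
            int((poor & ~fast).sum()),
            int((~poor & fast).sum()),
            int((~poor & ~fast).sum()),
        )
        test = association_test_2x2(table)
        orr = odds_ratio_woolf(table)
        rows.append(
            {
                "index": idx,
                "fast_good": fmt_count_pct(table.c, table.c + table.d),
                "fast_poor": fmt_count_pct(table.a, table.a + table.b),
                "p": round(test.p_value, 4),
                "or": round(orr.odds_ratio, 2),
                "ci_low": round(orr.ci_low, 2),
                "ci_high": round(orr.ci_high, 2),
                "or_method": orr.method,
                "threshold_s": float(sub[f"velocity_threshold_{idx}"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def outcome_table(scores: pd.DataFrame, adjustment: tuple[str, ...] = ("nihss",)) -> pd.DataFrame:
    """3-month outcome associations in the symptomatic group.

    Univariate rows compare good (mRS 0-2) vs poor (mRS > 2) outcomes.  For
    the two-vein ipsilateral CVF- category the Woolf OR is reported with
    good outcome as the case and CVF- = 2 as the exposure (the orientation
    whose interval is printed in the source tables), alongside univariate
    and covariate-adjusted logistic fits of the same contrast.
    """
    sym = scores[(scores["group"] == "symptomatic") & scores["poor_outcome"].notna()].copy()
    good = sym[sym["poor_outcome"] == 0]
    poor = sym[sym["poor_outcome"] == 1]
    rows = [
        _continuous_row("Age, years", good["age"], poor["age"], "t"),
        _continuous_row("NIHSS", good["nihss"], poor["nihss"], "mann_whitney"),
    ]
    for col, label in [
        ("hypertension", "Hypertension"),
        ("diabetes", "Diabetes"),
        ("smoking", "Smoking history"),
        ("angioplasty", "Angioplasty"),
    ]:
        rows.append(_count_row(label, good[col], poor[col]))
    rows.append(
        _count_row("Ipsilateral CVF-", good["ipsilateral_cvf_minus_n"] >= 1,
                   poor["ipsilateral_cvf_minus_n"] >= 1)
    )
    for n in (1, 2):
        rows.append(_count_row(f"CVF- = {n}", good["ipsilateral_cvf_minus_n"] == n,
                               poor["ipsilateral_cvf_minus_n"] == n))
    for idx in RCVF_INDICES:
        col = f"velocity_fast_{idx}"
        rows.append(_count_row(f"Slow {idx}", good[col] == 0, poor[col] == 0))
    rows.append(_count_row("Poor collateral status", good["collateral_status"] == "poor",
                           poor["collateral_status"] == "poor"))
    rows.append(_count_row("Compromised antegrade flow", good["antegrade_label"] == "compromised",
                           poor["antegrade_label"] == "compromised"))
    df = pd.DataFrame(rows)

    # odds-ratio columns for the CVF- = 2 contrast
    exposed = sym["ipsilateral_cvf_minus_n"] == 2
    favorable = (sym["poor_outcome"] == 0).astype(float)
    table = Contingency2x2(
        int((exposed & (favorable == 1)).sum()),
        int((~exposed & (favorable == 1)).sum()),
        int((exposed & (favorable == 0)).sum()),
        int((~exposed & (favorable == 0)).sum()),
    )
    orr = odds_ratio_woolf(table)
    df.attrs["cvf2_or"] = {
        "or": orr.odds_ratio,
        "ci_low": orr.ci_low,
        "ci_high": orr.ci_high,
        "method": orr.method,
    }
    for adjusted in (False, True):
        cols = ["exposed"] + (list(adjustment) if adjusted else [])
        X = pd.DataFrame({"exposed": exposed.astype(float)})
        for c in (adjustment if adjusted else ()):
            X[c] = sym[c].astype(float)
        key = "cvf2_logistic_adjusted" if adjusted else "cvf2_logistic"
        try:
            fit = logistic_regression(favorable.to_numpy(), X.to_numpy(), names=tuple(X.columns))
            df.attrs[key] = fit.summary_row("exposed")
        except (SeparationError, ValueError) as exc:
            df.attrs[key] = {"error": str(exc)}
    return df


def summarize_cohort(scores: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All five summary tables keyed by name."""
    for col in ("patient_id", "group", "rcvf21", "ipsilateral_cvf_minus_n"):
        if col not in scores.columns:
            raise ValueError(f"scores table is missing mandatory column {col!r}")
    return {
        "baseline": baseline_table(scores),
        "hemispheres": hemisphere_table(scores),
        "imaging": imaging_table(scores),
        "velocity": velocity_collateral_table(scores),
        "outcome": outcome_table(scores),
    }
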