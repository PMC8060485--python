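"""Shared fixtures: grids, gamma-variate parameter sets, and a hand-built
TAC table reproducing the first worked case's printed hemisphere readings."""

import numpy as np
import pandas as pd
import pytest

from cvflow.tac import AcquisitionGrid, GammaVariateParams, default_grid


@pytest.fixture
def grid19() -> AcquisitionGrid:
    return default_grid()


@pytest.fixture
def gv_params() -> GammaVariateParams:
    # t0=10, alpha=3, beta=2 -> analytic peak at t=16
    return GammaVariateParams(t0=10.0, alpha=3.0, beta=2.0, K=1.0, baseline=40.0)


# grid times chosen so the printed case-1 readings (A-TAC 16.2 s, V-TAC
# 24.8 s, vein onsets 19.0/20.9 s, clearances 32.7/37.7 s) are grid members
CASE1_TIMES = (10.0, 13.0, 16.2, 19.0, 20.9, 22.9, 24.8, 27.0, 29.0, 32.7, 35.0, 37.7, 40.0)


def _step_curve(times, baseline, onset, clearance, peak_time, peak=300.0, plateau=150.0):
    """Visible (>=50 HU enhancement) on [onset, clearance); unique max at peak_time."""
    vals = []
    for t in times:
        if onset <= t < clearance:
            vals.append(baseline + (peak if t == peak_time else plateau))
        else:
            vals.append(baseline)
    return vals


@pytest.fixture
def case1_tac_df() -> pd.DataFrame:
    """One-patient long-format TAC table whose scored CVF times equal the
    first worked case: contralateral (19.0, 24.8, 32.7), affected
    (20.9, 24.8, 37.7), A-TAC 16.2 s, V-TAC 24.8 s."""
    times = CASE1_TIMES
    base = 40.0
    rows = []

    def add(hemi, structure, values):
        for t, v in zip(times, values):
            rows.append(("case1", "asymptomatic", hemi, structure, t, v))

    # MCA: peak at 16.2 s (pre-venous), both sides
    mca = [base + (250.0 if t == 16.2 else (120.0 if t in (13.0, 19.0) else 0.0)) for t in times]
    add("affected", "MCA", mca)
    add("contralateral", "MCA", mca)
    # SSS: unique sampled peak at 24.8 s
    sss = [base + (400.0 if t == 24.8 else (200.0 if 19.0 <= t <= 29.0 else 0.0)) for t in times]
    add("affected", "SSS", sss)
    add("contralateral", "SSS", sss)
    for vein in ("SMCV", "VOT", "VOL"):
        add("contralateral", vein, _step_curve(times, base, 19.0, 32.7, 24.8))
        add("affected", vein, _step_curve(times, base, 20.9, 37.7, 24.8))
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "hemisphere", "structure", "time_s", "attenuation_hu"]
    )
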