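"""Seeded synthetic cohorts of per-vessel TACs plus clinical covariates.

No per-patient data accompany the study this package emulates, so the
generator builds cohorts with the same statistical structure the analysis
assumes, exposing the injected ground truth for recovery tests:

* every vessel's TAC is a gamma-variate bolus curve on the acquisition
  grid, with cortical-vein arrival = arterial arrival + venous transit;
* the affected hemisphere's veins are delayed by an onset shift delta1 and
  additionally widened in time so their peak lags by a further delta21
  (implemented as beta' = beta + delta21/alpha at fixed peak enhancement,
  so the peak moves by exactly delta1 + delta21);
* group-specific delay distributions are shifted log-normals matched to the
  published group medians (delta1: 2.0 s symptomatic / 1.8 s asymptomatic;
  delta21: 1.9 s / 0.1 s), allowing negative delta21;
* each vein is independently absent (a pure-noise curve) with a
  group-and-side-specific probability; bilateral absence is allowed;
* collateral status is linked probabilistically to whether the injected
  delta21 is fast (at or below the group's configured median), and the
  3-month outcome to the true ipsilateral CVF- count.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tac import AcquisitionGrid, GammaVariateParams, Tac, default_grid, sample_tac
from .timing import VEINS

__all__ = [
    "DelayDistribution",
    "VesselShape",
    "GroupParams",
    "CohortConfig",
    "CohortBundle",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "recovery_report",
]

#: seed used by the shipped analysis configuration
DEFAULT_SEED = 20210408

GROUPS = ("symptomatic", "asymptomatic")
HEMISPHERES = ("affected", "contralateral")


@dataclass(frozen=True)
class DelayDistribution:
    """Shifted log-normal delay: shift + LogNormal(ln(median), sigma) seconds.

    sigma = 0 collapses to the constant shift + median, which the recovery
    tests use for exact grid-shift oracles.  Samples are clipped to
    [clip_low, clip_high].
    """

    median: float
    sigma: float
    shift: float = 0.0
    clip_low: float = -2.5
    clip_high: float = 12.0

    @property
    def population_median(self) -> float:
        return self.shift + self.median

    def sample(self, rng: np.random.Generator) -> float:
        if self.sigma == 0.0:
            return self.population_median
        draw = self.shift + rng.lognormal(mean=np.log(self.median), sigma=self.sigma)
        return float(np.clip(draw, self.clip_low, self.clip_high))


@dataclass(frozen=True)
class VesselShape:
    """Gamma-variate shape for one vessel class, parameterized by the peak
    enhancement so that timescale changes do not change amplitude."""

    alpha: float
    beta: float
    peak_enhancement: float  # HU above baseline at the mode
    baseline: float = 40.0

    def params(self, t0: float, beta: float | None = None, peak: float | None = None) -> GammaVariateParams:
        beta = self.beta if beta is None else beta
        peak = self.peak_enhancement if peak is None else peak
        mode = self.alpha * beta
        K = peak / (mode**self.alpha * np.exp(-self.alpha))
        return GammaVariateParams(t0=t0, alpha=self.alpha, beta=beta, K=K, baseline=self.baseline)


def _veins_dict(smcv: float, vot: float, vol: float) -> dict[str, float]:
    return {"SMCV": smcv, "VOT": vot, "VOL": vol}


@dataclass(frozen=True)
class GroupParams:
    """Per-group delay distributions, vein-absence probabilities and the
    probabilistic links to collateral status and 3-month outcome."""

    delta1: DelayDistribution
    delta21: DelayDistribution
    absence_affected: dict[str, float]
    absence_contralateral: dict[str, float]
    p_poor_collateral_fast: float
    p_poor_collateral_slow: float
    p_preserved_antegrade: float
    # P(poor 3-month outcome | true ipsilateral CVF- count 0, 1, 2, 3)
    outcome_p_by_n: tuple[float, float, float, float] | None
    # demographics
    age_mean: float
    age_sd: float
    p_female: float
    p_hypertension: float
    p_diabetes: float
    p_smoking: float
    p_drinking: float
    p_lipid: float
    p_occlusion: float
    p_angioplasty: float = 0.0


def _default_symptomatic() -> GroupParams:
    return GroupParams(
        delta1=DelayDistribution(median=2.0, sigma=0.76, shift=0.0, clip_low=0.0),
        delta21=DelayDistribution(median=3.9, sigma=0.72, shift=-2.0),
        absence_affected=_veins_dict(0.19, 0.25, 0.28),
        absence_contralateral=_veins_dict(0.0, 0.0, 0.06),
        p_poor_collateral_fast=11 / 19,
        p_poor_collateral_slow=3 / 17,
        p_preserved_antegrade=15 / 36,
        outcome_p_by_n=(2 / 17, 3 / 12, 6 / 7, 6 / 7),
        age_mean=58.3,
        age_sd=9.2,
        p_female=0.25,
        p_hypertension=0.44,
        p_diabetes=0.33,
        p_smoking=0.64,
        p_drinking=0.25,
        p_lipid=0.72,
        p_occlusion=12 / 36,
        p_angioplasty=4 / 36,
    )


def _default_asymptomatic() -> GroupParams:
    return GroupParams(
        delta1=DelayDistribution(median=1.8, sigma=0.80, shift=0.0, clip_low=0.0),
        delta21=DelayDistribution(median=0.3, sigma=0.60, shift=-0.2),
        absence_affected=_veins_dict(0.05, 0.09, 0.05),
        absence_contralateral=_veins_dict(0.05, 0.0, 0.18),
        p_poor_collateral_fast=5 / 22,
        p_poor_collateral_slow=5 / 22,
        p_preserved_antegrade=10 / 22,
        outcome_p_by_n=None,  # asymptomatic patients carry no NIHSS/mRS
        age_mean=61.3,
        age_sd=11.0,
        p_female=0.27,
        p_hypertension=0.55,
        p_diabetes=0.32,
        p_smoking=0.46,
        p_drinking=0.36,
        p_lipid=0.71,
        p_occlusion=9 / 22,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort; the seed is mandatory."""

    seed: int
    n_symptomatic: int = 36
    n_asymptomatic: int = 22
    n_volumes: int = 19
    grid_spacing: float = 2.0
    grid_start: float = 8.0
    noise_sd: float = 5.0
    # bolus physiology
    arterial_t0_mean: float = 9.0
    arterial_t0_sd: float = 0.6
    venous_transit: float = 4.0  # cortical-vein arrival lag after arterial arrival, s
    arterial_shape: VesselShape = field(default_factory=lambda: VesselShape(3.0, 1.5, 350.0))
    vein_shape: VesselShape = field(default_factory=lambda: VesselShape(3.0, 1.8, 250.0))
    sss_shape: VesselShape = field(default_factory=lambda: VesselShape(3.0, 2.0, 420.0))
    sss_extra_lag: float = 0.5  # sinus fills just after the cortical veins
    vein_peak_jitter: float = 30.0  # per-vein uniform half-range around peak_enhancement, HU
    symptomatic: GroupParams = field(default_factory=_default_symptomatic)
    asymptomatic: GroupParams = field(default_factory=_default_asymptomatic)

    def grid(self) -> AcquisitionGrid:
        return default_grid(self.n_volumes, self.grid_spacing, self.grid_start)

    def group(self, name: str) -> GroupParams:
        if name == "symptomatic":
            return self.symptomatic
        if name == "asymptomatic":
            return self.asymptomatic
        raise ValueError(f"unknown group {name!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        for key in ("arterial_shape", "vein_shape", "sss_shape"):
            if key in raw:
                raw[key] = VesselShape(**raw[key])
        for key in ("symptomatic", "asymptomatic"):
            if key in raw:
                g = dict(raw[key])
                for dk in ("delta1", "delta21"):
                    if dk in g:
                        g[dk] = DelayDistribution(**g[dk])
                if "outcome_p_by_n" in g and g["outcome_p_by_n"] is not None:
                    g["outcome_p_by_n"] = tuple(g["outcome_p_by_n"])
                base = _default_symptomatic() if key == "symptomatic" else _default_asymptomatic()
                raw[key] = dataclasses.replace(base, **g)
        return cls(**raw)


@dataclass
class CohortBundle:
    """Generated cohort: long-format TACs, clinical records, ground truth."""

    tacs: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig


def _noise_only_tac(shape: VesselShape, grid: AcquisitionGrid, noise_sd: float,
                    rng: np.random.Generator) -> Tac:
    """An absent vein: baseline plus acquisition noise, no contrast passage."""
    values = shape.baseline + (rng.normal(0.0, noise_sd, size=len(grid)) if noise_sd > 0
                               else np.zeros(len(grid)))
    return Tac(grid, tuple(np.atleast_1d(values)), baseline=shape.baseline)


def generate_patient(
    config: CohortConfig, group: str, patient_id: str, rng: np.random.Generator
) -> tuple[dict[tuple[str, str], Tac], dict, dict]:
    """One patient: TACs keyed by (hemisphere, structure), a clinical record,
    and the injected ground truth."""
    gp = config.group(group)
    grid = config.grid()

    t0_art = float(np.clip(rng.normal(config.arterial_t0_mean, config.arterial_t0_sd),
                           config.grid_start + 0.2, config.grid_start + 6.0))
    t0_vein = t0_art + config.venous_transit
    delta1 = gp.delta1.sample(rng)
    delta21 = gp.delta21.sample(rng)
    beta_aff = max(config.vein_shape.beta + delta21 / config.vein_shape.alpha, 0.4)

    # clinical draws
    antegrade_preserved = rng.random() < gp.p_preserved_antegrade
    filling_ratio = float(rng.uniform(0.70, 1.0) if antegrade_preserved
                          else rng.uniform(0.15, 2.0 / 3.0))
    fast_truth = delta21 <= gp.delta21.population_median
    p_poor = gp.p_poor_collateral_fast if fast_truth else gp.p_poor_collateral_slow
    collateral_poor = rng.random() < p_poor
    if collateral_poor:
        grade_a = str(rng.choice(["none", "peripheral"], p=[0.4, 0.6]))
        grade_v = str(rng.choice(["none", "peripheral"], p=[0.3, 0.7]))
    else:
        grade_v = "complete"
        grade_a = str(rng.choice(["none", "peripheral", "complete"], p=[0.2, 0.5, 0.3]))

    absent = {
        ("affected", v): rng.random() < gp.absence_affected[v] for v in VEINS
    } | {
        ("contralateral", v): rng.random() < gp.absence_contralateral[v] for v in VEINS
    }
    n_ipsi_true = sum(
        absent[("affected", v)] and not absent[("contralateral", v)] for v in VEINS
    )

    # TACs
    tacs: dict[tuple[str, str], Tac] = {}
    art_contra = config.arterial_shape.params(t0_art)
    art_aff = config.arterial_shape.params(
        t0_art, peak=config.arterial_shape.peak_enhancement * (0.4 + 0.6 * filling_ratio)
    )
    tacs[("contralateral", "MCA")] = sample_tac(art_contra, grid, config.noise_sd, rng)
    tacs[("affected", "MCA")] = sample_tac(art_aff, grid, config.noise_sd, rng)
    sss = config.sss_shape.params(t0_vein + config.sss_extra_lag)
    sss_tac = sample_tac(sss, grid, config.noise_sd, rng)
    tacs[("affected", "SSS")] = sss_tac  # midline structure, duplicated per side
    tacs[("contralateral", "SSS")] = sss_tac
    for vein in VEINS:
        peak = config.vein_shape.peak_enhancement + (
            rng.uniform(-config.vein_peak_jitter, config.vein_peak_jitter)
            if config.vein_peak_jitter > 0 else 0.0
        )
        for hemi in HEMISPHERES:
            if absent[(hemi, vein)]:
                tacs[(hemi, vein)] = _noise_only_tac(config.vein_shape, grid, config.noise_sd, rng)
            elif hemi == "contralateral":
                tacs[(hemi, vein)] = sample_tac(
                    config.vein_shape.params(t0_vein, peak=peak), grid, config.noise_sd, rng
                )
            else:
                tacs[(hemi, vein)] = sample_tac(
                    config.vein_shape.params(t0_vein + delta1, beta=beta_aff, peak=peak),
                    grid, config.noise_sd, rng,
                )

    record = {
        "patient_id": patient_id,
        "group": group,
        "age": round(float(np.clip(rng.normal(gp.age_mean, gp.age_sd), 30, 92)), 1),
        "female": int(rng.random() < gp.p_female),
        "hypertension": int(rng.random() < gp.p_hypertension),
        "diabetes": int(rng.random() < gp.p_diabetes),
        "smoking": int(rng.random() < gp.p_smoking),
        "drinking": int(rng.random() < gp.p_drinking),
        "lipid_disorder": int(rng.random() < gp.p_lipid),
        "stenosis_class": "occlusion" if rng.random() < gp.p_occlusion else "70-99%",
        "antegrade_filling_ratio": round(filling_ratio, 3),
        "collateral_grade_atac": grade_a,
        "collateral_grade_vtac": grade_v,
        "angioplasty": int(rng.random() < gp.p_angioplasty),
        "nihss": np.nan,
        "mrs_3month": np.nan,
    }
    truth = {
        "patient_id": patient_id,
        "group": group,
        "delta1": delta1,
        "delta21": delta21,
        "fast_delta21": int(fast_truth),
        "collateral_poor": int(collateral_poor),
        "antegrade_preserved": int(antegrade_preserved),
        "n_ipsilateral_absent": n_ipsi_true,
        "poor_outcome": np.nan,
    }
    for hemi in HEMISPHERES:
        for vein in VEINS:
            truth[f"absent_{vein.lower()}_{'aff' if hemi == 'affected' else 'contra'}"] = int(
                absent[(hemi, vein)]
            )

    if gp.outcome_p_by_n is not None:
        poor = rng.random() < gp.outcome_p_by_n[min(n_ipsi_true, 3)]
        truth["poor_outcome"] = int(poor)
        if poor:
            record["mrs_3month"] = int(rng.choice([3, 4, 5, 6], p=[0.5, 0.3, 0.15, 0.05]))
            record["nihss"] = int(np.clip(rng.poisson(5), 0, 30))
        else:
            record["mrs_3month"] = int(rng.choice([0, 1, 2], p=[0.3, 0.4, 0.3]))
            record["nihss"] = int(np.clip(rng.poisson(3), 0, 30))
    return tacs, record, truth


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Deterministic cohort from the config seed: long-format TAC table plus
    clinical and ground-truth tables (one row per patient)."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    rows, clin_rows, truth_rows = [], [], []
    counts = {"symptomatic": config.n_symptomatic, "asymptomatic": config.n_asymptomatic}
    for group in GROUPS:
        for i in range(counts[group]):
            pid = f"{'S' if group == 'symptomatic' else 'A'}{i + 1:03d}"
            tacs, record, truth = generate_patient(config, group, pid, rng)
            clin_rows.append(record)
            truth_rows.append(truth)
            for (hemi, structure), tac in tacs.items():
                for t, v in zip(grid.times, tac.values):
                    rows.append((pid, group, hemi, structure, t, v))
    tac_df = pd.DataFrame(
        rows,
        columns=["patient_id", "group", "hemisphere", "structure", "time_s", "attenuation_hu"],
    )
    return CohortBundle(
        tacs=tac_df,
        clinical=pd.DataFrame(clin_rows),
        ground_truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write TAC/clinical/ground-truth CSVs and a manifest JSON; returns the
    manifest dict (file paths, config echo, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tacs": out / "tacs.csv",
        "clinical": out / "clinical.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    bundle.tacs.to_csv(paths["tacs"], index=False)
    bundle.clinical.to_csv(paths["clinical"], index=False)
    bundle.ground_truth.to_csv(paths["ground_truth"], index=False)
    manifest = {
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "files": {k: str(p) for k, p in paths.items()},
        "n_patients": int(len(bundle.clinical)),
    }
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def recovery_report(ground_truth: pd.DataFrame, scores: pd.DataFrame) -> dict:
    """Recovered-vs-injected metrics: delay bias/RMSE, vein-presence and
    collateral/outcome confusion counts."""
    gt = ground_truth.set_index("patient_id")
    sc = scores.set_index("patient_id")
    missing = set(gt.index) ^ set(sc.index)
    if missing:
        raise ValueError(f"patient id mismatch between truth and scores: {sorted(missing)[:5]}")
    sc = sc.loc[gt.index]

    report: dict = {}
    for truth_col, score_col in (("delta1", "rcvf1"), ("delta21", "rcvf21")):
        err = (sc[score_col] - gt[truth_col]).dropna()
        report[f"{score_col}_bias"] = float(err.mean())
        report[f"{score_col}_rmse"] = float(np.sqrt((err**2).mean()))

    conf = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}  # positive = present
    for vein in VEINS:
        for side in ("aff", "contra"):
            truth_present = 1 - gt[f"absent_{vein.lower()}_{side}"]
            scored_present = (sc[f"{vein.lower()}_{side}"] == "CVF+").astype(int)
            conf["tp"] += int(((truth_present == 1) & (scored_present == 1)).sum())
            conf["tn"] += int(((truth_present == 0) & (scored_present == 0)).sum())
            conf["fp"] += int(((truth_present == 0) & (scored_present == 1)).sum())
            conf["fn"] += int(((truth_present == 1) & (scored_present == 0)).sum())
    report["presence_confusion"] = conf
    report["presence_misclassified"] = conf["fp"] + conf["fn"]

    if "collateral_status" in sc.columns:
        agree = (sc["collateral_status"] == "poor") == (gt["collateral_poor"] == 1)
        report["collateral_agreement"] = float(agree.mean())
    both = gt["poor_outcome"].notna() & sc.get("poor_outcome", pd.Series(index=sc.index)).notna()
    if both.any():
        report["outcome_agreement"] = float(
            (gt.loc[both, "poor_outcome"] == sc.loc[both, "poor_outcome"]).mean()
        )
    return report
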