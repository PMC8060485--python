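"""End-to-end orchestration: simulate -> score -> analyze -> report.

Every stage reads and writes the package's stable file contracts (long TAC
CSV, clinical CSV, scores CSV, per-table CSVs) and the run is summarized in
a versioned manifest JSON.  Re-running with the same config and inputs
reproduces identical outputs; all randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scoring import add_velocity_labels, score_cohort
from .simulate import CohortConfig, generate_cohort, write_cohort
from .tables import summarize_cohort

__all__ = ["run_pipeline", "PipelineError", "MANIFEST_SCHEMA_VERSION"]

MANIFEST_SCHEMA_VERSION = 1
logger = logging.getLogger("cvflow")

STAGES = ("simulate", "score", "analyze", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and patient, if any)."""


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    return str(o)


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    tac_csv: str | Path | None = None,
    clinical_csv: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the selected stages and return the run manifest.

    When ``tac_csv``/``clinical_csv`` are supplied the simulate stage is
    skipped and the pipeline scores the provided data instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, seed=seed)
    manifest: dict = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "software_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "warnings": [],
    }
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    tac_df = clinical_df = scores = None
    try:
        if "simulate" in stages and tac_csv is None:
            t = time.perf_counter()
            bundle = generate_cohort(config)
            cohort_manifest = write_cohort(bundle, out)
            tac_df, clinical_df = bundle.tacs, bundle.clinical
            manifest["outputs"].update(cohort_manifest["files"])
            manifest["stages"]["simulate"] = {"seconds": round(time.perf_counter() - t, 3)}
            logger.info("simulate: %d patients", len(clinical_df))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    if tac_csv is not None:
        tac_df = pd.read_csv(tac_csv)
        manifest["outputs"]["tacs_input"] = str(tac_csv)
    if clinical_csv is not None:
        clinical_df = pd.read_csv(clinical_csv)
        manifest["outputs"]["clinical_input"] = str(clinical_csv)

    if "score" in stages:
        if tac_df is None:
            raise PipelineError("stage score failed: no TAC data (simulate or --tacs required)")
        t = time.perf_counter()
        try:
            scores = score_cohort(tac_df, clinical_df)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage score failed: {exc}") from exc
        try:
            scores = add_velocity_labels(scores)
        except ValueError as exc:
            # e.g. a score-only run with no symptomatic patients
            manifest["warnings"].append(f"velocity labels skipped: {exc}")
            logger.warning("velocity labels skipped: %s", exc)
        n_cens = int(
            scores[["censored_onset_aff", "censored_onset_contra",
                    "censored_clearance_aff", "censored_clearance_contra"]].to_numpy().sum()
        )
        if n_cens:
            manifest["warnings"].append(f"{n_cens} censored CVF time(s)")
            logger.warning("%d censored CVF time(s)", n_cens)
        scores_path = out / "scores.csv"
        scores.to_csv(scores_path, index=False)
        manifest["outputs"]["scores"] = str(scores_path)
        manifest["stages"]["score"] = {
            "seconds": round(time.perf_counter() - t, 3),
            "n_patients": int(len(scores)),
            "n_censored_times": n_cens,
        }

    results: dict = {}
    if "analyze" in stages:
        if scores is None:
            raise PipelineError("stage analyze failed: no scores (run the score stage first)")
        t = time.perf_counter()
        try:
            tables = summarize_cohort(scores)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage analyze failed: {exc}") from exc
        for name, table in tables.items():
            path = out / f"table_{name}.csv"
            table.to_csv(path, index=False)
            manifest["outputs"][f"table_{name}"] = str(path)
            for key, val in table.attrs.items():
                results[key] = val
        vel = tables["velocity"].set_index("index")
        results["velocity_or_rcvf21"] = {
            k: float(vel.loc["rcvf21", k]) for k in ("or", "ci_low", "ci_high")
        }
        manifest["stages"]["analyze"] = {"seconds": round(time.perf_counter() - t, 3)}

    if "report" in stages:
        results_path = out / "results.json"
        results_path.write_text(json.dumps(results, indent=2, default=_json_default))
        manifest["outputs"]["results"] = str(results_path)

    for path in manifest["outputs"].values():
        if not Path(path).exists():
            raise PipelineError(f"manifest lists missing output {path}")
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
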