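"""End-to-end orchestration: simulate -> clean -> summarize -> couple -> fit.

``run_pipeline`` executes every stage from one declarative config and writes
auditable per-stage reports (cleaning accounting, valid-day tallies, model
results, exclusion logs) plus a provenance log with the package version,
seed and a hash of the configuration.  The stage helpers
(:func:`process_cgm`, :func:`process_epochs`, :func:`process_cohort`) are
the same functions the tests drive, so a completed stage re-run from its
persisted inputs reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

import glucoupler
from glucoupler import actigraphy, association_models, cgm_ingest, coupling, glyco_metrics
from glucoupler.cgm_ingest import RECORD_USER
from glucoupler.synthetic_data import Cohort, SimulationConfig, generate_study_cohort


@dataclass
class RunConfig:
    """All thresholds and options of one pipeline run.

    Defaults reproduce the study's stated rules exactly: 86 consecutive
    glucose points for a valid glucose day, 600 worn minutes for a valid
    accelerometer day, 99/2019 CPM intensity cut-points, interpolation of
    at most 2 adjacent missing slots, a +/-3 min user-scan window, and >=7
    coupled valid days per included participant.  Any override is echoed in
    the run log.
    """

    seed: int = 0
    simulation: SimulationConfig | None = None
    glucose_valid_min_consecutive: int = cgm_ingest.VALID_DAY_MIN_CONSECUTIVE
    wear_valid_minutes: int = actigraphy.VALID_DAY_WEAR_MIN
    sedentary_max_cpm: int = actigraphy.SEDENTARY_MAX_CPM
    light_max_cpm: int = actigraphy.LIGHT_MAX_CPM
    nonwear_window_min: int = actigraphy.NONWEAR_WINDOW_MIN
    nonwear_max_interruption_min: int = actigraphy.NONWEAR_MAX_INTERRUPTION_MIN
    user_scan_window_min: int = cgm_ingest.USER_SCAN_WINDOW_MIN
    max_interpolation_run: int = cgm_ingest.MAX_INTERPOLATION_RUN
    min_coupled_days: int = coupling.MIN_COUPLED_DAYS
    correlation: str = "autoregressive"
    strata: tuple = ("all", "low_fit")
    include_sensitivity: bool = True

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def process_cgm(cgm: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean glucose exports and summarize each complete day.

    Returns (per participant-day glucose summaries, the cleaning accounting
    report).  Cleaning order is fixed: user-scan replacement, then bounded
    interpolation; metrics come from the largest consecutive block.
    """
    grids = cgm_ingest.build_day_grids(cgm)
    user = cgm[cgm["record_type"] == RECORD_USER]
    user_by_pid = dict(tuple(user.groupby("participant_id")))
    cleaned = []
    rows = []
    for g in grids:
        c = cgm_ingest.clean_day(
            g,
            user_by_pid.get(g.participant_id),
            window_min=config.user_scan_window_min,
            max_run=config.max_interpolation_run,
        )
        cleaned.append(c)
        row = glyco_metrics.summarize_glucose_day(
            c, min_consecutive=config.glucose_valid_min_consecutive
        )
        row["participant_id"] = c.participant_id
        rows.append(row)
    glucose_days = pd.DataFrame(rows)
    if not glucose_days.empty:
        glucose_days = glucose_days[
            [
                "participant_id",
                "date",
                "mean_glucose",
                "sd_glucose",
                "mage",
                "n_points",
                "largest_block",
                "valid",
            ]
        ]
    report = cgm_ingest.accounting(cleaned, min_consecutive=config.glucose_valid_min_consecutive)
    return glucose_days, report


def process_epochs(epochs: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Accelerometer epochs to daily behavior summaries (complete days only).

    The first and last calendar day of each participant are partial
    deployment days and are dropped, mirroring the glucose stream.
    """
    days = actigraphy.summarize_behavior(
        epochs,
        wear_threshold=config.wear_valid_minutes,
        window=config.nonwear_window_min,
        max_interruption=config.nonwear_max_interruption_min,
    )
    if days.empty:
        return days
    first = days.groupby("participant_id")["date"].transform("min")
    last = days.groupby("participant_id")["date"].transform("max")
    return days[(days["date"] > first) & (days["date"] < last)].reset_index(drop=True)


def process_cohort(
    cohort: Cohort, config: RunConfig
) -> dict:
    """Run cleaning, summarizing, coupling and selection on an in-memory cohort.

    Returns a dict with ``behavior_days``, ``glucose_days``, ``cleaning_report``,
    ``coupled``, ``analysis_table`` and ``exclusions``.
    """
    glucose_days, report = process_cgm(cohort.cgm, config)
    behavior_days = process_epochs(cohort.epochs, config)
    coupled = coupling.couple_days(behavior_days, glucose_days)
    valid_rows, exclusions = coupling.select_participants(
        coupled, min_coupled_days=config.min_coupled_days
    )
    table = coupling.build_analysis_table(valid_rows, cohort.profiles)
    return {
        "behavior_days": behavior_days,
        "glucose_days": glucose_days,
        "cleaning_report": report,
        "coupled": coupled,
        "analysis_table": table,
        "exclusions": exclusions,
    }


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Simulate a cohort and run every analysis stage, writing all reports.

    Writes, under ``outdir``: the simulated raw files, ``cleaning_report.csv``,
    ``behavior_days.csv``, ``glucose_days.csv``, ``analysis_table.csv``,
    ``exclusions.csv``, ``valid_day_tally.csv``, ``results.csv`` (the GEE
    battery), ``ancova.csv``, ``vif.csv`` and ``run_log.json``.  Stage
    failures abort with the stage name; outputs of completed stages are
    preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": glucoupler.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def _stage(name: str):
        log["stages"][name] = "started"
        return name

    try:
        stage = _stage("simulate")
        cohort, book = generate_study_cohort(config.simulation)
        from glucoupler.synthetic_data import write_cohort

        write_cohort(cohort, outdir / "simulated", book)
        log["stages"][stage] = {
            "participants": int(len(cohort.profiles)),
            "cgm_rows": int(len(cohort.cgm)),
            "epoch_rows": int(len(cohort.epochs)),
        }

        stage = _stage("process")
        stages = process_cohort(cohort, config)
        stages["cleaning_report"].to_csv(outdir / "cleaning_report.csv", index=False)
        stages["behavior_days"].to_csv(outdir / "behavior_days.csv", index=False)
        stages["glucose_days"].to_csv(outdir / "glucose_days.csv", index=False)
        stages["analysis_table"].to_csv(outdir / "analysis_table.csv", index=False)
        stages["exclusions"].to_csv(outdir / "exclusions.csv", index=False)
        coupled = stages["coupled"]
        tally = (
            coupled.groupby("participant_id")
            .agg(
                coupled_days=("valid", "size"),
                valid_behavior=("valid_behavior", "sum"),
                valid_glucose=("valid_glucose", "sum"),
                valid_coupled=("valid", "sum"),
            )
            .reset_index()
        )
        tally.to_csv(outdir / "valid_day_tally.csv", index=False)
        table = stages["analysis_table"]
        log["stages"][stage] = {
            "complete_days": int(len(coupled)),
            "valid_coupled_days": int(coupled["valid"].sum()),
            "included_participants": int(table["participant_id"].nunique()),
            "excluded_participants": int(len(stages["exclusions"])),
            "analysis_rows": int(len(table)),
        }

        stage = _stage("fit")
        strata = tuple(s for s in config.strata if s != "low_fit" or table["low_fitness"].any())
        results = association_models.run_model_battery(
            table,
            correlation=config.correlation,
            strata=strata,
            include_sensitivity=config.include_sensitivity,
        )
        results.to_csv(outdir / "results.csv", index=False)
        design = table[["sedentary_min", "wear_min", "age", "body_fat_pct"]].copy()
        design["sex_male"] = (table["sex"] == "M").astype(float)
        association_models.vif(design).rename_axis("predictor").reset_index().to_csv(
            outdir / "vif.csv", index=False
        )
        if table["low_fitness"].nunique() == 2:
            association_models.ancova_behavior_by_fitness(table).to_csv(
                outdir / "ancova.csv", index=False
            )
        log["stages"][stage] = {"fits": int(len(results)), "failed": int((results["error"] != "").sum())}
    except Exception as exc:
        log["error"] = f"stage {stage!r} failed: {exc}"
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        raise RuntimeError(log["error"]) from exc

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return outdir
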