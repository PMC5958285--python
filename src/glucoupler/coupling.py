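"""Day-level coupling of the two sensor streams and cohort inclusion rules.

A participant-day enters the analysis only when it is valid in *both*
streams (>=600 worn accelerometer minutes and >=86 consecutive glucose
points); participants contribute only if they have at least
``min_coupled_days`` (default 7) such coupled valid days.  Valid days are
ordered within participant (``day_index``) for the autoregressive working
correlation; gaps left by invalid days collapse by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_COUPLED_DAYS = 7

LOW_FITNESS_CATEGORIES = frozenset({"needs improvement", "fair", "good"})
HIGH_FITNESS_CATEGORIES = frozenset({"very good", "excellent"})


def _normalize_category(cat: str) -> str:
    return str(cat).strip().lower().replace("_", " ")


def couple_days(behavior_days: pd.DataFrame, glucose_days: pd.DataFrame) -> pd.DataFrame:
    """Inner-join daily behavior and glucose summaries on participant and date.

    A coupled day is valid iff both stream summaries are valid.  Duplicate
    participant-date keys in either input raise ``ValueError``.  Days present
    in only one stream produce no row.
    """
    for name, df in (("behavior", behavior_days), ("glucose", glucose_days)):
        if df.duplicated(subset=["participant_id", "date"]).any():
            raise ValueError(f"duplicate participant-date keys in {name} summaries")
    merged = behavior_days.merge(
        glucose_days,
        on=["participant_id", "date"],
        suffixes=("_behavior", "_glucose"),
        how="inner",
    )
    merged["valid"] = merged["valid_behavior"] & merged["valid_glucose"]
    return merged.sort_values(["participant_id", "date"]).reset_index(drop=True)


def select_participants(
    coupled: pd.DataFrame, min_coupled_days: int = MIN_COUPLED_DAYS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain participants with >= ``min_coupled_days`` valid coupled days.

    Returns (valid rows of included participants, exclusion log with each
    excluded participant's valid-day count).  Raises ``ValueError`` when no
    participant qualifies.
    """
    counts = coupled.groupby("participant_id")["valid"].sum()
    included = counts[counts >= min_coupled_days].index
    excluded = counts[counts < min_coupled_days]
    log = pd.DataFrame(
        {"participant_id": excluded.index, "valid_days": excluded.astype(int).values}
    )
    table = coupled[coupled["participant_id"].isin(included) & coupled["valid"]].copy()
    if table.empty:
        raise ValueError(
            f"no participant has >= {min_coupled_days} coupled valid days"
        )
    return table.reset_index(drop=True), log


def build_analysis_table(
    valid_days: pd.DataFrame,
    profiles: pd.DataFrame,
    calendar_day_index: bool = False,
) -> pd.DataFrame:
    """Attach participant covariates and the within-participant day order.

    ``day_index`` numbers each participant's valid days consecutively (the
    ordering used by the AR(1) working correlation); with
    ``calendar_day_index=True`` the calendar-day offset from the first valid
    day is used instead, preserving gaps.
    """
    table = valid_days.merge(
        profiles[["participant_id", "age", "sex", "body_fat_pct", "fitness_category"]],
        on="participant_id",
        how="left",
        validate="many_to_one",
    )
    if table["fitness_category"].isna().any():
        pid = table.loc[table["fitness_category"].isna(), "participant_id"].iloc[0]
        raise ValueError(f"participant {pid} missing from profiles")
    table = table.sort_values(["participant_id", "date"]).reset_index(drop=True)
    if calendar_day_index:
        first = table.groupby("participant_id")["date"].transform("min")
        table["day_index"] = [
            (d - f).days + 1 for d, f in zip(pd.to_datetime(table["date"]), pd.to_datetime(first))
        ]
    else:
        table["day_index"] = table.groupby("participant_id").cumcount() + 1
    cats = table["fitness_category"].map(_normalize_category)
    unknown = set(cats) - LOW_FITNESS_CATEGORIES - HIGH_FITNESS_CATEGORIES
    if unknown:
        raise ValueError(f"unknown fitness category: {sorted(unknown)!r}")
    table["low_fitness"] = cats.isin(LOW_FITNESS_CATEGORIES)
    return table


def stratify_by_fitness(
    table: pd.DataFrame, categories: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an analysis table into (low-fitness, high-fitness) strata.

    Low fitness comprises the *needs improvement*, *fair* and *good* health
    benefit zones; high fitness comprises *very good* and *excellent*.
    Unknown labels raise ``ValueError``.
    """
    cats = (categories if categories is not None else table["fitness_category"]).map(
        _normalize_category
    )
    unknown = set(cats) - LOW_FITNESS_CATEGORIES - HIGH_FITNESS_CATEGORIES
    if unknown:
        raise ValueError(f"unknown fitness category: {sorted(unknown)!r}")
    low = cats.isin(LOW_FITNESS_CATEGORIES).to_numpy()
    return (
        table[low].reset_index(drop=True),
        table[~low].reset_index(drop=True),
    )


def predicted_vo2max(o2_cost_l_min, age_years, weight_kg):
    """Aerobic fitness (mL/kg/min) from the submaximal step-test O2 cost.

    ``32.0 + 16.0*o2_cost - 0.24*age - 0.17*weight``, the published
    prediction equation for the modified Canadian Aerobic Fitness Test; the
    fitness category is then looked up in age/sex-specific health-benefit-zone
    tables supplied by the user (see :func:`categorize_fitness`).
    """
    return 32.0 + 16.0 * np.asarray(o2_cost_l_min) - 0.24 * np.asarray(age_years) - 0.17 * np.asarray(weight_kg)


def categorize_fitness(score, thresholds: pd.DataFrame) -> str:
    """Map a fitness score onto a category via a user-supplied threshold table.

    ``thresholds`` has columns ``category`` and ``min_score`` (ascending);
    the highest category whose ``min_score`` the score reaches is returned.
    """
    t = thresholds.sort_values("min_score")
    eligible = t[t["min_score"] <= score]
    if eligible.empty:
        return str(t["category"].iloc[0])
    return str(eligible["category"].iloc[-1])
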