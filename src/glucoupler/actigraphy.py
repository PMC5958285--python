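"""Accelerometer 60-s epoch processing: nonwear detection, intensity
classification and daily behavior summaries.

Epochs carry vertical-axis counts per minute (CPM).  A nonwear bout is a run
of at least ``window`` consecutive zero-count minutes, where interruptions of
at most ``max_interruption`` consecutive nonzero minutes do not terminate the
bout (the interruption minutes are themselves flagged nonwear but do not
count toward the zero-minute requirement).  Worn minutes are classified by
count cut-points into sedentary (0-99 CPM), light (100-2019 CPM) and
moderate-to-vigorous (MVPA, >=2020 CPM) intensity; a day is valid with
>=600 worn minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EPOCH_COLUMNS = ["participant_id", "timestamp", "axis1_counts"]

SEDENTARY_MAX_CPM = 99
LIGHT_MAX_CPM = 2019
VALID_DAY_WEAR_MIN = 600
NONWEAR_WINDOW_MIN = 60
NONWEAR_MAX_INTERRUPTION_MIN = 2


class EpochFileError(ValueError):
    """Raised when an epoch CSV violates the documented dialect."""


def read_epoch_file(path) -> pd.DataFrame:
    """Read a 60-s epoch CSV into a contiguous minute series.

    The dialect is ``participant_id,timestamp,axis1_counts`` with
    minute-resolution timestamps ``YYYY-MM-DD HH:MM``.  Timestamps must be
    strictly increasing at 60-s spacing within each calendar day; counts must
    be nonnegative integers.  Violations raise :class:`EpochFileError` naming
    the offending CSV line.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise EpochFileError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], format="%Y-%m-%d %H:%M", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise EpochFileError(f"{path}: unparseable timestamp at line {bad[0] + 2}")
    counts = pd.to_numeric(df["axis1_counts"], errors="coerce")
    bad = np.flatnonzero((counts.isna() | (counts < 0)).to_numpy())
    if bad.size:
        raise EpochFileError(
            f"{path}: negative or non-numeric count at line {bad[0] + 2}"
        )
    dup = ts.duplicated()
    if dup.any():
        t = ts[dup].iloc[0]
        raise EpochFileError(f"{path}: duplicated timestamp {t:%Y-%m-%d %H:%M}")
    if not ts.is_monotonic_increasing:
        i = int(np.flatnonzero(np.diff(ts.to_numpy()) < np.timedelta64(0))[0])
        raise EpochFileError(f"{path}: nonmonotone timestamp at line {i + 3}")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "timestamp": ts,
            "axis1_counts": counts.astype(np.int64),
        }
    )
    return out


def detect_nonwear(
    counts: np.ndarray,
    window: int = NONWEAR_WINDOW_MIN,
    max_interruption: int = NONWEAR_MAX_INTERRUPTION_MIN,
    interruption_cap_cpm: int | None = None,
) -> np.ndarray:
    """Return a boolean wear flag per epoch (True = worn).

    ``counts`` is a contiguous minute series.  A candidate bout accumulates
    zero-count minutes; a run of <= ``max_interruption`` consecutive nonzero
    minutes followed by further zeros extends the bout (interruption minutes
    are marked nonwear but do not count toward ``window``).  A longer nonzero
    run terminates the bout at the last zero epoch.  The bout is nonwear iff
    its accumulated zero minutes reach ``window``.  ``interruption_cap_cpm``
    optionally disqualifies interruptions containing any count above the cap.
    """
    counts = np.asarray(counts)
    n = counts.size
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear
    # run-length encode zero/nonzero
    is_zero = counts == 0
    change = np.flatnonzero(np.diff(is_zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    zero_run = is_zero[starts]

    i = 0
    n_runs = starts.size
    while i < n_runs:
        if not zero_run[i]:
            i += 1
            continue
        bout_start = starts[i]
        zero_minutes = ends[i] - starts[i]
        bout_end = ends[i]  # exclusive; trailing interruptions excluded
        j = i + 1
        while j + 1 < n_runs:
            interruption = ends[j] - starts[j]
            if interruption > max_interruption:
                break
            if interruption_cap_cpm is not None and (
                counts[starts[j] : ends[j]] > interruption_cap_cpm
            ).any():
                break
            # next run is zero by alternation of the encoding
            zero_minutes += ends[j + 1] - starts[j + 1]
            bout_end = ends[j + 1]
            j += 2
        if zero_minutes >= window:
            wear[bout_start:bout_end] = False
        i = j
    return wear


def classify_intensity(
    counts: np.ndarray,
    wear: np.ndarray,
    sedentary_max: int = SEDENTARY_MAX_CPM,
    light_max: int = LIGHT_MAX_CPM,
) -> np.ndarray:
    """Label worn epochs ``sedentary`` / ``light`` / ``mvpa`` by CPM cut-points.

    Nonworn epochs receive the empty label '' and are excluded from all
    minute totals.
    """
    counts = np.asarray(counts)
    wear = np.asarray(wear, dtype=bool)
    labels = np.full(counts.shape, "", dtype=object)
    labels[wear & (counts <= sedentary_max)] = "sedentary"
    labels[wear & (counts > sedentary_max) & (counts <= light_max)] = "light"
    labels[wear & (counts > light_max)] = "mvpa"
    return labels


def summarize_behavior_day(
    day: pd.DataFrame,
    wear_threshold: int = VALID_DAY_WEAR_MIN,
    **nonwear_kwargs,
) -> dict:
    """Summarize one calendar day of epochs into behavior minute totals.

    Returns wear/sedentary/light/MVPA minutes and the valid-day flag
    (wear >= ``wear_threshold`` minutes).
    """
    counts = day["axis1_counts"].to_numpy()
    wear = detect_nonwear(counts, **nonwear_kwargs)
    labels = classify_intensity(counts, wear)
    return {
        "wear_min": int(wear.sum()),
        "sedentary_min": int((labels == "sedentary").sum()),
        "light_min": int((labels == "light").sum()),
        "mvpa_min": int((labels == "mvpa").sum()),
        "valid": bool(wear.sum() >= wear_threshold),
    }


def summarize_behavior(
    epochs: pd.DataFrame,
    wear_threshold: int = VALID_DAY_WEAR_MIN,
    **nonwear_kwargs,
) -> pd.DataFrame:
    """Per participant-day behavior summaries from a long epoch table.

    Nonwear is detected on each participant's full contiguous series (bouts
    may span midnight) before minutes are tallied per calendar day.
    """
    rows = []
    for pid, grp in epochs.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        counts = grp["axis1_counts"].to_numpy()
        wear = detect_nonwear(counts, **nonwear_kwargs)
        labels = classify_intensity(counts, wear)
        dates = grp["timestamp"].dt.date.to_numpy()
        tmp = pd.DataFrame({"date": dates, "wear": wear, "label": labels})
        for date, day in tmp.groupby("date", sort=True):
            wear_min = int(day["wear"].sum())
            rows.append(
                {
                    "participant_id": pid,
                    "date": date,
                    "wear_min": wear_min,
                    "sedentary_min": int((day["label"] == "sedentary").sum()),
                    "light_min": int((day["label"] == "light").sum()),
                    "mvpa_min": int((day["label"] == "mvpa").sum()),
                    "valid": wear_min >= wear_threshold,
                }
            )
    return pd.DataFrame(rows)
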