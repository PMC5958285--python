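"""Flash-glucose-monitor export parsing and semiautomated cleaning.

The monitor logs interstitial glucose (mmol/L) two ways: automatic readings
on a 15-min grid, and user-initiated scans at arbitrary times.  Only
automatic readings form the analysis grid.  Cleaning proceeds in a fixed
order per calendar day:

1. missing grid slots take the value of a user scan within +/-3 min
   (nearest wins; ties go to the earlier scan);
2. runs of fewer than three adjacent missing slots flanked by filled values
   are linearly interpolated in time;
3. the largest consecutive run of filled slots is extracted, and a day is
   valid when that run reaches 86 points (>=90% of the nominal 96).

When the reader is not scanned within 8 h the sensor overwrites its oldest
data; the surviving automatic readings may restart on a shifted 15-min
phase, so a drifted day can legitimately hold 95-97 slots.  Missing slots
are therefore reconstructed between observed readings (aligned to the phase
of the later reading) rather than against a fixed nominal grid.  The first
and last calendar days of a recording are partial and excluded from
analysis.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CGM_COLUMNS = ["participant_id", "timestamp", "record_type", "glucose_mmol_l"]
RECORD_AUTOMATIC = 0
RECORD_USER = 1

SLOT_MINUTES = 15
NOMINAL_SLOTS_PER_DAY = 24 * 60 // SLOT_MINUTES  # 96
VALID_DAY_MIN_CONSECUTIVE = 86  # >=90% of 96, as an absolute count
USER_SCAN_WINDOW_MIN = 3
MAX_INTERPOLATION_RUN = 2

PROV_OBSERVED = "observed"
PROV_REPLACED = "replaced_from_user"
PROV_INTERPOLATED = "interpolated"
PROV_MISSING = "missing"


class CGMFileError(ValueError):
    """Raised when a glucose CSV violates the documented dialect."""


@dataclass
class DayGrid:
    """One calendar day of automatic-scan slots for one participant.

    ``values`` holds glucose in mmol/L with NaN for missing slots;
    ``provenance`` tracks how each slot was filled.  Slot times are minute
    resolution and 15 min apart within a continuous block (the spacing may
    break once where a scan gap shifted the grid phase).
    """

    participant_id: str
    date: datetime.date
    times: np.ndarray  # datetime64[m]
    values: np.ndarray  # float, NaN = missing
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    partial: bool = False

    def __post_init__(self):
        if self.provenance is None:
            prov = np.where(np.isnan(self.values), PROV_MISSING, PROV_OBSERVED)
            self.provenance = prov.astype(object)

    @property
    def n_slots(self) -> int:
        return len(self.times)

    def copy(self) -> "DayGrid":
        return DayGrid(
            self.participant_id,
            self.date,
            self.times.copy(),
            self.values.copy(),
            self.provenance.copy(),
            self.partial,
        )


def read_cgm_file(path, column_map: dict | None = None) -> pd.DataFrame:
    """Parse a glucose-monitor CSV export.

    Dialect: header ``participant_id,timestamp,record_type,glucose_mmol_l``,
    timestamps ``YYYY-MM-DD HH:MM``, record_type 0 = automatic, 1 = user.
    ``column_map`` optionally renames columns of other exports onto this
    dialect.  Malformed rows raise :class:`CGMFileError` with their CSV line
    number; an empty file returns an empty frame.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CGMFileError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        return df[CGM_COLUMNS]
    ts = pd.to_datetime(df["timestamp"], format="%Y-%m-%d %H:%M", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise CGMFileError(f"{path}: unparseable timestamp at line {bad[0] + 2}")
    rtype = pd.to_numeric(df["record_type"], errors="coerce")
    bad = np.flatnonzero(~rtype.isin([RECORD_AUTOMATIC, RECORD_USER]).to_numpy())
    if bad.size:
        raise CGMFileError(f"{path}: unknown record type at line {bad[0] + 2}")
    glu = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = np.flatnonzero((~np.isfinite(glu) | (glu <= 0)).to_numpy())
    if bad.size:
        raise CGMFileError(
            f"{path}: nonpositive or non-numeric glucose at line {bad[0] + 2}"
        )
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "timestamp": ts,
            "record_type": rtype.astype(int),
            "glucose_mmol_l": glu.astype(float),
        }
    )
    for _, grp in out.groupby(["participant_id", "record_type"]):
        t = grp["timestamp"].to_numpy()
        if (np.diff(t) <= np.timedelta64(0)).any():
            i = int(np.flatnonzero(np.diff(t) <= np.timedelta64(0))[0])
            raise CGMFileError(
                f"{path}: timestamps not strictly increasing near line "
                f"{grp.index[i + 1] + 2}"
            )
    return out


def _reconstruct_slots(auto_times: np.ndarray, slot_minutes: int) -> tuple[np.ndarray, np.ndarray]:
    """Infer missing slot times between observed automatic readings.

    Between consecutive observed readings separated by more than one slot,
    the expected number of lost readings is ``round(gap/slot) - 1``, placed
    on the phase of the later reading (the sensor restarts its grid at the
    recovering scan).  Returns (all slot times, observed mask).
    """
    step = np.timedelta64(slot_minutes, "m")
    pieces, observed = [], []
    for k, t in enumerate(auto_times):
        if k > 0:
            gap = (t - auto_times[k - 1]) / step
            n_missing = int(round(float(gap))) - 1
            if n_missing > 0:
                miss = t - step * np.arange(n_missing, 0, -1)
                pieces.append(miss)
                observed.append(np.zeros(n_missing, dtype=bool))
        pieces.append(np.array([t]))
        observed.append(np.ones(1, dtype=bool))
    times = np.concatenate(pieces)
    return times, np.concatenate(observed)


def build_day_grids(
    readings: pd.DataFrame,
    slot_minutes: int = SLOT_MINUTES,
    include_partial: bool = False,
) -> list[DayGrid]:
    """Assemble per-day automatic-scan grids for every participant.

    Readings are split at local-midnight boundaries; the first and last
    calendar days of each participant's record are partial (the device is
    deployed and removed mid-day) and are dropped unless
    ``include_partial=True``.  Grid-phase drift after scan gaps is preserved,
    so complete days may hold 95-97 slots.
    """
    grids: list[DayGrid] = []
    auto = readings[readings["record_type"] == RECORD_AUTOMATIC]
    for pid, grp in auto.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        t = grp["timestamp"].to_numpy().astype("datetime64[m]")
        if t.size == 0:
            continue
        times, observed = _reconstruct_slots(t, slot_minutes)
        values = np.full(times.size, np.nan)
        values[observed] = np.nan  # filled below
        obs_vals = grp["glucose_mmol_l"].to_numpy()
        values[observed] = obs_vals
        dates = times.astype("datetime64[D]")
        uniq = np.unique(dates)
        first, last = uniq[0], uniq[-1]
        for d in uniq:
            sel = dates == d
            partial = bool(d == first or d == last)
            if partial and not include_partial:
                continue
            grids.append(
                DayGrid(
                    participant_id=pid,
                    date=d.astype(datetime.date),
                    times=times[sel],
                    values=values[sel],
                    partial=partial,
                )
            )
    return grids


def replace_from_user_scans(
    grid: DayGrid,
    user_readings: pd.DataFrame,
    window_min: int = USER_SCAN_WINDOW_MIN,
) -> DayGrid:
    """Fill missing slots from user scans within ``+/-window_min`` minutes.

    The nearest-in-time user scan wins; at equal distance the earlier scan is
    chosen.  Applied before interpolation; observed slots are never touched.
    """
    out = grid.copy()
    if user_readings is None or len(user_readings) == 0:
        return out
    user = user_readings.sort_values("timestamp")
    ut = user["timestamp"].to_numpy().astype("datetime64[m]")
    uv = user["glucose_mmol_l"].to_numpy()
    win = np.timedelta64(window_min, "m")
    for i in np.flatnonzero(np.isnan(out.values)):
        slot = out.times[i]
        lo = np.searchsorted(ut, slot - win, side="left")
        hi = np.searchsorted(ut, slot + win, side="right")
        if lo == hi:
            continue
        cand = np.arange(lo, hi)
        dist = np.abs((ut[cand] - slot) / np.timedelta64(1, "m"))
        best = cand[np.argmin(dist)]  # argmin takes the first == earlier on ties
        out.values[i] = uv[best]
        out.provenance[i] = PROV_REPLACED
    return out


def interpolate_gaps(
    grid: DayGrid,
    max_run: int = MAX_INTERPOLATION_RUN,
    bridge_replaced: bool = True,
) -> DayGrid:
    """Linearly interpolate runs of at most ``max_run`` adjacent missing slots.

    A run is filled only when both flanking slots hold values; interpolation
    is linear in clock time.  Runs touching the day boundary stay missing,
    as do runs of three or more.  With ``bridge_replaced=False`` slots
    replaced from user scans do not count as flanks.
    """
    out = grid.copy()
    filled = ~np.isnan(out.values)
    if not bridge_replaced:
        filled &= out.provenance != PROV_REPLACED
    missing = np.isnan(out.values)
    n = out.n_slots
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run = j - i
        if run <= max_run and i > 0 and j < n and filled[i - 1] and filled[j]:
            t0 = out.times[i - 1].astype("int64")
            t1 = out.times[j].astype("int64")
            v0, v1 = out.values[i - 1], out.values[j]
            for k in range(i, j):
                tk = out.times[k].astype("int64")
                frac = (tk - t0) / (t1 - t0)
                out.values[k] = v0 + frac * (v1 - v0)
                out.provenance[k] = PROV_INTERPOLATED
        i = j
    return out


def clean_day(
    grid: DayGrid,
    user_readings: pd.DataFrame | None = None,
    window_min: int = USER_SCAN_WINDOW_MIN,
    max_run: int = MAX_INTERPOLATION_RUN,
    bridge_replaced: bool = True,
) -> DayGrid:
    """User-scan replacement followed by bounded interpolation (fixed order)."""
    out = grid
    if user_readings is not None:
        out = replace_from_user_scans(out, user_readings, window_min=window_min)
    return interpolate_gaps(out, max_run=max_run, bridge_replaced=bridge_replaced)


def largest_consecutive_block(grid: DayGrid) -> slice:
    """Longest run of consecutive filled slots (earlier block wins ties)."""
    filled = ~np.isnan(grid.values)
    best_start, best_len = 0, 0
    i, n = 0, grid.n_slots
    while i < n:
        if not filled[i]:
            i += 1
            continue
        j = i
        while j < n and filled[j]:
            j += 1
        if j - i > best_len:
            best_start, best_len = i, j - i
        i = j
    return slice(best_start, best_start + best_len)


def is_valid_glucose_day(
    grid: DayGrid, min_consecutive: int = VALID_DAY_MIN_CONSECUTIVE
) -> bool:
    """A day is valid when its largest consecutive block reaches 86 points."""
    block = largest_consecutive_block(grid)
    return (block.stop - block.start) >= min_consecutive


def accounting(
    grids: list[DayGrid], min_consecutive: int = VALID_DAY_MIN_CONSECUTIVE
) -> pd.DataFrame:
    """Per-participant and overall data-point accounting after cleaning.

    Counts observed, replaced, interpolated and missing slots (which sum to
    the slot total), valid days, and the average available points and
    largest block per day.  The final row aggregates the cohort.
    """
    per: dict[str, dict] = {}
    for g in grids:
        rec = per.setdefault(
            g.participant_id,
            {
                "participant_id": g.participant_id,
                "days": 0,
                "total_slots": 0,
                "observed": 0,
                "replaced": 0,
                "interpolated": 0,
                "missing": 0,
                "valid_days": 0,
                "_block_sum": 0,
            },
        )
        rec["days"] += 1
        rec["total_slots"] += g.n_slots
        prov = g.provenance
        rec["observed"] += int(np.sum(prov == PROV_OBSERVED))
        rec["replaced"] += int(np.sum(prov == PROV_REPLACED))
        rec["interpolated"] += int(np.sum(prov == PROV_INTERPOLATED))
        rec["missing"] += int(np.sum(prov == PROV_MISSING))
        block = largest_consecutive_block(g)
        rec["_block_sum"] += block.stop - block.start
        rec["valid_days"] += int((block.stop - block.start) >= min_consecutive)
    rows = []
    for rec in per.values():
        rec = dict(rec)
        days = rec["days"]
        rec["avg_points_per_day"] = (rec["total_slots"] - rec["missing"]) / days
        rec["avg_largest_block"] = rec.pop("_block_sum") / days
        rows.append(rec)
    df = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
    if df.empty:
        return df
    total = df.drop(columns="participant_id").sum(numeric_only=True)
    total["participant_id"] = "TOTAL"
    total["avg_points_per_day"] = (total["total_slots"] - total["missing"]) / total["days"]
    total["avg_largest_block"] = (df["avg_largest_block"] * df["days"]).sum() / total["days"]
    return pd.concat([df, total.to_frame().T[df.columns]], ignore_index=True)
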