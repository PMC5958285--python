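"""Synthetic coupled-sensor cohorts with known ground truth.

The generator emulates a free-living deployment in nondiabetic adults:
each participant wears a waist accelerometer (60-s epochs, waking hours)
and a flash glucose monitor (automatic interstitial readings every 15 min)
for ``n_days`` complete days plus partial first and last days, the device
being deployed and collected mid-morning.

Daily behavior minutes (sedentary / light / MVPA) are drawn with a
participant-level random intercept and day-level AR(1) correlation; wear
time is their sum, since every worn minute belongs to exactly one intensity
class.  The glucose trace is a participant baseline plus a 24-h circadian
sinusoid, per-meal gamma-shaped excursion kernels, day-level random
effects, and white measurement noise.  Behavior couples to glucose two
ways, for low-fitness participants by default:

* a uniform daily *level* shift ``sum_b beta_b * (minutes_b - mean_b)``
  applied to the whole day's trace, so the linear GEE target on daily mean
  glucose is exact; meal kernels are centered to contribute zero net area
  to the daily mean, keeping the target uncontaminated;
* a daily shift of the meal-excursion amplitude,
  ``sum_b mage_beta_b * (minutes_b - mean_b)``, which moves the day's MAGE
  by approximately that amount without touching the daily mean.

Ground truth (per participant-day fitness group, true minutes and true
shifts) is returned alongside the data for parameter-recovery testing.
Missingness injection reproduces the flash-monitor failure mode: when the
reader is not scanned overnight, automatic data older than 8 h before the
recovering scan are lost, and the surviving grid may restart on a shifted
phase (days with 95-97 points); isolated 1-2 point dropouts are injected
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from glucoupler.cgm_ingest import RECORD_AUTOMATIC, RECORD_USER

BEHAVIORS = ("sedentary", "light", "mvpa")

_LOW_FIT_CATEGORIES = ("needs improvement", "fair", "good")
_HIGH_FIT_CATEGORIES = ("very good", "excellent")
# within-group category frequencies of the emulated cohort
_LOW_FIT_PROBS = (2 / 16, 10 / 16, 4 / 16)
_HIGH_FIT_PROBS = (7 / 13, 6 / 13)

# meal excursion kernel: peak-normalized gamma shape, peak at 45 min,
# truncated at 4 h
_KERNEL_PEAK_MIN = 45.0
_KERNEL_SHAPE = 2.0
_KERNEL_SUPPORT_MIN = 240.0


def _kernel(u_min: np.ndarray) -> np.ndarray:
    u = np.asarray(u_min, dtype=float)
    r = u / _KERNEL_PEAK_MIN
    out = np.where(
        (u >= 0) & (u <= _KERNEL_SUPPORT_MIN),
        r**_KERNEL_SHAPE * np.exp(_KERNEL_SHAPE * (1.0 - r)),
        0.0,
    )
    return out


_KERNEL_AREA_MIN = float(np.trapezoid(_kernel(np.arange(0.0, _KERNEL_SUPPORT_MIN + 1))))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the target population: 29 participants aged 30-60,
    13 complete monitoring days, behavior means/SDs of 576.4 (67.8),
    269.1 (59.8) and 49.6 (29.9) min/day for sedentary, light and MVPA
    (wear = their sum, 895.1 min), mean glucose 5.1 mmol/L with 0.5 between-
    participant SD, and adjusted low-fitness effect sizes of 0.00067,
    -0.00042 and -0.00154 mmol/L per minute on daily mean glucose (0.00202,
    -0.00216, -0.00130 on MAGE via meal-amplitude modulation).
    """

    n_participants: int = 29
    n_days: int = 13
    seed: int = 0
    # effects on daily mean glucose, mmol/L per minute (low fitness)
    beta_sed: float = 0.00067
    beta_light: float = -0.00042
    beta_mvpa: float = -0.00154
    # effects on daily MAGE via meal amplitude, mmol/L per minute
    mage_beta_sed: float = 0.00202
    mage_beta_light: float = -0.00216
    mage_beta_mvpa: float = -0.00130
    prop_low_fitness: float = 16 / 29
    effects_low_fitness_only: bool = True
    behavior_means: dict = field(
        default_factory=lambda: {
            "sedentary": 576.4,
            "light": 269.1,
            "mvpa": 49.6,
            "wear": 895.1,
        }
    )
    behavior_sds: dict = field(
        default_factory=lambda: {
            "sedentary": 67.8,
            "light": 59.8,
            "mvpa": 29.9,
            "wear": 58.8,
        }
    )
    glucose_base_mean: float = 5.1
    glucose_between_sd: float = 0.5
    glucose_day_sd: float = 0.15
    glucose_within_sd: float = 0.25
    meal_count_per_day: int = 3
    meal_amplitude_mean: float = 2.4
    meal_amplitude_sd: float = 0.6
    circadian_amplitude: float = 0.3
    day_ar1_rho: float = 0.3
    p_scan_gap_per_night: float = 0.3
    gap_min_minutes: float = 15.0
    gap_max_minutes: float = 210.0
    p_phase_drift: float = 0.5
    p_point_dropout: float = 0.002
    nonwear_bout_rate: float = 0.3
    user_scans_per_day: float = 4.0
    slot_minutes: int = 15
    start_date: str = "2016-06-06"

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first invalid field."""
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise ValueError("n_participants must be a positive integer")
        if not (isinstance(self.n_days, (int, np.integer)) and self.n_days >= 1):
            raise ValueError("n_days must be a positive integer")
        for name in (
            "glucose_between_sd",
            "glucose_day_sd",
            "glucose_within_sd",
            "meal_amplitude_mean",
            "meal_amplitude_sd",
            "circadian_amplitude",
            "nonwear_bout_rate",
            "user_scans_per_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("prop_low_fitness", "p_scan_gap_per_night", "p_phase_drift", "p_point_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 < self.day_ar1_rho < 1.0:
            raise ValueError("day_ar1_rho must be in (-1, 1)")
        for b in BEHAVIORS + ("wear",):
            if self.behavior_means.get(b, -1) < 0:
                raise ValueError(f"behavior_means[{b!r}] must be nonnegative")
            if self.behavior_sds.get(b, -1) < 0:
                raise ValueError(f"behavior_sds[{b!r}] must be nonnegative")
        if sum(self.behavior_means[b] for b in BEHAVIORS) > self.behavior_means["wear"] + 1e-9:
            raise ValueError("behavior_means: sedentary+light+mvpa must not exceed wear")
        if self.gap_min_minutes < 0 or self.gap_max_minutes < self.gap_min_minutes:
            raise ValueError("gap_max_minutes must be >= gap_min_minutes >= 0")
        if self.meal_count_per_day < 0:
            raise ValueError("meal_count_per_day must be nonnegative")

    @property
    def betas(self) -> dict:
        return {"sedentary": self.beta_sed, "light": self.beta_light, "mvpa": self.beta_mvpa}

    @property
    def mage_betas(self) -> dict:
        return {
            "sedentary": self.mage_beta_sed,
            "light": self.mage_beta_light,
            "mvpa": self.mage_beta_mvpa,
        }

    def expected_missing_fraction(self) -> float:
        """Expected fraction of automatic points removed by missingness injection."""
        mean_gap = (self.gap_min_minutes + self.gap_max_minutes) / 2.0
        per_night = self.p_scan_gap_per_night * mean_gap / self.slot_minutes
        slots_per_day = 24 * 60 / self.slot_minutes
        return per_night / slots_per_day + self.p_point_dropout


class Cohort(NamedTuple):
    """In-memory synthetic cohort: one row per record in each long table."""

    profiles: pd.DataFrame
    cgm: pd.DataFrame
    epochs: pd.DataFrame
    truth: pd.DataFrame


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal SD ``sd``."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for d in range(1, n):
        e[d] = rho * e[d - 1] + rng.normal(0.0, innov_sd)
    return e


def _draw_profiles(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_participants
    low = rng.random(n) < config.prop_low_fitness
    cats = np.empty(n, dtype=object)
    for i in range(n):
        if low[i]:
            cats[i] = rng.choice(_LOW_FIT_CATEGORIES, p=_LOW_FIT_PROBS)
        else:
            cats[i] = rng.choice(_HIGH_FIT_CATEGORIES, p=_HIGH_FIT_PROBS)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": rng.integers(30, 61, n),
            "sex": np.where(rng.random(n) < 12 / 29, "M", "F"),
            "body_fat_pct": np.round(np.clip(rng.normal(27.0, 9.7, n), 8.0, 55.0), 1),
            "weight_kg": np.round(np.clip(rng.normal(72.0, 12.0, n), 45.0, 120.0), 1),
            "fitness_category": cats,
        }
    )


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a clean (no missingness) coupled cohort with ground truth.

    Each participant contributes ``n_days + 2`` calendar days; the first and
    last are partial (deployment and collection around 10:00).  Identical
    ``config`` (including seed) gives byte-identical outputs.  Apply
    :func:`inject_missingness` afterwards — or use
    :func:`generate_study_cohort` — for study-like glucose data loss.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants + 2)
    profiles = _draw_profiles(np.random.default_rng(children[0]), config)
    low_fit = profiles["fitness_category"].isin(_LOW_FIT_CATEGORIES).to_numpy()

    n_total = config.n_days + 2
    start = np.datetime64(config.start_date)
    day_starts_min = np.arange(n_total) * 1440  # minutes since start midnight
    deploy_start_min = 10 * 60  # device deployed ~10:00 on day 1
    deploy_end_min = (n_total - 1) * 1440 + 10 * 60

    cgm_frames, epoch_frames, truth_rows = [], [], []
    for i, pid in enumerate(profiles["participant_id"]):
        rng = np.random.default_rng(children[i + 1])
        has_effect = low_fit[i] or not config.effects_low_fitness_only

        # --- daily behavior targets: intercept + AR(1), split half/half ---
        targets = {}
        for b in BEHAVIORS:
            sd_b = config.behavior_sds[b] / np.sqrt(2.0)
            u = rng.normal(0.0, sd_b)
            e = _ar1(rng, n_total, config.day_ar1_rho, sd_b)
            targets[b] = np.maximum(config.behavior_means[b] + u + e, 0.0).astype(int)

        # --- epoch construction (1440 min/day) ---
        counts = np.zeros(n_total * 1440, dtype=np.int64)
        labels = np.zeros(n_total * 1440, dtype="U1")
        true_min = {b: np.zeros(n_total, dtype=int) for b in BEHAVIORS}
        for d in range(n_total):
            n_b = {b: int(targets[b][d]) for b in BEHAVIORS}
            total = sum(n_b.values())
            # daytime nonwear bouts interrupt the worn span without
            # consuming the drawn class minutes: removing minutes across
            # classes would correlate the three behaviors and break their
            # designed independence
            bout_durs = [int(rng.integers(60, 121)) for _ in range(rng.poisson(config.nonwear_bout_rate))]
            bout_total = sum(bout_durs)
            # long days start earlier rather than shrinking the drawn minutes
            wake = 420 + int(rng.integers(-30, 31))
            wake = max(240, min(wake, 1435 - total - bout_total))
            if wake + total + bout_total > 1435:  # absurdly long draw: drop bouts
                bout_durs, bout_total = [], 0
            if wake + total > 1435:
                scale = (1435 - wake) / total
                n_b = {b: int(n_b[b] * scale) for b in BEHAVIORS}
                total = sum(n_b.values())
            lab = np.concatenate(
                [np.full(n_b["sedentary"], "S"), np.full(n_b["light"], "L"), np.full(n_b["mvpa"], "M")]
            )
            rng.shuffle(lab)
            cnt = np.empty(total, dtype=np.int64)
            cnt[lab == "S"] = rng.integers(0, 100, n_b["sedentary"])
            cnt[lab == "L"] = rng.integers(100, 2020, n_b["light"])
            cnt[lab == "M"] = rng.integers(2020, 6000, n_b["mvpa"])
            offset = np.zeros(total, dtype=int)
            for dur in bout_durs:
                offset[int(rng.integers(0, total + 1)) :] += dur
            pos = d * 1440 + wake + np.arange(total) + offset
            counts[pos] = cnt
            labels[pos] = lab
        # deployment boundaries: zero out before/after the monitored window
        counts[:deploy_start_min] = 0
        labels[:deploy_start_min] = ""
        counts[deploy_end_min:] = 0
        labels[deploy_end_min:] = ""
        for b, code in zip(BEHAVIORS, ("S", "L", "M")):
            lab_days = labels.reshape(n_total, 1440)
            true_min[b] = (lab_days == code).sum(axis=1)

        # --- ground-truth daily shifts ---
        mean_shift = np.zeros(n_total)
        mage_shift = np.zeros(n_total)
        if has_effect:
            for b in BEHAVIORS:
                dev = true_min[b] - config.behavior_means[b]
                mean_shift += config.betas[b] * dev
                mage_shift += config.mage_betas[b] * dev

        # --- glucose trace ---
        base = config.glucose_base_mean + rng.normal(0.0, config.glucose_between_sd)
        day_re = _ar1(rng, n_total, config.day_ar1_rho, config.glucose_day_sd)
        meal_t, meal_a, meal_day = [], [], []
        meal_hours = (8.0, 13.0, 19.0, 11.0, 16.0, 21.0)
        for d in range(n_total):
            for m in range(config.meal_count_per_day):
                t = d * 1440 + meal_hours[m % 6] * 60 + rng.normal(0.0, 45.0)
                amp = rng.normal(config.meal_amplitude_mean, config.meal_amplitude_sd)
                amp = max(amp + mage_shift[d], 0.2)
                meal_t.append(t)
                meal_a.append(amp)
                meal_day.append(d)
        meal_t = np.asarray(meal_t)
        meal_a = np.asarray(meal_a)
        # per-day meal level correction so meals add zero net daily mean
        meal_level = np.zeros(n_total)
        for t, a, d in zip(meal_t, meal_a, meal_day):
            meal_level[d] += a * _KERNEL_AREA_MIN / 1440.0

        def trace(t_min: np.ndarray) -> np.ndarray:
            t_min = np.asarray(t_min, dtype=float)
            day = np.clip((t_min // 1440).astype(int), 0, n_total - 1)
            g = base + day_re[day] + mean_shift[day] - meal_level[day]
            tod_h = (t_min % 1440) / 60.0
            g = g + config.circadian_amplitude * np.cos(2 * np.pi * (tod_h - 16.0) / 24.0)
            for tm, am in zip(meal_t, meal_a):
                j0 = np.searchsorted(t_min, tm)
                j1 = np.searchsorted(t_min, tm + _KERNEL_SUPPORT_MIN)
                g[j0:j1] += am * _kernel(t_min[j0:j1] - tm)
            return g

        phase = int(rng.integers(0, config.slot_minutes))
        auto_t = np.arange(deploy_start_min + phase, deploy_end_min, config.slot_minutes, dtype=float)
        auto_v = trace(auto_t) + rng.normal(0.0, config.glucose_within_sd, auto_t.size)
        user_t = []
        for d in range(n_total):
            for _ in range(rng.poisson(config.user_scans_per_day)):
                user_t.append(d * 1440 + rng.uniform(7 * 60, 23 * 60))
        user_t = np.sort(
            np.unique(
                np.array([t for t in user_t if deploy_start_min <= t < deploy_end_min]).astype(int)
            )
        ).astype(float)
        user_v = trace(user_t) + rng.normal(0.0, config.glucose_within_sd, user_t.size)

        auto_ts = start.astype("datetime64[m]") + auto_t.astype(np.int64)
        user_ts = start.astype("datetime64[m]") + user_t.astype(np.int64)
        cgm_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": np.concatenate([auto_ts, user_ts]),
                    "record_type": np.concatenate(
                        [
                            np.full(auto_ts.size, RECORD_AUTOMATIC),
                            np.full(user_ts.size, RECORD_USER),
                        ]
                    ),
                    "glucose_mmol_l": np.round(
                        np.clip(np.concatenate([auto_v, user_v]), 0.5, None), 1
                    ),
                }
            )
        )
        epoch_ts = start.astype("datetime64[m]") + np.arange(n_total * 1440)
        epoch_frames.append(
            pd.DataFrame(
                {"participant_id": pid, "timestamp": epoch_ts, "axis1_counts": counts}
            )
        )
        for d in range(n_total):
            truth_rows.append(
                {
                    "participant_id": pid,
                    "date": (start + np.timedelta64(d, "D")).astype("datetime64[D]").astype(object),
                    "low_fitness": bool(low_fit[i]),
                    "sedentary_min": int(true_min["sedentary"][d]),
                    "light_min": int(true_min["light"][d]),
                    "mvpa_min": int(true_min["mvpa"][d]),
                    "wear_min": int(sum(true_min[b][d] for b in BEHAVIORS)),
                    "mean_shift": float(mean_shift[d]),
                    "mage_shift": float(mage_shift[d]),
                    "partial": d in (0, n_total - 1),
                }
            )

    cgm = pd.concat(cgm_frames, ignore_index=True)
    cgm["timestamp"] = cgm["timestamp"].astype("datetime64[s]")
    epochs = pd.concat(epoch_frames, ignore_index=True)
    epochs["timestamp"] = epochs["timestamp"].astype("datetime64[s]")
    return Cohort(profiles, cgm, epochs, pd.DataFrame(truth_rows))


def inject_missingness(
    cgm: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject flash-monitor data loss into automatic readings.

    Per night and participant, with probability ``p_scan_gap_per_night`` a
    contiguous span of ``gap_min_minutes``-``gap_max_minutes`` of automatic
    readings starting between 21:30 and 23:30 is deleted (the reader was not
    scanned in time, so the sensor overwrote data older than 8 h before the
    recovering scan).  With probability ``p_phase_drift`` the surviving grid
    after the gap shifts phase by 1-7 min, producing 95-97-slot days.
    Isolated dropouts remove each remaining point with probability
    ``p_point_dropout``.  Returns the thinned table and a per-participant
    bookkeeping frame (``gap_deleted``, ``dropout_deleted``, ``n_gaps``,
    ``n_drifts``).  With all rates zero the input is returned unchanged.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    out_frames, book = [], []
    n_total = config.n_days + 2
    for pid, grp in cgm.groupby("participant_id", sort=True):
        grp = grp.sort_values(["record_type", "timestamp"], kind="stable")
        is_auto = grp["record_type"].to_numpy() == RECORD_AUTOMATIC
        auto = grp[is_auto].copy()
        other = grp[~is_auto]
        t0 = auto["timestamp"].to_numpy().min().astype("datetime64[D]").astype("datetime64[m]")
        t_min = (
            (auto["timestamp"].to_numpy().astype("datetime64[m]") - t0)
            / np.timedelta64(1, "m")
        ).astype(float)
        keep = np.ones(t_min.size, dtype=bool)
        n_gap_del = n_gaps = n_drifts = 0
        for d in range(n_total - 1):
            if rng.random() >= config.p_scan_gap_per_night:
                continue
            g0 = d * 1440 + rng.uniform(21.5 * 60, 23.5 * 60)
            span = rng.uniform(config.gap_min_minutes, config.gap_max_minutes)
            sel = (t_min >= g0) & (t_min < g0 + span) & keep
            if not sel.any():
                continue
            n_gaps += 1
            n_gap_del += int(sel.sum())
            keep[sel] = False
            if rng.random() < config.p_phase_drift:
                delta = int(rng.integers(1, 8)) * (1 if rng.random() < 0.5 else -1)
                t_min[t_min >= g0 + span] += delta
                n_drifts += 1
        drop = (rng.random(t_min.size) < config.p_point_dropout) & keep
        n_drop_del = int(drop.sum())
        keep &= ~drop
        auto["timestamp"] = (t0 + t_min.astype(np.int64)).astype("datetime64[s]")
        out = pd.concat([auto[keep], other]).sort_values(
            ["timestamp", "record_type"], kind="stable"
        )
        out_frames.append(out)
        book.append(
            {
                "participant_id": pid,
                "gap_deleted": n_gap_del,
                "dropout_deleted": n_drop_del,
                "n_gaps": n_gaps,
                "n_drifts": n_drifts,
            }
        )
    return (
        pd.concat(out_frames, ignore_index=True),
        pd.DataFrame(book),
    )


def generate_study_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Clean cohort plus study-like glucose missingness, deterministically.

    Returns the cohort (with thinned glucose) and the missingness
    bookkeeping.  The injection uses a dedicated substream of the master
    seed, so results are reproducible for a given config.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(config.n_participants + 3)[-1]
    )
    cgm, book = inject_missingness(cohort.cgm, config, rng)
    return Cohort(cohort.profiles, cgm, cohort.epochs, cohort.truth), book


def simulate_analysis_table(
    config: SimulationConfig,
    seed: int | None = None,
    outcome_rho: float | None = None,
) -> pd.DataFrame:
    """Directly simulate a daily-level analysis table (no sensor traces).

    A fast path sharing the trace generator's statistical skeleton —
    participant intercepts, AR(1) day effects, behavior-coupled shifts on
    mean glucose and MAGE — used for calibration studies that need many
    replicates (type-I error, working-correlation selection).  ``outcome_rho``
    overrides the AR(1) correlation of the outcome day effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rho_y = config.day_ar1_rho if outcome_rho is None else outcome_rho
    profiles = _draw_profiles(rng, config)
    low_fit = profiles["fitness_category"].isin(_LOW_FIT_CATEGORIES).to_numpy()
    rows = []
    for i, pid in enumerate(profiles["participant_id"]):
        has_effect = low_fit[i] or not config.effects_low_fitness_only
        beh = {}
        for b in BEHAVIORS:
            sd_b = config.behavior_sds[b] / np.sqrt(2.0)
            beh[b] = np.maximum(
                config.behavior_means[b]
                + rng.normal(0.0, sd_b)
                + _ar1(rng, config.n_days, config.day_ar1_rho, sd_b),
                0.0,
            )
        mean_shift = np.zeros(config.n_days)
        mage_shift = np.zeros(config.n_days)
        if has_effect:
            for b in BEHAVIORS:
                dev = beh[b] - config.behavior_means[b]
                mean_shift += config.betas[b] * dev
                mage_shift += config.mage_betas[b] * dev
        base = config.glucose_base_mean + rng.normal(0.0, config.glucose_between_sd)
        day_re = _ar1(rng, config.n_days, rho_y, config.glucose_day_sd)
        mean_glucose = base + day_re + mean_shift + rng.normal(0.0, 0.03, config.n_days)
        sd_glucose = np.clip(0.9 + 0.3 * day_re / max(config.glucose_day_sd, 1e-9) * 0.25
                             + rng.normal(0.0, 0.1, config.n_days), 0.05, None)
        mage = np.clip(
            config.meal_amplitude_mean
            + day_re
            + mage_shift
            + rng.normal(0.0, config.meal_amplitude_sd / np.sqrt(3), config.n_days),
            0.1,
            None,
        )
        for d in range(config.n_days):
            rows.append(
                {
                    "participant_id": pid,
                    "day_index": d + 1,
                    "sedentary_min": beh["sedentary"][d],
                    "light_min": beh["light"][d],
                    "mvpa_min": beh["mvpa"][d],
                    "wear_min": beh["sedentary"][d] + beh["light"][d] + beh["mvpa"][d],
                    "mean_glucose": mean_glucose[d],
                    "sd_glucose": sd_glucose[d],
                    "mage": mage[d],
                    "age": profiles["age"].iloc[i],
                    "sex": profiles["sex"].iloc[i],
                    "body_fat_pct": profiles["body_fat_pct"].iloc[i],
                    "fitness_category": profiles["fitness_category"].iloc[i],
                    "low_fitness": bool(low_fit[i]),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir, book: pd.DataFrame | None = None) -> None:
    """Write a cohort to ``profiles.csv``, ``truth.csv``, ``cgm/P###.csv`` and
    ``acc/P###.csv`` in the documented CSV dialects."""
    outdir = Path(outdir)
    (outdir / "cgm").mkdir(parents=True, exist_ok=True)
    (outdir / "acc").mkdir(parents=True, exist_ok=True)
    cohort.profiles.to_csv(outdir / "profiles.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    if book is not None:
        book.to_csv(outdir / "missingness.csv", index=False)
    for pid, grp in cohort.cgm.groupby("participant_id"):
        grp = grp.copy()
        grp["timestamp"] = grp["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
        grp.to_csv(outdir / "cgm" / f"{pid}.csv", index=False)
    for pid, grp in cohort.epochs.groupby("participant_id"):
        grp = grp.copy()
        grp["timestamp"] = grp["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
        grp.to_csv(outdir / "acc" / f"{pid}.csv", index=False)


def ground_truth_check(truth: pd.DataFrame, config: SimulationConfig) -> bool:
    """Verify the ground-truth identity: shifts equal ``sum_b beta_b *
    (minutes_b - mean_b)`` for affected participant-days and zero otherwise."""
    dev = {
        b: truth[f"{b}_min" if b != "sedentary" else "sedentary_min"]
        - config.behavior_means[b]
        for b in BEHAVIORS
    }
    expected = sum(config.betas[b] * dev[b] for b in BEHAVIORS)
    if config.effects_low_fitness_only:
        expected = expected.where(truth["low_fitness"], 0.0)
    return bool(np.allclose(truth["mean_shift"], expected, atol=1e-9))
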