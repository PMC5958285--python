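"""Daily glycemic-variability metrics: mean glucose, SD of glucose, and the
mean amplitude of glycemic excursions (MAGE).

MAGE is computed with the classical turning-point procedure: the series is
reduced to alternating local minima and maxima (plateaus of equal values
contribute their midpoint), an excursion between consecutive turning points
qualifies when its absolute amplitude strictly exceeds one standard
deviation of the whole block, and MAGE is the mean of the qualifying
amplitudes counted in the direction of the first qualifying excursion
(ascending: nadir-to-peak; descending: peak-to-nadir).  When no excursion
qualifies — a constant day, or fluctuations all within one SD — MAGE is
undefined and reported as NaN.  The directional variants MAGE+ and MAGE-
and their average are exposed for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glucoupler.cgm_ingest import (
    VALID_DAY_MIN_CONSECUTIVE,
    DayGrid,
    is_valid_glucose_day,
    largest_consecutive_block,
)


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a glucose block.

    The SD is NaN for fewer than two values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
    return mean, sd


def turning_points(values, smooth: bool = False) -> np.ndarray:
    """Indices of alternating local extrema, including both endpoints.

    Runs of equal consecutive values are collapsed and represented by their
    midpoint index.  With ``smooth=True`` a 3-point moving average is applied
    before detection (indices still refer to the raw series).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.arange(v.size)
    if smooth:
        v = np.convolve(v, np.ones(3) / 3, mode="same")
        v[0], v[-1] = values[0], values[-1]
    # collapse plateaus: runs of equal adjacent values -> midpoint index
    keep = np.concatenate(([True], np.diff(v) != 0))
    run_starts = np.flatnonzero(keep)
    run_ends = np.concatenate((run_starts[1:], [v.size])) - 1
    mid = (run_starts + run_ends) // 2
    cv = v[run_starts]
    if cv.size == 1:  # constant series
        return np.array([mid[0]])
    d = np.sign(np.diff(cv))
    interior = np.flatnonzero(d[1:] != d[:-1]) + 1
    idx = np.concatenate(([0], interior, [cv.size - 1]))
    return mid[idx]


@dataclass(frozen=True)
class MageResult:
    mage: float
    mage_plus: float
    mage_minus: float
    mage_avg: float
    sd: float
    n_qualifying: int


def mage_components(values, smooth: bool = False) -> MageResult:
    """Full MAGE decomposition for one glucose block.

    ``mage`` follows the first-qualifying-direction convention; ``mage_plus``
    and ``mage_minus`` average the ascending and descending qualifying
    amplitudes respectively, and ``mage_avg`` is their mean.  All values are
    NaN when undefined.
    """
    v = np.asarray(values, dtype=float)
    nan = float("nan")
    if v.size < 3:
        return MageResult(nan, nan, nan, nan, nan, 0)
    sd = float(v.std(ddof=1))
    tp = turning_points(v, smooth=smooth)
    if tp.size < 2 or sd == 0.0:
        return MageResult(nan, nan, nan, nan, sd, 0)
    deltas = np.diff(v[tp])
    qualifying = np.abs(deltas) > sd
    if not qualifying.any():
        return MageResult(nan, nan, nan, nan, sd, 0)
    amp = np.abs(deltas[qualifying])
    up = deltas[qualifying] > 0
    mage_plus = float(amp[up].mean()) if up.any() else nan
    mage_minus = float(amp[~up].mean()) if (~up).any() else nan
    first_up = bool(up[0])
    mage_val = mage_plus if first_up else mage_minus
    both = up.any() and (~up).any()
    mage_avg = float((mage_plus + mage_minus) / 2) if both else mage_val
    return MageResult(mage_val, mage_plus, mage_minus, mage_avg, sd, int(amp.size))


def mage(values, smooth: bool = False) -> float:
    """MAGE of a glucose block (NaN when undefined)."""
    return mage_components(values, smooth=smooth).mage


def summarize_glucose_day(
    grid: DayGrid,
    min_consecutive: int = VALID_DAY_MIN_CONSECUTIVE,
    smooth: bool = False,
) -> dict:
    """Daily glucose summary computed on the largest consecutive block.

    Mean, SD and MAGE are evaluated on the longest run of filled slots of a
    cleaned day grid; the valid flag requires that run to reach
    ``min_consecutive`` points.  Metrics are reported for invalid days too
    (diagnostics); an undefined MAGE propagates as NaN.
    """
    block = largest_consecutive_block(grid)
    vals = grid.values[block]
    mean, sd = mean_sd(vals)
    return {
        "date": grid.date,
        "mean_glucose": mean,
        "sd_glucose": sd,
        "mage": mage(vals, smooth=smooth),
        "n_points": int(np.sum(~np.isnan(grid.values))),
        "largest_block": int(block.stop - block.start),
        "valid": is_valid_glucose_day(grid, min_consecutive=min_consecutive),
    }
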