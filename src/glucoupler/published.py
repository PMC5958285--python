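"""Published GEE coefficients of the source study, usable as model inputs.

The study's per-minute association estimates (mmol/L per minute of daily
behavior) for the whole sample and the low-fitness stratum, as printed in
its results tables, are bundled here so that behavioral-context predictions
and simulation parameterizations can be driven from the published numbers
without re-keying them.  ``model`` "one" is univariable; "two" adjusts for
wear minutes, age, sex and percent body fat.
"""

from __future__ import annotations

import pandas as pd

from glucoupler.association_models import predicted_change

_ROWS = [
    # outcome, model, stratum, exposure, beta, ci_low, ci_high, p
    ("mean_glucose", "one", "all", "sedentary_min", 0.00006, -0.00018, 0.00030, 0.63),
    ("mean_glucose", "one", "all", "light_min", -0.00005, -0.00040, 0.00029, 0.76),
    ("mean_glucose", "one", "all", "mvpa_min", -0.00053, -0.00128, 0.00023, 0.17),
    ("mean_glucose", "one", "low_fit", "sedentary_min", 0.00016, -0.00011, 0.00043, 0.25),
    ("mean_glucose", "one", "low_fit", "light_min", -0.00042, -0.00080, -0.00004, 0.03),
    ("mean_glucose", "one", "low_fit", "mvpa_min", -0.00160, -0.00255, -0.00064, 0.001),
    ("mean_glucose", "two", "all", "sedentary_min", 0.00019, -0.00018, 0.00055, 0.32),
    ("mean_glucose", "two", "all", "light_min", -0.00005, -0.00041, 0.00031, 0.77),
    ("mean_glucose", "two", "all", "mvpa_min", -0.00053, -0.00127, 0.00022, 0.17),
    ("mean_glucose", "two", "low_fit", "sedentary_min", 0.00067, 0.00030, 0.00103, 0.001),
    ("mean_glucose", "two", "low_fit", "light_min", -0.00042, -0.00078, -0.00006, 0.02),
    ("mean_glucose", "two", "low_fit", "mvpa_min", -0.00154, -0.00250, -0.00058, 0.002),
    ("sd_glucose", "one", "all", "sedentary_min", 0.00005, -0.00021, 0.00030, 0.73),
    ("sd_glucose", "one", "all", "light_min", -0.00019, -0.00058, 0.00020, 0.33),
    ("sd_glucose", "one", "all", "mvpa_min", 0.00008, -0.00043, 0.00059, 0.76),
    ("sd_glucose", "one", "low_fit", "sedentary_min", 0.00017, -0.00024, 0.00057, 0.42),
    ("sd_glucose", "one", "low_fit", "light_min", -0.00046, -0.00090, -0.00002, 0.04),
    ("sd_glucose", "one", "low_fit", "mvpa_min", -0.00040, -0.00146, 0.00066, 0.46),
    ("sd_glucose", "two", "all", "sedentary_min", 0.00018, -0.00015, 0.00051, 0.29),
    ("sd_glucose", "two", "all", "light_min", -0.00025, -0.00063, 0.00012, 0.19),
    ("sd_glucose", "two", "all", "mvpa_min", 0.00012, -0.00036, 0.00059, 0.62),
    ("sd_glucose", "two", "low_fit", "sedentary_min", 0.00059, 0.00037, 0.00081, 0.001),
    ("sd_glucose", "two", "low_fit", "light_min", -0.00062, -0.00085, -0.00039, 0.001),
    ("sd_glucose", "two", "low_fit", "mvpa_min", -0.00044, -0.00130, 0.00041, 0.31),
    ("mage", "one", "all", "sedentary_min", 0.00035, -0.00053, 0.00123, 0.44),
    ("mage", "one", "all", "light_min", -0.00079, -0.00204, 0.00046, 0.22),
    ("mage", "one", "all", "mvpa_min", -0.00008, -0.00173, 0.00157, 0.93),
    ("mage", "one", "low_fit", "sedentary_min", 0.00074, -0.00073, 0.00221, 0.33),
    ("mage", "one", "low_fit", "light_min", -0.00156, -0.00291, -0.00022, 0.02),
    ("mage", "one", "low_fit", "mvpa_min", -0.00076, -0.00492, 0.00341, 0.72),
    ("mage", "two", "all", "sedentary_min", 0.00088, -0.00023, 0.00199, 0.12),
    ("mage", "two", "all", "light_min", -0.00107, -0.00232, 0.00018, 0.09),
    ("mage", "two", "all", "mvpa_min", 0.00004, -0.00155, 0.00162, 0.96),
    ("mage", "two", "low_fit", "sedentary_min", 0.00202, 0.00131, 0.00273, 0.001),
    ("mage", "two", "low_fit", "light_min", -0.00216, -0.00285, -0.00146, 0.001),
    ("mage", "two", "low_fit", "mvpa_min", -0.00130, -0.00429, 0.00169, 0.39),
]

STUDY_GEE_COEFFICIENTS = pd.DataFrame(
    _ROWS, columns=["outcome", "model", "stratum", "exposure", "beta", "ci_low", "ci_high", "p"]
)

HEALTHY_REFERENCE_MAGE_MMOL_L = 1.4
"""Average MAGE reported for healthy white adults, used as the reference
magnitude when expressing predicted MAGE changes as a percentage."""


def published_beta(outcome: str, exposure: str, stratum: str = "low_fit", model: str = "two") -> float:
    """Look up one published per-minute coefficient (mmol/L per minute)."""
    t = STUDY_GEE_COEFFICIENTS
    sel = t[
        (t["outcome"] == outcome)
        & (t["exposure"] == exposure)
        & (t["stratum"] == stratum)
        & (t["model"] == model)
    ]
    if len(sel) != 1:
        raise KeyError(f"no published coefficient for {outcome}~{exposure} [{stratum}/{model}]")
    return float(sel["beta"].iloc[0])


def worked_behavioral_context(minutes: float = 60.0) -> dict:
    """The study's behavioral-context translations, recomputed.

    Scales the adjusted low-fitness coefficients to a ``minutes``-long
    behavior change: the expected rise in daily mean glucose from more
    sedentary time, the expected fall from more MVPA, the expected fall in
    MAGE from more light activity, and the latter as a percentage of the
    healthy reference MAGE (1.4 mmol/L).
    """
    sed = predicted_change(published_beta("mean_glucose", "sedentary_min"), minutes)
    mvpa = predicted_change(published_beta("mean_glucose", "mvpa_min"), minutes)
    light_mage = predicted_change(published_beta("mage", "light_min"), minutes)
    return {
        "mean_glucose_rise_sedentary": round(sed, 2),
        "mean_glucose_fall_mvpa": round(abs(mvpa), 2),
        "mage_fall_light": round(abs(light_mage), 2),
        "mage_fall_light_pct_reference": round(
            100.0 * abs(round(light_mage, 2)) / HEALTHY_REFERENCE_MAGE_MMOL_L
        ),
    }
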