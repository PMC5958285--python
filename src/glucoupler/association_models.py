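"""GEE association models between daily behaviors and glycemic variability.

Each exposure (sedentary, light or MVPA minutes) enters a separate
Gaussian identity-link GEE for each outcome (daily mean glucose, SD of
glucose, MAGE), with participants as clusters and rows ordered by valid-day
index.  Model one is univariable; model two adjusts for accelerometer wear
minutes, age, sex and percent body fat.  The working correlation
(autoregressive AR(1) on within-participant day order, unstructured, or
independence) is selected by Pan's QIC — lower is better — and inference
uses robust (sandwich) standard errors with normal-approximation 95% CIs.

Supporting diagnostics mirror the analysis plan: variance inflation factors
for the adjusted design, an ANCOVA comparing participant-level behavior
between fitness groups adjusted for wear time, a wear-time sensitivity
refit, and the behavioral-context translation ``beta * minutes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.cov_struct import Autoregressive, Independence, Unstructured

OUTCOMES = ("mean_glucose", "sd_glucose", "mage")
EXPOSURES = ("sedentary_min", "light_min", "mvpa_min")
MODEL_TWO_COVARIATES = ("wear_min", "age", "sex", "body_fat_pct")

Z_95 = 1.959963984540054  # normal 97.5% quantile


class GEEFitError(RuntimeError):
    """Raised when a GEE fit fails (singular design, nonconvergence)."""


@dataclass(frozen=True)
class ModelSpec:
    """One exposure-outcome model of the battery."""

    outcome: str
    exposure: str
    adjusted: bool = False  # model two: wear, age, sex, body fat
    stratum: str = "all"  # "all" | "low_fit" | "high_fit"
    include_wear: bool = True  # False = wear-time sensitivity refit

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in EXPOSURES:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.stratum not in ("all", "low_fit", "high_fit"):
            raise ValueError(f"unknown stratum {self.stratum!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        if not self.adjusted:
            return ()
        covs = tuple(c for c in MODEL_TWO_COVARIATES if self.include_wear or c != "wear_min")
        return covs


@dataclass(frozen=True)
class GEEResult:
    """Point estimate and inference for one exposure-outcome GEE."""

    exposure: str
    outcome: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    working_correlation: str
    qic: float
    n_obs: int
    n_clusters: int
    covariates: tuple[str, ...] = ()
    stratum: str = "all"
    model: str = "one"
    n_dropped_missing_outcome: int = 0
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum,
            "model": self.model,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "qic": self.qic,
            "corstr": self.working_correlation,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }


def _cov_struct(name: str):
    if name == "autoregressive":
        return Autoregressive(grid=True)
    if name == "independence":
        return Independence()
    if name == "unstructured":
        return Unstructured()
    raise ValueError(f"unknown working correlation {name!r}")


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    df = table
    if spec.stratum == "low_fit":
        df = df[df["low_fitness"]]
    elif spec.stratum == "high_fit":
        df = df[~df["low_fitness"]]
    cols = ["participant_id", "day_index", spec.outcome, spec.exposure, *spec.covariates]
    df = df[list(dict.fromkeys(cols))].copy()
    n0 = len(df)
    df = df.dropna(subset=[spec.outcome])
    n_dropped = n0 - len(df)
    df = df.sort_values(["participant_id", "day_index"], kind="stable")
    return df.reset_index(drop=True), n_dropped


def qic(result, scale: float | None = None) -> float:
    """Pan's quasi-likelihood under the independence model criterion.

    ``-2 QL + 2 trace(A^-1 V_r)`` with the quasi-likelihood evaluated at the
    GEE solution under the independence working model, A the naive and V_r
    the robust covariance.  A fixed ``scale`` should be supplied when
    comparing correlation structures on the same data.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value, _qicu = result.qic(scale=scale)
    return float(value)


def fit_gee(
    table: pd.DataFrame,
    spec: ModelSpec,
    correlation: str = "autoregressive",
    maxiter: int = 60,
    ctol: float = 1e-6,
    qic_scale: float | None = None,
) -> GEEResult:
    """Fit one exposure-outcome GEE and return its summary.

    Rows with a missing outcome (undefined MAGE) are dropped and counted.
    A constant outcome yields a degenerate zero-effect result rather than a
    numerical failure; other failures raise :class:`GEEFitError`.
    """
    df, n_dropped = _prepare(table, spec)
    if len(df) < 10:
        raise GEEFitError(
            f"{spec.outcome}~{spec.exposure} [{spec.stratum}]: "
            f"only {len(df)} usable rows"
        )
    n_clusters = df["participant_id"].nunique()
    if n_clusters < 2:
        raise GEEFitError(
            f"{spec.outcome}~{spec.exposure} [{spec.stratum}]: "
            f"needs >= 2 clusters, got {n_clusters}"
        )
    model_label = "two" if spec.adjusted else "one"
    if np.ptp(df[spec.outcome].to_numpy()) == 0.0:
        return GEEResult(
            exposure=spec.exposure,
            outcome=spec.outcome,
            beta=0.0,
            ci_low=0.0,
            ci_high=0.0,
            p_value=float("nan"),
            working_correlation=correlation,
            qic=float("nan"),
            n_obs=len(df),
            n_clusters=n_clusters,
            covariates=spec.covariates,
            stratum=spec.stratum,
            model=model_label,
            n_dropped_missing_outcome=n_dropped,
            degenerate=True,
        )
    rhs = [spec.exposure] + [
        f"C(sex)" if c == "sex" else c for c in spec.covariates
    ]
    formula = f"{spec.outcome} ~ " + " + ".join(rhs)
    kwargs = {}
    if correlation == "unstructured":
        kwargs["time"] = (df["day_index"].to_numpy() - 1).astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.gee(
                formula,
                groups="participant_id",
                data=df,
                family=sm.families.Gaussian(),
                cov_struct=_cov_struct(correlation),
                **kwargs,
            )
            res = model.fit(maxiter=maxiter, ctol=ctol)
    except Exception as exc:  # singular design, nonconvergence
        raise GEEFitError(
            f"{spec.outcome}~{spec.exposure} [{spec.stratum}]: {exc}"
        ) from exc
    beta = float(res.params[spec.exposure])
    se = float(res.bse[spec.exposure])
    if not np.isfinite(beta) or not np.isfinite(se):
        raise GEEFitError(
            f"{spec.outcome}~{spec.exposure} [{spec.stratum}]: nonfinite estimate"
        )
    p = float(res.pvalues[spec.exposure])
    return GEEResult(
        exposure=spec.exposure,
        outcome=spec.outcome,
        beta=beta,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        p_value=p,
        working_correlation=correlation,
        qic=qic(res, scale=qic_scale),
        n_obs=len(df),
        n_clusters=n_clusters,
        covariates=spec.covariates,
        stratum=spec.stratum,
        model=model_label,
        n_dropped_missing_outcome=n_dropped,
    )


def compare_correlation_structures(
    table: pd.DataFrame,
    spec: ModelSpec,
    structures: tuple[str, ...] = ("independence", "autoregressive"),
) -> dict[str, float]:
    """QIC per working correlation structure on identical data.

    The quasi-likelihood scale is fixed from the independence fit so the
    criteria are comparable; the structure with the lowest QIC is preferred.
    With 13 occasions per cluster the unstructured comparison is barely
    identified at small cohort sizes and can be unstable.
    """
    df, _ = _prepare(table, spec)
    base = fit_gee(table, spec, correlation="independence")
    rhs = [spec.exposure] + [f"C(sex)" if c == "sex" else c for c in spec.covariates]
    formula = f"{spec.outcome} ~ " + " + ".join(rhs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scale = float(
            smf.gee(
                formula,
                groups="participant_id",
                data=df,
                family=sm.families.Gaussian(),
                cov_struct=Independence(),
            )
            .fit()
            .scale
        )
    out = {}
    for s in structures:
        out[s] = fit_gee(table, spec, correlation=s, qic_scale=scale).qic
    return out


def run_model_battery(
    table: pd.DataFrame,
    correlation: str = "autoregressive",
    strata: tuple[str, ...] = ("all", "low_fit"),
    include_sensitivity: bool = True,
) -> pd.DataFrame:
    """All primary fits: 2 models x strata x 3 exposures x 3 outcomes.

    Sensitivity refits repeat model two without the wear-minutes covariate.
    Per-fit failures are recorded (``error`` column) without aborting the
    battery; the result is a tidy frame mirroring the published table
    layout.
    """
    rows = []
    specs: list[tuple[ModelSpec, str]] = []
    for stratum in strata:
        for adjusted in (False, True):
            for outcome in OUTCOMES:
                for exposure in EXPOSURES:
                    specs.append(
                        (
                            ModelSpec(outcome, exposure, adjusted=adjusted, stratum=stratum),
                            "primary",
                        )
                    )
    if include_sensitivity:
        for stratum in strata:
            for outcome in OUTCOMES:
                for exposure in EXPOSURES:
                    specs.append(
                        (
                            ModelSpec(
                                outcome,
                                exposure,
                                adjusted=True,
                                stratum=stratum,
                                include_wear=False,
                            ),
                            "sensitivity_no_wear",
                        )
                    )
    for spec, kind in specs:
        row = {
            "analysis": kind,
            "stratum": spec.stratum,
            "model": "two" if spec.adjusted else "one",
            "exposure": spec.exposure,
            "outcome": spec.outcome,
            "error": "",
        }
        try:
            res = fit_gee(table, spec, correlation=correlation)
            row.update(res.as_row())
        except GEEFitError as exc:
            row.update(
                {
                    "beta": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "p": float("nan"),
                    "qic": float("nan"),
                    "corstr": correlation,
                    "n_obs": 0,
                    "n_clusters": 0,
                    "error": str(exc),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor ``1/(1-R^2_j)`` per design column.

    Each predictor is regressed on the others (with intercept); exact
    collinearity reports ``inf`` for the offending column.  Values below ~5
    (here the analysis plan's check is < 2.7) indicate no multicollinearity
    concern.
    """
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("vif needs >= 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("vif needs n > p")
    out = {}
    for col in X.columns:
        y = X[col].to_numpy()
        others = sm.add_constant(X.drop(columns=col).to_numpy())
        r = sm.OLS(y, others).fit()
        r2 = min(float(r.rsquared), 1.0)
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def ancova_behavior_by_fitness(
    table: pd.DataFrame,
    behaviors: tuple[str, ...] = EXPOSURES,
) -> pd.DataFrame:
    """Fitness-group ANCOVA on participant-level mean behaviors.

    Daily rows are averaged per participant; each behavior is modeled as
    ``behavior ~ fitness_group + wear_min`` by OLS, and the group effect's
    F statistic and p-value are reported.  Requires both strata nonempty.
    """
    per = (
        table.groupby(["participant_id", "low_fitness"], as_index=False)[
            list(behaviors) + ["wear_min"]
        ].mean()
    )
    if per["low_fitness"].nunique() < 2:
        raise ValueError("ancova requires both fitness strata to be nonempty")
    rows = []
    for b in behaviors:
        full = smf.ols(f"{b} ~ C(low_fitness) + wear_min", data=per).fit()
        reduced = smf.ols(f"{b} ~ wear_min", data=per).fit()
        comp = full.compare_f_test(reduced)
        rows.append({"behavior": b, "F": float(comp[0]), "p": float(comp[1])})
    return pd.DataFrame(rows)


def predicted_change(beta: float, minutes: float) -> float:
    """Behavioral-context translation: expected outcome change (mmol/L) for a
    ``minutes``-long change in daily behavior, ``beta * minutes``."""
    return float(beta) * float(minutes)


def display_predicted_change(beta: float, minutes: float) -> float:
    """``predicted_change`` rounded to 2 decimals for reporting."""
    return round(predicted_change(beta, minutes), 2)
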