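# Methods notes

This note records the scientific and numerical choices behind
`glucoupler`: what each stage assumes, where the underlying study protocol
left a decision open, and what the synthetic cohorts do and do not emulate.

## CGM cleaning

Automatic readings arrive on a 15-min grid (96 per complete day).  Flash
monitors lose data when the reader is not scanned within 8 h: the sensor
keeps only the 8 h preceding the recovering scan, and the surviving grid
may restart on a shifted phase, so a real day can hold 95–97 points.  The
ingest therefore reconstructs missing slots *between* observed readings
(`round(gap/15) − 1` slots, aligned to the later reading's phase) rather
than forcing a nominal 96-slot grid.

Cleaning order is fixed and idempotent: (1) a missing slot takes the value
of a user scan within ±3 min — nearest wins, equal distances resolve to the
earlier scan (a deterministic, documented tie rule); (2) runs of ≤2 adjacent
missing slots with filled values on both sides are linearly interpolated in
clock time; runs of ≥3, and runs touching the day boundary, stay missing.
Observed values are never modified.  Decisions the protocol leaves open:

* **Valid-day threshold.** The rule is quoted as ≥90% consecutive values
  with the integer 86/96 printed; the printed integer governs (90% of 96
  is 86.4), and the same absolute 86 applies to drifted 95/97-slot days.
* **"Adjacent"** means adjacent grid slots, not wall-clock proximity.
* Days are cleaned independently; interpolation never bridges midnight,
  because validity is defined per calendar day.
* Replaced-from-user slots count as interpolation flanks by default
  (`bridge_replaced=False` turns this off).
* The first and last calendar days of every recording are partial
  (mid-morning deployment/collection) and are excluded before analysis.

## Actigraphy

The nonwear rule is a 60-minute window of consecutive zero counts, with
interruptions of at most 2 consecutive nonzero minutes tolerated:
interruption minutes are flagged nonwear but do not count toward the
60-zero-minute requirement, and a third consecutive nonzero minute ends
the candidate bout at the last zero epoch.  The 60-minute window (not 60
seconds, which would mark nearly all sleep-adjacent data nonwear and
contradict a ≥600-min wear day) follows the standard waist-worn adult
protocol; the window, interruption length and an optional interruption
magnitude cap are configurable.  Nonwear epochs contribute to no intensity
total.  Worn minutes partition exactly into sedentary (0–99 CPM), light
(100–2019) and MVPA (≥2020); consequently **wear = sedentary + light +
MVPA** by construction — a fact that matters for modeling (below).

## MAGE

The variant implemented is the classical turning-point MAGE: collapse
plateaus of equal consecutive values (the plateau midpoint is the turning
point), reduce the series to alternating local extrema including both
endpoints, qualify excursions whose absolute amplitude **strictly
exceeds** one sample SD (n−1) of the whole block, and average qualifying
amplitudes in the direction of the first qualifying excursion.  Strict
inequality makes the constant day cleanly undefined; undefined MAGE
propagates as a missing outcome and is dropped listwise in MAGE models
only, with counts logged.  MAGE+, MAGE− and their average are also
exposed.  Metrics are computed on the day's largest consecutive block, the
same series the validity rule inspects.  No pre-smoothing is applied by
default (a 3-point moving average is available).

## GEE battery

Exposures enter one at a time (each results row is a separate model).
Model two adjusts for wear minutes, age, sex (indicator, female reference)
and percent body fat.  The working correlation is AR(1) on the
within-participant order of *valid* days (gaps from invalid days collapse;
calendar-aware indexing is available), compared against independence and
unstructured alternatives by Pan's QIC with the quasi-likelihood scale
fixed from the independence fit so the criteria are comparable.  With 13
occasions and few clusters the unstructured comparison is barely
identified and is flagged as unstable.  Inference uses robust sandwich
standard errors, 95% CIs as β ± 1.96·SE, α = .05, no multiple-testing
correction.  Convergence: 60 iterations at 1e−6 relative tolerance;
nonconvergence raises, never silently.  A constant outcome returns a
degenerate zero-effect result.  GEE and QIC computations are delegated to
`statsmodels`; tests pin the behavior to closed forms (OLS equivalence for
size-1 clusters, the 2p penalty limit) and to independent auxiliary
regressions for VIF.

## Synthetic cohorts

The generator's defaults are the emulated study's conditions: 29
participants (configurable), 13 complete days plus partial boundary days,
behavior means/SDs 576.4 (67.8) / 269.1 (59.8) / 49.6 (29.9) min per day,
glucose base 5.1 mmol/L with 0.5 between-participant SD, and adjusted
low-fitness effect sizes 0.00067 / −0.00042 / −0.00154 mmol/L·min⁻¹ on
daily mean glucose and 0.00202 / −0.00216 / −0.00130 on MAGE.  About 55%
of participants are low-fitness (needs improvement / fair / good zones);
effects apply to them only, by default.

Structural choices, made once:

* **Behavior.**  Each behavior's variance splits evenly between a
  participant intercept and an AR(1) day series (ρ = 0.3; the day-to-day
  correlation magnitude is not reported anywhere, so this is a free
  choice).  Wear is the sum of the three classes.  Epoch days place the
  worn span after a ~07:00 wake time (long days start earlier rather than
  shrinking the drawn minutes) and draw per-minute counts uniformly within
  each class's CPM range.  Poisson(0.3/day) nonwear bouts of 60–120 min
  *interrupt* the worn span without consuming class minutes: removing
  minutes across classes would correlate the three behaviors, and the
  generator's contract is that they are independent.  Ground-truth minutes
  are counted from the epoch labels actually laid down, so detector
  recovery is exact up to boundary absorption of isolated zero-count
  sedentary minutes.
* **Glucose trace** (no mechanistic model is prescribed, so the simplest
  structure making mean/SD/MAGE nondegenerate and the GEE target linear):
  baseline + participant intercept + AR(1) day effect (SD 0.15) + 24-h
  circadian cosine (amplitude 0.3, acrophase 16:00) + 3 gamma-shaped meal
  kernels/day (peak 45 min, ~4-h support, amplitude ~N(2.4, 0.6)) + white
  noise (SD 0.25), quantized to 0.1 mmol/L like the device.  Meal kernels
  are **centered to zero net daily area**, so the behavior effect on daily
  mean glucose is applied as an exact uniform level shift and the MAGE
  effect (added to meal amplitudes) cannot leak into the mean-glucose
  target.  The MAGE coupling is approximate by design — amplitude shifts
  move MAGE by roughly, not exactly, the configured amount — so recovery
  tests check CI coverage for the mean-glucose betas and sign patterns for
  MAGE.
* **Missingness.**  Per night, with probability 0.3, a uniform
  15–210 min span of automatic readings is deleted and the subsequent grid
  may drift phase by 1–7 min; isolated points drop at rate 0.002.  The
  implied overall missing fraction (~2.5%) and the resulting ~93–94
  available points/day match the emulated deployment.  With drift enabled
  the slot reconstruction can differ from the injected count by ±1 point
  per gap (the lost phase is unobservable); bookkeeping equality is exact
  with drift off, and tested that way.
* **Seeds.**  One master seed fans out via `SeedSequence.spawn` to
  profile, per-participant and missingness substreams; identical configs
  give byte-identical output files.

A daily-level shortcut (`simulate_analysis_table`) draws the analysis
table directly from the same statistical skeleton, skipping trace and
epoch construction; it exists for calibration studies needing hundreds of
replicates (type-I error, QIC selection) where trace-level simulation adds
nothing but runtime.

What the generator does **not** emulate: insulin–glucose physiology, diet
beyond abstract meal kernels, posture (counts cannot see it), sleep
architecture, device miscalibration, or behavior-dependent nonwear.
Passing recovery tests therefore shows the *pipeline* is unbiased and
calibrated under the assumed structure, not that the structure is true of
any real cohort.

## Parameter-recovery design

Because wear is identically the sum of the three exposures, adjusting a
single-exposure model for wear changes the estimand: the wear-adjusted
coefficient mixes the exposure's own effect with the (negative of the)
wear-weighted average of the other behaviors' effects — an isotemporal,
substitution-like contrast.  Recovery of the *generating* marginal betas
is therefore tested with models adjusted for age, sex and percent body fat
but not wear (the package's wear-time sensitivity configuration); the
full battery including wear adjustment is still fitted and calibrated
under the null, where the distinction vanishes.  Simulation sizes — 60
replicates of 100 participants × 13 days for recovery, 100 replicates for
QIC selection and null calibration — were chosen to keep Monte-Carlo error
on coverage and rejection rates near one percentage point.

## Known limitations

* The 86-point rule on drifted 95/97-slot days, the EasyGV-internal MAGE
  conventions, and the original unstructured-correlation comparison are
  under-specified upstream; the choices here are documented above and
  configurable where reasonable.
* Robust sandwich CIs under-cover slightly at small cluster counts
  (~29); no small-sample correction is applied, matching the emulated
  analysis.
* Bout-level and real-time analyses, isotemporal substitution models, and
  mixed-effects alternatives are out of scope.
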