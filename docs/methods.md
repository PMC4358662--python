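# Methods

## The model

Development of poikilotherms is modeled by thermal summation: above a
developmental minimum `T_min` (°C) and below an upper optimum, the development
rate for a cumulative event (oviposition → entry into stage s) is linear in
temperature, `1/D(T) = b (T − T_min)`, so the event requires a fixed thermal
dose `ADD = 1/b` (°C·day). The model's assumptions are (i) linearity of rate
over the included temperature range, (ii) constant ADD across that range, and
(iii) equally spaced, low-variance temperature treatments. The package's job is
to estimate `T_min` and ADD from stage-frequency cohort data and to certify,
not assume, the range over which (i)–(ii) hold.

### Stage transitions

Destructive sampling never follows an individual, so stage-transition timing
must be read off cohort frequencies. For each stage and temperature the
package forms the cumulative proportion of *live* individuals at or past the
stage (replicates pooled per sample time, dead individuals out of the
denominator) and fits a Gaussian-family curve to the rising limb by nonlinear
least squares:

* `gaussian_cumulative` — Φ((t−μ)/σ), 2 parameters;
* `gaussian_cumulative_scaled` — a·Φ((t−μ)/σ), 3 parameters;
* `gaussian_peak` — a·exp(−(t−μ)²/2σ²), 3 parameters;
* `gaussian_peak_baseline` — y0 + a·exp(−(t−μ)²/2σ²), 4 parameters.

Selection is by small-sample AIC (AICc, counting the residual variance as a
parameter). The 50% transition point t50 is the time at which the fitted curve
crosses half of its span: μ exactly for the cumulative forms, and the
numerically solved rising-limb half-maximum (analytically μ − σ√(2 ln 2)) for
the peak forms. Standard errors propagate from the fit covariance by the delta
method. A probit regression (inverse-normal of the proportion against time,
with a 1/(2n) continuity correction at 0 and 1) provides an independent
cross-check estimator; the Gaussian t50 feeds the pipeline.

Two eligibility rules keep t50 an interpolation rather than an extrapolation:

* **Completion** — the observed series must reach a proportion ≥ 0.95. A limb
  only half-covered by the sampling window (e.g., adult emergence at a cold
  temperature that outlasts the experiment) would otherwise pin the midpoint
  from one tail; such series are refused, and the temperature drops out of
  that event's regression exactly as blank cells do in published tables.
* **Peak-family eligibility** — the peak forms are candidates only when the
  raw series actually declines after its maximum. On monotone cumulative data
  a free-roaming peak can bend the rising limb to chase noise; restricting it
  to peak-shaped inputs removes that failure mode without dropping the family.

### Rates and pruning

Cumulative t50s (hours) become durations (days, ÷24); stage durations are
successive differences at the same temperature. Rates 1/D are regressed on
measured chamber-mean temperature by OLS (nominal temperature by config
switch). The Wald–Wolfowitz runs test on the residual signs, ordered by
temperature, detects systematic curvature; while it rejects, the endpoint
temperature with the larger absolute standardized residual is removed
(policies: `max_std_resid` default, `low_first`, `alternate`). Interior
temperatures are never removed — curvature lives at the thermal extremes.

The runs test is exact (combinatorial distribution of the run count given the
sign counts) up to n = 20, normal with continuity correction above. The
`runs_test` operation defaults to the two-sided p-value; the pipeline prunes
with the one-sided *too-few-runs* alternative at `runs_alpha = 0.10`.
This is a deliberate choice: curvature produces too few runs, never too many,
and the exact test is so discrete at these sample sizes that two-sided testing
at α = 0.05 cannot reject *any* pattern for n ≤ 7 (the minimum attainable
one-sided p at n = 7 is 0.057). Final published-scale regressions have 4–10
points; a 0.05 two-sided rule would make the pruning step a no-op. The slope
t-test below stays at α = 0.05.

### Degree-day validation

From the pruned regression, `T_min` = x-intercept and ADD = 1/slope. The core
assumption is then checked directly: per-temperature accumulations
`D(T)·(T − T_min)` must form a line with no slope. `validate_flatness` fits
OLS of accumulation on temperature and requires a two-sided slope t-test
p ≥ 0.05 and a runs test p ≥ 0.10 on the residual signs. On failure the
endpoint temperature with the larger absolute standardized residual is removed
and the whole procedure (pruning → extraction → accumulation → validation)
restarts. If the fitted x-intercept lands at or above an included temperature,
no degree-days can accumulate there; the lowest temperature is removed and the
loop restarts. The accepted model's valid range is the min–max of the
surviving temperatures.

Known limitation, established during design: with ≤ 8 temperatures, a *single*
curved endpoint (≈10–15% rate deviation) is statistically invisible — the
biased x-intercept bends the accumulations into a U whose inflated residual
variance masks both the slope test and the runs test. The machinery reliably
removes block-patterned curvature (two or more deviating temperatures at one
end) and single *cold*-end outliers, but a lone deviating top temperature can
survive validation and bias ADD upward by ~10%. This is a property of the
published procedure itself at its own sample sizes, not of this
implementation; the synthetic world (below) is therefore built so the
temperatures outside the linear range are bounded by data availability and
mortality, as they were in the real study.

## The synthetic cohort world

No raw per-cup counts are deposited for the reference study, so the simulator
generates them under a stated world whose defaults come from that study's own
printed numbers:

| parameter | default | basis |
|---|---|---|
| event ADD (E→L1 … E→A) | 8.2, 21.3, 35.2, 82.5, 107.5, 230.2 °C·day | printed regression ADD values |
| `t_min` | 9.5 °C | biological minimum bracketed between 7.5 and 10 °C; printed x-intercepts 10.3–10.7 |
| linear range (`t_low`, `t_high`) | 15–30 °C | printed valid ranges |
| `curvature_low` | 1.6 (rate ×1.6 below 15 °C) | near-threshold flattening: observed cold-end rates sit *above* the extrapolated line (a printed first-transition x-intercept of 12.6 °C above its coldest data is only possible that way); also the largest factor keeping rate monotone in T |
| `curvature_high` | 0.85 (rate ×0.85 above 30 °C) | post-optimum plateau |
| `cv_transition` | 0.08 | normally distributed transition data with moderate spread |
| mortality | 0.4–0.6 cold, ≈0.1 mid-range, 1.0 at 32.5 °C | mortality reported highest at 10–17.5 °C and 32.5 °C; complete pre-adult mortality at 32.5 °C reproduces its blank regression row while leaving early stages measurable |
| design | 11 temperatures 7.5–32.5 °C, 4 chambers, 20 eggs/cup, 5 sample times per stage | the study design |
| observation horizon | 45 days (`schedule_from_truth`) | a realistic experiment length; cold-temperature late events fall outside it, mirroring the published blank cells |
| chamber jitter | ±0.4 °C per chamber, drawn once | stated incubator accuracy |

Each individual gets one truncated-normal speed factor (mean 1, sd = cv,
truncated at 0) multiplying all its event times. This preserves
within-individual event order and makes the cohort's proportion-entered curve
an exact cumulative Gaussian in time — the estimator's own model, so transition
fits are unbiased by construction and recovery tests probe the pipeline, not a
distribution mismatch. Death times are uniform over the individual's own
pre-adult period (or the observation window where no development occurs), so
early stages remain measurable at high-mortality temperatures. Curvature is
keyed to the *nominal* treatment temperature so chamber jitter cannot place
replicates on both sides of a breakpoint; the linear term uses the measured
chamber temperature.

The `default_schedule()` fixture reproduces the published a-priori sampling
table verbatim (cumulative stage boundaries divided into 5 equal pulls); it is
tied to that study's prior literature, not to this synthetic truth, so
pipeline runs use `schedule_from_truth`, which derives boundaries the same way
the study did — from prior knowledge of expected event times, padded by 3
individual SDs and clipped to the horizon.

What a green recovery test establishes: under a thermal-summation world with
Gaussian individual variation, realistic design, mortality, jitter and
curvature confined outside the linear range, the full chain (simulate →
proportions → Gaussian fits → t50 → durations → pruning → validation) returns
the true `t_min` within 1 °C and ADD within 5% (medians over 200 cohorts),
with removals confined to endpoint temperatures. What it does not establish:
robustness to non-Gaussian or stage-specific variation, fluctuating
temperatures, staging error, or curvature shapes other than piecewise
multiplicative — none of which the reference analysis handles either.

## Numerical choices

* Residuals with |r| ≤ 1e−9 × max|y| count as zeros and are dropped before
  runs testing, and an exactly-linear accumulation set passes the slope test
  directly; otherwise float noise on noiseless data produces random sign
  patterns and spurious pruning.
* Transition fits start from probit-heuristic initial values with σ bounded
  positive; tied AICc resolves to the first (fewest-parameter) family.
  RSS is floored at 1e−300 inside the log for exact fits.
* Report tables round half-even at 1 decimal in *decimal* arithmetic
  (`Decimal(repr(x))`), and table means are computed as exact decimal means of
  the printed-precision cells — binary-float rounding would turn a mean of
  48.95 into 48.9 instead of the correct 49.0.
* Sample times are quantized to 0.001 h so observation tables survive CSV
  round trips bit-exactly; chamber temperatures are recorded at 0.001 °C.
* `flag_outliers` measures "extended duration" against the pooled entry
  distribution into the *succeeding* stage (median + k·IQR, k = 3 default):
  the egg stage has no entry spread of its own (all individuals enter at
  oviposition), so the literal same-stage rule would flag everything.

## Open design points, as resolved

* The four Gaussian forms of the original analysis are in an unavailable
  companion reference; the 2/3-parameter cumulative and 3/4-parameter peak
  set with AICc selection stands in for them, and the probit construction is
  kept as a cross-check rather than combined with the Gaussian estimate.
* Replicates are pooled per sample time (live-count weighting) rather than
  fitted per chamber: the reference reports a single transition curve per
  temperature.
* Percent-time-in-stage uses the egg-to-adult duration as denominator; this
  choice reproduces the published mean row exactly.
* The published SE row matches neither the column SD nor SD/√n of the printed
  cells; the package reports SD/√n and does not chase the printed row.
* Manual exclusion masks are possible by subsetting the duration table before
  `fit_degree_day_model`, covering exclusions that were data-availability
  driven rather than test driven.
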