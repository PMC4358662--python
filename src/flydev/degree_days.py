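"""Degree-day (thermal summation) models with validated linear ranges.

From a pruned rate regression, the x-intercept estimates the developmental
minimum ``t_min`` and the reciprocal slope the accumulated degree-days (ADD)
for the event.  The model is then validated: per-temperature accumulations
``duration * (T - t_min)`` must form a line with no slope.  Where validation
fails, the offending endpoint temperature is removed and the whole procedure
restarts, until a temperature range satisfying all degree-day assumptions
remains — that range bounds the model's validity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import statsmodels.api as sm

from .rates import (
    RateError,
    RateRegression,
    ZERO_RESIDUAL_RTOL,
    ols_rate_fit,
    prune_nonlinear,
    runs_test,
)


class DegreeDayError(ValueError):
    """No valid degree-day model can be constructed."""


def round1(x: float) -> float:
    """Half-even rounding at 1 decimal in decimal (not binary) arithmetic."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def decimal_mean(values) -> float:
    """Exact decimal mean of printed-precision values (so 48.95 -> 48.95, not 48.9499...)."""
    dec = [Decimal(repr(float(v))) for v in values]
    return float(sum(dec) / len(dec))


@dataclass
class DegreeDayConfig:
    runs_alpha: float = 0.10
    slope_alpha: float = 0.05
    alternative: str = "fewer"
    policy: str = "max_std_resid"


@dataclass
class FlatnessResult:
    slope: float
    slope_p: float
    runs_p: float
    passed: bool
    residuals: np.ndarray


@dataclass
class DegreeDayModel:
    label: str
    t_min: float
    add: float
    valid_range: tuple[float, float]
    per_temp_add: dict[float, float]
    regression: RateRegression
    validation: FlatnessResult
    exclusions: list[tuple[float, str]] = field(default_factory=list)

    @property
    def calc_mean(self) -> float:
        return float(np.mean(list(self.per_temp_add.values())))

    @property
    def calc_se(self) -> float:
        vals = list(self.per_temp_add.values())
        if len(vals) < 2:
            return 0.0
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    @property
    def pct_deviation(self) -> float:
        return (self.calc_mean - self.add) / self.add * 100.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "t_min_c": self.t_min,
            "add_deg_day": self.add,
            "valid_range_c": list(self.valid_range),
            "per_temp_add": {str(t): v for t, v in sorted(self.per_temp_add.items())},
            "r2": self.regression.r2,
            "n": self.regression.n_included,
            "calc_add_mean": self.calc_mean,
            "calc_add_se": self.calc_se,
            "pct_deviation": self.pct_deviation,
            "flatness_slope": self.validation.slope,
            "flatness_slope_p": self.validation.slope_p,
            "flatness_runs_p": self.validation.runs_p,
            "exclusions": [{"temperature": t, "reason": r} for t, r in self.exclusions],
        }


def add_accumulations(durations: dict[float, float], t_min: float) -> dict[float, float]:
    """Per-temperature degree-day accumulations ``duration_days * (T - t_min)``."""
    for t in durations:
        if t <= t_min:
            raise DegreeDayError(
                f"temperature {t} degC at or below the developmental minimum {t_min:.2f} degC")
    return {t: d * (t - t_min) for t, d in sorted(durations.items())}


def validate_flatness(per_temp_add: dict[float, float], config: DegreeDayConfig | None = None
                      ) -> FlatnessResult:
    """Check that accumulations form a line with no slope.

    OLS of ADD on temperature; the slope must not differ from zero (two-sided
    t-test at ``slope_alpha``) and the residual signs must pass a runs test at
    ``runs_alpha``.  A degenerate runs sequence (all residual signs equal or
    all residuals zero) passes the runs component.
    """
    config = config or DegreeDayConfig()
    if len(per_temp_add) < 3:
        raise DegreeDayError(f"flatness validation needs >= 3 temperatures, got {len(per_temp_add)}")
    temps = np.array(sorted(per_temp_add))
    adds = np.array([per_temp_add[t] for t in temps])
    model = sm.OLS(adds, sm.add_constant(temps)).fit()
    slope = float(model.params[1])
    resid = np.asarray(model.resid)
    scale = max(float(np.abs(adds).max()), 1e-300)
    if float(np.abs(resid).max()) <= ZERO_RESIDUAL_RTOL * scale:
        # exact line: float-noise residuals carry no slope-test information
        slope_p = 1.0 if abs(slope) * float(np.ptp(temps)) <= ZERO_RESIDUAL_RTOL * scale else 0.0
    elif float(model.bse[1]) == 0.0 or not np.isfinite(model.bse[1]):
        slope_p = 1.0 if abs(slope) <= ZERO_RESIDUAL_RTOL * scale else 0.0
    else:
        slope_p = float(model.pvalues[1])
    signs = np.sign(np.where(np.abs(resid) <= ZERO_RESIDUAL_RTOL * scale, 0.0, resid))
    result = runs_test(signs[signs != 0], alternative=config.alternative)
    runs_p = 1.0 if result.degenerate else result.p_value
    passed = slope_p >= config.slope_alpha and runs_p >= config.runs_alpha
    return FlatnessResult(slope=slope, slope_p=slope_p, runs_p=runs_p,
                          passed=passed, residuals=resid)


def fit_degree_day_model(
    durations: dict[float, float],
    label: str = "",
    config: DegreeDayConfig | None = None,
) -> DegreeDayModel:
    """The full iterative degree-day construction for one event or stage.

    Alternates (1) runs-test pruning of the rate regression, (2) extraction of
    ``t_min`` and ADD, (3) per-temperature accumulation, and (4) the flatness
    validation.  A validation failure removes the endpoint temperature with the
    larger absolute standardized accumulation residual and restarts; a fitted
    ``t_min`` at or above an included temperature removes the lowest
    temperature (no degree-days can accumulate there).  Raises
    :class:`DegreeDayError` when fewer than 4 temperatures remain.
    """
    config = config or DegreeDayConfig()
    if len(durations) < 4:
        raise DegreeDayError(f"{label}: needs durations at >= 4 temperatures")
    available = dict(sorted(durations.items()))
    exclusions: list[tuple[float, str]] = []
    while True:
        if len(available) < 4:
            raise DegreeDayError(
                f"{label}: no valid degree-day range (only {len(available)} temperatures left)")
        temps = list(available)
        rates = [1.0 / available[t] for t in temps]
        try:
            reg = prune_nonlinear(temps, rates, label=label, runs_alpha=config.runs_alpha,
                                  alternative=config.alternative, policy=config.policy)
        except RateError as err:
            raise DegreeDayError(str(err)) from None
        included = {float(t): available[float(t)] for t in reg.temperatures}
        t_min = reg.x_intercept
        if min(included) <= t_min:
            bad = min(included)
            exclusions.append((bad, f"x-intercept {t_min:.2f} degC at or above this temperature"))
            del available[bad]
            continue
        accs = add_accumulations(included, t_min)
        flat = validate_flatness(accs, config)
        if flat.passed:
            exclusions.extend(reg.excluded)
            return DegreeDayModel(
                label=label, t_min=t_min, add=reg.add,
                valid_range=(min(included), max(included)),
                per_temp_add=accs, regression=reg,
                validation=flat, exclusions=exclusions,
            )
        temps_in = sorted(accs)
        sd = float(np.std(flat.residuals))
        std = flat.residuals / sd if sd > 0 else flat.residuals
        drop = temps_in[0] if abs(std[0]) >= abs(std[-1]) else temps_in[-1]
        exclusions.append(
            (drop, f"degree-day accumulation not flat (slope p={flat.slope_p:.3g}, "
                   f"runs p={flat.runs_p:.3g})"))
        del available[drop]


def summarize_add(model_or_values, regression_add: float | None = None) -> dict:
    """Published-style summary of per-temperature accumulations, at 1 decimal.

    ``calc_mean`` is the arithmetic mean over included temperatures (decimal
    arithmetic, half-even rounding), ``calc_se`` the sample SD over sqrt(n),
    and ``pct_deviation`` the relative difference between the calculated mean
    and the regression ADD.  A single-temperature model reports SE 0 with a flag.
    """
    if isinstance(model_or_values, DegreeDayModel):
        values = list(model_or_values.per_temp_add.values())
        reg_add = model_or_values.add
    else:
        values = list(model_or_values)
        reg_add = regression_add
    if not values:
        raise DegreeDayError("no per-temperature accumulations to summarize")
    mean = decimal_mean(values)
    single = len(values) < 2
    se = 0.0 if single else float(np.std(values, ddof=1) / math.sqrt(len(values)))
    out = {
        "calc_mean": round1(mean),
        "calc_se": round1(se),
        "n": len(values),
        "single_temperature": single,
    }
    if reg_add is not None:
        out["regression_add"] = round1(reg_add)
        out["pct_deviation"] = round1((mean - reg_add) / reg_add * 100.0)
    return out
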