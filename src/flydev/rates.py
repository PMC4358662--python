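"""Development rates versus temperature: durations, OLS fits, runs testing, pruning.

Development rate is the reciprocal of time in stage (1/day) and is treated as
linear in temperature over the mid-range.  The Wald-Wolfowitz runs test on the
signs of regression residuals (ordered by temperature) detects systematic
curvature; temperatures are pruned from the ends of the range until the
included points are consistent with a line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reference import DURATION_STAGES, EVENTS

#: Residuals within this relative magnitude of the largest fitted value are
#: treated as zeros and dropped before runs testing (noiseless data otherwise
#: yields meaningless float-noise sign patterns).
ZERO_RESIDUAL_RTOL = 1e-9


class RateError(ValueError):
    """A rate regression cannot be formed."""


# -- durations ------------------------------------------------------------------

def durations_from_t50(points: pd.DataFrame, use_nominal_temps: bool = False) -> pd.DataFrame:
    """Durations (days) from cumulative 50% transition points.

    Cumulative event durations are ``t50 / 24``; stage durations are successive
    differences of cumulative t50s at the same temperature.  A missing
    intermediate event leaves the stage durations that involve it absent,
    mirroring blank cells in the published table.

    Parameters
    ----------
    points
        Table with columns ``stage`` (event label), ``temp_c``,
        ``temp_nominal_c`` and ``t50_h`` as produced by
        :func:`flydev.transitions.transition_points`.
    """
    temp_col = "temp_nominal_c" if use_nominal_temps else "temp_c"
    rows = []
    for nominal, sub in points.groupby("temp_nominal_c"):
        t50s = dict(zip(sub["stage"], sub["t50_h"]))
        temp = float(sub[temp_col].iloc[0])
        for event in EVENTS:
            if event in t50s:
                rows.append({"label": event, "temperature": temp,
                             "temp_nominal_c": nominal, "duration_days": t50s[event] / 24.0})
        prev = 0.0
        available = True
        for event, stage in zip(EVENTS, DURATION_STAGES):
            if event not in t50s:
                available = False
                continue
            if available:
                rows.append({"label": stage, "temperature": temp,
                             "temp_nominal_c": nominal,
                             "duration_days": (t50s[event] - prev) / 24.0})
            prev = t50s[event]
            available = True
    frame = pd.DataFrame(rows, columns=["label", "temperature", "temp_nominal_c",
                                        "duration_days"])
    if (frame["duration_days"] <= 0).any():
        bad = frame[frame["duration_days"] <= 0]
        raise RateError(f"non-positive stage durations: {bad.to_dict('records')}")
    return frame


def duration_map(durations: pd.DataFrame, label: str) -> dict[float, float]:
    """{temperature: duration_days} for one event or stage label."""
    sub = durations[durations["label"] == label]
    return dict(zip(sub["temperature"], sub["duration_days"]))


# -- runs test --------------------------------------------------------------------

@dataclass
class RunsTestResult:
    p_value: float
    n_runs: int
    n_pos: int
    n_neg: int
    alternative: str
    degenerate: bool = False
    method: str = "exact"


def _runs_distribution(n_pos: int, n_neg: int) -> dict[int, float]:
    """Exact distribution of the number of runs given the sign counts."""
    n = n_pos + n_neg
    total = comb(n, n_pos)
    dist: dict[int, float] = {}
    for r in range(2, n + 1):
        if r % 2 == 0:
            m = r // 2
            num = 2 * comb(n_pos - 1, m - 1) * comb(n_neg - 1, m - 1)
        else:
            m = (r - 1) // 2
            num = (comb(n_pos - 1, m - 1) * comb(n_neg - 1, m)
                   + comb(n_pos - 1, m) * comb(n_neg - 1, m - 1))
        if num:
            dist[r] = num / total
    return dist


def count_runs(signs: np.ndarray) -> int:
    return 1 + int(np.sum(signs[1:] != signs[:-1]))


def runs_test(signs, alternative: str = "two-sided", exact_max_n: int = 20) -> RunsTestResult:
    """Wald-Wolfowitz runs test on a sequence of residual signs.

    Zeros are dropped.  The p-value is exact (combinatorial distribution of the
    run count given the sign counts) for ``n <= exact_max_n``, and a normal
    approximation with continuity correction above.  ``alternative`` is
    ``"two-sided"`` (twice the smaller tail), ``"fewer"`` (too few runs --
    the one-sided alternative produced by curvature) or ``"more"``.

    A sequence with only one sign carries no information about runs: the result
    is flagged degenerate with ``p = nan``.
    """
    if alternative not in ("two-sided", "fewer", "more"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = np.sign(np.asarray(list(signs), dtype=float))
    arr = arr[arr != 0]
    n_pos = int(np.sum(arr > 0))
    n_neg = int(np.sum(arr < 0))
    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(float("nan"), 0 if arr.size == 0 else 1,
                              n_pos, n_neg, alternative, degenerate=True)
    r = count_runs(arr)
    n = n_pos + n_neg
    if n <= exact_max_n:
        dist = _runs_distribution(n_pos, n_neg)
        lower = sum(p for k, p in dist.items() if k <= r)
        upper = sum(p for k, p in dist.items() if k >= r)
        method = "exact"
    else:
        mean = 1.0 + 2.0 * n_pos * n_neg / n
        var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n * n * (n - 1.0))
        sd = math.sqrt(var)
        from scipy.stats import norm
        lower = float(norm.cdf((r - mean + 0.5) / sd))
        upper = float(norm.sf((r - mean - 0.5) / sd))
        method = "normal"
    if alternative == "fewer":
        p = lower
    elif alternative == "more":
        p = upper
    else:
        p = 2.0 * min(lower, upper)
    return RunsTestResult(min(p, 1.0), r, n_pos, n_neg, alternative, method=method)


# -- OLS rate fit -----------------------------------------------------------------

@dataclass
class RateRegression:
    label: str
    temperatures: np.ndarray
    rates: np.ndarray
    slope: float
    intercept: float
    x_intercept: float
    r2: float
    slope_se: float
    slope_p: float
    residuals: np.ndarray
    excluded: list[tuple[float, str]] = field(default_factory=list)
    runs_p: float = float("nan")

    @property
    def n_included(self) -> int:
        return len(self.temperatures)

    @property
    def add(self) -> float:
        """Accumulated degree-days implied by the fit (1/slope), degC day."""
        return 1.0 / self.slope


def ols_rate_fit(temperatures, rates, label: str = "") -> RateRegression:
    """Ordinary least squares of development rate (1/day) on temperature (degC)."""
    temps = np.asarray(temperatures, dtype=float)
    y = np.asarray(rates, dtype=float)
    order = np.argsort(temps)
    temps, y = temps[order], y[order]
    if len(temps) < 3:
        raise RateError(f"{label}: insufficient linear range ({len(temps)} points, need >= 3)")
    model = sm.OLS(y, sm.add_constant(temps)).fit()
    intercept, slope = model.params
    if slope <= 0:
        raise RateError(f"{label}: fitted slope {slope:.3g} is not positive")
    return RateRegression(
        label=label, temperatures=temps, rates=y,
        slope=float(slope), intercept=float(intercept),
        x_intercept=float(-intercept / slope), r2=float(model.rsquared),
        slope_se=float(model.bse[1]), slope_p=float(model.pvalues[1]),
        residuals=np.asarray(model.resid),
    )


def residual_signs(regression: RateRegression) -> np.ndarray:
    """Residual signs ordered by temperature, with numerical zeros dropped."""
    res = regression.residuals
    scale = max(float(np.max(np.abs(regression.rates))), 1e-300)
    res = np.where(np.abs(res) <= ZERO_RESIDUAL_RTOL * scale, 0.0, res)
    signs = np.sign(res)
    return signs[signs != 0]


def prune_nonlinear(
    temperatures,
    rates,
    label: str = "",
    runs_alpha: float = 0.10,
    alternative: str = "fewer",
    policy: str = "max_std_resid",
) -> RateRegression:
    """Iteratively remove endpoint temperatures until residuals pass a runs test.

    At each step an OLS line is fitted, the residual signs (ordered by
    temperature) are runs-tested, and if ``p < runs_alpha`` one endpoint
    temperature is removed: the one with the larger absolute standardized
    residual (default policy), the lower end first (``low_first``), or
    alternating ends (``alternate``).  Interior temperatures are never removed.
    Stops when the test passes or 3 points remain; raises if no linear range is
    found.  Every removal is recorded in ``excluded``.
    """
    if policy not in ("max_std_resid", "low_first", "alternate"):
        raise ValueError(f"unknown pruning policy {policy!r}")
    pairs = sorted(zip(np.asarray(temperatures, float), np.asarray(rates, float)))
    if len(pairs) < 4:
        raise RateError(f"{label}: pruning needs >= 4 points")
    excluded: list[tuple[float, str]] = []
    take_low = True
    while True:
        temps = [t for t, _ in pairs]
        y = [r for _, r in pairs]
        reg = ols_rate_fit(temps, y, label=label)
        signs = residual_signs(reg)
        result = runs_test(signs, alternative=alternative)
        reg.runs_p = result.p_value
        reg.excluded = list(excluded)
        if result.degenerate or result.p_value >= runs_alpha:
            return reg
        if len(pairs) <= 3:
            raise RateError(f"{label}: no linear range found (runs p={result.p_value:.3g} at n=3)")
        sd = float(np.std(reg.residuals))
        std = reg.residuals / sd if sd > 0 else reg.residuals
        if policy == "max_std_resid":
            drop_low = abs(std[0]) >= abs(std[-1])
        elif policy == "low_first":
            drop_low = True
        else:
            drop_low = take_low
            take_low = not take_low
        idx = 0 if drop_low else len(pairs) - 1
        removed_t = pairs[idx][0]
        excluded.append((removed_t, f"runs test p={result.p_value:.4g} < {runs_alpha}"))
        pairs.pop(idx)
        if len(pairs) < 3:
            raise RateError(f"{label}: no linear range found")
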