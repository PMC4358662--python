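"""Stage-transition curves and 50% transition points.

Counts are converted to the cumulative proportion of live individuals at or
past a stage versus time, a Gaussian-family curve is fitted to the rising limb
by nonlinear least squares (small-sample AIC selects among four forms), and the
time at which the fitted curve crosses half of its span is the 50% transition
point (t50) with a delta-method standard error.  A probit fit is provided as an
independent cross-check estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .reference import EVENTS, STAGES
from .simulate import COUNT_COLUMNS, ObservationSet

_HALF_WIDTH = math.sqrt(2.0 * math.log(2.0))  # peak half-maximum offset in sigma units


class TransitionError(ValueError):
    """A proportion series cannot be formed or fitted."""


@dataclass
class ProportionSeries:
    """Cumulative proportion entered a stage vs time at one temperature."""

    stage: str
    temperature: float  # mean measured chamber temperature, degC
    times_h: np.ndarray
    proportions: np.ndarray
    n_total: np.ndarray  # live individuals behind each proportion

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise TransitionError("sample times must be strictly increasing")
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise TransitionError("proportions must lie in [0, 1]")
        if np.any(self.n_total <= 0):
            raise TransitionError("each point needs at least one live individual")


# -- Gaussian family -----------------------------------------------------------

def _cum2(t, mu, sigma):
    return ndtr((t - mu) / sigma)


def _cum3(t, a, mu, sigma):
    return a * ndtr((t - mu) / sigma)


def _peak3(t, a, mu, sigma):
    return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _peak4(t, a, mu, sigma, y0):
    return y0 + a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


_FAMILIES: dict[str, dict] = {
    "gaussian_cumulative": {"f": _cum2, "names": ("mu", "sigma"), "cumulative": True},
    "gaussian_cumulative_scaled": {"f": _cum3, "names": ("a", "mu", "sigma"), "cumulative": True},
    "gaussian_peak": {"f": _peak3, "names": ("a", "mu", "sigma"), "cumulative": False},
    "gaussian_peak_baseline": {"f": _peak4, "names": ("a", "mu", "sigma", "y0"), "cumulative": False},
}


@dataclass
class TransitionCurve:
    family: str
    params: dict[str, float]
    cov: np.ndarray
    fit_r2: float
    aicc: float
    included_times_h: np.ndarray
    stage: str = ""
    temperature: float = float("nan")

    @property
    def cumulative(self) -> bool:
        return _FAMILIES[self.family]["cumulative"]

    def __call__(self, t):
        f = _FAMILIES[self.family]["f"]
        names = _FAMILIES[self.family]["names"]
        return f(np.asarray(t, dtype=float), *(self.params[k] for k in names))

    @property
    def span(self) -> tuple[float, float]:
        """(low, high) asymptotic values of the fitted curve."""
        y0 = self.params.get("y0", 0.0)
        a = self.params.get("a", 1.0)
        return (y0, y0 + a) if self.cumulative else (y0, y0 + a)

    def midpoint_value(self) -> float:
        lo, hi = self.span
        return 0.5 * (lo + hi)


@dataclass
class TransitionPoint:
    stage: str
    temperature: float
    t50_h: float
    se_t50_h: float
    source_curve: TransitionCurve = field(repr=False)


# -- proportions ---------------------------------------------------------------

def proportion_entered(
    obs: ObservationSet, stage: str, temperature: float, pooling: str = "pooled"
) -> ProportionSeries:
    """Proportion of live individuals at or past ``stage``, pooled over replicates.

    "Entered" is cumulative: an individual in any later stage has entered this
    one, so the rising limb is monotone in expectation.  Dead individuals leave
    the denominator.  Sample times with no live individuals are dropped; if no
    sample time has any, an error names the temperature.
    """
    if stage not in STAGES[1:]:
        raise TransitionError(f"no transition into stage {stage!r}")
    if pooling != "pooled":
        raise TransitionError(f"unknown pooling rule {pooling!r}")
    sub = obs.frame[obs.frame["temp_nominal_c"] == temperature]
    if sub.empty:
        raise TransitionError(f"no observations at {temperature} degC")
    idx = STAGES.index(stage)
    past_cols = [f"count_{s}" for s in STAGES[idx:]]
    live_cols = [f"count_{s}" for s in STAGES]
    grouped = sub.groupby("sample_time_h")[list(COUNT_COLUMNS)].sum()
    live = grouped[live_cols].sum(axis=1)
    keep = live > 0
    if not keep.any():
        raise TransitionError(f"no live individuals at any sample time at {temperature} degC")
    entered = grouped.loc[keep, past_cols].sum(axis=1)
    live = live[keep]
    return ProportionSeries(
        stage=stage,
        temperature=float(sub["temp_measured_c"].mean()),
        times_h=live.index.to_numpy(dtype=float),
        proportions=(entered / live).to_numpy(dtype=float),
        n_total=live.to_numpy(dtype=float),
    )


def rising_limb(series: ProportionSeries) -> ProportionSeries:
    """Truncate after the first local maximum reaching 95% of the series span.

    Keeps the leading plateau and the rising portion of the curve (the 0%-100%
    transition), discarding any later decline or noise around the upper plateau.
    """
    y = series.proportions
    lo, hi = y.min(), y.max()
    if hi <= lo:
        return series
    thresh = lo + 0.95 * (hi - lo)
    cut = len(y)
    for i, v in enumerate(y):
        if v >= thresh and (i == len(y) - 1 or y[i + 1] <= v):
            cut = i + 1
            break
    return ProportionSeries(series.stage, series.temperature,
                            series.times_h[:cut], y[:cut], series.n_total[:cut])


def _initial_guess(t, y, family):
    """Probit-heuristic starting values (robust for steps and clean limbs)."""
    lo, hi = y.min(), y.max()
    a0 = max(hi - lo, 1e-3)
    n = 50.0
    p = np.clip((y - lo) / a0, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    z = ndtri(p)
    if np.ptp(z) > 0 and np.ptp(t) > 0:
        slope, inter = np.polyfit(t, z, 1)
    else:
        slope, inter = 0.0, 0.0
    if slope > 1e-12:
        mu0, sigma0 = -inter / slope, 1.0 / slope
    else:
        mu0 = float(np.interp(0.5 * (lo + hi), y, t)) if np.ptp(y) > 0 else float(np.median(t))
        sigma0 = max(np.ptp(t) / 6.0, 1e-3)
    sigma0 = float(np.clip(sigma0, 1e-6, np.ptp(t) if np.ptp(t) > 0 else 1.0))
    if family == "gaussian_cumulative":
        return [mu0, sigma0]
    if family == "gaussian_cumulative_scaled":
        return [min(max(hi, 1e-3), 1.0), mu0, sigma0]
    if family == "gaussian_peak":
        return [min(max(hi, 1e-3), 1.0), mu0 + _HALF_WIDTH * sigma0, sigma0]
    return [max(a0, 1e-3), mu0 + _HALF_WIDTH * sigma0, sigma0, lo]


def _bounds(family, t):
    big = max(np.ptp(t), abs(t.max()), 1.0) * 10.0
    if family == "gaussian_cumulative":
        return ([t.min() - big, 1e-9], [t.max() + big, big])
    if family == "gaussian_cumulative_scaled":
        return ([1e-9, t.min() - big, 1e-9], [1.5, t.max() + big, big])
    if family == "gaussian_peak":
        return ([1e-9, t.min() - big, 1e-9], [1.5, t.max() + big, big])
    return ([1e-9, t.min() - big, 1e-9, -0.5], [1.5, t.max() + big, big, 0.5])


def fit_transition(
    series: ProportionSeries,
    families: tuple[str, ...] | None = None,
    completion: float = 0.95,
) -> TransitionCurve:
    """Fit the Gaussian family set to the rising limb; select by small-sample AIC.

    Requires at least 4 points with a non-degenerate span after the rising-limb
    restriction, and that the transition is essentially complete within the
    sampled window (maximum observed proportion >= ``completion``) — only the
    0%-100% portion of a curve reflects the transition, and a half-observed
    limb would extrapolate its midpoint.  The peak families are only candidates
    when the raw series actually declines after its maximum (peak-shaped data);
    on monotone cumulative series they can bend the rising limb to chase noise.
    Raises :class:`TransitionError` with per-family diagnostics if no candidate
    converges.
    """
    if families is None:
        y_raw = series.proportions
        i_max = int(np.argmax(y_raw))
        span_raw = np.ptp(y_raw)
        declines = span_raw > 0 and i_max < len(y_raw) - 1 and \
            float(y_raw[i_max:].min()) < y_raw.min() + 0.8 * span_raw
        families = tuple(_FAMILIES) if declines else (
            "gaussian_cumulative", "gaussian_cumulative_scaled")
    limb = rising_limb(series)
    t, y = limb.times_h, limb.proportions
    if len(t) < 4:
        raise TransitionError(
            f"{series.stage} at {series.temperature:.1f} degC: only {len(t)} points on the rising limb")
    if np.ptp(y) <= 0:
        raise TransitionError(
            f"{series.stage} at {series.temperature:.1f} degC: degenerate series (no transition observed)")
    if y.max() < completion:
        raise TransitionError(
            f"{series.stage} at {series.temperature:.1f} degC: transition not completed within "
            f"the sampled window (max proportion {y.max():.2f} < {completion})")
    n = len(t)
    tss = float(np.sum((y - y.mean()) ** 2))
    results, failures = [], {}
    for fam in families:
        form = _FAMILIES[fam]
        k = len(form["names"]) + 1  # + residual variance
        if n - k - 1 < 1:
            failures[fam] = "too few points for this family"
            continue
        p0 = _initial_guess(t, y, fam)
        try:
            popt, pcov = optimize.curve_fit(
                form["f"], t, y, p0=p0, bounds=_bounds(fam, t), maxfev=5000)
        except (RuntimeError, ValueError) as err:
            failures[fam] = str(err)
            continue
        rss = float(np.sum((y - form["f"](t, *popt)) ** 2))
        aicc = n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        results.append((aicc, fam, dict(zip(form["names"], popt)), pcov, r2))
    if not results:
        raise TransitionError(
            f"{series.stage} at {series.temperature:.1f} degC: no family converged: {failures}")
    aicc, fam, params, pcov, r2 = min(results, key=lambda r: r[0])
    return TransitionCurve(family=fam, params=params, cov=np.asarray(pcov), fit_r2=r2,
                           aicc=aicc, included_times_h=t, stage=series.stage,
                           temperature=series.temperature)


def t50(curve: TransitionCurve) -> TransitionPoint:
    """Time at which the fitted curve crosses half of its span.

    For the cumulative families this is the fitted center ``mu`` exactly; for
    the peak families the midpoint of the rising limb is solved numerically on
    the fitted curve.  The standard error propagates from the fit covariance by
    the delta method.  Errors if the crossing lies outside the included sample
    times.
    """
    names = _FAMILIES[curve.family]["names"]
    mu = curve.params["mu"]
    sigma = curve.params["sigma"]
    if curve.cumulative:
        t_half = mu
        grad = np.array([1.0 if k == "mu" else 0.0 for k in names])
    else:
        target = curve.midpoint_value()
        lo_t = mu - 12.0 * sigma
        try:
            t_half = optimize.brentq(lambda x: curve(x) - target, lo_t, mu, xtol=1e-12)
        except ValueError as err:
            raise TransitionError(f"curve never reaches half of its span: {err}") from None
        grad = np.array([0.0, 1.0, -_HALF_WIDTH, 0.0][: len(names)])
    lo, hi = curve.included_times_h[0], curve.included_times_h[-1]
    if not lo <= t_half <= hi:
        raise TransitionError(
            f"t50 {t_half:.2f} h outside included sample times [{lo:.2f}, {hi:.2f}]")
    var = float(grad @ curve.cov @ grad)
    return TransitionPoint(stage=curve.stage, temperature=curve.temperature,
                           t50_h=float(t_half), se_t50_h=math.sqrt(max(var, 0.0)),
                           source_curve=curve)


def probit_t50(series: ProportionSeries) -> float:
    """Independent probit estimate of the 50% transition time.

    Proportions are mapped through the inverse normal with a 1/(2n) continuity
    correction at 0 and 1, a line is fitted against time, and t50 is the time
    at probit zero.
    """
    limb = rising_limb(series)
    p = limb.proportions.copy()
    n = limb.n_total
    p = np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    z = ndtri(p)
    if np.ptp(z) <= 0:
        raise TransitionError("probit fit needs variation in proportions")
    slope, inter = np.polyfit(limb.times_h, z, 1)
    if slope <= 0:
        raise TransitionError("probit slope not positive")
    return float(-inter / slope)


# -- outlier flagging ----------------------------------------------------------

def _entry_quantile(series: ProportionSeries, q: float) -> float | None:
    """Time at which the entered proportion crosses q (linear interpolation)."""
    y, t = series.proportions, series.times_h
    above = np.nonzero(y >= q)[0]
    if len(above) == 0:
        return None
    i = above[0]
    if i == 0:
        return float(t[0])
    return float(t[i - 1] + (q - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1]))


def flag_outliers(obs: ObservationSet, k: float = 3.0) -> tuple[ObservationSet, pd.DataFrame]:
    """Exclude individuals with extraordinarily extended stage durations.

    For each temperature and stage, the pooled entry distribution into the
    succeeding stage gives a median and IQR; individuals still recorded in the
    stage at sample times beyond ``median + k * IQR`` are removed from the
    counts.  Returns the filtered observations and an exclusion log (empty if
    nothing was excluded).  ``k = inf`` disables exclusion.
    """
    frame = obs.frame.copy()
    log_rows = []
    if not math.isinf(k):
        for temperature in obs.temperatures():
            for s_idx, stage in enumerate(STAGES[:-1]):
                next_stage = STAGES[s_idx + 1]
                try:
                    series = proportion_entered(obs, next_stage, temperature)
                except TransitionError:
                    continue
                med = _entry_quantile(series, 0.5)
                q1 = _entry_quantile(series, 0.25)
                q3 = _entry_quantile(series, 0.75)
                if med is None or q1 is None or q3 is None:
                    continue
                threshold = med + k * (q3 - q1)
                col = f"count_{stage}"
                late = (frame["temp_nominal_c"] == temperature) & \
                       (frame["sample_time_h"] > threshold) & (frame[col] > 0)
                for ridx in frame.index[late]:
                    log_rows.append({
                        "temperature": temperature, "stage": stage,
                        "replicate_id": frame.at[ridx, "replicate_id"],
                        "sample_time_h": frame.at[ridx, "sample_time_h"],
                        "n_excluded": int(frame.at[ridx, col]),
                        "threshold_h": threshold,
                    })
                    frame.at[ridx, col] = 0
    log = pd.DataFrame(log_rows, columns=["temperature", "stage", "replicate_id",
                                          "sample_time_h", "n_excluded", "threshold_h"])
    return ObservationSet(frame, n_individuals=obs.n_individuals), log


def transition_points(
    obs: ObservationSet,
    temperatures: list[float] | None = None,
    events: tuple[str, ...] = EVENTS,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every (event, temperature) transition; skip unfittable combinations.

    Returns a tidy table ``stage,temp_c,t50_h,se_h,family,r2`` of cumulative
    transition points plus a log of skipped combinations with reasons.
    """
    temps = temperatures if temperatures is not None else obs.temperatures()
    rows, skipped = [], []
    for temperature in temps:
        for event in events:
            stage = event.split("-")[1]
            try:
                series = proportion_entered(obs, stage, temperature)
                curve = fit_transition(series)
                point = t50(curve)
            except TransitionError as err:
                skipped.append(f"{event} at {temperature} degC: {err}")
                continue
            rows.append({"stage": event, "temp_c": point.temperature,
                         "temp_nominal_c": temperature, "t50_h": point.t50_h,
                         "se_h": point.se_t50_h, "family": curve.family,
                         "r2": curve.fit_r2})
    return pd.DataFrame(rows, columns=["stage", "temp_c", "temp_nominal_c",
                                       "t50_h", "se_h", "family", "r2"]), skipped
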