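"""Synthetic blow-fly cohort simulator with recoverable ground truth.

The generator emulates a constant-temperature destructive-sampling rearing
study: cups of eggs are held at a series of temperatures and whole cups are
pulled and staged at scheduled times, so stage-frequency time series are built
across experimental units rather than by following individuals.

The underlying development model is thermal summation: each cumulative event
(oviposition to entry into stage s) requires a fixed number of degree-days
above a developmental minimum ``t_min``, so at constant temperature ``T`` the
expected event time is ``24 * ADD_e / ((T - t_min) * c(T))`` hours, where
``c(T)`` is a piecewise curvature factor that bends the rate away from the
linear law outside a stated mid-range.  Individual variation enters as a
single truncated-normal multiplier per individual applied to all of its event
times, which makes the cohort's proportion-entered curve an exact cumulative
Gaussian in time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .reference import (
    EVENTS,
    NOMINAL_TEMPERATURES_C,
    SAMPLE_TIME_BOUNDARIES_H,
    STAGES,
)

COUNT_COLUMNS = tuple(f"count_{s}" for s in STAGES) + ("count_dead",)
CSV_COLUMNS = ("replicate_id", "temp_nominal_c", "temp_measured_c", "sample_time_h") + COUNT_COLUMNS

#: Stated default ground truth: event degree-day requirements from the published
#: regression results, developmental minimum inside the published 7.5-10 degC
#: bracket, curvature outside the published 15-30 degC linear range, and
#: mortality highest at 10-17.5 degC and complete at 32.5 degC.
DEFAULT_STAGE_ADD = {
    "E-L1": 8.2, "E-L2": 21.3, "E-L3f": 35.2, "E-L3m": 82.5, "E-P": 107.5, "E-A": 230.2,
}
DEFAULT_MORTALITY = {
    7.5: 0.50, 10.0: 0.60, 12.5: 0.50, 15.0: 0.45, 17.5: 0.40, 20.0: 0.12,
    22.5: 0.08, 25.0: 0.08, 27.5: 0.10, 30.0: 0.15, 32.5: 1.00,
}


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a synthetic cohort.

    Parameters
    ----------
    stage_add
        Accumulated degree-days (degC day) for each cumulative event, strictly
        increasing along the event sequence.
    t_min
        Developmental minimum (degC): the x-intercept of the linear mid-range
        rate law.  No development occurs at or below it.
    curvature_low, curvature_high
        Multiplicative factors applied to the linear rate below ``t_low`` and
        above ``t_high``.  Values > 1 model the near-threshold flattening of
        real rate curves (observed rates above the extrapolated line); values
        < 1 model the post-optimum plateau.
    cv_transition
        Coefficient of variation of individual transition times (> 0 for a
        stochastic cohort; 0 gives the deterministic limit).
    mortality
        Per-cohort probability an individual dies before adulthood, by nominal
        temperature.
    seed
        RNG seed; identical seed and design reproduce the cohort byte for byte.
    """

    stage_add: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_ADD))
    t_min: float = 9.5
    t_low: float = 15.0
    t_high: float = 30.0
    curvature_low: float = 1.6
    curvature_high: float = 0.85
    cv_transition: float = 0.08
    mortality: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_MORTALITY))
    seed: int = 0

    def __post_init__(self) -> None:
        adds = [self.stage_add[e] for e in EVENTS if e in self.stage_add]
        if list(self.stage_add) and any(b <= a for a, b in zip(adds, adds[1:])):
            raise ValueError("stage_add must be strictly increasing along the event sequence")
        if self.cv_transition < 0:
            raise ValueError("cv_transition must be >= 0")
        if self.curvature_low < 0 or self.curvature_high < 0:
            raise ValueError("curvature factors must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in self.mortality.values()):
            raise ValueError("mortality probabilities must lie in [0, 1]")

    def curvature(self, temperature: float) -> float:
        if temperature < self.t_low:
            return self.curvature_low
        if temperature > self.t_high:
            return self.curvature_high
        return 1.0

    def rate_per_day(self, event: str, temperature: float) -> float:
        """Development rate 1/day for a cumulative event at a constant temperature."""
        if temperature <= self.t_min:
            return 0.0
        return (temperature - self.t_min) * self.curvature(temperature) / self.stage_add[event]

    def expected_event_times_h(self, temperature: float,
                               condition: float | None = None) -> dict[str, float] | None:
        """Deterministic event times (hours), or None below the developmental minimum.

        ``condition`` is the nominal treatment temperature used to select the
        curvature regime (so chambers jittered across a breakpoint stay in
        their treatment's regime); it defaults to ``temperature``.
        """
        curv = self.curvature(temperature if condition is None else condition)
        if temperature <= self.t_min or curv == 0.0:
            return None
        denom = (temperature - self.t_min) * curv
        return {e: 24.0 * self.stage_add[e] / denom for e in EVENTS}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mortality"] = {str(k): v for k, v in d["mortality"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        d["mortality"] = {float(k): v for k, v in d["mortality"].items()}
        return cls(**d)


@dataclass
class DesignConfig:
    """Experimental design: which cups exist and when they are pulled.

    ``schedule`` maps ``(nominal_temperature, event)`` to the sample times
    (hours after oviposition) of that life-stage interval; each list is
    strictly increasing with ``samples_per_stage`` entries.
    """

    temperatures: list[tuple[float, float]]
    schedule: dict[tuple[float, str], list[float]]
    n_replicates: int = 4
    n_individuals: int = 20
    samples_per_stage: int = 5
    photoperiod_label: str = "16:8 L:D"
    temperature_jitter_c: float = 0.4

    def __post_init__(self) -> None:
        nominals = [t[0] for t in self.temperatures]
        steps = np.diff(sorted(nominals))
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("nominal temperatures must be equally spaced")
        for key, times in self.schedule.items():
            if len(times) != self.samples_per_stage:
                raise ValueError(f"schedule {key} must have {self.samples_per_stage} sample times")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"schedule {key} sample times must be strictly increasing")
            if times[0] <= 0:
                raise ValueError(f"schedule {key} sample times must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["schedule"] = {f"{t}|{e}": v for (t, e), v in d["schedule"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DesignConfig":
        d = json.loads(text)
        d["temperatures"] = [tuple(t) for t in d["temperatures"]]
        sched = {}
        for key, v in d["schedule"].items():
            t, e = key.split("|")
            sched[(float(t), e)] = list(v)
        d["schedule"] = sched
        return cls(**d)


class ObservationSet:
    """Tidy destructive-sampling counts: one row per cup pulled and staged.

    Wraps a :class:`pandas.DataFrame` with the CSV layout
    ``replicate_id,temp_nominal_c,temp_measured_c,sample_time_h,count_E,...,count_dead``.
    """

    def __init__(self, frame: pd.DataFrame, n_individuals: int | None = None):
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        counts = frame[list(COUNT_COLUMNS)]
        if (counts < 0).any().any():
            raise ValueError("stage counts must be non-negative")
        if (frame["sample_time_h"] <= 0).any():
            raise ValueError("sample times must be positive")
        if n_individuals is not None and (counts.sum(axis=1) > n_individuals).any():
            raise ValueError("row counts exceed the number of individuals per cup")
        self.frame = frame.reset_index(drop=True)
        self.n_individuals = n_individuals

    def temperatures(self) -> list[float]:
        return sorted(self.frame["temp_nominal_c"].unique())

    def to_csv(self, path) -> None:
        # default float formatting is shortest-round-trip: read(write(x)) == x
        self.frame.to_csv(path, index=False, columns=list(CSV_COLUMNS))

    @classmethod
    def read_csv(cls, path, n_individuals: int | None = None) -> "ObservationSet":
        return cls(pd.read_csv(path), n_individuals=n_individuals)

    def __len__(self) -> int:
        return len(self.frame)


def default_schedule() -> DesignConfig:
    """The packaged a-priori design: published cumulative stage-boundary times.

    Each life-stage interval (previous boundary, boundary] is divided into 5
    equal sample times; temperatures run 7.5-32.5 degC at 2.5 degC steps.
    """
    schedule: dict[tuple[float, str], list[float]] = {}
    for temp in NOMINAL_TEMPERATURES_C:
        bounds = SAMPLE_TIME_BOUNDARIES_H[temp]
        prev = 0.0
        for event, bound in zip(EVENTS, bounds):
            width = bound - prev
            schedule[(temp, event)] = [round(prev + width * k / 5.0, 3) for k in range(1, 6)]
            prev = float(bound)
    return DesignConfig(temperatures=[(t, t) for t in NOMINAL_TEMPERATURES_C], schedule=schedule)


def schedule_boundary(design: DesignConfig, temperature: float, event: str) -> float:
    """Upper boundary (h) of a life-stage interval: its last sample time."""
    return design.schedule[(temperature, event)][-1]


def schedule_from_truth(
    truth: SimulationTruth,
    temperatures: tuple[float, ...] = NOMINAL_TEMPERATURES_C,
    samples_per_stage: int = 5,
    n_replicates: int = 4,
    n_individuals: int = 20,
    horizon_days: float = 45.0,
    pad_sd: float = 3.0,
) -> DesignConfig:
    """Derive a sampling design from prior knowledge of the truth.

    Mirrors how the reference design was built from earlier literature: each
    stage-interval boundary is the expected event time padded by ``pad_sd``
    individual standard deviations (covering the transition's upper tail),
    clipped to an observation horizon.  Events whose whole window lies beyond
    the horizon are simply never sampled - the cold-temperature late events
    drop out of the data, as in the reference study.

    Temperatures at or below the developmental minimum reuse the schedule of
    the coldest developing temperature (the reference design likewise reused
    one cold-column schedule).
    """
    horizon_h = horizon_days * 24.0
    pad = 1.0 + pad_sd * truth.cv_transition
    schedule: dict[tuple[float, str], list[float]] = {}
    developing = [t for t in temperatures if truth.expected_event_times_h(t) is not None]
    if not developing:
        raise ValueError("no temperature in the design is above the developmental minimum")
    coldest = min(developing)
    for temp in temperatures:
        source = temp if truth.expected_event_times_h(temp) is not None else coldest
        times = truth.expected_event_times_h(source)
        prev = 0.0
        for event in EVENTS:
            bound = min(times[event] * pad, horizon_h)
            if bound <= prev:  # interval entirely beyond the horizon
                continue
            width = bound - prev
            # quantized to 0.001 h so sample times survive CSV round trips exactly
            schedule[(temp, event)] = [round(prev + width * k / samples_per_stage, 3)
                                       for k in range(1, samples_per_stage + 1)]
            prev = bound
    return DesignConfig(
        temperatures=[(t, t) for t in temperatures],
        schedule=schedule,
        n_replicates=n_replicates,
        n_individuals=n_individuals,
        samples_per_stage=samples_per_stage,
    )


def _truncnorm_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal multipliers: mean 1, sd cv, truncated at 0 (inverse CDF)."""
    if cv == 0.0:
        return np.ones(n)
    lo = ndtr((0.0 - 1.0) / cv)
    u = rng.random(n)
    return 1.0 + cv * ndtri(lo + u * (1.0 - lo))


def simulate_individual(
    truth: SimulationTruth, temperature: float, rng: np.random.Generator
) -> dict[str, float] | None:
    """Event times (h) for one individual, or None below the developmental minimum."""
    base = truth.expected_event_times_h(temperature)
    if base is None:
        return None
    factor = float(_truncnorm_factors(1, truth.cv_transition, rng)[0])
    return {e: t * factor for e, t in base.items()}


def simulate_cohort(truth: SimulationTruth, design: DesignConfig,
                    rng: np.random.Generator | None = None) -> ObservationSet:
    """Simulate the full destructive-sampling experiment.

    For every scheduled (temperature, sample time, replicate) a fresh cup of
    ``n_individuals`` is drawn.  Each individual gets one truncated-normal
    speed factor; it is classified into the latest event whose realized
    transition time is at or before the sample time (pharate individuals
    between apolysis and ecdysis therefore count as the earlier stage).
    Mortality assigns a pre-adult death time uniform over the individual's own
    egg-to-adult period; dead individuals are counted in ``count_dead``.

    Deterministic given ``truth.seed`` and the design.
    """
    if not design.schedule:
        raise ValueError("design has an empty schedule")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    n = design.n_individuals
    rows: list[list] = []
    for nominal, measured in design.temperatures:
        events_here = [e for e in EVENTS if (nominal, e) in design.schedule]
        if not events_here:
            continue
        offsets = (rng.uniform(-design.temperature_jitter_c, design.temperature_jitter_c,
                               size=design.n_replicates)
                   if design.temperature_jitter_c > 0 else np.zeros(design.n_replicates))
        chamber_temps = measured + offsets
        base_by_rep = [truth.expected_event_times_h(ct, condition=nominal)
                       for ct in chamber_temps]
        window_end = max(t for e in events_here for t in design.schedule[(nominal, e)])
        p_die = truth.mortality.get(nominal, 0.0)
        for event in events_here:
            for sample_time in design.schedule[(nominal, event)]:
                for rep in range(design.n_replicates):
                    base = base_by_rep[rep]
                    factors = _truncnorm_factors(n, truth.cv_transition, rng)
                    if base is None:
                        stage_idx = np.zeros(n, dtype=int)
                        t_adult = np.full(n, window_end)
                    else:
                        times = np.outer(factors, [base[e] for e in EVENTS])
                        stage_idx = (times <= sample_time).sum(axis=1)
                        t_adult = times[:, -1]
                    dies = rng.random(n) < p_die
                    death_time = rng.uniform(0.0, np.maximum(t_adult, 1e-9))
                    dead_now = dies & (death_time <= sample_time)
                    counts = np.bincount(stage_idx[~dead_now], minlength=len(STAGES))
                    rows.append([f"R{rep + 1}", nominal, round(chamber_temps[rep], 3),
                                 sample_time, *counts.tolist(), int(dead_now.sum())])
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    return ObservationSet(frame, n_individuals=n)
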