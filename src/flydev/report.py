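"""Summary tables, the end-to-end pipeline, and the reproduction report.

Produces the study-style outputs: percent of total development spent in each
stage per temperature (with a mean row), a two-study percent-in-stage
comparison, a regression-results table, and the full simulate -> fit -> model
pipeline with a decision log and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .degree_days import (
    DegreeDayConfig,
    DegreeDayError,
    DegreeDayModel,
    decimal_mean,
    fit_degree_day_model,
    round1,
    summarize_add,
)
from .rates import duration_map, durations_from_t50
from .reference import DURATION_STAGES, EVENTS
from .simulate import (
    DesignConfig,
    ObservationSet,
    SimulationTruth,
    schedule_from_truth,
    simulate_cohort,
)
from .transitions import flag_outliers, transition_points

__version__ = "0.1.0"
logger = logging.getLogger("flydev")


class ReportError(ValueError):
    pass


# -- percent time in stage -------------------------------------------------------

@dataclass
class PercentTimeTable:
    """Stage durations as percent of total (egg-to-adult) development time.

    ``rows`` maps temperature to {stage: percent at 1 decimal}; the mean row is
    the unweighted decimal mean of the temperature rows per stage.
    """

    rows: dict[float, dict[str, float]]
    stages: tuple[str, ...] = DURATION_STAGES

    def __post_init__(self) -> None:
        for t, row in self.rows.items():
            total = float(sum(Decimal(repr(row[s])) for s in self.stages if s in row))
            if set(self.stages) <= set(row) and abs(total - 100.0) > 0.3:
                raise ReportError(f"percent row at {t} degC sums to {total}, not 100 +/- 0.3")

    @property
    def mean_row(self) -> dict[str, float]:
        out = {}
        for s in self.stages:
            vals = [row[s] for row in self.rows.values() if s in row]
            if vals:
                out[s] = round1(decimal_mean(vals))
        return out

    def to_frame(self) -> pd.DataFrame:
        recs = [{"temperature": t, **row} for t, row in sorted(self.rows.items())]
        recs.append({"temperature": "mean", **self.mean_row})
        return pd.DataFrame(recs)


def percent_time_in_stage(durations: pd.DataFrame) -> tuple[PercentTimeTable, list[str]]:
    """Percent of the egg-to-adult duration spent in each stage, per temperature.

    Temperatures without a total (E-A) duration are omitted with a log entry.
    """
    rows, log = {}, []
    for temp, sub in durations.groupby("temperature"):
        d = dict(zip(sub["label"], sub["duration_days"]))
        if "E-A" not in d:
            log.append(f"{temp} degC omitted: no egg-to-adult total")
            continue
        total = d["E-A"]
        rows[float(temp)] = {s: round1(d[s] / total * 100.0) for s in DURATION_STAGES if s in d}
    return PercentTimeTable(rows=rows), log


@dataclass
class StudyComparison:
    labels: tuple[str, str]
    row_a: dict[str, float]
    row_b: dict[str, float]
    difference: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": self.labels[0], **self.row_a},
            {"source": self.labels[1], **self.row_b},
            {"source": "difference", **self.difference},
        ])


def compare_studies(row_a: dict[str, float], row_b: dict[str, float],
                    labels: tuple[str, str] = ("this study", "reference")) -> StudyComparison:
    """Percent-in-stage difference row (a minus b, percentage points, exact decimals)."""
    if set(row_a) != set(row_b):
        raise ReportError(f"stage labels differ: {sorted(row_a)} vs {sorted(row_b)}")
    diff = {s: float(Decimal(repr(row_a[s])) - Decimal(repr(row_b[s]))) for s in row_a}
    return StudyComparison(labels=labels, row_a=dict(row_a), row_b=dict(row_b), difference=diff)


# -- regression-results table ------------------------------------------------------

def regression_table(models: dict[str, DegreeDayModel],
                     columns: tuple[str, ...] = reference.REGRESSION_COLUMNS) -> pd.DataFrame:
    """Published-layout table: per-temperature ADD cells plus summary rows.

    One column per event/stage; blank cells where a temperature was excluded or
    had no data.
    """
    temps = sorted({t for m in models.values() for t in m.per_temp_add})
    recs = []
    for t in temps:
        rec = {"row": f"{t:g}"}
        for col in columns:
            m = models.get(col)
            rec[col] = round1(m.per_temp_add[t]) if m and t in m.per_temp_add else None
        recs.append(rec)
    summary_rows = {
        "dev_min_x_intercept": lambda m: round(m.t_min, 1),
        "regression_add_1_over_slope": lambda m: round1(m.add),
        "r2": lambda m: round(m.regression.r2, 2),
        "n": lambda m: m.regression.n_included,
        "range_min": lambda m: m.valid_range[0],
        "range_max": lambda m: m.valid_range[1],
        "calc_add_mean": lambda m: summarize_add(m)["calc_mean"],
        "se": lambda m: round(m.calc_se, 2),
        "pct_deviation": lambda m: summarize_add(m)["pct_deviation"],
    }
    for name, fn in summary_rows.items():
        rec = {"row": name}
        for col in columns:
            m = models.get(col)
            rec[col] = fn(m) if m else None
        recs.append(rec)
    return pd.DataFrame(recs)


# -- pipeline ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    outdir: str = "flydev-out"
    observations_csv: str | None = None  # fit an existing table instead of simulating
    seed: int = 0
    runs_alpha: float = 0.10
    slope_alpha: float = 0.05
    prune_policy: str = "max_std_resid"
    use_nominal_temps: bool = False
    outlier_k: float = 3.0
    horizon_days: float = 45.0
    labels: tuple[str, ...] = EVENTS + DURATION_STAGES

    def degree_day_config(self) -> DegreeDayConfig:
        return DegreeDayConfig(runs_alpha=self.runs_alpha, slope_alpha=self.slope_alpha,
                               policy=self.prune_policy)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    observations: ObservationSet
    points: pd.DataFrame
    durations: pd.DataFrame
    models: dict[str, DegreeDayModel]
    percent_table: PercentTimeTable
    decision_log: pd.DataFrame
    manifest: dict
    outdir: Path = field(default=None)


def run_pipeline(config: PipelineConfig, truth: SimulationTruth | None = None,
                 design: DesignConfig | None = None, write: bool = True) -> PipelineResult:
    """Execute transitions -> rates -> degree-day models -> report end to end.

    Either fits an existing observations CSV or simulates a cohort from
    ``truth`` (default stated truth, seeded from the config).  Writes all
    artifacts plus a decision log (one entry per excluded observation group,
    pruned temperature and validation round) and a manifest with the seed,
    config hash and package version.
    """
    log_entries: list[dict] = []
    if config.observations_csv:
        obs = ObservationSet.read_csv(config.observations_csv)
        truth = None
    else:
        truth = truth or SimulationTruth(seed=config.seed)
        design = design or schedule_from_truth(truth, horizon_days=config.horizon_days)
        obs = simulate_cohort(truth, design)
    obs, outlier_log = flag_outliers(obs, k=config.outlier_k)
    for rec in outlier_log.to_dict("records"):
        log_entries.append({"step": "outlier", **rec})
    points, skipped = transition_points(obs)
    for msg in skipped:
        log_entries.append({"step": "transition_skipped", "detail": msg})
    durations = durations_from_t50(points, use_nominal_temps=config.use_nominal_temps)
    models: dict[str, DegreeDayModel] = {}
    dd_config = config.degree_day_config()
    for label in config.labels:
        dmap = duration_map(durations, label)
        try:
            model = fit_degree_day_model(dmap, label=label, config=dd_config)
        except DegreeDayError as err:
            log_entries.append({"step": "degree_day_failed", "label": label, "detail": str(err)})
            continue
        for t, reason in model.exclusions:
            log_entries.append({"step": "pruned", "label": label,
                                "temperature": t, "detail": reason})
        models[label] = model
    percent_table, pct_log = percent_time_in_stage(durations)
    for msg in pct_log:
        log_entries.append({"step": "percent_table", "detail": msg})
    decision_log = pd.DataFrame(log_entries)
    manifest = {
        "package": "flydev",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "n_observation_rows": len(obs),
        "n_models": len(models),
    }
    result = PipelineResult(observations=obs, points=points, durations=durations,
                            models=models, percent_table=percent_table,
                            decision_log=decision_log, manifest=manifest)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        obs.to_csv(outdir / "observations.csv")
        points.to_csv(outdir / "transition_points.csv", index=False)
        durations.to_csv(outdir / "durations.csv", index=False)
        with open(outdir / "degree_day_models.json", "w") as fh:
            json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=2)
        regression_table(models, columns=tuple(models)).to_csv(
            outdir / "regression_table.csv", index=False)
        percent_table.to_frame().to_csv(outdir / "percent_time.csv", index=False)
        decision_log.to_csv(outdir / "decision_log.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        result.outdir = outdir
        logger.info("pipeline artifacts written to %s", outdir)
    return result


# -- reproduction of the published tables ------------------------------------------

def reproduce_reference() -> dict:
    """Recompute the published summary rows from the published cells.

    Returns, for every regression column, the recomputed calculated-ADD mean
    (with the printed value and delta), the percent-time mean row, the
    two-study difference row, and a duration round-trip refit of the first
    transition column against its printed regression ADD.
    """
    add_means = {}
    for col, cells in reference.REGRESSION_ADD_CELLS.items():
        s = summarize_add(cells.values(),
                          regression_add=reference.REGRESSION_SUMMARY[col]["regression_add"])
        printed = reference.REGRESSION_SUMMARY[col]["calc_add_mean"]
        add_means[col] = {"recomputed": s["calc_mean"], "printed": printed,
                          "delta": round1(s["calc_mean"] - printed),
                          "pct_deviation": s["pct_deviation"],
                          "printed_pct_deviation": reference.REGRESSION_SUMMARY[col]["pct_deviation"]}
    table = PercentTimeTable(rows=reference.PERCENT_TIME_ROWS)
    mean_row = {
        s: {"recomputed": v, "printed": reference.PERCENT_TIME_MEAN_ROW[s]}
        for s, v in table.mean_row.items()
    }
    comparison = compare_studies(reference.STUDY_PERCENT_ROW, reference.KAMAL_PERCENT_ROW,
                                 labels=("this study 27.5C", "Kamal 26.7C"))
    diff = {s: {"recomputed": round1(v), "printed": reference.PRINTED_DIFFERENCE_ROW[s]}
            for s, v in comparison.difference.items()}
    from .rates import ols_rate_fit as _fit
    durations = reference.printed_column_durations("E-L1")
    temps = sorted(durations)
    reg = _fit(temps, [1.0 / durations[t] for t in temps], label="E-L1")
    roundtrip = {"column": "E-L1", "refit_add": round1(reg.add),
                 "printed_add": reference.REGRESSION_SUMMARY["E-L1"]["regression_add"],
                 "refit_t_min": round(reg.x_intercept, 2),
                 "printed_t_min": reference.REGRESSION_SUMMARY["E-L1"]["dev_min"]}
    return {"calculated_add_mean": add_means, "percent_time_mean": mean_row,
            "study_difference": diff, "duration_roundtrip": roundtrip}
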