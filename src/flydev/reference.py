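"""Published reference values for *Lucilia sericata* development.

These constants transcribe the summary tables of a published constant-temperature
rearing study of the blow fly *L. sericata* (11 temperatures, 7.5-32.5 degC at
2.5 degC steps; 20 eggs per cup; 4 replicate chambers; 5 destructive sample
times per life stage).  They serve three purposes:

* the a-priori sampling schedule (:data:`SAMPLE_TIME_BOUNDARIES_H`) used by
  :func:`flydev.simulate.default_schedule`;
* printed per-temperature degree-day columns and summary rows used by the
  reproduction report and by consistency tests;
* the percent-time-in-stage rows and the Kamal (1958) comparison row.

Blank cells in the printed regression table (temperatures excluded as
non-linear, or without data) are represented by the absence of the key.
"""

from __future__ import annotations

EVENTS = ("E-L1", "E-L2", "E-L3f", "E-L3m", "E-P", "E-A")
"""Cumulative developmental events: oviposition to entry into each stage."""

STAGES = ("E", "L1", "L2", "L3f", "L3m", "P", "A")
"""Stage sequence: egg, instars 1-2, feeding/migratory third instar, puparium, adult."""

DURATION_STAGES = ("Egg", "L1", "L2", "L3f", "L3m", "P")
"""Stages with a finite duration (adult ends the record)."""

NOMINAL_TEMPERATURES_C = (7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0, 32.5)

#: Cumulative stage-boundary sample-time limits (hours after oviposition), one
#: column per nominal temperature, one row per life-stage interval in EVENTS
#: order.  Each interval is split into 5 equally spaced sample times.
SAMPLE_TIME_BOUNDARIES_H: dict[float, tuple[int, ...]] = {
    7.5: (35, 56, 79, 143, 335, 527),
    10.0: (35, 56, 79, 143, 335, 527),
    12.5: (35, 56, 79, 143, 335, 527),
    15.0: (17, 28, 39, 71, 167, 263),
    17.5: (12, 19, 26, 48, 112, 176),
    20.0: (9, 14, 20, 36, 84, 132),
    22.5: (7, 11, 16, 29, 67, 105),
    25.0: (6, 9, 13, 24, 56, 88),
    27.5: (5, 8, 11, 20, 48, 75),
    30.0: (4, 7, 10, 18, 42, 66),
    32.5: (4, 6, 9, 16, 37, 59),
}

#: Measured chamber temperatures appearing in the printed results (degC).
MEASURED_TEMPERATURES_C = (10.4, 12.7, 15.1, 17.5, 20.1, 22.5, 25.0, 27.5, 30.0, 32.5)

#: Printed per-temperature degree-day accumulations (degC day) for each
#: regression column; keys are measured temperatures, blanks omitted.
REGRESSION_ADD_CELLS: dict[str, dict[float, float]] = {
    "E-L1": {15.1: 5.3, 17.5: 9.4, 20.1: 8.7, 22.5: 9.2, 25.0: 8.8, 27.5: 7.4, 30.0: 8.3},
    "E-L2": {15.1: 24.4, 17.5: 24.0, 20.1: 22.4, 22.5: 22.4, 25.0: 22.7, 27.5: 21.5, 30.0: 19.7},
    "E-L3f": {15.1: 34.4, 17.5: 40.3, 20.1: 36.9, 22.5: 39.0, 25.0: 37.7, 27.5: 33.1, 30.0: 33.9},
    "E-L3m": {15.1: 82.4, 17.5: 86.7, 20.1: 89.3, 22.5: 81.1, 25.0: 75.3, 27.5: 97.2, 30.0: 76.8},
    "E-P": {17.5: 97.8, 20.1: 88.0, 22.5: 102.9, 25.0: 102.4, 27.5: 112.8, 30.0: 114.1},
    "E-A": {17.5: 218.2, 20.1: 217.3, 22.5: 210.3, 25.0: 221.2, 27.5: 242.1, 30.0: 239.7},
    "Egg": {15.1: 12.0, 17.5: 15.3, 20.1: 12.4, 22.5: 12.1, 25.0: 10.9, 27.5: 8.9, 30.0: 9.8},
    "L1": {15.1: 14.9, 17.5: 11.0, 20.1: 11.5, 22.5: 11.5, 25.0: 12.6, 27.5: 13.2, 30.0: 10.5},
    "L2": {15.1: 9.9, 17.5: 17.5, 20.1: 15.3, 22.5: 17.5, 25.0: 15.6, 27.5: 11.8, 30.0: 14.6},
    "L3f": {17.5: 45.8, 20.1: 54.5, 22.5: 42.2, 25.0: 37.5, 27.5: 67.7, 30.0: 44.0},
    "L3m": {17.5: 22.3, 22.5: 28.1, 25.0: 31.6, 27.5: 22.2, 30.0: 40.5},
    "P": {17.5: 129.8, 20.1: 136.2, 22.5: 112.7, 25.0: 123.4, 27.5: 133.6, 30.0: 129.3},
}

REGRESSION_COLUMNS = tuple(REGRESSION_ADD_CELLS)

#: Printed regression summary rows, per column (same order as REGRESSION_COLUMNS).
REGRESSION_SUMMARY: dict[str, dict[str, float]] = {
    col: dict(zip(("dev_min", "regression_add", "r2", "n", "range_min", "range_max",
                   "calc_add_mean", "se", "pct_deviation"), vals))
    for col, vals in {
        "E-L1": (12.6, 8.2, 0.96, 4, 15, 30, 8.2, 1.31, -0.8),
        "E-L2": (10.8, 21.3, 0.97, 4, 15, 30, 22.5, 1.46, 5.4),
        "E-L3f": (10.5, 35.2, 0.97, 4, 15, 30, 36.5, 2.56, 3.5),
        "E-L3m": (8.8, 82.5, 0.95, 4, 15, 30, 84.1, 7.05, 1.9),
        "E-P": (10.3, 107.5, 0.96, 4, 17.5, 30, 103.0, 8.86, -4.2),
        "E-A": (10.7, 230.2, 0.98, 4, 17.5, 30, 224.8, 11.86, -2.3),
        "Egg": (9.5, 10.3, 0.96, 3, 15, 30, 11.6, 1.92, 13.3),
        "L1": (10.9, 11.7, 0.96, 3, 15, 30, 12.2, 1.41, 4.1),
        "L2": (9.3, 14.3, 0.89, 4, 15, 30, 14.6, 2.61, 2.4),
        "L3f": (6.6, 47.2, 0.78, 4, 17.5, 30, 48.6, 9.95, 3.1),
        "L3m": (11.5, 29.8, 0.80, 4, 17.5, 30, 28.9, 6.80, -3.0),
        "P": (10.4, 127.9, 0.97, 4, 17.5, 30, 127.5, 7.70, -0.3),
    }.items()
}

#: Printed percent-of-total-development time per stage, by measured temperature.
PERCENT_TIME_ROWS: dict[float, dict[str, float]] = {
    10.4: {"Egg": 4.7, "L1": 5.4, "L2": 1.4, "L3f": 5.5, "L3m": 37.3, "P": 45.7},
    12.7: {"Egg": 1.4, "L1": 3.3, "L2": 3.3, "L3f": 6.9, "L3m": 51.9, "P": 33.2},
    15.1: {"Egg": 3.0, "L1": 4.6, "L2": 2.8, "L3f": 7.9, "L3m": 52.2, "P": 29.5},
    17.5: {"Egg": 6.2, "L1": 4.2, "L2": 7.5, "L3f": 13.2, "L3m": 11.7, "P": 57.1},
    20.1: {"Egg": 5.1, "L1": 5.6, "L2": 6.0, "L3f": 18.2, "L3m": 4.3, "P": 60.8},
    22.5: {"Egg": 5.0, "L1": 5.9, "L2": 7.4, "L3f": 14.9, "L3m": 14.5, "P": 52.3},
    25.0: {"Egg": 4.5, "L1": 5.2, "L2": 7.1, "L3f": 13.2, "L3m": 15.2, "P": 54.7},
    27.5: {"Egg": 5.2, "L1": 3.7, "L2": 5.4, "L3f": 22.0, "L3m": 9.7, "P": 54.1},
    30.0: {"Egg": 3.9, "L1": 4.1, "L2": 6.0, "L3f": 14.7, "L3m": 18.1, "P": 53.2},
    32.5: {"Egg": 3.9, "L1": 3.0, "L2": 3.4, "L3f": 16.7, "L3m": 24.1, "P": 48.9},
}

#: Printed mean row of the percent-time table.
PERCENT_TIME_MEAN_ROW = {"Egg": 4.3, "L1": 4.5, "L2": 5.0, "L3f": 13.3, "L3m": 23.9, "P": 49.0}

#: Percent-in-stage comparison rows: this study at 27.5 degC vs Kamal (1958) at 26.7 degC.
STUDY_PERCENT_ROW = {"Egg": 5.2, "L1": 3.7, "L2": 5.4, "L3f": 22.0, "L3m": 9.7, "P": 54.1}
KAMAL_PERCENT_ROW = {"Egg": 5.2, "L1": 5.7, "L2": 3.4, "L3f": 11.5, "L3m": 25.9, "P": 48.0}

#: Printed difference row (this study minus Kamal, percentage points).  The L1,
#: L2 and P cells do not equal exact subtraction of the printed rows (they carry
#: the source's unrounded intermediates) and are retained verbatim.
PRINTED_DIFFERENCE_ROW = {"Egg": 0.0, "L1": -2.1, "L2": 1.9, "L3f": 10.5, "L3m": -16.2, "P": 5.8}


def printed_column_durations(column: str) -> dict[float, float]:
    """Reconstruct stage/event durations (days) from a printed regression column.

    Inverts the degree-day identity ``ADD = duration * (T - t_min)`` using the
    column's printed per-temperature ADD cells and printed x-intercept, giving a
    duration table consistent with the printed regression for round-trip checks.
    """
    cells = REGRESSION_ADD_CELLS[column]
    t_min = REGRESSION_SUMMARY[column]["dev_min"]
    return {t: add / (t - t_min) for t, add in cells.items()}
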