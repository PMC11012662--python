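"""Published summary tables of the reference rater study.

The digital back-photo asymmetry tool was validated in a multicenter
reliability study: 15 back-view photographs of adolescent idiopathic
scoliosis patients, each measured twice (three weeks apart) by 12
trained observers (6 research coordinators, 6 spine surgeons).  The
study reports only summary tables — descriptives of the round-1
measurements, per-measure inter-observer ICCs with 95% CIs and F
values, the 12 x 10 matrix of per-observer test-retest ICCs, and its
per-measure aggregation.  Those printed tables are reproduced here as
reference datasets: they are the inputs for checking the package's
arithmetic conventions (SEM formula, WAD sign, total-mean
aggregations) against the study's printed numbers.

Raw per-rating data were not published, so per-measure ICCs themselves
cannot be recomputed from these tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_descriptives",
    "reference_interobserver",
    "reference_intraobserver_matrix",
    "reference_intraobserver_summary",
]

# Round-1 descriptives per measure: n, min, max, mean, sd, median, iqr, sem.
# Angles in degrees; SA/WA/PA/TA dimensionless left/right area parameters.
_DESCRIPTIVES = [
    ("SHA", 15, -7.5, 2.43, -2.5, 2.6, -2.8, 3.83, 0.30),
    ("AHA", 15, -7.8, -0.85, -4.4, 2.2, -3.9, 3.0, 1.17),
    ("WHA", 15, -3.1, 6.58, 2.0, 3.0, 1.7, 3.7, 0.57),
    ("LWA", 15, 128.4, 157.18, 144.8, 9.5, 145.9, 17.4, 0.95),
    ("RWA", 15, 132.3, 163.58, 147.9, 8.1, 146.7, 12.1, 1.3),
    ("WAD", 15, -35.2, 24.88, -3.1, 14.9, -6.4, 21.8, 1.15),
    ("SA", 15, 0.80, 1.14, 0.94, 0.09, 0.93, 0.1, 0.02),
    ("WA", 15, 0.52, 0.93, 0.71, 0.12, 0.69, 0.2, 0.06),
    ("PA", 15, 0.45, 1.69, 0.83, 0.3, 0.78, 0.3, 0.12),
    ("TA", 15, 0.64, 1.06, 0.81, 0.12, 0.81, 0.2, 0.05),
]

# Inter-observer (round 1, 12 raters): ICC, 95% CI bounds, F value.
_INTEROBSERVER = [
    ("SHA", 0.986, 0.972, 0.994, 81.5),
    ("AHA", 0.973, 0.942, 0.990, 62.9),
    ("WHA", 0.963, 0.929, 0.986, 28.0),
    ("LWA", 0.990, 0.979, 0.996, 124.7),
    ("RWA", 0.972, 0.946, 0.989, 37.0),
    ("WAD", 0.994, 0.988, 0.998, 161.2),
    ("SA", 0.976, 0.951, 0.991, 56.8),
    ("WA", 0.987, 0.975, 0.995, 89.7),
    ("PA", 0.986, 0.973, 0.995, 77.3),
    ("TA", 0.988, 0.977, 0.995, 100.0),
]

# Per-observer test-retest (round 1 vs round 2) ICCs, one row per observer.
_INTRAOBSERVER_MATRIX = {
    "Obsv1": (0.946, 0.985, 0.955, 0.977, 0.99, 0.988, 0.927, 0.977, 0.98, 0.969),
    "Obsv2": (0.953, 0.978, 0.926, 0.918, 0.934, 0.997, 0.962, 0.972, 0.994, 0.988),
    "Obsv3": (0.752, 0.791, 0.734, 0.946, 0.887, 0.968, 0.785, 0.899, 0.931, 0.86),
    "Obsv4": (0.992, 0.99, 0.637, 0.99, 0.988, 0.997, 0.966, 0.979, 0.989, 0.98),
    "Obsv5": (0.908, 0.954, 0.943, 0.98, 0.815, 0.947, 0.966, 0.957, 0.961, 0.959),
    "Obsv6": (0.96, 0.975, 0.926, 0.963, 0.979, 0.98, 0.934, 0.98, 0.865, 0.986),
    "Obsv7": (0.931, 0.973, 0.881, 0.973, 0.974, 0.994, 0.901, 0.957, 0.984, 0.971),
    "Obsv8": (0.962, 0.974, 0.985, 0.983, 0.98, 0.99, 0.879, 0.945, 0.989, 0.952),
    "Obsv9": (0.962, 0.985, 0.987, 0.986, 0.941, 0.994, 0.937, 0.978, 0.991, 0.976),
    "Obsv10": (0.993, 0.989, 0.982, 0.993, 0.997, 0.996, 0.941, 0.975, 0.994, 0.975),
    "Obsv11": (0.921, 0.818, 0.655, 0.923, 0.609, 0.931, 0.894, 0.92, 0.946, 0.951),
    "Obsv12": (0.913, 0.966, 0.535, 0.778, 0.796, 0.916, 0.919, 0.974, 0.969, 0.973),
}

# Printed per-measure aggregation of the matrix above: mean, sd, min, max.
_INTRAOBSERVER_SUMMARY = [
    ("SHA", 0.93, 0.06, 0.752, 0.993),
    ("AHA", 0.95, 0.06, 0.791, 0.990),
    ("WHA", 0.84, 0.16, 0.535, 0.987),
    ("LWA", 0.95, 0.06, 0.778, 0.993),
    ("RWA", 0.91, 0.12, 0.609, 0.997),
    ("WAD", 0.97, 0.03, 0.916, 0.997),
    ("SA", 0.92, 0.05, 0.785, 0.966),
    ("WA", 0.96, 0.03, 0.899, 0.980),
    ("PA", 0.97, 0.04, 0.865, 0.994),
    ("TA", 0.96, 0.03, 0.860, 0.988),
]

_MEASURES = ("SHA", "AHA", "WHA", "LWA", "RWA", "WAD", "SA", "WA", "PA", "TA")


def reference_descriptives() -> pd.DataFrame:
    """Round-1 descriptives of the reference study, one row per measure."""
    return pd.DataFrame(
        _DESCRIPTIVES,
        columns=["measure", "n", "min", "max", "mean", "sd", "median", "iqr", "sem"],
    )


def reference_interobserver() -> pd.DataFrame:
    """Reference inter-observer ICC table (ICC, 95% CI, F), one row per measure."""
    return pd.DataFrame(
        _INTEROBSERVER, columns=["measure", "icc", "ci_low", "ci_high", "f_value"]
    )


def reference_intraobserver_matrix() -> pd.DataFrame:
    """Reference 12-observer x 10-measure matrix of test-retest ICCs."""
    df = pd.DataFrame.from_dict(_INTRAOBSERVER_MATRIX, orient="index", columns=_MEASURES)
    df.index.name = "rater_id"
    return df


def reference_intraobserver_summary() -> pd.DataFrame:
    """Reference per-measure aggregation (mean, sd, min, max) of the matrix."""
    return pd.DataFrame(
        _INTRAOBSERVER_SUMMARY, columns=["measure", "mean", "sd", "min", "max"]
    ).set_index("measure")
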