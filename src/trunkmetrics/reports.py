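"""CSV/JSON report writers.

Rounding happens only here, at the configured printed precision:
angles 2 decimals, ICCs 3, SEM and aggregates 2, ratios 3.  The JSON
bundle keeps full precision alongside the chosen ICC form so a report
is always traceable to its conventions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .geometry import MEASURES, AsymmetryProfile, HemitrunkAreas
from .reliability import InterObserverResult, IntraObserverResult, TTestResult

__all__ = [
    "profile_row",
    "write_profiles_csv",
    "write_reliability_reports",
]

_ANGLE_MEASURES = ("SHA", "AHA", "WHA", "LWA", "RWA", "WAD")

_AREA_COLUMNS = (
    "shoulder_left_px2", "shoulder_right_px2",
    "waist_left_px2", "waist_right_px2",
    "pelvic_left_px2", "pelvic_right_px2",
)


def profile_row(photo_id: str, profile: AsymmetryProfile,
                areas: HemitrunkAreas) -> dict[str, float | str]:
    """One report row: the 10 parameters plus raw areas and plumbline."""
    vals = profile.as_dict()
    row: dict[str, float | str] = {"photo_id": photo_id}
    for m in MEASURES:
        row[m] = round(vals[m], 2) if m in _ANGLE_MEASURES else round(vals[m], 3)
    for col in _AREA_COLUMNS:
        row[col] = round(getattr(areas, col), 1)
    row["plumbline_x"] = round(areas.plumbline_x, 2)
    return row


def write_profiles_csv(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Profile table with a leading comment line documenting units."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(
            "# SHA,AHA,WHA,LWA,RWA,WAD in degrees (clockwise-positive from the back); "
            "SA,WA,PA,TA dimensionless left/right area ratios; "
            "*_px2 raw hemitrunk region areas in square pixels; "
            "plumbline_x in pixels\n"
        )
        pd.DataFrame(rows).to_csv(fh, index=False)


def _round_icc_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in ("icc", "ci_low", "ci_high", "p_value"):
            out[col] = out[col].round(3)
        elif col in ("f_value",):
            out[col] = out[col].round(1)
    return out


def write_reliability_reports(
    outdir: str | Path,
    descriptives: pd.DataFrame,
    inter: InterObserverResult,
    intra: IntraObserverResult | None = None,
    group_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the full reliability report set; returns the paths written.

    Files: descriptives.csv (with SEM), interobserver_icc.csv,
    intraobserver_icc_matrix.csv + intraobserver_summary.csv (when a
    second occasion exists), group_comparison.csv (when group labels
    were given), and report.json with full-precision values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    desc = descriptives.copy()
    for col in ("min", "max", "mean", "sd", "median", "iqr", "sem"):
        desc[col] = desc[col].round(2)
    p = outdir / "descriptives.csv"
    desc.to_csv(p, index=False)
    written["descriptives"] = p

    inter_frame = inter.to_frame()
    p = outdir / "interobserver_icc.csv"
    with open(p, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# ICC form: {inter.form.value}; occasion: {inter.occasion}\n")
        _round_icc_frame(inter_frame).to_csv(fh, index=False)
    written["interobserver"] = p

    bundle: dict[str, object] = {
        "icc_form_interobserver": inter.form.value,
        "interobserver": inter_frame.to_dict(orient="records"),
        "descriptives": descriptives.to_dict(orient="records"),
    }

    if intra is not None:
        p = outdir / "intraobserver_icc_matrix.csv"
        with open(p, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# ICC form: {intra.form.value}; per rater, round 1 vs round 2\n")
            intra.matrix.round(3).to_csv(fh)
        written["intraobserver_matrix"] = p

        summary = intra.aggregate.round(2)
        summary.loc["Total Mean"] = intra.total_mean.round(3)
        p = outdir / "intraobserver_summary.csv"
        summary.to_csv(p)
        written["intraobserver_summary"] = p

        bundle["icc_form_intraobserver"] = intra.form.value
        bundle["intraobserver_matrix"] = intra.matrix.to_dict(orient="index")
        bundle["intraobserver_aggregate"] = intra.aggregate.to_dict(orient="index")
        bundle["intraobserver_total_mean"] = intra.total_mean.to_dict()

    if group_table is not None:
        p = outdir / "group_comparison.csv"
        gt = group_table.copy()
        for col in ("mean_a", "sd_a", "mean_b", "sd_b"):
            if col in gt.columns:
                gt[col] = gt[col].round(2)
        for col in ("t", "p"):
            if col in gt.columns:
                gt[col] = gt[col].round(3)
        gt.to_csv(p, index=False)
        written["group_comparison"] = p
        bundle["group_comparison"] = group_table.to_dict(orient="records")

    p = outdir / "report.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=1, default=float)
    written["bundle"] = p
    return written
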