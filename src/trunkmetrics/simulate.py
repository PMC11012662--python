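"""Synthetic back-view rater studies with known variance components.

The simulator re-creates, in silico, the design of a photographic
reliability study: a cohort of subjects with subject-level trunk
deformity, each "photographed" once, then landmark-tagged by every
rater on every occasion with rater-level tagging jitter.  Defaults
match the reference design: 15 subjects, 12 raters, 2 occasions.

Generation model
----------------
* A bilaterally symmetric landmark template (all angles 0, all area
  ratios 1) sized to the photograph.
* Per subject, drawn once: rigid tilts of the shoulder, axilla and
  waist pairs about their midpoints (so the induced SHA/AHA/WHA equal
  the drawn tilts exactly), a horizontal shift of C7 (trunk shift,
  moving the plumbline and hence the area ratios), and left/right
  waist-depth perturbations that vary LWA/RWA independently.
* Per rater x occasion x landmark: isotropic Gaussian pixel jitter,
  emulating mouse-click imprecision; optionally a per-rater systematic
  vertical offset of the RIGHT-side landmarks (a rater who habitually
  tags the patient's right side too low), which biases every tilt by a
  rater-specific constant and so makes agreement and consistency ICCs
  diverge.  A whole-image vertical offset would be invisible: all ten
  parameters are translation invariant.

Each (rater, occasion, subject) stream is seeded via
``numpy.random.SeedSequence(seed, spawn_key=...)`` so results are
byte-reproducible and adding raters never perturbs existing draws.

For calibration, the first-order error a pixel jitter of sd j induces
on a pair-tilt angle with endpoint separation s is
``sqrt(2) * j / s`` radians, exposed as :func:`expected_angle_error_sd`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, TrunkMetricsError
from .geometry import MEASURES, measure_profile
from .landmarks import LANDMARK_NAMES, BackLandmarks, PixelPoint
from .reliability import RatingsTable

__all__ = [
    "CohortSimConfig",
    "SubjectDeformity",
    "SimulatedStudy",
    "make_template",
    "apply_deformity",
    "simulate_ratings",
    "expected_angle_error_sd",
    "pair_span",
]

#: Template landmark positions as (x, y) fractions of (width, height).
_TEMPLATE_FRACTIONS: dict[str, tuple[float, float]] = {
    "shoulder_left": (0.32, 0.17),
    "shoulder_right": (0.68, 0.17),
    "axilla_left": (0.33, 0.25),
    "axilla_right": (0.67, 0.25),
    "waist_left": (0.42, 0.41),
    "waist_right": (0.58, 0.41),
    "iliac_left": (0.40, 0.51),
    "iliac_right": (0.60, 0.51),
    "c7": (0.50, 0.14),
}


def make_template(height: int = 1500, width: int = 1000,
                  photo_id: str = "template") -> BackLandmarks:
    """A perfectly symmetric landmark set for a height x width photograph.

    Symmetric about the vertical through C7: all six angles measure 0
    (with LWA == RWA) and all four area ratios measure exactly 1.
    """
    if height <= 0 or width <= 0:
        raise TrunkMetricsError("template dimensions must be positive")
    pts = {
        name: PixelPoint(fx * width, fy * height)
        for name, (fx, fy) in _TEMPLATE_FRACTIONS.items()
    }
    rec = BackLandmarks(photo_id=photo_id, image_width=width, image_height=height, **pts)
    rec.validate()
    return rec


@dataclass(frozen=True)
class SubjectDeformity:
    """Subject-level deformity parameters, all zero for a symmetric trunk.

    Tilts are degrees, clockwise-positive viewed from the back; the
    trunk shift moves C7 horizontally (positive toward the patient's
    right, i.e. larger image x); waist depths push the minimal-waist
    points toward the midline (deeper indentation, smaller waistline
    angle on that side).
    """

    shoulder_tilt_deg: float = 0.0
    axilla_tilt_deg: float = 0.0
    waist_tilt_deg: float = 0.0
    trunk_shift_px: float = 0.0
    waist_depth_left_px: float = 0.0
    waist_depth_right_px: float = 0.0


def _rotate_pair(left: PixelPoint, right: PixelPoint, tilt_deg: float
                 ) -> tuple[PixelPoint, PixelPoint]:
    """Rigid rotation of a pair about its midpoint by the given tilt.

    In the y-down image frame a clockwise-positive tilt is the rotation
    matrix [[c, -s], [s, c]]: starting from a horizontal pair, the
    right endpoint moves down (larger y) for a positive tilt.
    """
    mx = (left.x + right.x) / 2.0
    my = (left.y + right.y) / 2.0
    th = math.radians(tilt_deg)
    c, s = math.cos(th), math.sin(th)

    def rot(p: PixelPoint) -> PixelPoint:
        dx, dy = p.x - mx, p.y - my
        return PixelPoint(mx + c * dx - s * dy, my + s * dx + c * dy)

    return rot(left), rot(right)


def apply_deformity(template: BackLandmarks, params: SubjectDeformity) -> BackLandmarks:
    """Deform a template by subject-level parameters; validates the result."""
    pts = template.points()
    for level, tilt in (
        ("shoulder", params.shoulder_tilt_deg),
        ("axilla", params.axilla_tilt_deg),
        ("waist", params.waist_tilt_deg),
    ):
        pts[f"{level}_left"], pts[f"{level}_right"] = _rotate_pair(
            pts[f"{level}_left"], pts[f"{level}_right"], tilt
        )
    wl, wr = pts["waist_left"], pts["waist_right"]
    pts["waist_left"] = PixelPoint(wl.x + params.waist_depth_left_px, wl.y)
    pts["waist_right"] = PixelPoint(wr.x - params.waist_depth_right_px, wr.y)
    pts["c7"] = PixelPoint(pts["c7"].x + params.trunk_shift_px, pts["c7"].y)

    rec = replace(template, **pts)
    rec.validate()
    cx = rec.c7.x
    for level in ("shoulder", "axilla", "waist", "iliac"):
        if not (rec.point(f"{level}_left").x < cx < rec.point(f"{level}_right").x):
            raise DegenerateGeometryError(
                f"deformity pushes the C7 plumbline outside the trunk at {level} level"
            )
    return rec


@dataclass
class CohortSimConfig:
    """Design and variance components of a synthetic rater study.

    Defaults reproduce the reference design (15 photographs, 12
    observers, 2 rounds) with deformity and jitter magnitudes chosen so
    simulated cohorts land in a clinically plausible regime: pair tilts
    with a 3-degree SD, trunk shifts and waist-depth asymmetries of a
    few pixels on a 1000x1500 px photograph, and 2 px of tagging jitter
    (about half a degree of angle error on a 360 px shoulder span).
    """

    n_subjects: int = 15
    n_raters: int = 12
    n_occasions: int = 2
    template_height: int = 1500
    template_width: int = 1000
    subject_tilt_sd_deg: float = 3.0
    subject_shift_sd_px: float = 10.0
    waist_depth_sd_px: float = 8.0
    landmark_jitter_sd_px: float = 2.0
    rater_bias_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2:
            raise TrunkMetricsError("need at least 2 subjects and 2 raters")
        if self.n_occasions < 1:
            raise TrunkMetricsError("need at least 1 occasion")
        for name in ("subject_tilt_sd_deg", "subject_shift_sd_px", "waist_depth_sd_px",
                     "landmark_jitter_sd_px", "rater_bias_sd_px"):
            if getattr(self, name) < 0:
                raise TrunkMetricsError(f"{name} must be >= 0")


@dataclass
class SimulatedStudy:
    """Output bundle of one simulated rater study."""

    config: CohortSimConfig
    truth: pd.DataFrame                    # one row per subject: params + true measures
    ratings: RatingsTable                  # long-format rated measures
    landmarks: dict[tuple[str, int], list[BackLandmarks]]  # (rater_id, occasion) -> records


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _rater_ids(k: int) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(k)]


def simulate_ratings(config: CohortSimConfig) -> SimulatedStudy:
    """Run the full synthetic study: subjects, then rater x occasion tagging.

    Deterministic for a fixed seed.  Per-entity substreams mean that
    enlarging the design (more raters or occasions) leaves all existing
    draws unchanged.
    """
    template = make_template(config.template_height, config.template_width)
    subjects = _subject_ids(config.n_subjects)
    raters = _rater_ids(config.n_raters)

    truth_rows = []
    true_lms: list[BackLandmarks] = []
    for s_idx, sid in enumerate(subjects):
        rng = _rng(config.seed, 0, s_idx)
        params = SubjectDeformity(
            shoulder_tilt_deg=rng.normal(0.0, config.subject_tilt_sd_deg),
            axilla_tilt_deg=rng.normal(0.0, config.subject_tilt_sd_deg),
            waist_tilt_deg=rng.normal(0.0, config.subject_tilt_sd_deg),
            trunk_shift_px=rng.normal(0.0, config.subject_shift_sd_px),
            waist_depth_left_px=rng.normal(0.0, config.waist_depth_sd_px),
            waist_depth_right_px=rng.normal(0.0, config.waist_depth_sd_px),
        )
        lms = apply_deformity(replace(template, photo_id=sid), params)
        true_lms.append(lms)
        profile = measure_profile(lms).as_dict()
        truth_rows.append(
            {
                "subject_id": sid,
                "shoulder_tilt_deg": params.shoulder_tilt_deg,
                "axilla_tilt_deg": params.axilla_tilt_deg,
                "waist_tilt_deg": params.waist_tilt_deg,
                "trunk_shift_px": params.trunk_shift_px,
                "waist_depth_left_px": params.waist_depth_left_px,
                "waist_depth_right_px": params.waist_depth_right_px,
                **{f"true_{m}": profile[m] for m in MEASURES},
            }
        )

    rating_rows = []
    landmark_files: dict[tuple[str, int], list[BackLandmarks]] = {}
    for r_idx, rid in enumerate(raters):
        bias_rng = _rng(config.seed, 2, r_idx)
        bias_y = bias_rng.normal(0.0, config.rater_bias_sd_px) if config.rater_bias_sd_px > 0 else 0.0
        for occ in range(1, config.n_occasions + 1):
            tagged_records = []
            for s_idx, (sid, lms) in enumerate(zip(subjects, true_lms)):
                rng = _rng(config.seed, 1, r_idx, occ, s_idx)
                jitter = rng.normal(0.0, config.landmark_jitter_sd_px, size=(9, 2))
                pts = {
                    name: PixelPoint(
                        lms.point(name).x + jitter[i, 0],
                        lms.point(name).y + jitter[i, 1]
                        + (bias_y if name.endswith("_right") else 0.0),
                    )
                    for i, name in enumerate(LANDMARK_NAMES)
                }
                tagged = replace(lms, photo_id=sid, **pts)
                tagged.validate()
                tagged_records.append(tagged)
                profile = measure_profile(tagged).as_dict()
                rating_rows.extend(
                    {
                        "subject_id": sid,
                        "rater_id": rid,
                        "occasion": occ,
                        "measure": m,
                        "value": profile[m],
                    }
                    for m in MEASURES
                )
            landmark_files[(rid, occ)] = tagged_records

    return SimulatedStudy(
        config=config,
        truth=pd.DataFrame(truth_rows),
        ratings=RatingsTable(pd.DataFrame(rating_rows)),
        landmarks=landmark_files,
    )


def expected_angle_error_sd(jitter_sd: float, span: float) -> float:
    """First-order SD (degrees) of a pair-tilt angle under endpoint jitter.

    Both endpoints' vertical coordinates jittered independently with SD
    ``jitter_sd`` tilt the pair by roughly (y_r - y_l)/span radians,
    hence an angle SD of sqrt(2) * jitter_sd / span radians.
    """
    if span <= 0:
        raise TrunkMetricsError("span must be positive")
    return math.degrees(math.sqrt(2.0) * jitter_sd / span)


def pair_span(lms: BackLandmarks, level: str) -> float:
    """Euclidean separation of a left/right landmark pair (e.g. 'shoulder')."""
    left = lms.point(f"{level}_left")
    right = lms.point(f"{level}_right")
    return math.hypot(right.x - left.x, right.y - left.y)
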