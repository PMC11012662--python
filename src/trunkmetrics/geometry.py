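"""The ten trunk-asymmetry parameters computed from one landmark set.

Six angles and four hemitrunk area ratios:

* SHA, AHA, WHA — shoulder, axilla and waist height angles: the signed
  tilt of each left/right landmark pair against the image horizontal.
  Sign convention (viewer behind the patient): a clockwise tilt is
  positive.  In the y-down image frame that is simply
  ``atan2(right.y - left.y, right.x - left.x)`` — positive when the
  patient's right-side point sits lower in the image.
* LWA, RWA — left and right waistline angles: the interior angle at the
  minimal-waist point between the rays to the same-side axilla point
  and the same-side iliac-crest point.  A deeply indented waist gives a
  smaller (more acute) angle; a straight flank approaches 180 deg.
* WAD — waistline angle difference, LWA - RWA, sign retained.
* SA, WA, PA, TA — shoulder, waist, pelvic and total hemitrunk area
  ratios.  The vertical plumbline through C7 splits the trunk into left
  and right hemitrunks; horizontal levels at the shoulder, axilla,
  waist and iliac landmarks bound three quadrilaterals per side, whose
  shoelace areas (in square pixels) are reported as left/right ratios.
  A perfectly symmetric trunk gives ratios of exactly 1; pixel units
  cancel, so no calibration is needed.

Angles are degrees at full double precision; rounding belongs to the
report layer only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, SideOrderError, UndefinedRatioError
from .landmarks import BackLandmarks, PixelPoint

__all__ = [
    "MEASURES",
    "AsymmetryProfile",
    "HemitrunkAreas",
    "signed_tilt_deg",
    "height_angles",
    "waistline_angle",
    "waistline_angle_difference",
    "polygon_area_px2",
    "hemitrunk_areas",
    "area_ratios",
    "measure_profile",
]

#: Report order of the ten parameters.
MEASURES: tuple[str, ...] = (
    "SHA", "AHA", "WHA", "LWA", "RWA", "WAD", "SA", "WA", "PA", "TA",
)


@dataclass(frozen=True)
class AsymmetryProfile:
    """The ten asymmetry parameters of one photograph."""

    sha_deg: float
    aha_deg: float
    wha_deg: float
    lwa_deg: float
    rwa_deg: float
    wad_deg: float
    sa_ratio: float
    wa_ratio: float
    pa_ratio: float
    ta_ratio: float

    def __post_init__(self) -> None:
        # WAD is definitionally LWA - RWA; enforce on every profile.
        if self.wad_deg != self.lwa_deg - self.rwa_deg:
            raise ValueError("wad_deg must equal lwa_deg - rwa_deg exactly")

    def as_dict(self) -> dict[str, float]:
        """Values keyed by the canonical measure names (SHA ... TA)."""
        return {
            "SHA": self.sha_deg,
            "AHA": self.aha_deg,
            "WHA": self.wha_deg,
            "LWA": self.lwa_deg,
            "RWA": self.rwa_deg,
            "WAD": self.wad_deg,
            "SA": self.sa_ratio,
            "WA": self.wa_ratio,
            "PA": self.pa_ratio,
            "TA": self.ta_ratio,
        }


@dataclass(frozen=True)
class HemitrunkAreas:
    """Raw per-side region areas (square pixels) and the plumbline column."""

    plumbline_x: float
    shoulder_left_px2: float
    shoulder_right_px2: float
    waist_left_px2: float
    waist_right_px2: float
    pelvic_left_px2: float
    pelvic_right_px2: float

    def left_total(self) -> float:
        return self.shoulder_left_px2 + self.waist_left_px2 + self.pelvic_left_px2

    def right_total(self) -> float:
        return self.shoulder_right_px2 + self.waist_right_px2 + self.pelvic_right_px2


def signed_tilt_deg(left: PixelPoint, right: PixelPoint) -> float:
    """Signed tilt of a left/right pair, degrees, clockwise-positive.

    Clockwise as seen by the viewer standing behind the patient, i.e.
    positive when the patient's right-side point is lower in the image
    (larger y in the y-down frame).  Value lies in (-90, 90).
    """
    if right.x <= left.x:
        raise SideOrderError(
            f"right point x={right.x} must exceed left point x={left.x}"
        )
    return math.degrees(math.atan2(right.y - left.y, right.x - left.x))


def height_angles(lms: BackLandmarks) -> tuple[float, float, float]:
    """(SHA, AHA, WHA): signed tilts of the shoulder, axilla and waist pairs."""
    return (
        signed_tilt_deg(lms.shoulder_left, lms.shoulder_right),
        signed_tilt_deg(lms.axilla_left, lms.axilla_right),
        signed_tilt_deg(lms.waist_left, lms.waist_right),
    )


def waistline_angle(axilla: PixelPoint, waist: PixelPoint, iliac: PixelPoint) -> float:
    """Interior angle at the waist point between rays to axilla and iliac.

    Degrees in (0, 180]; 180 when the three points are collinear with
    the waist between the other two (a straight flank).
    """
    v1 = (axilla.x - waist.x, axilla.y - waist.y)
    v2 = (iliac.x - waist.x, iliac.y - waist.y)
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("waist point coincides with axilla or iliac point")
    cos_theta = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_theta))))


def waistline_angle_difference(lwa_deg: float, rwa_deg: float) -> float:
    """WAD = LWA - RWA, sign retained (negative when the right waist is straighter)."""
    return lwa_deg - rwa_deg


def polygon_area_px2(vertices: Sequence[PixelPoint | tuple[float, float]]) -> float:
    """Absolute shoelace area of a polygon, in square pixels.

    Orientation-independent; collinear vertices give 0.
    """
    if len(vertices) < 3:
        raise DegenerateGeometryError("polygon needs at least 3 vertices")
    xs = np.array([v.x if isinstance(v, PixelPoint) else v[0] for v in vertices])
    ys = np.array([v.y if isinstance(v, PixelPoint) else v[1] for v in vertices])
    return 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(np.roll(xs, -1), ys)))


def _side_regions(lms: BackLandmarks, side: str, px: float):
    """The three quadrilaterals of one hemitrunk, shoulder to pelvis.

    Each region is bounded laterally by the trunk edge between two
    adjacent same-side landmarks, medially by the C7 plumbline, and top
    and bottom by the horizontals through those landmarks; the plumbline
    corners take the same-side landmark heights.
    """
    sh = lms.point(f"shoulder_{side}")
    ax = lms.point(f"axilla_{side}")
    wa = lms.point(f"waist_{side}")
    il = lms.point(f"iliac_{side}")
    return (
        [(px, sh.y), (sh.x, sh.y), (ax.x, ax.y), (px, ax.y)],
        [(px, ax.y), (ax.x, ax.y), (wa.x, wa.y), (px, wa.y)],
        [(px, wa.y), (wa.x, wa.y), (il.x, il.y), (px, il.y)],
    )


def hemitrunk_areas(lms: BackLandmarks) -> HemitrunkAreas:
    """Split the trunk at the C7 plumbline and measure the six region areas.

    Raises :class:`DegenerateGeometryError` when the plumbline falls
    outside the trunk (C7 x not strictly between every left/right pair).
    A waist point not strictly between its axilla and iliac levels only
    warns — the areas remain well defined.
    """
    px = lms.c7.x
    for level in ("shoulder", "axilla", "waist", "iliac"):
        left = lms.point(f"{level}_left")
        right = lms.point(f"{level}_right")
        if not (left.x < px < right.x):
            raise DegenerateGeometryError(
                f"photo {lms.photo_id!r}: C7 plumbline x={px} outside the trunk at "
                f"{level} level ({left.x} .. {right.x})"
            )
    for side in ("left", "right"):
        ax = lms.point(f"axilla_{side}")
        wa = lms.point(f"waist_{side}")
        il = lms.point(f"iliac_{side}")
        if not (ax.y < wa.y < il.y):
            warnings.warn(
                f"photo {lms.photo_id!r}: {side} waist point not strictly between "
                "axilla and iliac levels; region polygons may degenerate",
                stacklevel=2,
            )

    left_regions = _side_regions(lms, "left", px)
    right_regions = _side_regions(lms, "right", px)
    la = [polygon_area_px2(r) for r in left_regions]
    ra = [polygon_area_px2(r) for r in right_regions]
    return HemitrunkAreas(
        plumbline_x=px,
        shoulder_left_px2=la[0],
        shoulder_right_px2=ra[0],
        waist_left_px2=la[1],
        waist_right_px2=ra[1],
        pelvic_left_px2=la[2],
        pelvic_right_px2=ra[2],
    )


def area_ratios(areas: HemitrunkAreas) -> tuple[float, float, float, float]:
    """(SA, WA, PA, TA) left/right area ratios; TA pools the three regions."""
    pairs = {
        "shoulder": (areas.shoulder_left_px2, areas.shoulder_right_px2),
        "waist": (areas.waist_left_px2, areas.waist_right_px2),
        "pelvic": (areas.pelvic_left_px2, areas.pelvic_right_px2),
    }
    for region, (_, right) in pairs.items():
        if right == 0.0:
            raise UndefinedRatioError(f"right {region} area is zero; ratio undefined")
    sa = pairs["shoulder"][0] / pairs["shoulder"][1]
    wa = pairs["waist"][0] / pairs["waist"][1]
    pa = pairs["pelvic"][0] / pairs["pelvic"][1]
    ta = areas.left_total() / areas.right_total()
    return sa, wa, pa, ta


def measure_profile(lms: BackLandmarks) -> AsymmetryProfile:
    """Compute all ten asymmetry parameters for one landmark set."""
    lms.validate()
    sha, aha, wha = height_angles(lms)
    lwa = waistline_angle(lms.axilla_left, lms.waist_left, lms.iliac_left)
    rwa = waistline_angle(lms.axilla_right, lms.waist_right, lms.iliac_right)
    sa, wa, pa, ta = area_ratios(hemitrunk_areas(lms))
    return AsymmetryProfile(
        sha_deg=sha,
        aha_deg=aha,
        wha_deg=wha,
        lwa_deg=lwa,
        rwa_deg=rwa,
        wad_deg=waistline_angle_difference(lwa, rwa),
        sa_ratio=sa,
        wa_ratio=wa,
        pa_ratio=pa,
        ta_ratio=ta,
    )
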