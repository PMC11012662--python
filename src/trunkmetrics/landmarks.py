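"""Data model, validation and file I/O for back-view landmark sets.

One record holds the nine anatomical points an evaluator tags on a
back-view clinical photograph: the two acromion endpoints (shoulders),
the two superior points of the posterior axillary folds (axillae), the
two minimal-waist points, the two most lateral iliac-crest points, and
the C7 spinous process.

Coordinates live in the raster image frame: origin at the top-left
corner, x increasing rightward, y increasing DOWNWARD, units raw pixels.
No calibration object is supported — every downstream parameter is an
angle or a left/right ratio, so pixel units cancel.

Side labels are patient-anatomical.  In a back view the patient's left
side appears on the image left, hence the hard invariant
``left.x < right.x`` for every left/right pair; violating it almost
always means the annotator swapped sides.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import LandmarkParseError, SchemaError, SideInversionError

__all__ = [
    "LANDMARK_NAMES",
    "SIDE_PAIRS",
    "PixelPoint",
    "BackLandmarks",
    "QualityReport",
    "read_landmarks",
    "write_landmarks",
    "check_quality",
]

#: Canonical landmark order used by every writer and reader.
LANDMARK_NAMES: tuple[str, ...] = (
    "shoulder_left",
    "shoulder_right",
    "axilla_left",
    "axilla_right",
    "waist_left",
    "waist_right",
    "iliac_left",
    "iliac_right",
    "c7",
)

#: The four left/right pairs, keyed by anatomical level.
SIDE_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("shoulder", "shoulder_left", "shoulder_right"),
    ("axilla", "axilla_left", "axilla_right"),
    ("waist", "waist_left", "waist_right"),
    ("iliac", "iliac_left", "iliac_right"),
)


@dataclass(frozen=True)
class PixelPoint:
    """A point in image pixel coordinates (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y)):
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise LandmarkParseError(f"coordinate {name}={v!r} is not finite")
        # normalise numpy scalars to builtin floats for clean I/O and equality
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))

    def translated(self, dx: float, dy: float) -> "PixelPoint":
        return PixelPoint(self.x + dx, self.y + dy)


@dataclass(frozen=True)
class BackLandmarks:
    """The nine tagged points of one back-view photograph."""

    photo_id: str
    shoulder_left: PixelPoint
    shoulder_right: PixelPoint
    axilla_left: PixelPoint
    axilla_right: PixelPoint
    waist_left: PixelPoint
    waist_right: PixelPoint
    iliac_left: PixelPoint
    iliac_right: PixelPoint
    c7: PixelPoint
    image_width: int | None = None
    image_height: int | None = None

    def point(self, name: str) -> PixelPoint:
        if name not in LANDMARK_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def points(self) -> dict[str, PixelPoint]:
        """All nine landmarks keyed by name, in canonical order."""
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def validate(self) -> None:
        """Raise :class:`SideInversionError` on any left/right inversion.

        Completeness and finite coordinates are already enforced at
        construction time; side order is the remaining hard rule.
        """
        bad = [
            level
            for level, left, right in SIDE_PAIRS
            if self.point(left).x >= self.point(right).x
        ]
        if bad:
            raise SideInversionError(
                f"photo {self.photo_id!r}: side inversion at {', '.join(bad)} "
                "(patient-left landmark must have smaller x than patient-right)"
            )

    # --- geometric helpers used by the simulator and property tests ---

    def translated(self, dx: float, dy: float) -> "BackLandmarks":
        return replace(
            self, **{n: self.point(n).translated(dx, dy) for n in LANDMARK_NAMES}
        )

    def scaled(self, factor: float, cx: float = 0.0, cy: float = 0.0) -> "BackLandmarks":
        """Uniform scaling about (cx, cy)."""
        return replace(
            self,
            **{
                n: PixelPoint(
                    cx + factor * (self.point(n).x - cx),
                    cy + factor * (self.point(n).y - cy),
                )
                for n in LANDMARK_NAMES
            },
        )


@dataclass
class QualityReport:
    """Outcome of the structural quality check for one record.

    ``passed`` is false only when a hard rule fails (side inversion);
    soft findings (low resolution, odd vertical ordering) are warnings.
    """

    photo_id: str
    passed: bool
    warnings: list[str] = field(default_factory=list)


def check_quality(lms: BackLandmarks, min_short_side: int = 200) -> QualityReport:
    """Structural quality check; reports, never raises.

    Hard failure: left/right side inversion.  Soft warnings: image short
    side below ``min_short_side`` (when dimensions were recorded),
    shoulder/axilla/waist/iliac vertical ordering broken on a side, or
    C7 tagged below an axilla.
    """
    warnings: list[str] = []
    passed = True
    for level, left, right in SIDE_PAIRS:
        if lms.point(left).x >= lms.point(right).x:
            passed = False
            warnings.append(f"side-inversion:{level}")

    if lms.image_width is not None and lms.image_height is not None:
        if min(lms.image_width, lms.image_height) < min_short_side:
            warnings.append(f"low-resolution:short-side<{min_short_side}px")

    for side in ("left", "right"):
        ys = [lms.point(f"{lvl}_{side}").y for lvl in ("shoulder", "axilla", "waist", "iliac")]
        if any(a > b for a, b in zip(ys, ys[1:])):
            warnings.append(f"ordering:{side}:shoulder-axilla-waist-iliac-not-descending")
    if lms.c7.y > min(lms.axilla_left.y, lms.axilla_right.y):
        warnings.append("ordering:c7-below-axilla-level")

    return QualityReport(photo_id=lms.photo_id, passed=passed, warnings=warnings)


# ---------------------------------------------------------------------------
# File I/O
#
# JSON schema: top-level list of objects
#   {"photo_id": str, "image_width": int|null, "image_height": int|null,
#    "landmarks": {"shoulder_left": [x, y], ..., "c7": [x, y]}}
# CSV schema: header row, one row per photograph, columns photo_id,
#   image_width, image_height, then <name>_x,<name>_y for the nine names.
# Both round-trip coordinates exactly at double precision.
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "csv"):
            raise ValueError(f"unknown landmark file format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer landmark format from {path.name!r}; pass format=")


def _coerce_coord(value: object, photo_id: str, key: str) -> float:
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise LandmarkParseError(
            f"photo {photo_id!r}, landmark {key!r}: non-numeric coordinate {value!r}"
        ) from exc
    if not math.isfinite(v):
        raise LandmarkParseError(
            f"photo {photo_id!r}, landmark {key!r}: non-finite coordinate {value!r}"
        )
    return v


def _record_from_points(
    photo_id: str,
    pts: Mapping[str, PixelPoint],
    image_width: int | None,
    image_height: int | None,
) -> BackLandmarks:
    rec = BackLandmarks(
        photo_id=photo_id,
        image_width=image_width,
        image_height=image_height,
        **{name: pts[name] for name in LANDMARK_NAMES},
    )
    rec.validate()
    return rec


def read_landmarks(path: str | Path, fmt: str | None = None) -> list[BackLandmarks]:
    """Read and validate landmark records from a JSON or CSV file.

    Every returned record has passed structural validation; side labels
    refer to the patient's left/right.  Raises :class:`SchemaError` on a
    missing landmark, :class:`LandmarkParseError` on a bad coordinate and
    :class:`SideInversionError` on swapped sides.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        return _read_json(path)
    return _read_csv(path)


def _read_json(path: Path) -> list[BackLandmarks]:
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a top-level list of records")
    records = []
    for i, obj in enumerate(raw):
        photo_id = str(obj.get("photo_id", f"record-{i}"))
        lm = obj.get("landmarks")
        if not isinstance(lm, dict):
            raise SchemaError(f"photo {photo_id!r}: missing 'landmarks' object")
        pts = {}
        for name in LANDMARK_NAMES:
            if name not in lm:
                raise SchemaError(f"photo {photo_id!r}: missing landmark {name!r}")
            xy = lm[name]
            if not isinstance(xy, (list, tuple)) or len(xy) != 2:
                raise SchemaError(f"photo {photo_id!r}: landmark {name!r} must be [x, y]")
            pts[name] = PixelPoint(
                _coerce_coord(xy[0], photo_id, name), _coerce_coord(xy[1], photo_id, name)
            )
        records.append(
            _record_from_points(
                photo_id, pts, _opt_int(obj.get("image_width")), _opt_int(obj.get("image_height"))
            )
        )
    return records


def _opt_int(v: object) -> int | None:
    if v is None or v == "":
        return None
    return int(v)  # type: ignore[arg-type]


def _csv_header() -> list[str]:
    cols = ["photo_id", "image_width", "image_height"]
    for name in LANDMARK_NAMES:
        cols += [f"{name}_x", f"{name}_y"]
    return cols


def _read_csv(path: Path) -> list[BackLandmarks]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty CSV, header required")
        records = []
        for lineno, row in enumerate(reader, start=2):
            photo_id = str(row.get("photo_id") or f"line-{lineno}")
            pts = {}
            for name in LANDMARK_NAMES:
                xk, yk = f"{name}_x", f"{name}_y"
                if row.get(xk) in (None, "") or row.get(yk) in (None, ""):
                    raise SchemaError(
                        f"photo {photo_id!r} (line {lineno}): missing landmark {name!r}"
                    )
                pts[name] = PixelPoint(
                    _coerce_coord(row[xk], photo_id, xk), _coerce_coord(row[yk], photo_id, yk)
                )
            records.append(
                _record_from_points(
                    photo_id, pts, _opt_int(row.get("image_width")), _opt_int(row.get("image_height"))
                )
            )
    return records


def write_landmarks(
    records: Iterable[BackLandmarks], path: str | Path, fmt: str | None = None
) -> None:
    """Write records to JSON or CSV; reading the file back is an exact round trip."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = list(records)
    for rec in records:
        rec.validate()
    if fmt == "json":
        payload = [
            {
                "photo_id": rec.photo_id,
                "image_width": rec.image_width,
                "image_height": rec.image_height,
                "landmarks": {n: [rec.point(n).x, rec.point(n).y] for n in LANDMARK_NAMES},
            }
            for rec in records
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_csv_header())
        for rec in records:
            row: list[object] = [
                rec.photo_id,
                "" if rec.image_width is None else rec.image_width,
                "" if rec.image_height is None else rec.image_height,
            ]
            for name in LANDMARK_NAMES:
                p = rec.point(name)
                row += [repr(p.x), repr(p.y)]
            writer.writerow(row)
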