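"""Landmark file I/O, ruler calibration, bilateral averaging and the sella frame.

The on-disk dialect is a small CSV: one metadata comment line, a header
``landmark,x,y[,side]``, then one row per digitised point.  The 10-mm
calibration ruler is carried as two ordinary landmarks ``RULER_A``/``RULER_B``.
Coordinates are written with shortest round-trip float formatting so a
read/write cycle is bit-exact.

The standardised reference frame follows the usual cephalometric convention:
sella (S) is the origin, the "true horizontal" x-axis is the S->N line rotated
7.0 degrees clockwise (SN inclines ~7 degrees upward anteriorly relative to
true horizontal), +x is anterior and +y superior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .geometry import Line, Point2D, rotate_point

#: Landmarks that must be present (after bilateral averaging) for the arcial
#: analysis.  See the glossary in the package README for definitions.
REQUIRED_LANDMARKS = (
    "S", "N", "ANS", "PNS", "Go", "Me", "Pog", "Sp", "Si", "U1", "L1", "U6", "L6",
)

#: Synonym table mapping common long names onto the canonical short names.
LANDMARK_SYNONYMS = {
    "Sella": "S",
    "Nasion": "N",
    "Gonion": "Go",
    "Menton": "Me",
    "Pogonion": "Pog",
    "Gnathion": "Gn",
    "SellaInferior": "Si",
    "SellaPosterior": "Sp",
}

#: Default clockwise rotation (degrees) from the S->N line to true horizontal.
TRUE_HORIZONTAL_OFFSET_DEG = 7.0

RULER_NAMES = ("RULER_A", "RULER_B")


class LandmarkParseError(ValueError):
    """Raised when a landmark CSV file is malformed; message names the line."""


@dataclass
class LandmarkSet:
    """Named 2-D points for one subject (one radiograph).

    ``x_anterior``/``y_up`` record the axis convention of the *stored*
    coordinates (+1 when raw +x already points anterior / +y superior).
    :func:`to_internal_orientation` flips signs into the package convention
    anterior = +x, superior = +y.
    """

    subject_id: str
    points: dict[str, Point2D]
    units: str = "mm"  # "px" | "mm"
    side_pairs: dict[str, tuple[Point2D, Point2D]] = field(default_factory=dict)
    x_anterior: int = 1
    y_up: int = 1
    unknown_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.units not in ("px", "mm"):
            raise ValueError(f"units must be 'px' or 'mm', got {self.units!r}")
        if self.x_anterior not in (1, -1) or self.y_up not in (1, -1):
            raise ValueError("axis orientation flags must be +1 or -1")
        dup = set(self.points) & set(self.side_pairs)
        if dup:
            raise ValueError(f"names present both as single points and pairs: {sorted(dup)}")

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing landmarks {missing}")

    def map_points(self, fn) -> "LandmarkSet":
        return replace(
            self,
            points={k: fn(p) for k, p in self.points.items()},
            side_pairs={k: (fn(a), fn(b)) for k, (a, b) in self.side_pairs.items()},
        )


@dataclass(frozen=True)
class Calibration:
    """A known physical distance digitised in pixels (10-mm ruler by default)."""

    ruler_a: Point2D
    ruler_b: Point2D
    known_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.ruler_a.distance_to(self.ruler_b) == 0.0:
            raise ValueError("ruler endpoints coincide")
        if self.known_length_mm <= 0:
            raise ValueError("known ruler length must be positive")

    @property
    def scale_mm_per_px(self) -> float:
        return self.known_length_mm / self.ruler_a.distance_to(self.ruler_b)


@dataclass(frozen=True)
class ReferenceFrame:
    """Sella-origin frame; +x anterior along true horizontal, +y superior."""

    origin: Point2D
    x_axis_direction_deg: float


def _fmt(v: float) -> str:
    return repr(float(v))


def write_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a :class:`LandmarkSet` in the canonical CSV dialect."""
    lines = [
        f"# units={ls.units} x_anterior={ls.x_anterior:+d} y_up={ls.y_up:+d} subject={ls.subject_id}",
        "landmark,x,y,side",
    ]
    for name, p in ls.points.items():
        lines.append(f"{name},{_fmt(p.x)},{_fmt(p.y)},")
    for name, (pl, pr) in ls.side_pairs.items():
        lines.append(f"{name},{_fmt(pl.x)},{_fmt(pl.y)},L")
        lines.append(f"{name},{_fmt(pr.x)},{_fmt(pr.y)},R")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_metadata(line: str, lineno: int) -> dict[str, str]:
    meta: dict[str, str] = {}
    for tok in line.lstrip("#").split():
        if "=" not in tok:
            raise LandmarkParseError(f"line {lineno}: malformed metadata token {tok!r}")
        k, v = tok.split("=", 1)
        meta[k] = v
    return meta


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV file, validating names and coordinates.

    Unknown landmark names are preserved and recorded in ``unknown_names``;
    duplicate rows (same name and side) raise :class:`LandmarkParseError`
    naming the offending line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_seen = False
    points: dict[str, Point2D] = {}
    halves: dict[str, dict[str, Point2D]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line and not meta:
                meta = _parse_metadata(line, lineno)
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:3] != ["landmark", "x", "y"]:
                raise LandmarkParseError(
                    f"line {lineno}: expected header 'landmark,x,y[,side]', got {line!r}")
            header_seen = True
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) < 3:
            raise LandmarkParseError(f"line {lineno}: expected at least 3 columns")
        name = LANDMARK_SYNONYMS.get(cells[0], cells[0])
        try:
            x, y = float(cells[1]), float(cells[2])
        except ValueError as exc:
            raise LandmarkParseError(f"line {lineno}: non-numeric coordinate") from exc
        side = cells[3].upper() if len(cells) > 3 and cells[3] else ""
        if side not in ("", "L", "R"):
            raise LandmarkParseError(f"line {lineno}: side must be L or R, got {side!r}")
        pt = Point2D(x, y)
        if side:
            slot = halves.setdefault(name, {})
            if side in slot or name in points:
                raise LandmarkParseError(f"line {lineno}: duplicate landmark {name!r} ({side})")
            slot[side] = pt
        else:
            if name in points or name in halves:
                raise LandmarkParseError(f"line {lineno}: duplicate landmark {name!r}")
            points[name] = pt
    if not header_seen:
        raise LandmarkParseError("missing header row 'landmark,x,y[,side]'")
    side_pairs: dict[str, tuple[Point2D, Point2D]] = {}
    for name, slot in halves.items():
        if set(slot) != {"L", "R"}:
            raise LandmarkParseError(f"landmark {name!r}: needs both L and R rows")
        side_pairs[name] = (slot["L"], slot["R"])
    known = set(REQUIRED_LANDMARKS) | set(LANDMARK_SYNONYMS.values()) | set(RULER_NAMES) | {"Gn", "PV"}
    unknown = tuple(sorted((set(points) | set(side_pairs)) - known))
    return LandmarkSet(
        subject_id=meta.get("subject", path.stem),
        points=points,
        units=meta.get("units", "mm"),
        side_pairs=side_pairs,
        x_anterior=int(meta.get("x_anterior", "+1")),
        y_up=int(meta.get("y_up", "+1")),
        unknown_names=unknown,
    )


def to_internal_orientation(ls: LandmarkSet) -> LandmarkSet:
    """Flip stored coordinates into the anterior=+x, superior=+y convention."""
    if ls.x_anterior == 1 and ls.y_up == 1:
        return ls
    sx, sy = ls.x_anterior, ls.y_up
    out = ls.map_points(lambda p: Point2D(sx * p.x, sy * p.y))
    out.x_anterior = 1
    out.y_up = 1
    return out


def extract_calibration(ls: LandmarkSet, known_length_mm: float = 10.0) -> Calibration:
    ls.require(*RULER_NAMES)
    return Calibration(ls.points["RULER_A"], ls.points["RULER_B"], known_length_mm)


def calibrate(ls: LandmarkSet, cal: Calibration) -> LandmarkSet:
    """Scale a pixel-space landmark set isotropically into millimetres."""
    if ls.units != "px":
        raise ValueError("calibrate expects a pixel-space landmark set")
    s = cal.scale_mm_per_px
    out = ls.map_points(lambda p: Point2D(s * p.x, s * p.y))
    out.units = "mm"
    return out


def average_bilateral(ls: LandmarkSet) -> LandmarkSet:
    """Replace each left/right pair by its arithmetic midpoint under the base name."""
    if not ls.side_pairs:
        return ls
    points = dict(ls.points)
    for name, (pl, pr) in ls.side_pairs.items():
        if name in points:
            raise ValueError(f"landmark {name!r} exists both as a pair and a single point")
        points[name] = Point2D((pl.x + pr.x) / 2.0, (pl.y + pr.y) / 2.0)
    return replace(ls, points=points, side_pairs={})


def build_frame(ls: LandmarkSet,
                horizontal_offset_deg: float = TRUE_HORIZONTAL_OFFSET_DEG) -> ReferenceFrame:
    """Sella-origin frame with x-axis = S->N rotated clockwise by the offset.

    After the transform N sits ``horizontal_offset_deg`` above the x-axis, i.e.
    at (|SN| cos 7deg, |SN| sin 7deg) with the default constant.  Requires the
    set to be in mm and internal orientation.
    """
    if ls.units != "mm":
        raise ValueError("build_frame requires millimetre coordinates (calibrate first)")
    if ls.x_anterior != 1 or ls.y_up != 1:
        raise ValueError("build_frame requires internal axis orientation")
    ls.require("S", "N")
    s, n = ls.points["S"], ls.points["N"]
    if s.distance_to(n) == 0.0:
        raise ValueError("S and N coincide: frame undefined")
    sn_dir = math.degrees(math.atan2(n.y - s.y, n.x - s.x))
    return ReferenceFrame(origin=s, x_axis_direction_deg=sn_dir - horizontal_offset_deg)


def to_frame(ls: LandmarkSet, frame: ReferenceFrame) -> LandmarkSet:
    """Express all points in frame coordinates (rigid transform, mm)."""
    shifted = ls.map_points(lambda p: Point2D(p.x - frame.origin.x, p.y - frame.origin.y))
    origin = Point2D(0.0, 0.0)
    return shifted.map_points(
        lambda p: rotate_point(p, origin, -frame.x_axis_direction_deg))
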