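"""2-D construction geometry for cephalometric arcial analysis.

Directed lines are stored as an anchor point plus an *undirected* direction
angle in degrees, normalised to [0, 180), so that vertical reference planes
are representable (a slope-intercept form is not).  Circles are centre +
radius.  All angles are degrees throughout the package, matching the 0.1-degree
reporting precision conventional in digital cephalometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

# Lines whose directions differ by less than this (mod 180 deg) are treated as
# parallel: far below the ~0.1 deg precision of digitised tracings.
PARALLEL_TOL_DEG = 1e-7

# A line is tangent to a circle when |distance(centre, line) - r| <= this * r.
TANGENT_TOL_REL = 1e-9


@dataclass(frozen=True)
class Point2D:
    """A point in the plane, coordinates in consistent length units (mm or px)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def normalize_direction(angle_deg: float) -> float:
    """Normalise an undirected line direction to [0, 180)."""
    a = float(angle_deg) % 180.0
    # guard against -1e-16 % 180 == 180.0 - eps artefacts
    return a if a < 180.0 else 0.0


@dataclass(frozen=True)
class Line:
    """Infinite line through ``anchor`` with undirected direction ``direction_deg``."""

    anchor: Point2D
    direction_deg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.direction_deg):
            raise ValueError("non-finite line direction")
        object.__setattr__(self, "direction_deg", normalize_direction(self.direction_deg))

    def direction_vector(self) -> np.ndarray:
        t = math.radians(self.direction_deg)
        return np.array([math.cos(t), math.sin(t)])

    def normal_vector(self) -> np.ndarray:
        t = math.radians(self.direction_deg)
        return np.array([-math.sin(t), math.cos(t)])

    def point_at(self, t: float) -> Point2D:
        p = self.anchor.as_array() + t * self.direction_vector()
        return Point2D(p[0], p[1])

    @staticmethod
    def through(a: Point2D, b: Point2D) -> "Line":
        """Line through two distinct points."""
        if a.distance_to(b) == 0.0:
            raise ValueError("cannot build a line through two coincident points")
        ang = math.degrees(math.atan2(b.y - a.y, b.x - a.x))
        return Line(a, normalize_direction(ang))


@dataclass(frozen=True)
class Circle:
    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0.0):
            raise ValueError(f"circle radius must be positive, got {self.radius}")


def angle_difference_deg(a: float, b: float) -> float:
    """Smallest difference between two undirected directions, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def intersect_lines(a: Line, b: Line) -> Optional[Point2D]:
    """Intersection of two lines, or ``None`` for (near-)parallel input."""
    if angle_difference_deg(a.direction_deg, b.direction_deg) < PARALLEL_TOL_DEG:
        return None
    da, db = a.direction_vector(), b.direction_vector()
    # solve anchor_a + t*da = anchor_b + s*db
    m = np.column_stack([da, -db])
    rhs = b.anchor.as_array() - a.anchor.as_array()
    t, _ = np.linalg.solve(m, rhs)
    p = a.anchor.as_array() + t * da
    return Point2D(p[0], p[1])


def perpendicular_distance(p: Point2D, l: Line) -> float:
    """Euclidean distance from ``p`` to the infinite line ``l``."""
    return abs(float(l.normal_vector() @ (p.as_array() - l.anchor.as_array())))


def project_onto_line(p: Point2D, l: Line) -> float:
    """Signed parameter t of the foot of the perpendicular from ``p`` on ``l``."""
    return float(l.direction_vector() @ (p.as_array() - l.anchor.as_array()))


def intersect_line_circle(l: Line, c: Circle) -> list[Point2D]:
    """Real intersection points of a line and a circle.

    Returns 0, 1 (tangency within ``TANGENT_TOL_REL * radius``) or 2 points,
    ordered by position along the line's direction.
    """
    d = perpendicular_distance(c.center, l)
    t_foot = project_onto_line(c.center, l)
    if abs(d - c.radius) <= TANGENT_TOL_REL * c.radius:
        return [l.point_at(t_foot)]
    if d > c.radius:
        return []
    half = math.sqrt(c.radius * c.radius - d * d)
    return [l.point_at(t_foot - half), l.point_at(t_foot + half)]


def least_squares_point(lines: Sequence[Line]) -> tuple[Point2D, float]:
    """Point minimising the sum of squared perpendicular distances to all lines.

    Closed form via the normal equations: with unit normals n_i and anchors a_i,
    minimise sum((n_i . p - n_i . a_i)^2).  Returns the optimum and the
    root-mean-square residual distance.  Raises for fewer than two lines or an
    all-(near-)parallel pencil, where the optimum is not unique.
    """
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    dirs = [l.direction_deg for l in lines]
    if all(angle_difference_deg(d, dirs[0]) < PARALLEL_TOL_DEG for d in dirs[1:]):
        raise ValueError("all lines are parallel: concurrency point undefined")
    a = np.zeros((2, 2))
    b = np.zeros(2)
    for l in lines:
        n = l.normal_vector()
        a += np.outer(n, n)
        b += n * float(n @ l.anchor.as_array())
    p = np.linalg.solve(a, b)
    pt = Point2D(p[0], p[1])
    sq = [perpendicular_distance(pt, l) ** 2 for l in lines]
    return pt, math.sqrt(sum(sq) / len(sq))


def mean_direction(angles_deg: Sequence[float]) -> float:
    """Circular mean of undirected directions (axial data).

    Angles are doubled, vector-averaged and halved, the standard treatment for
    axial quantities, so 179 deg and 1 deg average to 0 deg rather than 90 deg.
    """
    if len(angles_deg) == 0:
        raise ValueError("need at least one angle")
    doubled = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    v = np.array([np.cos(doubled).mean(), np.sin(doubled).mean()])
    if float(np.hypot(*v)) < 1e-12:
        raise ValueError("directions are perfectly spread: mean direction undefined")
    return normalize_direction(math.degrees(math.atan2(v[1], v[0])) / 2.0)


def rotate_point(p: Point2D, center: Point2D, angle_deg: float) -> Point2D:
    """Rigid rotation of ``p`` about ``center``; positive angles counter-clockwise."""
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    dx, dy = p.x - center.x, p.y - center.y
    return Point2D(center.x + c * dx - s * dy, center.y + s * dx + c * dy)
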