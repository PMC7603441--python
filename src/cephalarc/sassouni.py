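"""The arcial construction: four planes, point O, two arcs, Go/Pog estimation.

The construction extends four cephalometric reference planes posteriorly:

* mandibular plane (MdP), through gonion and menton;
* occlusal plane, through the U1/L1 incisal midpoint and U6/L6 molar midpoint;
* palatal plane, through ANS and PNS;
* basal (anterior cranial base) plane, through Si with the S->N direction.

In a well-proportioned face the four planes meet at a single point O.  Real
faces rarely oblige, so a theoretical O is used: either the least-squares
concurrency point of the four lines, or the centroid of their pairwise
intersections.  Two circles centred at O — the anterior arc of radius |O-ANS|
and the posterior arc of radius |O-Sp| — intersect the mandibular plane at the
estimated pogonion and gonion respectively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

from .geometry import (
    Circle,
    Line,
    Point2D,
    PARALLEL_TOL_DEG,
    angle_difference_deg,
    intersect_line_circle,
    intersect_lines,
    least_squares_point,
    perpendicular_distance,
)
from .landmarks_io import LandmarkSet

PALATE_SHAPES = ("concave", "convex", "horizontal")
MANDIBLE_SHAPES = ("curved", "horizontal", "oblique")

STRATEGIES = ("least_squares", "pairwise_mean")


@dataclass(frozen=True)
class SassouniPlanes:
    mandibular: Line  # OG
    occlusal: Line    # OP
    palatal: Line     # ON
    basal: Line       # OS'

    def as_list(self) -> list[Line]:
        return [self.mandibular, self.occlusal, self.palatal, self.basal]


@dataclass(frozen=True)
class SassouniConstruction:
    planes: SassouniPlanes
    O: Point2D
    O_residual: float  # rms perpendicular distance of O to the four planes (mm)
    anterior_arc: Circle   # radius |O - ANS|
    posterior_arc: Circle  # radius |O - Sp|
    strategy: str


@dataclass(frozen=True)
class MandibleEstimate:
    subject_id: str
    est_Go: Optional[Point2D]
    est_Pog: Optional[Point2D]
    traced_Go: Point2D
    traced_Pog: Point2D
    dGo: Optional[tuple[float, float]]   # estimated - traced, per axis (mm)
    dPog: Optional[tuple[float, float]]
    gap_Go: Optional[float]  # Euclidean norm of dGo (mm)
    gap_Pog: Optional[float]

    @property
    def complete(self) -> bool:
        return self.est_Go is not None and self.est_Pog is not None


@dataclass(frozen=True)
class ShapeLabels:
    palate: str    # concave | convex | horizontal
    mandible: str  # curved | oblique | horizontal
    source: str    # "visual" | "heuristic"

    def __post_init__(self) -> None:
        if self.palate not in PALATE_SHAPES:
            raise ValueError(f"unknown palate shape {self.palate!r}")
        if self.mandible not in MANDIBLE_SHAPES:
            raise ValueError(f"unknown mandible shape {self.mandible!r}")


def _plane(name: str, a: Point2D, b: Point2D) -> Line:
    if a.distance_to(b) == 0.0:
        raise ValueError(f"degenerate {name} plane: defining landmarks coincide")
    return Line.through(a, b)


def build_planes(ls: LandmarkSet) -> SassouniPlanes:
    """Build the four reference planes from a frame-coordinate landmark set."""
    ls.require("Go", "Me", "ANS", "PNS", "S", "N", "Si", "U1", "L1", "U6", "L6")
    p = ls.points
    mid_inc = Point2D((p["U1"].x + p["L1"].x) / 2, (p["U1"].y + p["L1"].y) / 2)
    mid_mol = Point2D((p["U6"].x + p["L6"].x) / 2, (p["U6"].y + p["L6"].y) / 2)
    sn = _plane("basal", p["S"], p["N"])
    return SassouniPlanes(
        mandibular=_plane("mandibular", p["Go"], p["Me"]),
        occlusal=_plane("occlusal", mid_inc, mid_mol),
        palatal=_plane("palatal", p["ANS"], p["PNS"]),
        basal=Line(p["Si"], sn.direction_deg),
    )


def locate_point_O(planes: SassouniPlanes,
                   strategy: str = "least_squares") -> tuple[Point2D, float]:
    """Locate the theoretical convergence point O and its rms residual.

    ``least_squares`` minimises the summed squared perpendicular distances to
    the four planes (exact under concurrency).  ``pairwise_mean`` averages all
    pairwise intersections of non-parallel plane pairs, offered for
    sensitivity analysis.
    """
    lines = planes.as_list()
    if strategy == "least_squares":
        return least_squares_point(lines)
    if strategy == "pairwise_mean":
        pts = []
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                if angle_difference_deg(lines[i].direction_deg,
                                        lines[j].direction_deg) < PARALLEL_TOL_DEG:
                    continue
                q = intersect_lines(lines[i], lines[j])
                if q is not None:
                    pts.append(q)
        if not pts:
            raise ValueError("all plane pairs parallel: point O undefined")
        o = Point2D(sum(q.x for q in pts) / len(pts), sum(q.y for q in pts) / len(pts))
        sq = [perpendicular_distance(o, l) ** 2 for l in lines]
        return o, math.sqrt(sum(sq) / len(sq))
    raise ValueError(f"unknown strategy {strategy!r}")


def build_construction(ls: LandmarkSet,
                       strategy: str = "least_squares") -> SassouniConstruction:
    """Planes + point O + both arcs for one frame-coordinate subject."""
    ls.require("ANS", "Sp")
    planes = build_planes(ls)
    o, residual = locate_point_O(planes, strategy)
    r_ant = o.distance_to(ls.points["ANS"])
    r_post = o.distance_to(ls.points["Sp"])
    if r_ant == 0.0 or r_post == 0.0:
        raise ValueError("point O coincides with ANS or Sp: zero-radius arc")
    return SassouniConstruction(
        planes=planes,
        O=o,
        O_residual=residual,
        anterior_arc=Circle(o, r_ant),
        posterior_arc=Circle(o, r_post),
        strategy=strategy,
    )


def _select_root(points: list[Point2D], o: Point2D, prefer_anterior: bool) -> Optional[Point2D]:
    """Pick the anatomically meaningful arc/MdP intersection.

    Both arcs are centred at O, and the mandibular plane runs close to O, so
    the two circle-line roots generically straddle O; the root posterior of O
    is a geometric mirror with no anatomical meaning.  Candidates anterior of
    O are kept; among them gonion is the more posterior root (smaller frame x)
    and pogonion the more anterior (larger x).  If no root lies anterior of O
    the construction has failed for this subject.
    """
    if not points:
        return None
    anterior = [p for p in points if p.x > o.x]
    if not anterior:
        return None
    key = (lambda p: p.x) if prefer_anterior else (lambda p: -p.x)
    return max(anterior, key=key)


def estimate_gonion(c: SassouniConstruction) -> Optional[Point2D]:
    """Posterior arc intersected with the mandibular plane; ``None`` on a miss."""
    pts = intersect_line_circle(c.planes.mandibular, c.posterior_arc)
    return _select_root(pts, c.O, prefer_anterior=False)


def estimate_pogonion(c: SassouniConstruction) -> Optional[Point2D]:
    """Anterior arc intersected with the mandibular plane; ``None`` on a miss."""
    pts = intersect_line_circle(c.planes.mandibular, c.anterior_arc)
    return _select_root(pts, c.O, prefer_anterior=True)


def compare_estimates(subject_id: str,
                      est_Go: Optional[Point2D], est_Pog: Optional[Point2D],
                      traced_Go: Point2D, traced_Pog: Point2D) -> MandibleEstimate:
    """Per-axis differences (estimated minus traced) and Euclidean gaps."""
    def diff(est: Optional[Point2D], traced: Point2D):
        if est is None:
            return None, None
        d = (est.x - traced.x, est.y - traced.y)
        return d, math.hypot(*d)

    d_go, gap_go = diff(est_Go, traced_Go)
    d_pog, gap_pog = diff(est_Pog, traced_Pog)
    return MandibleEstimate(subject_id, est_Go, est_Pog, traced_Go, traced_Pog,
                            d_go, d_pog, gap_go, gap_pog)


def estimate_mandible(ls: LandmarkSet, strategy: str = "least_squares") -> MandibleEstimate:
    """Convenience: construction + both estimates + comparison for one subject."""
    c = build_construction(ls, strategy)
    return compare_estimates(ls.subject_id, estimate_gonion(c), estimate_pogonion(c),
                             ls.points["Go"], ls.points["Pog"])


# -- shape classification -----------------------------------------------------

#: Palate: |signed deviation of the vault point from the ANS-PNS chord| / chord
#: length must exceed this to leave "horizontal" (boundary stays horizontal).
PALATE_DEVIATION_THRESHOLD = 0.05
#: Mandible: MdP-to-basal-plane divergence angle (deg); strictly below the low
#: threshold -> horizontal (hypodivergent), strictly above the high ->
#: oblique (hyperdivergent), else curved.
DIVERGENCE_LOW_DEG = 22.0
DIVERGENCE_HIGH_DEG = 32.0


def classify_shapes_heuristic(ls: LandmarkSet,
                              palate_threshold: float = PALATE_DEVIATION_THRESHOLD,
                              divergence_low_deg: float = DIVERGENCE_LOW_DEG,
                              divergence_high_deg: float = DIVERGENCE_HIGH_DEG,
                              convex_is_inferior: bool = True) -> ShapeLabels:
    """Rule-based palate/mandible shape labels for frame-coordinate landmarks.

    The study's own labels were assigned visually; this heuristic exists to
    label synthetic cohorts.  The palate uses the perpendicular deviation of an
    optional vault point ``PV`` from the ANS-PNS chord (deviation toward
    inferior counted positive when ``convex_is_inferior``); the mandible uses
    the divergence angle between the mandibular and basal planes.
    """
    planes = build_planes(ls)
    if "PV" in ls.points:
        chord = planes.palatal
        pv = ls.points["PV"]
        n = chord.normal_vector()
        signed = float(n @ (pv.as_array() - chord.anchor.as_array()))
        # normal of a near-horizontal chord points superior; inferior deviation
        # is therefore the negative half-space
        if convex_is_inferior:
            signed = -signed
        chord_len = ls.points["ANS"].distance_to(ls.points["PNS"])
        dev = signed / chord_len
        if dev > palate_threshold:
            palate = "convex"
        elif dev < -palate_threshold:
            palate = "concave"
        else:
            palate = "horizontal"
    else:
        palate = "horizontal"  # provenance: no vault point digitised
    divergence = angle_difference_deg(planes.mandibular.direction_deg,
                                      planes.basal.direction_deg)
    if divergence > divergence_high_deg:
        mandible = "oblique"
    elif divergence < divergence_low_deg:
        mandible = "horizontal"
    else:
        mandible = "curved"
    return ShapeLabels(palate=palate, mandible=mandible, source="heuristic")


# -- serialisation ------------------------------------------------------------

def _pt(p: Optional[Point2D]):
    return None if p is None else [p.x, p.y]


def construction_record(ls: LandmarkSet, c: SassouniConstruction,
                        est: MandibleEstimate) -> dict:
    """Per-subject JSON-serialisable record of the construction and estimates."""
    return {
        "subject_id": ls.subject_id,
        "strategy": c.strategy,
        "O": _pt(c.O),
        "O_residual_mm": c.O_residual,
        "radius_anterior_mm": c.anterior_arc.radius,
        "radius_posterior_mm": c.posterior_arc.radius,
        "plane_directions_deg": {
            "mandibular": c.planes.mandibular.direction_deg,
            "occlusal": c.planes.occlusal.direction_deg,
            "palatal": c.planes.palatal.direction_deg,
            "basal": c.planes.basal.direction_deg,
        },
        "est_Go": _pt(est.est_Go),
        "est_Pog": _pt(est.est_Pog),
        "traced_Go": _pt(est.traced_Go),
        "traced_Pog": _pt(est.traced_Pog),
        "dGo": est.dGo,
        "dPog": est.dPog,
        "gap_Go_mm": est.gap_Go,
        "gap_Pog_mm": est.gap_Pog,
        "flags": [] if est.complete else ["arc_intersection_missing"],
    }


def dump_record(record: dict) -> str:
    return json.dumps(record, indent=2, sort_keys=True)
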