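"""Synthetic cephalometric cohorts with known ground truth.

The generator builds an *ideal* template face in frame coordinates (sella at
the origin, true horizontal +x anterior, +y superior) in which the four
reference planes are exactly concurrent at a chosen point O and every
arc-membership relation of the well-proportioned face holds: ANS, N, U1 and
(optionally offset) Pog on the anterior arc, Go and Sp on the posterior arc,
Pog on the mandibular plane in ideal mode.  Cohorts perturb the template with
a sagittal mandibular displacement for skeletal class II/III subjects and
isotropic Gaussian digitisation jitter, and can be written to disk as
pixel-space landmark CSVs with a 10-mm ruler so the whole calibration /
frame-building pipeline is exercised.

What this emulates — and what it does not: landmark-level digitisation error
and gross sagittal class differences, with a single rigid facial archetype.
It does not model population covariance of craniofacial shape, growth, or
sex differences, so cohort-level dispersion statistics are conventional
defaults, not estimates of any real population.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import Circle, Line, Point2D, intersect_line_circle, rotate_point
from .landmarks_io import LandmarkSet, write_landmarks
from .sassouni import (MANDIBLE_SHAPES, PALATE_SHAPES, ShapeLabels)
from .association import STUDY_SHAPE_COUNTS

#: Landmarks displaced sagittally for skeletal class II/III subjects.
MANDIBULAR_LANDMARKS = ("Go", "Me", "Pog", "Gn")

#: Reference-cohort skeletal class mix (I, II, III) out of 100 subjects.
STUDY_CLASS_MIX = (0.28, 0.26, 0.46)


def _u(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array([math.cos(t), math.sin(t)])


@dataclass(frozen=True)
class TemplateConfig:
    """Geometry of the ideal template face (frame mm).

    Plane angles are signed slopes of the anterior ray in degrees (positive =
    rising anteriorly).  The default O and radii give |SN| ~ 71 mm, the
    operating range of the published Go-Me predictive equation.
    ``pog_arc_offset_deg`` slides pogonion counter-clockwise along the
    anterior arc, lifting it off the mandibular plane (0 = ideal mode, where
    the Go/Pog estimates are exact by construction; ~1.5 deg gives the few
    millimetres of chin elevation seen anatomically).
    """

    O: tuple[float, float] = (-90.0, -14.0)
    basal_angle_deg: float = 7.0       # must equal the S->N inclination
    palatal_angle_deg: float = -3.0
    occlusal_angle_deg: float = -10.0
    mandibular_angle_deg: float = -25.0
    r_anterior: float = 162.0
    r_posterior: float = 83.0
    pns_setback_mm: float = 52.0   # PNS behind the anterior arc along the palatal plane
    molar_setback_mm: float = 45.0  # U6/L6 behind the arc along the occlusal plane
    me_setback_mm: float = 8.0      # Me behind the arc along the mandibular plane
    sp_angle_deg: float = 8.3       # direction O->Sp (Sp on the posterior arc)
    si_x_mm: float = 0.0            # Si = basal-plane point at this frame x
    pog_arc_offset_deg: float = 0.0

    def plane_angles(self) -> dict[str, float]:
        return {
            "mandibular": self.mandibular_angle_deg,
            "occlusal": self.occlusal_angle_deg,
            "palatal": self.palatal_angle_deg,
            "basal": self.basal_angle_deg,
        }


def study_template_config() -> TemplateConfig:
    """Template flavour used for study-like cohorts: pogonion sits ~4 mm
    above the mandibular plane, as on a real chin, so the documented inferior
    bias of the pogonion estimate is reproduced."""
    return replace(TemplateConfig(), pog_arc_offset_deg=1.5)


@dataclass(frozen=True)
class TemplateTruth:
    """Ground truth stored alongside a generated template."""

    O: Point2D
    plane_angles_deg: dict[str, float]  # normalised to [0, 180)
    r_anterior: float
    r_posterior: float
    landmarks: dict[str, Point2D]


def make_ideal_template(cfg: TemplateConfig = TemplateConfig()) -> tuple[LandmarkSet, TemplateTruth]:
    """Build the template landmark set; planes are concurrent at O exactly."""
    o = Point2D(*cfg.O)
    if cfg.r_anterior <= 0 or cfg.r_posterior <= 0:
        raise ValueError("arc radii must be positive")
    for name, setback in (("PNS", cfg.pns_setback_mm), ("molar", cfg.molar_setback_mm),
                          ("Me", cfg.me_setback_mm)):
        if not 0 < setback < cfg.r_anterior:
            raise ValueError(f"{name} setback must lie in (0, r_anterior)")
    oa = o.as_array()
    ant = Circle(o, cfg.r_anterior)
    # N: anterior intersection of the line through S=(0,0) with the S->N
    # direction (= basal direction) and the anterior arc.
    sn_line = Line(Point2D(0.0, 0.0), cfg.basal_angle_deg)
    roots = intersect_line_circle(sn_line, ant)
    if not roots:
        raise ValueError("anterior arc does not reach the S->N line: N unreachable")
    n_pt = max(roots, key=lambda p: p.x)
    if n_pt.x <= 0:
        raise ValueError("anterior arc intersects the S->N line only posteriorly")

    def on_arc(radius: float, angle_deg: float) -> Point2D:
        p = oa + radius * _u(angle_deg)
        return Point2D(p[0], p[1])

    # Si: point of the basal plane (through O at the basal angle) at frame x = si_x
    t_si = (cfg.si_x_mm - o.x) / math.cos(math.radians(cfg.basal_angle_deg))
    si = Point2D(cfg.si_x_mm, o.y + t_si * math.sin(math.radians(cfg.basal_angle_deg)))
    if si.y >= 0:
        raise ValueError("basal plane passes above sella: inconsistent template")

    u1 = on_arc(cfg.r_anterior, cfg.occlusal_angle_deg)
    u6 = on_arc(cfg.r_anterior - cfg.molar_setback_mm, cfg.occlusal_angle_deg)
    pog = on_arc(cfg.r_anterior, cfg.mandibular_angle_deg + cfg.pog_arc_offset_deg)
    me = on_arc(cfg.r_anterior - cfg.me_setback_mm, cfg.mandibular_angle_deg)
    points = {
        "S": Point2D(0.0, 0.0),
        "N": n_pt,
        "ANS": on_arc(cfg.r_anterior, cfg.palatal_angle_deg),
        "PNS": on_arc(cfg.r_anterior - cfg.pns_setback_mm, cfg.palatal_angle_deg),
        "U1": u1,
        "L1": u1,
        "U6": u6,
        "L6": u6,
        "Pog": pog,
        "Me": me,
        "Go": on_arc(cfg.r_posterior, cfg.mandibular_angle_deg),
        "Sp": on_arc(cfg.r_posterior, cfg.sp_angle_deg),
        "Si": si,
    }
    points["Gn"] = Point2D((pog.x + me.x) / 2, (pog.y + me.y) / 2)
    ls = LandmarkSet(subject_id="template", points=points, units="mm")
    truth = TemplateTruth(
        O=o,
        plane_angles_deg={k: v % 180.0 for k, v in cfg.plane_angles().items()},
        r_anterior=cfg.r_anterior,
        r_posterior=cfg.r_posterior,
        landmarks=dict(points),
    )
    return ls, truth


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the reference validation cohort: n = 100 subjects with a
    28/26/46 skeletal class I/II/III mix, +-6 mm sagittal mandibular
    displacement for class II (posterior) and III (anterior), 0.5 mm
    digitisation jitter per axis, and palate x mandible shape labels drawn
    from the reference joint frequencies.
    """

    n: int = 100
    class_mix: tuple[float, float, float] = STUDY_CLASS_MIX
    class_shift_mm: float = 6.0
    digitization_sd: float = 0.5
    label_joint: np.ndarray = field(
        default_factory=lambda: STUDY_SHAPE_COUNTS / STUDY_SHAPE_COUNTS.sum())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")
        if self.digitization_sd < 0:
            raise ValueError("digitisation sd must be non-negative")
        j = np.asarray(self.label_joint, dtype=float)
        if j.shape != (3, 3) or abs(j.sum() - 1.0) > 1e-9 or (j < 0).any():
            raise ValueError("label joint must be a 3x3 probability table")


def _jitter(ls: LandmarkSet, sd: float, rng: np.random.Generator) -> LandmarkSet:
    if sd == 0.0:
        return ls
    points = {k: Point2D(p.x + rng.normal(0, sd), p.y + rng.normal(0, sd))
              for k, p in ls.points.items()}
    pairs = {k: (Point2D(a.x + rng.normal(0, sd), a.y + rng.normal(0, sd)),
                 Point2D(b.x + rng.normal(0, sd), b.y + rng.normal(0, sd)))
             for k, (a, b) in ls.side_pairs.items()}
    return replace(ls, points=points, side_pairs=pairs)


def sample_shape_labels(n: int, joint: Optional[np.ndarray] = None,
                        seed: int | np.random.Generator = 0) -> list[ShapeLabels]:
    """Draw n palate/mandible label pairs from a 3x3 joint distribution."""
    j = (STUDY_SHAPE_COUNTS / STUDY_SHAPE_COUNTS.sum()
         if joint is None else np.asarray(joint, dtype=float))
    if j.shape != (3, 3) or abs(j.sum() - 1.0) > 1e-9:
        raise ValueError("joint must be a 3x3 table summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(9, size=n, p=j.ravel())
    return [ShapeLabels(palate=PALATE_SHAPES[i // 3], mandible=MANDIBLE_SHAPES[i % 3],
                        source="visual") for i in idx]


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    template_cfg: Optional[TemplateConfig] = None
                    ) -> list[tuple[LandmarkSet, dict]]:
    """Generate ``spec.n`` subjects from the template.

    Class II/III subjects have their mandibular landmarks (Go, Me, Pog, Gn)
    shifted posteriorly/anteriorly by ``class_shift_mm``; every landmark then
    receives independent Gaussian jitter.  Metadata records the class, shape
    labels, true (pre-jitter) landmarks and the seed.
    """
    cfg = study_template_config() if template_cfg is None else template_cfg
    template, truth = make_ideal_template(cfg)
    rng = np.random.default_rng(spec.seed)
    classes = rng.choice(("I", "II", "III"), size=spec.n, p=spec.class_mix)
    labels = sample_shape_labels(spec.n, spec.label_joint, rng)
    cohort: list[tuple[LandmarkSet, dict]] = []
    for i in range(spec.n):
        shift = {"I": 0.0, "II": -spec.class_shift_mm, "III": spec.class_shift_mm}[classes[i]]
        points = dict(template.points)
        for name in MANDIBULAR_LANDMARKS:
            if name in points:
                p = points[name]
                points[name] = Point2D(p.x + shift, p.y)
        true_ls = replace(template, subject_id=f"subj{i:04d}", points=points)
        noisy = _jitter(true_ls, spec.digitization_sd, rng)
        meta = {
            "subject_id": noisy.subject_id,
            "skeletal_class": str(classes[i]),
            "palate_shape": labels[i].palate,
            "mandible_shape": labels[i].mandible,
            "label_source": labels[i].source,
            "true_landmarks": {k: [p.x, p.y] for k, p in true_ls.points.items()},
            "seed": spec.seed,
        }
        cohort.append((noisy, meta))
    return cohort


def digitize_repeat(ls: LandmarkSet, sd: float,
                    seed: int | np.random.Generator) -> LandmarkSet:
    """Emulate a repeat digitisation: Gaussian noise of ``sd`` mm per axis."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _jitter(ls, sd, rng)


def sample_sn_gome(n: int, seed: int | np.random.Generator,
                   slope: float = 0.5426, intercept: float = 22.65,
                   noise_sd: float = 4.5, sn_mean: float = 71.0,
                   sn_sd: float = 3.5) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (|SN|, Go-Me) pairs from the published linear relation.

    The SN spread (sd 3.5 mm) is chosen so the implied correlation (~0.38)
    matches the reported correlation strength; the residual sd of 4.5 mm is
    the generating condition for the regression-recovery checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sn = rng.normal(sn_mean, sn_sd, size=n)
    gome = intercept + slope * sn + rng.normal(0, noise_sd, size=n)
    return sn, gome


# -- raw-image emulation and on-disk cohorts ---------------------------------

@dataclass(frozen=True)
class ImageParams:
    """Mapping from frame mm to a digitiser's pixel space (y axis down)."""

    px_per_mm: float = 7.5
    origin_px: tuple[float, float] = (600.0, 420.0)
    rotation_deg: float = 12.0  # head tilt of the radiograph in the image
    ruler_origin_px: tuple[float, float] = (60.0, 60.0)


def to_image_coordinates(ls: LandmarkSet, params: ImageParams = ImageParams()) -> LandmarkSet:
    """Express a frame-mm landmark set as pixel image coordinates.

    Applies rotation + scale + offset, flips the y axis (image rows grow
    downward) and adds the RULER_A/RULER_B calibration pair 10 mm apart.
    """
    if ls.units != "mm":
        raise ValueError("expected a millimetre landmark set")
    c = Point2D(0.0, 0.0)

    def fwd(p: Point2D) -> Point2D:
        q = rotate_point(p, c, params.rotation_deg)
        # stored image y runs downward: flag y_up = -1 below
        return Point2D(q.x * params.px_per_mm + params.origin_px[0],
                       -(q.y * params.px_per_mm) + params.origin_px[1])

    out = ls.map_points(fwd)
    rx, ry = params.ruler_origin_px
    out.points["RULER_A"] = Point2D(rx, ry)
    out.points["RULER_B"] = Point2D(rx + 10.0 * params.px_per_mm, ry)
    out.units = "px"
    out.x_anterior = 1
    out.y_up = -1
    return out


def split_bilateral(ls: LandmarkSet, names: Sequence[str] = ("Go",),
                    offset_mm: float = 0.8) -> LandmarkSet:
    """Replace landmarks by symmetric left/right pairs (midpoint preserved)."""
    points = dict(ls.points)
    pairs = dict(ls.side_pairs)
    for name in names:
        if name in points:
            p = points.pop(name)
            pairs[name] = (Point2D(p.x, p.y + offset_mm / 2.0),
                           Point2D(p.x, p.y - offset_mm / 2.0))
    return replace(ls, points=points, side_pairs=pairs)


def write_cohort(cohort: list[tuple[LandmarkSet, dict]], outdir: str | Path,
                 as_image: bool = True,
                 image_params: ImageParams = ImageParams(),
                 bilateral: Sequence[str] = ("Go",),
                 bilateral_offset_mm: float = 0.8) -> Path:
    """Write a cohort as landmark CSVs plus a metadata JSON; returns the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for ls, meta in cohort:
        out = split_bilateral(ls, bilateral, bilateral_offset_mm)
        if as_image:
            out = to_image_coordinates(out, image_params)
        write_landmarks(out, outdir / f"{ls.subject_id}.csv")
        metas.append(meta)
    (outdir / "metadata.json").write_text(json.dumps(metas, indent=2, sort_keys=True))
    return outdir
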