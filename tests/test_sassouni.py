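import math
from dataclasses import replace

import numpy as np
import pytest

from cephalarc.geometry import (Circle, Line, Point2D, perpendicular_distance,
                                rotate_point)
from cephalarc.sassouni import (SassouniConstruction, SassouniPlanes,
                                build_construction, build_planes,
                                classify_shapes_heuristic, compare_estimates,
                                estimate_gonion, estimate_mandible,
                                estimate_pogonion, locate_point_O)
from cephalarc.synthetic import TemplateConfig, make_ideal_template


class TestBuildPlanes:
    def test_planes_contain_their_defining_landmarks(self, ideal_template):
        ls, _ = ideal_template
        planes = build_planes(ls)
        for plane, names in ((planes.mandibular, ("Go", "Me")),
                             (planes.palatal, ("ANS", "PNS")),
                             (planes.basal, ("Si",))):
            for n in names:
                assert perpendicular_distance(ls.points[n], plane) < 1e-12

    def test_closed_occlusion_passes_through_tooth_points(self, ideal_template):
        ls, _ = ideal_template  # template has U1=L1 and U6=L6
        planes = build_planes(ls)
        assert perpendicular_distance(ls.points["U1"], planes.occlusal) < 1e-12
        assert perpendicular_distance(ls.points["U6"], planes.occlusal) < 1e-12

    def test_plane_directions_match_generator_ground_truth(self, ideal_template):
        ls, truth = ideal_template
        planes = build_planes(ls)
        for name, line in (("mandibular", planes.mandibular),
                           ("occlusal", planes.occlusal),
                           ("palatal", planes.palatal),
                           ("basal", planes.basal)):
            assert line.direction_deg == pytest.approx(
                truth.plane_angles_deg[name], abs=1e-9)

    def test_degenerate_plane_names_the_culprit(self, ideal_template):
        ls, _ = ideal_template
        bad = replace(ls, points={**ls.points, "Me": ls.points["Go"]})
        with pytest.raises(ValueError, match="mandibular"):
            build_planes(bad)


class TestLocatePointO:
    def test_concurrent_planes_agree_under_both_strategies(self, ideal_template):
        ls, truth = ideal_template
        planes = build_planes(ls)
        for strategy in ("least_squares", "pairwise_mean"):
            o, res = locate_point_O(planes, strategy)
            assert (o.x, o.y) == pytest.approx((truth.O.x, truth.O.y), abs=1e-8)
            assert res < 1e-8

    def test_perturbed_planes_match_grid_search(self, ideal_template, rng):
        ls, truth = ideal_template
        pts = {k: Point2D(p.x + rng.normal(0, 1.0), p.y + rng.normal(0, 1.0))
               for k, p in ls.points.items()}
        planes = build_planes(replace(ls, points=pts))
        o, _ = locate_point_O(planes, "least_squares")
        xs = np.arange(o.x - 0.5, o.x + 0.5, 1e-3)
        ys = np.arange(o.y - 0.5, o.y + 0.5, 1e-3)
        gx, gy = np.meshgrid(xs, ys)
        total = np.zeros_like(gx)
        for l in planes.as_list():
            n = l.normal_vector()
            total += (n[0] * (gx - l.anchor.x) + n[1] * (gy - l.anchor.y)) ** 2
        i = np.unravel_index(np.argmin(total), total.shape)
        assert math.hypot(gx[i] - o.x, gy[i] - o.y) < 1e-2

    def test_residual_invariant_under_rigid_motion(self, ideal_template, rng):
        ls, _ = ideal_template
        pts = {k: Point2D(p.x + rng.normal(0, 1.5), p.y + rng.normal(0, 1.5))
               for k, p in ls.points.items()}
        noisy = replace(ls, points=pts)
        _, res0 = locate_point_O(build_planes(noisy))
        centre = Point2D(13.0, -42.0)
        moved = replace(noisy, points={
            k: rotate_point(Point2D(p.x + 25.0, p.y - 11.0), centre, 33.0)
            for k, p in pts.items()})
        _, res1 = locate_point_O(build_planes(moved))
        assert res1 == pytest.approx(res0, rel=1e-9, abs=1e-9)


class TestConstruction:
    def test_arc_radii_by_definition(self, ideal_template):
        ls, _ = ideal_template
        c = build_construction(ls)
        assert c.anterior_arc.radius == pytest.approx(
            c.O.distance_to(ls.points["ANS"]), abs=1e-12)
        assert c.posterior_arc.radius == pytest.approx(
            c.O.distance_to(ls.points["Sp"]), abs=1e-12)

    def test_anterior_arc_passes_through_canonical_landmarks(self, ideal_template):
        ls, _ = ideal_template
        c = build_construction(ls)
        for name in ("ANS", "N", "U1", "Pog"):
            assert c.O.distance_to(ls.points[name]) == pytest.approx(
                c.anterior_arc.radius, abs=1e-6)
        for name in ("Go", "Sp"):
            assert c.O.distance_to(ls.points[name]) == pytest.approx(
                c.posterior_arc.radius, abs=1e-6)

    def test_strategy_recorded(self, ideal_template):
        ls, _ = ideal_template
        assert build_construction(ls, "pairwise_mean").strategy == "pairwise_mean"


class TestEstimates:
    def test_ideal_template_estimates_are_exact(self, ideal_template):
        ls, _ = ideal_template
        est = estimate_mandible(ls)
        assert est.gap_Go < 1e-6
        assert est.gap_Pog < 1e-6

    def test_estimates_lie_on_arc_and_mandibular_plane(self, study_cohort_dir):
        from cephalarc.pipeline import process_subject
        for f in sorted(study_cohort_dir.glob("*.csv"))[:8]:
            ls, _ = process_subject(f)
            c = build_construction(ls)
            go, pog = estimate_gonion(c), estimate_pogonion(c)
            for p, arc in ((go, c.posterior_arc), (pog, c.anterior_arc)):
                assert p is not None
                assert abs(p.distance_to(c.O) - arc.radius) <= 1e-9 * arc.radius
                assert perpendicular_distance(p, c.planes.mandibular) <= 1e-9

    def test_arc_missing_the_plane_returns_none(self, ideal_template):
        ls, _ = ideal_template
        c = build_construction(ls)
        # push the mandibular plane far below the posterior arc's reach
        far_planes = SassouniPlanes(
            mandibular=Line(Point2D(0.0, -500.0), c.planes.mandibular.direction_deg),
            occlusal=c.planes.occlusal, palatal=c.planes.palatal,
            basal=c.planes.basal)
        miss = SassouniConstruction(
            planes=far_planes, O=c.O, O_residual=c.O_residual,
            anterior_arc=c.anterior_arc, posterior_arc=c.posterior_arc,
            strategy=c.strategy)
        assert estimate_gonion(miss) is None
        assert estimate_pogonion(miss) is None

    def test_pogonion_above_plane_is_estimated_inferiorly(self, study_template):
        ls, _ = study_template  # traced Pog elevated above the MdP
        c = build_construction(ls)
        planes = c.planes
        assert perpendicular_distance(ls.points["Pog"], planes.mandibular) > 1.0
        est = estimate_pogonion(c)
        assert est is not None
        assert est.y < ls.points["Pog"].y

    def test_gonion_root_is_the_anatomical_one(self, ideal_template):
        # the posterior arc cuts the MdP twice; the root behind O is a mirror
        # image and must never be selected
        ls, truth = ideal_template
        c = build_construction(ls)
        go = estimate_gonion(c)
        assert go.x > c.O.x
        assert go.distance_to(ls.points["Go"]) < 1e-6


class TestCompareEstimates:
    def test_zero_and_three_four_five(self):
        t = Point2D(10, 10)
        m = compare_estimates("s", t, Point2D(13, 14), t, t)
        assert m.gap_Go == 0.0
        assert m.dPog == (3.0, 4.0)
        assert m.gap_Pog == pytest.approx(5.0, abs=1e-12)

    def test_missing_estimate_flags_subject(self):
        t = Point2D(0, 0)
        m = compare_estimates("s", None, t, t, t)
        assert m.gap_Go is None and m.dGo is None
        assert not m.complete

    def test_gap_equals_independent_hypot(self, rng):
        for _ in range(20):
            e = Point2D(*rng.normal(0, 50, 2))
            t = Point2D(*rng.normal(0, 50, 2))
            m = compare_estimates("s", e, e, t, t)
            by_hand = math.sqrt((e.x - t.x) ** 2 + (e.y - t.y) ** 2)
            assert m.gap_Go == pytest.approx(by_hand, abs=1e-12)


class TestShapeClassification:
    def make_with_pv(self, ls, deviation_frac):
        ans, pns = ls.points["ANS"], ls.points["PNS"]
        chord = Line.through(ans, pns)
        mid = Point2D((ans.x + pns.x) / 2, (ans.y + pns.y) / 2)
        n = chord.normal_vector()  # points superior for a near-horizontal chord
        L = ans.distance_to(pns)
        pv = Point2D(mid.x - n[0] * deviation_frac * L, mid.y - n[1] * deviation_frac * L)
        return replace(ls, points={**ls.points, "PV": pv})

    def test_vault_on_chord_is_horizontal(self, ideal_template):
        ls, _ = ideal_template
        labels = classify_shapes_heuristic(self.make_with_pv(ls, 0.0))
        assert labels.palate == "horizontal"
        assert labels.source == "heuristic"

    def test_inferior_vault_is_convex_superior_is_concave(self, ideal_template):
        ls, _ = ideal_template
        assert classify_shapes_heuristic(self.make_with_pv(ls, 0.10)).palate == "convex"
        assert classify_shapes_heuristic(self.make_with_pv(ls, -0.10)).palate == "concave"

    def test_boundary_deviation_stays_horizontal(self, ideal_template):
        # horizontal chord of length 64 (a power of two) makes the normalised
        # deviation land exactly on the threshold float: the closed interval
        # keeps the label "horizontal"
        ls, _ = ideal_template
        t = 0.1
        pts = {**ls.points,
               "ANS": Point2D(72.0, -20.0), "PNS": Point2D(8.0, -20.0),
               "PV": Point2D(40.0, -20.0 - t * 64.0)}
        labels = classify_shapes_heuristic(replace(ls, points=pts), palate_threshold=t)
        assert labels.palate == "horizontal"
        just_over = {**pts, "PV": Point2D(40.0, -20.0 - t * 64.0 - 1e-9)}
        assert classify_shapes_heuristic(replace(ls, points=just_over),
                                         palate_threshold=t).palate == "convex"

    def test_divergence_thresholds(self, ideal_template):
        # default template divergence is exactly 32 deg (boundary -> curved);
        # steepening the mandibular plane to 40 deg makes it oblique
        ls, _ = ideal_template
        assert classify_shapes_heuristic(ls).mandible == "curved"
        steep, _ = make_ideal_template(TemplateConfig(mandibular_angle_deg=-33.0))
        assert classify_shapes_heuristic(steep).mandible == "oblique"
        shallow, _ = make_ideal_template(TemplateConfig(mandibular_angle_deg=-14.0))
        assert classify_shapes_heuristic(shallow).mandible == "horizontal"
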