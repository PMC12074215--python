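"""Oriented-box algebra, ProbIoU and polygon IoU against independent oracles."""

import math

import numpy as np
import pytest
import shapely

from oeyolo.geometry import (
    Detection,
    Gaussian2D,
    InvalidBoxError,
    InvalidQuadError,
    OrientedBox,
    bhattacharyya_coefficient,
    box_to_gaussian,
    box_to_vertices,
    canonicalize_box,
    clip_polygon,
    min_area_rect,
    polygon_area,
    polygon_iou,
    prob_iou,
    rotated_nms,
    vertices_to_box,
)

from conftest import random_box


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bc_quadrature(g1: Gaussian2D, g2: Gaussian2D, lo=-6.0, hi=7.0, step=0.01) -> float:
    """Grid quadrature of the Bhattacharyya integral ∫ sqrt(p q) dx."""
    xs = np.arange(lo, hi, step)
    X, Y = np.meshgrid(xs, xs)

    def pdf(g):
        d = np.stack([X - g.mu[0], Y - g.mu[1]], axis=-1)
        inv = np.linalg.inv(g.sigma)
        det = np.linalg.det(g.sigma)
        e = np.einsum("...i,ij,...j->...", d, inv, d)
        return np.exp(-0.5 * e) / (2 * np.pi * np.sqrt(det))

    return float(np.sum(np.sqrt(pdf(g1) * pdf(g2))) * step * step)


def iou_rasterized(a: OrientedBox, b: OrientedBox, n: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo IoU estimate by sampling the union's bounding window."""
    rng = np.random.default_rng(seed)
    va, vb = box_to_vertices(a), box_to_vertices(b)
    allv = np.vstack([va, vb])
    lo, hi = allv.min(axis=0), allv.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n, 2))

    def inside(box, p):
        d = p - np.array([box.cx, box.cy])
        c, s = math.cos(box.theta), math.sin(box.theta)
        u = d[:, 0] * c + d[:, 1] * s
        v = -d[:, 0] * s + d[:, 1] * c
        return (np.abs(u) <= box.w / 2) & (np.abs(v) <= box.h / 2)

    ia, ib = inside(a, pts), inside(b, pts)
    union = np.count_nonzero(ia | ib)
    return float(np.count_nonzero(ia & ib) / union) if union else 0.0


def min_rect_bruteforce(points: np.ndarray, n_angles: int = 3600) -> float:
    """Min enclosing-rectangle area by dense angle sweep (oracle)."""
    best = np.inf
    for ang in np.linspace(0.0, np.pi / 2, n_angles):
        c, s = math.cos(ang), math.sin(ang)
        R = np.array([[c, s], [-s, c]])
        q = points @ R.T
        ext = q.max(axis=0) - q.min(axis=0)
        best = min(best, ext[0] * ext[1])
    return float(best)


# ---------------------------------------------------------------------------
# canonical form and vertex conversions
# ---------------------------------------------------------------------------

class TestCanonicalForm:
    def test_side_swap_rotates_by_half_pi(self):
        b = canonicalize_box(OrientedBox(0, 0, 2, 4, 0))
        assert (b.w, b.h) == (4, 2)
        assert b.theta == pytest.approx(-math.pi / 2)

    def test_pi_periodicity(self):
        b = canonicalize_box(OrientedBox(0, 0, 4, 2, math.pi))
        assert b.theta == pytest.approx(0.0)

    def test_rejects_nonpositive_sides(self):
        with pytest.raises(InvalidBoxError):
            OrientedBox(0, 0, -1, 2, 0)
        with pytest.raises(InvalidBoxError):
            OrientedBox(0, 0, 1, 0, 0)

    def test_vertex_set_preserved(self, rng):
        for _ in range(50):
            b = OrientedBox(
                float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10)),
                float(rng.uniform(1, 20)), float(rng.uniform(1, 20)),
                float(rng.uniform(-7, 7)),
            )
            v0 = np.array(sorted(map(tuple, np.round(box_to_vertices(b), 6))))
            v1 = np.array(sorted(map(tuple, np.round(box_to_vertices(canonicalize_box(b)), 6))))
            np.testing.assert_allclose(v0, v1, atol=1e-5)


class TestVertexConversion:
    def test_axis_aligned_corners(self):
        v = box_to_vertices(OrientedBox(100, 50, 40, 10, 0))
        expect = {(80, 45), (120, 45), (120, 55), (80, 55)}
        assert {tuple(map(round, p)) for p in v} == expect

    def test_diagonal_square(self):
        v = box_to_vertices(OrientedBox(0, 0, 2, 2, math.pi / 4))
        np.testing.assert_allclose(np.hypot(v[:, 0], v[:, 1]), math.sqrt(2), atol=1e-9)

    def test_round_trip(self, rng):
        for _ in range(50):
            b = random_box(rng)
            b2 = vertices_to_box(box_to_vertices(b))
            assert b2.cx == pytest.approx(b.cx, abs=1e-4)
            assert b2.cy == pytest.approx(b.cy, abs=1e-4)
            assert b2.w == pytest.approx(b.w, abs=1e-4)
            assert b2.h == pytest.approx(b.h, abs=1e-4)

    def test_named_example_round_trip(self):
        b = vertices_to_box(box_to_vertices(OrientedBox(5, 5, 6, 2, 0.3)))
        assert (b.cx, b.cy, b.w, b.h, b.theta) == pytest.approx((5, 5, 6, 2, 0.3), abs=1e-6)

    def test_axis_aligned_square_zero_angle(self):
        b = vertices_to_box([(0, 0), (2, 0), (2, 2), (0, 2)])
        assert b.theta == pytest.approx(0.0, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(InvalidQuadError):
            vertices_to_box([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_min_area_rect_matches_brute_force(self, rng):
        # the dense angle sweep upper-bounds the true minimum (discretized),
        # so the exact result must not exceed it and must enclose the points
        for _ in range(20):
            pts = rng.uniform(-10, 10, size=(7, 2))
            rect = min_area_rect(pts)
            sweep = min_rect_bruteforce(pts)
            assert rect.area <= sweep * (1 + 1e-9)
            assert rect.area >= sweep * (1 - 1e-3)
            c, s = math.cos(rect.theta), math.sin(rect.theta)
            d = pts - [rect.cx, rect.cy]
            u = d[:, 0] * c + d[:, 1] * s
            v = -d[:, 0] * s + d[:, 1] * c
            assert np.all(np.abs(u) <= rect.w / 2 + 1e-6)
            assert np.all(np.abs(v) <= rect.h / 2 + 1e-6)

    def test_enclosing_rect_at_least_quad_area(self, rng):
        for _ in range(20):
            quad = rng.uniform(-10, 10, size=(4, 2))
            hull = shapely.convex_hull(shapely.multipoints(quad))
            if hull.geom_type != "Polygon":
                continue
            rect = min_area_rect(np.asarray(hull.exterior.coords)[:-1])
            assert rect.area >= hull.area - 1e-9


# ---------------------------------------------------------------------------
# Gaussian surrogate and ProbIoU
# ---------------------------------------------------------------------------

class TestGaussianConversion:
    def test_isotropic_square(self):
        g = box_to_gaussian(OrientedBox(0, 0, 2, 2, 0))
        np.testing.assert_allclose(g.mu, [0, 0])
        np.testing.assert_allclose(g.sigma, np.diag([1 / 3, 1 / 3]))

    def test_axis_swap_at_quarter_turn(self):
        g = box_to_gaussian(OrientedBox(0, 0, 4, 2, math.pi / 2))
        np.testing.assert_allclose(g.sigma, np.diag([1 / 3, 4 / 3]), atol=1e-12)

    def test_off_diagonal_at_eighth_turn(self):
        g = box_to_gaussian(OrientedBox(0, 0, 4, 2, math.pi / 4))
        # explicit R diag R^T product: off-diagonal (w^2 - h^2) / 24
        a, b = 16 / 12, 4 / 12
        R = np.array([[math.cos(math.pi / 4), -math.sin(math.pi / 4)],
                      [math.sin(math.pi / 4), math.cos(math.pi / 4)]])
        expect = R @ np.diag([a, b]) @ R.T
        np.testing.assert_allclose(g.sigma, expect, atol=1e-12)
        assert g.sigma[0, 1] == pytest.approx(0.5)

    def test_determinant_rotation_invariant(self, rng):
        for _ in range(20):
            b = random_box(rng)
            det = np.linalg.det(box_to_gaussian(b).sigma)
            assert det == pytest.approx((b.w**2 / 12) * (b.h**2 / 12), rel=1e-9)


class TestBhattacharyya:
    def test_identity(self):
        g = box_to_gaussian(OrientedBox(1, 2, 3, 4, 0.5))
        assert bhattacharyya_coefficient(g, g) == pytest.approx(1.0)

    def test_far_separation_decays(self):
        g1 = Gaussian2D([0, 0], np.eye(2))
        g2 = Gaussian2D([1e6, 0], np.eye(2))
        assert bhattacharyya_coefficient(g1, g2) < 1e-12

    def test_matches_quadrature(self):
        g1 = box_to_gaussian(OrientedBox(0, 0, 2, 2, 0))
        g2 = box_to_gaussian(OrientedBox(1, 0, 2, 2, 0))
        assert bhattacharyya_coefficient(g1, g2) == pytest.approx(
            bc_quadrature(g1, g2), abs=1e-3
        )

    def test_degenerate_covariance_raises(self):
        bad = Gaussian2D([0, 0], np.zeros((2, 2)))
        good = Gaussian2D([0, 0], np.eye(2))
        with pytest.raises(np.linalg.LinAlgError):
            bhattacharyya_coefficient(bad, good)


class TestProbIoU:
    def test_self_overlap_is_one(self, rng):
        for _ in range(20):
            b = random_box(rng)
            assert prob_iou(b, b) == pytest.approx(1.0, abs=1e-9)

    def test_far_boxes_zero(self):
        a = OrientedBox(0, 0, 2, 2, 0)
        b = OrientedBox(1e6, 0, 2, 2, 0)
        assert prob_iou(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_value_from_quadrature_oracle(self):
        a = OrientedBox(0, 0, 2, 2, 0)
        b = OrientedBox(1, 0, 2, 2, 0)
        bc = bc_quadrature(box_to_gaussian(a), box_to_gaussian(b))
        assert prob_iou(a, b) == pytest.approx(1 - math.sqrt(1 - bc), abs=2e-3)

    def test_literal_hellinger_switch(self):
        a = OrientedBox(0, 0, 2, 2, 0)
        b = OrientedBox(1, 0, 2, 2, 0)
        bc = bhattacharyya_coefficient(box_to_gaussian(a), box_to_gaussian(b))
        assert prob_iou(a, b, hellinger_sqrt=False) == pytest.approx(bc, abs=1e-12)

    def test_symmetry_and_rigid_motion_invariance(self, rng):
        for _ in range(30):
            a, b = random_box(rng), random_box(rng)
            v = prob_iou(a, b)
            assert v == pytest.approx(prob_iou(b, a), abs=1e-9)
            dx, dy, phi = rng.uniform(-50, 50), rng.uniform(-50, 50), rng.uniform(-3, 3)
            c, s = math.cos(phi), math.sin(phi)

            def move(box):
                x = c * box.cx - s * box.cy + dx
                y = s * box.cx + c * box.cy + dy
                return OrientedBox(x, y, box.w, box.h, box.theta + phi)

            assert prob_iou(move(a), move(b)) == pytest.approx(v, abs=1e-6)

    def test_bounded(self, rng):
        for _ in range(30):
            v = prob_iou(random_box(rng), random_box(rng))
            assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# polygon IoU and NMS
# ---------------------------------------------------------------------------

class TestPolygonIoU:
    def test_identical(self):
        b = OrientedBox(3, 4, 5, 2, 0.7)
        assert polygon_iou(b, b) == pytest.approx(1.0)

    def test_disjoint(self):
        assert polygon_iou(OrientedBox(0, 0, 2, 2, 0), OrientedBox(3, 0, 1, 1, 0)) == 0.0

    def test_octagonal_overlap(self):
        a = OrientedBox(0, 0, 2, 2, 0)
        b = OrientedBox(0, 0, 2, 2, math.pi / 4)
        # exact value: intersection is a regular octagon, 8(sqrt(2)-1);
        # IoU = inter / (8 - inter)
        inter = 8 * (math.sqrt(2) - 1)
        assert polygon_iou(a, b) == pytest.approx(inter / (8 - inter), rel=1e-9)

    def test_against_shapely_and_rasterization(self, rng):
        for i in range(40):
            a, b = random_box(rng, 30, 2, 40), random_box(rng, 30, 2, 40)
            mine = polygon_iou(a, b)
            pa = shapely.Polygon(box_to_vertices(a))
            pb = shapely.Polygon(box_to_vertices(b))
            ref = pa.intersection(pb).area / pa.union(pb).area
            assert mine == pytest.approx(ref, abs=1e-9)
            if i < 10:
                assert mine == pytest.approx(iou_rasterized(a, b, seed=i), abs=0.02)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_box(rng), random_box(rng)
            assert polygon_iou(a, b) == pytest.approx(polygon_iou(b, a), abs=1e-12)

    def test_clip_empty_when_disjoint(self):
        a = box_to_vertices(OrientedBox(0, 0, 2, 2, 0))
        b = box_to_vertices(OrientedBox(10, 10, 2, 2, 0))
        assert polygon_area(clip_polygon(a, b)) == 0.0


def nms_bruteforce(dets, thr):
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, dets[i].class_id, i))
    kept = []
    for i in order:
        if all(polygon_iou(dets[j].box, dets[i].box) <= thr for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


class TestRotatedNMS:
    def test_duplicate_suppressed(self):
        b = OrientedBox(0, 0, 4, 2, 0.3)
        out = rotated_nms([Detection(b, 0.9), Detection(b, 0.8)], 0.35)
        assert len(out) == 1 and out[0].score == 0.9

    def test_disjoint_survive(self):
        d = [Detection(OrientedBox(0, 0, 2, 2, 0), 0.5),
             Detection(OrientedBox(10, 0, 2, 2, 0), 0.9)]
        out = rotated_nms(d, 0.35)
        assert len(out) == 2
        assert [x.score for x in out] == [0.9, 0.5]  # score-sorted output

    def test_empty(self):
        assert rotated_nms([], 0.5) == []

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(10):
            dets = [
                Detection(random_box(rng, 30, 4, 40), float(rng.uniform(0, 1)))
                for _ in range(50)
            ]
            mine = rotated_nms(dets, 0.35)
            ref = nms_bruteforce(dets, 0.35)
            assert [(d.score, d.box) for d in mine] == [(d.score, d.box) for d in ref]

    def test_survivor_pairwise_iou_bounded(self, rng):
        dets = [Detection(random_box(rng, 20, 4, 40), float(rng.uniform(0, 1)))
                for _ in range(40)]
        out = rotated_nms(dets, 0.3)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert polygon_iou(a.box, b.box) <= 0.3 + 1e-12
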