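import numpy as np
import pytest

from lassokit.generation import (
    LassoConformation,
    LoopConformation,
    build_lasso,
    sample_equilateral_polygon,
)
from lassokit.surface import (
    DegenerateSurfaceError,
    SurfaceParams,
    _fan_triangulation,
    classify_lasso,
    count_piercings,
    span_minimal_surface,
)

from conftest import make_square_loop, regular_polygon


def fan_area(pts):
    verts, tris = _fan_triangulation(pts)
    v = verts[tris]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    ).sum()


class TestSpanning:
    def test_planar_polygon_area_exact(self):
        """The minimal surface of a planar convex loop is the flat region."""
        n = 12
        r = 0.5 / np.sin(np.pi / n)
        loop = LoopConformation(regular_polygon(n, r))
        surf = span_minimal_surface(loop)
        exact = 0.5 * n * r * r * np.sin(2 * np.pi / n)
        assert abs(surf.area - exact) / exact < 1e-3

    def test_disk_area_of_64gon(self):
        """A fine regular polygon's spanning surface approaches the disk."""
        n = 64
        r = 3.0
        loop = span_minimal_surface(regular_polygon(n, r))
        assert abs(loop.area - np.pi * r * r) / (np.pi * r * r) < 0.02

    def test_area_below_fan_and_monotone(self, rng):
        for _ in range(5):
            loop = sample_equilateral_polygon(40, rng)
            surf = span_minimal_surface(loop)
            assert surf.area <= fan_area(loop.vertices) + 1e-9

    def test_mesh_is_disk(self, rng):
        loop = sample_equilateral_polygon(25, rng)
        surf = span_minimal_surface(loop)
        assert surf.euler_characteristic() == 1
        # boundary traces the loop: all loop vertices sit on the boundary
        bset = set(surf.boundary_loop.tolist())
        assert set(range(25)) <= bset

    def test_off_export_round_trip(self, tmp_path, rng):
        loop = sample_equilateral_polygon(12, rng)
        surf = span_minimal_surface(loop)
        path = tmp_path / "surf.off"
        surf.to_off(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        nv, nt, _ = (int(v) for v in lines[1].split())
        assert nv == surf.vertices.shape[0]
        assert nt == surf.triangles.shape[0]
        first_vertex = np.array([float(v) for v in lines[2].split()])
        np.testing.assert_allclose(first_vertex, surf.vertices[0], atol=1e-8)

    def test_degenerate_collinear_loop_raises(self):
        pts = np.stack([np.linspace(0, 1, 6), np.zeros(6), np.zeros(6)], axis=1)
        with pytest.raises(DegenerateSurfaceError):
            span_minimal_surface(pts)


class TestPiercings:
    def test_vertical_tail_one_crossing(self):
        surf = span_minimal_surface(make_square_loop())
        # tail leaves the anchor along the base, slides under the square,
        # and rises through (0.5, 0.5): exactly one upward crossing
        tail = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.5, 0.5, -0.75],
                [0.5, 0.5, 2.0],
            ]
        )
        rec = count_piercings(surf, tail, anchor_index=0)
        assert rec.totals == [1]
        assert rec.signed_sums == [1]

    def test_tail_above_plane_no_crossing(self):
        surf = span_minimal_surface(make_square_loop())
        tail = np.array(
            [[0.0, 0.0, 0.0], [0.3, 0.4, 0.8], [0.6, 0.2, 1.5], [2.0, 2.0, 2.0]]
        )
        rec = count_piercings(surf, tail, anchor_index=0)
        assert rec.totals == [0]

    def test_there_and_back_two_opposite_crossings(self):
        surf = span_minimal_surface(make_square_loop())
        tail = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.3, 0.3, -1.0],
                [0.7, 0.6, 1.0],
                [0.2, 0.6, 1.2],
                [0.25, 0.7, -1.0],
            ]
        )
        rec = count_piercings(surf, tail, anchor_index=0)
        assert rec.totals == [2]
        assert rec.signed_sums == [0]
        signs = [c[2] for c in rec.crossings[0]]
        assert sorted(signs) == [-1, 1]

    def test_non_finite_tail_rejected(self):
        surf = span_minimal_surface(make_square_loop())
        tail = np.array([[0.0, 0.0, 0.0], [np.nan, 0.0, 1.0]])
        with pytest.raises(ValueError):
            count_piercings(surf, tail, anchor_index=0)

    def test_crossings_sorted_by_arc_length(self, rng):
        loop = sample_equilateral_polygon(30, rng)
        lasso = build_lasso(loop, [30], rng)
        _, rec = classify_lasso(lasso)
        segs = [c[0] for c in rec.crossings[0]]
        assert segs == sorted(segs)


class TestClassification:
    def test_no_tails_is_trivial(self, rng):
        loop = sample_equilateral_polygon(10, rng)
        lasso = build_lasso(loop, [], rng)
        label, rec = classify_lasso(lasso)
        assert label.label == "L0"
        assert label.n_piercings_total == 0

    def test_single_pass_is_l1(self):
        loop = LoopConformation(make_square_loop())
        tail = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, -0.75], [0.5, 0.5, 2.0]])
        lasso = LassoConformation(loop, (tail,), (0,))
        label, _ = classify_lasso(lasso)
        assert label.label == "L1"

    def test_there_and_back_is_l2(self):
        loop = LoopConformation(make_square_loop())
        tail = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.3, 0.3, -1.0],
                [0.7, 0.6, 1.0],
                [0.2, 0.6, 1.2],
                [0.25, 0.7, -1.0],
            ]
        )
        lasso = LassoConformation(loop, (tail,), (0,))
        label, _ = classify_lasso(lasso)
        assert label.label == "L2"
        assert label.n_piercings_total == 2

    def test_rigid_motion_and_scaling_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        loop = sample_equilateral_polygon(20, rng)
        lasso = build_lasso(loop, [20], rng)
        label0, _ = classify_lasso(lasso)
        rot = Rotation.random(random_state=3).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        scale = 2.7
        loop2 = LoopConformation(
            scale * (lasso.loop.vertices @ rot.T) + shift, edge_length=scale
        )
        tail2 = scale * (lasso.tails[0] @ rot.T) + shift
        lasso2 = LassoConformation(loop2, (tail2,), (0,))
        label2, _ = classify_lasso(lasso2)
        assert label2.label == label0.label

    def test_tail_reversal_flips_signs_keeps_total(self):
        """Reversing the tail traversal direction flips every crossing
        sign but preserves the total crossing count."""
        loop = LoopConformation(make_square_loop())
        tail = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.3, 0.3, -1.0],
                [0.7, 0.6, 1.0],
                [0.2, 0.6, 1.2],
            ]
        )
        surf = span_minimal_surface(loop)
        fwd = count_piercings(surf, tail, anchor_index=0)
        rev = count_piercings(surf, tail[::-1].copy(), anchor_index=0)
        assert fwd.totals == rev.totals
        assert sorted(c[2] for c in fwd.crossings[0]) == sorted(
            -c[2] for c in rev.crossings[0]
        )

    def test_parity_invariant_under_refinement(self, rng):
        """For tails ending far from the loop, the per-tail crossing
        parity must not depend on the mesh refinement level."""
        checked = 0
        for i in range(10):
            loop = sample_equilateral_polygon(40, rng)
            lasso = build_lasso(loop, [40], rng)
            tail = lasso.tails[0]
            diam = np.ptp(loop.vertices, axis=0).max()
            if np.linalg.norm(tail[-1] - loop.vertices.mean(axis=0)) <= diam:
                continue
            coarse = span_minimal_surface(lasso.loop, SurfaceParams(max_triangles=600))
            fine = span_minimal_surface(lasso.loop, SurfaceParams(max_triangles=10000))
            rc = count_piercings(coarse, tail, 0)
            rf = count_piercings(fine, tail, 0)
            assert rc.totals[0] % 2 == rf.totals[0] % 2
            checked += 1
        assert checked >= 3

    def test_two_tail_label(self):
        loop = LoopConformation(make_square_loop())
        up = np.array([[0.0, 0.0, 0.0], [0.4, 0.4, -0.75], [0.4, 0.4, 2.0]])
        down = np.array([[0.0, 0.0, 0.0], [0.6, 0.6, 0.75], [0.6, 0.6, -2.0]])
        lasso = LassoConformation(loop, (up, down), (0, 0))
        label, rec = classify_lasso(lasso)
        assert label.label == "LL1,1"
        assert label.n_piercings_total == 2
        # parity of totals equals parity of signed sums, per tail
        for tot, sgn in zip(rec.totals, rec.signed_sums):
            assert tot % 2 == abs(sgn) % 2
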