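"""Converter correctness: anchoring vectors, centroid grouping, POI objects,
parallelepiped volumes and landmark affine recovery."""

import numpy as np
import pytest

from locarekit.core_model import Cylinder, LineString, Polyhedron, Sphere, validate_object
from locarekit.converters import (
    AffineTransform,
    CentroidRecord,
    LandmarkPair,
    QuickNIIAnchoring,
    apply_affine,
    estimate_affine,
    nutil_to_points,
    pois_to_spheres,
    quicknii_pixel_to_atlas,
    quicknii_to_polygon,
    track_to_cylinder,
    volume_to_polyhedron,
)
from locarekit.geometry import measure

from conftest import random_object


def _anchoring(o, u, v, w=100, h=80, sid="s1"):
    return QuickNIIAnchoring(sid, tuple(o), tuple(u), tuple(v), w, h)


class TestQuickNII:
    def test_axis_aligned_corners(self):
        poly = quicknii_to_polygon(_anchoring((0, 0, 0), (10, 0, 0), (0, 0, -8)))
        assert poly.coordinates == (
            (0, 0, 0), (10, 0, 0), (10, 0, -8), (0, 0, -8)
        )

    def test_far_corner_by_componentwise_addition(self):
        # independent oracle: far corner = o + u + v computed per component
        o, u, v = (1, 2, 3), (2, 0, 1), (0, 3, 0)
        expected_far = tuple(o[i] + u[i] + v[i] for i in range(3))
        assert expected_far == (3, 5, 4)
        poly = quicknii_to_polygon(_anchoring(o, u, v))
        assert poly.coordinates[2] == expected_far

    def test_always_four_triplets_and_parallelogram_closure(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            o, u, v = rng.normal(0, 10, (3, 3))
            poly = quicknii_to_polygon(_anchoring(o, u, v))
            c = np.asarray(poly.coordinates)
            assert c.shape == (4, 3)
            np.testing.assert_allclose(c[3] - c[2], c[0] - c[1], atol=1e-12)
            assert validate_object(poly) == []

    def test_degenerate_anchoring_rejected(self):
        with pytest.raises(ValueError, match="degenerate-anchoring"):
            quicknii_to_polygon(_anchoring((0, 0, 0), (1, 0, 0), (2, 0, 0)))

    def test_pixel_corners_map_onto_ring_vertices(self):
        a = _anchoring((1, 2, 3), (2, 0, 1), (0, 3, 0), w=64, h=32)
        ring = quicknii_to_polygon(a).coordinates
        corners = [(0, 0), (64, 0), (64, 32), (0, 32)]
        for px, expected in zip(corners, ring):
            assert quicknii_pixel_to_atlas(a, px) == expected

    def test_pixel_center_bilinear(self):
        a = _anchoring((0, 0, 0), (10, 0, 0), (0, 0, -8), w=100, h=80)
        assert quicknii_pixel_to_atlas(a, (50, 40)) == (5, 0, -4)

    def test_pixel_out_of_bounds_rejected(self):
        a = _anchoring((0, 0, 0), (10, 0, 0), (0, 0, -8))
        with pytest.raises(ValueError, match="outside image bounds"):
            quicknii_pixel_to_atlas(a, (101, 0))


class TestNutil:
    def test_ungrouped_concatenation(self):
        recs = [CentroidRecord(f"c{i}", (i, i, i)) for i in range(3)]
        pts = nutil_to_points(recs)
        assert len(pts) == 1 and len(pts[0].coordinates) == 3

    def test_group_by_region_label(self):
        # hash-partition oracle: labels A,A,B -> group sizes {A: 2, B: 1}
        recs = [
            CentroidRecord("1", (0, 0, 0), "A"),
            CentroidRecord("2", (1, 1, 1), "A"),
            CentroidRecord("3", (2, 2, 2), "B"),
        ]
        pts = nutil_to_points(recs, group_by="regionLabel")
        sizes = {p.properties.name: len(p.coordinates) for p in pts}
        assert sizes == {"A": 2, "B": 1}

    def test_every_centroid_appears_exactly_once(self):
        rng = np.random.default_rng(1)
        recs = [
            CentroidRecord(f"c{i}", tuple(rng.uniform(0, 100, 3)),
                           ["A", "B", "C"][i % 3])
            for i in range(30)
        ]
        pts = nutil_to_points(recs, group_by="regionLabel")
        emitted = [c for p in pts for c in p.coordinates]
        assert sorted(emitted) == sorted(tuple(r.centroid) for r in recs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no-records"):
            nutil_to_points([])


class TestPOIs:
    def test_seventeen_electrode_montage(self):
        centers = [(i, 2 * i, 90) for i in range(17)]
        spheres = pois_to_spheres(centers, 0.5)
        assert len(spheres) == 17
        assert all(isinstance(s, Sphere) and s.radius == 0.5 for s in spheres)
        assert [s.centroid for s in spheres] == [tuple(map(float, c)) for c in centers]

    def test_concentric_injection_core_shell(self):
        c = (40.0, 40.0, 40.0)
        spheres = pois_to_spheres([c, c], [2.0, 5.0])
        assert len(spheres) == 2
        assert spheres[0].centroid == spheres[1].centroid
        assert (spheres[0].radius, spheres[1].radius) == (2.0, 5.0)

    def test_empty_centers(self):
        assert pois_to_spheres([], 1.0) == []

    def test_nonpositive_radius_names_index(self):
        with pytest.raises(ValueError, match=r"radius\[1\]"):
            pois_to_spheres([(0, 0, 0), (1, 1, 1)], [1.0, -2.0])

    def test_track_with_radius_is_cylinder(self):
        cyl = track_to_cylinder([(0, 0, 0), (0, 0, -5)], radius=0.1)
        assert isinstance(cyl, Cylinder)
        assert measure(cyl)["length"] == 5.0

    def test_track_without_radius_is_linestring(self):
        ls = track_to_cylinder([(0, 0, 0), (0, 0, -5)])
        assert isinstance(ls, LineString) and len(ls.coordinates) == 2

    def test_sixteen_site_array_order_preserved(self):
        sites = [(0.0, 0.0, -float(i)) for i in range(16)]
        ls = track_to_cylinder(sites)
        assert len(ls.coordinates) == 16
        assert list(ls.coordinates) == sites

    def test_single_vertex_rejected(self):
        with pytest.raises(ValueError):
            track_to_cylinder([(0, 0, 0)])


class TestVolumeToPolyhedron:
    def test_unit_cube(self):
        cube = volume_to_polyhedron((0, 0, 0), np.eye(3))
        assert len(cube.vertices) == 8 and len(cube.faces) == 6
        m = measure(cube)
        assert m["volume"] == pytest.approx(1.0, rel=1e-12)
        assert m["area"] == pytest.approx(6.0, rel=1e-12)

    def test_sheared_volume_matches_determinant(self):
        edges = ((2, 0, 0), (1, 3, 0), (0, 0, 4))
        # determinant oracle, computed by cofactor expansion: 2*(3*4) = 24
        assert abs(np.linalg.det(edges)) == pytest.approx(24.0, rel=1e-14)
        poly = volume_to_polyhedron((5, 5, 5), edges)
        assert measure(poly)["volume"] == pytest.approx(24.0, rel=1e-12)

    def test_random_parallelepipeds_closed_and_det_volume(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            E = rng.normal(0, 5, (3, 3))
            if abs(np.linalg.det(E)) < 0.5:
                continue
            poly = volume_to_polyhedron(rng.normal(0, 10, 3), E)
            assert validate_object(poly) == []
            assert measure(poly)["volume"] == pytest.approx(
                abs(np.linalg.det(E)), rel=1e-12
            )

    def test_volume_cross_checked_against_trimesh(self):
        trimesh = pytest.importorskip("trimesh")
        edges = ((2, 0, 0), (1, 3, 0), (0, 1, 4))
        poly = volume_to_polyhedron((0, 0, 0), edges)
        from locarekit.geometry import tessellate

        mesh = tessellate(poly)
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
        assert tm.is_watertight
        assert measure(poly)["volume"] == pytest.approx(tm.volume, rel=1e-9)

    def test_degenerate_edges_rejected(self):
        with pytest.raises(ValueError, match="degenerate-volume"):
            volume_to_polyhedron((0, 0, 0), ((1, 0, 0), (2, 0, 0), (0, 0, 1)))


def _random_affine(rng):
    M = rng.normal(0, 1, (3, 3))
    while abs(np.linalg.det(M)) < 0.2:
        M = rng.normal(0, 1, (3, 3))
    return M, rng.normal(0, 10, 3)


class TestEstimateAffine:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        M, t = _random_affine(rng)
        S = rng.uniform(-10, 10, (10, 3))
        pairs = [LandmarkPair(tuple(s), tuple(M @ s + t)) for s in S]
        T = estimate_affine(pairs)
        np.testing.assert_allclose(T.matrix, M, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-9)
        assert T.rmsResidual < 1e-9

    def test_identity_tetrahedron(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        T = estimate_affine([LandmarkPair(p, p) for p in pts])
        np.testing.assert_allclose(T.matrix, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_four_noncoplanar_pairs_exact(self):
        rng = np.random.default_rng(4)
        M, t = _random_affine(rng)
        S = np.array([(0, 0, 0), (3, 0, 0), (0, 4, 0), (1, 1, 5)], float)
        pairs = [LandmarkPair(tuple(s), tuple(M @ s + t)) for s in S]
        T = estimate_affine(pairs)
        assert T.rmsResidual < 1e-9

    def test_noise_residual_matches_sigma(self):
        """With Gaussian noise sigma=0.1 on targets the RMS residual is a
        consistent noise estimate: within [0.5, 1.5] x sigma per seed, and
        the fit equals the normal-equations solution."""
        sigma = 0.1
        for seed in range(100):
            rng = np.random.default_rng(seed)
            M, t = _random_affine(rng)
            S = rng.uniform(-10, 10, (50, 3))
            T_clean = S @ M.T + t
            noisy = T_clean + rng.normal(0, sigma, T_clean.shape)
            fit = estimate_affine(
                [LandmarkPair(tuple(s), tuple(y)) for s, y in zip(S, noisy)]
            )
            assert 0.5 * sigma <= fit.rmsResidual <= 1.5 * sigma
            # normal-equations oracle
            A = np.hstack([S, np.ones((50, 1))])
            X = np.linalg.solve(A.T @ A, A.T @ noisy)
            np.testing.assert_allclose(fit.matrix, X[:3].T, atol=1e-8)

    def test_coplanar_sources_rejected(self):
        pts = [(i, j, 0.0) for i in range(2) for j in range(3)]
        with pytest.raises(ValueError, match="rank-deficient-landmarks"):
            estimate_affine([LandmarkPair(p, p) for p in pts])


class TestApplyAffine:
    def test_identity_leaves_object_unchanged(self, props):
        T = AffineTransform(np.eye(3), np.zeros(3))
        s = Sphere((1.0, 1.0, 1.0), 2.0, props)
        assert apply_affine(T, s) == s

    def test_translation_preserves_radius(self, props):
        T = AffineTransform(np.eye(3), (0, 0, 10))
        out = apply_affine(T, Sphere((1.0, 1.0, 1.0), 2.0, props))
        assert out.centroid == (1, 1, 11) and out.radius == 2.0

    def test_uniform_scale_scales_radius(self, props):
        T = AffineTransform(2 * np.eye(3), np.zeros(3))
        out = apply_affine(T, Sphere((0.0, 0.0, 0.0), 1.0, props))
        assert out.radius == pytest.approx(2.0)  # cbrt(det(2I)) = 2

    def test_volume_scales_by_det(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            M, t = _random_affine(rng)
            T = AffineTransform(M, t)
            poly = random_object(rng, kind="polyhedron")
            v0 = measure(poly)["volume"]
            v1 = measure(apply_affine(T, poly))["volume"]
            assert v1 == pytest.approx(abs(np.linalg.det(M)) * v0, rel=1e-6)

    def test_atlas_mesh_not_transformable(self, props):
        from locarekit.core_model import AtlasMeshRef

        T = AffineTransform(np.eye(3), np.zeros(3))
        with pytest.raises(TypeError, match="not-transformable"):
            apply_affine(T, AtlasMeshRef("toy:region/000", "r", props))

    def test_registration_pipeline_recovers_targets_as_noise_vanishes(self):
        """estimate_affine composed with apply_affine reproduces simulated
        target points with RMS error shrinking to zero with the noise."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            M, t = _random_affine(rng)
            S = rng.uniform(-8, 8, (30, 3))
            errors = []
            for sigma in (0.1, 0.0):
                noisy = S @ M.T + t + rng.normal(0, sigma, (30, 3))
                fit = estimate_affine(
                    [LandmarkPair(tuple(s), tuple(y)) for s, y in zip(S, noisy)]
                )
                pred = fit(S)
                errors.append(
                    float(np.sqrt(np.mean(np.sum((pred - (S @ M.T + t)) ** 2, axis=1))))
                )
            assert errors[1] < 1e-9 and errors[1] <= errors[0]
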