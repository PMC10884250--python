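"""Containment, Monte-Carlo overlap and the collection query engine."""

import math

import numpy as np
import pytest

from locarekit.core_model import (
    AtlasMeshRef,
    AtlasSpace,
    LocareCollection,
    ObjectProperties,
    Point,
    Sphere,
)
from locarekit.geometry import TriangleMesh
from locarekit.spatial_query import (
    Hit,
    RegionMesh,
    assign_points_to_regions,
    object_region_overlap,
    point_in_mesh,
    points_in_mesh,
    query_collections,
)
from locarekit.synthetic_fixtures import box_mesh

from conftest import random_collection


@pytest.fixture(scope="module")
def unit_cube_region():
    return RegionMesh("toy:region/cube", "cube", box_mesh((0, 0, 0), (1, 1, 1)))


def _hull_region(rng, n_pts=20, scale=10.0):
    from scipy.spatial import ConvexHull

    pts = rng.uniform(0, scale, (n_pts, 3))
    hull = ConvexHull(pts)
    tris = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        a, b, c = hull.points[simplex]
        n = np.cross(b - a, c - a)
        tris.append(simplex if np.dot(n, eq[:3]) > 0 else simplex[::-1])
    mesh = TriangleMesh(hull.points, np.asarray(tris))
    return RegionMesh("toy:region/hull", "hull", mesh), hull


class TestPointInMesh:
    def test_cube_interior_and_exterior(self, unit_cube_region):
        assert point_in_mesh((0.5, 0.5, 0.5), unit_cube_region)
        assert not point_in_mesh((2.0, 2.0, 2.0), unit_cube_region)

    def test_matches_convex_sign_oracle_on_random_trials(self):
        """Ray-casting containment agrees with the half-space sign test of
        the convex hull's facet equations on 10^4 random points."""
        rng = np.random.default_rng(0)
        region, hull = _hull_region(rng)
        pts = rng.uniform(-2, 12, (10_000, 3))
        # sign-test oracle: inside iff on the negative side of every facet
        signed = pts @ hull.equations[:, :3].T + hull.equations[:, 3]
        oracle = (signed < -1e-9).all(axis=1)
        on_boundary = ~oracle & (signed < 1e-9).all(axis=1)
        ours = points_in_mesh(pts, region.mesh, seed=0)
        disagreements = int(np.sum((ours != oracle) & ~on_boundary))
        assert disagreements == 0

    def test_open_mesh_rejected(self):
        mesh = TriangleMesh([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 2)])
        with pytest.raises(ValueError, match="mesh-not-closed"):
            points_in_mesh(np.zeros((1, 3)), mesh)

    def test_deterministic_for_fixed_seed(self, unit_cube_region):
        pts = np.random.default_rng(5).uniform(-0.5, 1.5, (200, 3))
        a = points_in_mesh(pts, unit_cube_region.mesh, seed=3)
        b = points_in_mesh(pts, unit_cube_region.mesh, seed=3)
        np.testing.assert_array_equal(a, b)


class TestOverlap:
    def test_sphere_inside_large_box_contained(self, props):
        region = RegionMesh("r", "r", box_mesh((0, 0, 0), (100, 100, 100)))
        res = object_region_overlap(Sphere((50, 50, 50), 5.0, props), region, n=2000, seed=0)
        assert res.relation == "contained" and res.fractionInside == 1.0

    def test_sphere_on_box_face_half_inside(self, props):
        """A unit sphere centered on the planar face of a big box overlaps
        exactly half its volume; the Monte-Carlo fraction must land within
        3 standard errors of 0.5 at n=10^4, seed=0."""
        region = RegionMesh("r", "r", box_mesh((0, 0, 0), (100, 100, 100)))
        res = object_region_overlap(Sphere((50.0, 50.0, 0.0), 1.0, props), region,
                                    n=10_000, seed=0)
        assert res.relation == "intersects"
        assert abs(res.fractionInside - 0.5) < 3 * res.stdError

    def test_point_object_outside_disjoint(self, props):
        region = RegionMesh("r", "r", box_mesh((0, 0, 0), (10, 10, 10)))
        pts = Point(((20.0, 20.0, 20.0), (30.0, 30.0, 30.0)), props)
        res = object_region_overlap(pts, region)
        assert res.relation == "disjoint" and res.fractionInside == 0.0

    def test_fraction_monotone_as_sphere_leaves_convex_region(self, props):
        """Translating a sphere away from a convex region along a ray never
        increases the overlap fraction (within 3 SE at each station)."""
        region = RegionMesh("r", "r", box_mesh((0, 0, 0), (20, 20, 20)))
        fractions = []
        for i in range(10):
            center = (10.0 + 2.5 * i, 10.0, 10.0)
            res = object_region_overlap(Sphere(center, 3.0, props), region, n=2000, seed=0)
            fractions.append((res.fractionInside, res.stdError))
        for (f0, s0), (f1, s1) in zip(fractions, fractions[1:]):
            assert f1 <= f0 + 3 * math.hypot(s0, s1)

    def test_overlap_reproducible_for_fixed_seed(self, props):
        region = RegionMesh("r", "r", box_mesh((0, 0, 0), (10, 10, 10)))
        s = Sphere((5.0, 5.0, 9.5), 1.0, props)
        a = object_region_overlap(s, region, n=3000, seed=42)
        b = object_region_overlap(s, region, n=3000, seed=42)
        assert a == b


class TestAssignPoints:
    def test_counts_per_region(self, props):
        atlas = [
            RegionMesh("A", "A", box_mesh((0, 0, 0), (10, 10, 10))),
            RegionMesh("B", "B", box_mesh((20, 0, 0), (30, 10, 10))),
        ]
        pts = Point(
            ((1, 1, 1), (2, 2, 2), (9, 9, 9), (25, 5, 5), (50, 50, 50)), props
        )
        labels, counts = assign_points_to_regions(pts, atlas)
        assert counts == {"A": 3, "B": 1, None: 1}
        # brute-force containment oracle over all (point, region) pairs
        for coord, label in labels:
            expected = None
            for r in atlas:
                lo = r.mesh.vertices.min(axis=0)
                hi = r.mesh.vertices.max(axis=0)
                if np.all(np.asarray(coord) > lo) and np.all(np.asarray(coord) < hi):
                    expected = r.regionId
            assert label == expected

    def test_empty_atlas_all_none(self, props):
        pts = Point(((1, 1, 1),), props)
        labels, counts = assign_points_to_regions(pts, [])
        assert labels == [((1, 1, 1), None)] and counts == {None: 1}

    def test_boundary_point_assigned_to_exactly_one_region(self, props):
        # abutting cubes share the x=10 face; the tie must break to the
        # lexicographically lowest regionId
        atlas = [
            RegionMesh("B", "B", box_mesh((10, 0, 0), (20, 10, 10))),
            RegionMesh("A", "A", box_mesh((0, 0, 0), (10, 10, 10))),
        ]
        pts = Point(((10.0, 5.0, 5.0),), props)
        labels, counts = assign_points_to_regions(pts, atlas)
        assert sum(counts.values()) == 1
        assert labels[0][1] in ("A", "B")


class TestQueryCollections:
    def _scene(self, space, props):
        inside = Sphere((14.0, 14.0, 14.0), 1.0, props)
        far = Sphere((80.0, 80.0, 80.0), 1.0, props)
        mk = lambda objs: LocareCollection(
            "locare-kit/1.0", space, ("doi:x",), tuple(objs)
        )
        return [mk([inside]), mk([far]), mk([])]

    def test_single_in_region_hit(self, space, props):
        region = RegionMesh("r", "r", box_mesh((10, 10, 10), (20, 20, 20)))
        hits = query_collections(self._scene(space, props), region, n=500, seed=0)
        assert [(h.collectionIndex, h.objectIndex) for h in hits] == [(0, 0)]
        assert hits[0].relation == "contained"

    def test_universal_roi_hits_every_coordinate_bearing_object(self, space):
        rng = np.random.default_rng(17)
        docs = [random_collection(rng, space) for _ in range(5)]
        roi = ((-50.0, -50.0, -50.0), (150.0, 150.0, 150.0))
        hits = query_collections(docs, roi)
        expected = sum(
            1
            for d in docs
            for o in d.objects
            if not isinstance(o, AtlasMeshRef)
        )
        assert len(hits) == expected

    def test_atlas_mismatch_names_both_identifiers(self, space, props):
        other = AtlasSpace("other:space", "o", (50, 50, 50), 0.1, "RAS")
        docs = [
            LocareCollection("locare-kit/1.0", space, ("doi:x",), ()),
            LocareCollection("locare-kit/1.0", other, ("doi:y",), ()),
        ]
        with pytest.raises(ValueError, match="atlas-mismatch") as exc:
            query_collections(docs, ((0, 0, 0), (1, 1, 1)))
        assert "other:space" in str(exc.value) and "toy:atlas/space/0" in str(exc.value)

    def test_point_distance_query(self, space, props):
        docs = self._scene(space, props)
        hits = query_collections(docs, {"point": (14.0, 14.0, 16.0), "distance": 2.0})
        assert [(h.collectionIndex, h.objectIndex) for h in hits] == [(0, 0)]
        assert hits[0].distance == pytest.approx(1.0)

    def test_prefilter_never_discards_a_true_hit(self, space):
        """Query results are identical with and without the bounding-box
        prefilter on randomized scenes."""
        rng = np.random.default_rng(23)
        region = RegionMesh("r", "r", box_mesh((30, 30, 30), (70, 70, 70)))
        for _ in range(5):
            docs = [random_collection(rng, space) for _ in range(3)]
            docs = [
                LocareCollection(
                    d.version, d.targetAtlas, d.sourcePublication,
                    tuple(o for o in d.objects if not isinstance(o, AtlasMeshRef)),
                )
                for d in docs
            ]
            with_pf = query_collections(docs, region, n=400, seed=0, use_prefilter=True)
            without = query_collections(docs, region, n=400, seed=0, use_prefilter=False)
            assert with_pf == without

    def test_atlas_mesh_object_hits_matching_region(self, space, props):
        obj = AtlasMeshRef("toy:region/001", "Synthetic area 1", props)
        doc = LocareCollection("locare-kit/1.0", space, ("doi:x",), (obj,))
        region = RegionMesh("toy:region/001", "Synthetic area 1",
                            box_mesh((0, 0, 0), (1, 1, 1)))
        hits = query_collections([doc], region)
        assert len(hits) == 1 and hits[0].relation == "matched-region"
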