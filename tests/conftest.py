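"""Shared fixtures: a toy atlas, object properties, and seeded random
generators for valid geometric objects and collections."""

from __future__ import annotations

import numpy as np
import pytest

from locarekit import DIALECT_VERSION
from locarekit.core_model import (
    AtlasMeshRef,
    AtlasSpace,
    Cylinder,
    LineString,
    LocareCollection,
    ObjectProperties,
    Point,
    Polygon,
    Polyhedron,
    Sphere,
)
from locarekit.converters import volume_to_polyhedron
from locarekit.synthetic_fixtures import make_atlas


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(n_regions=8, dims=(100, 100, 100), seed=0)


@pytest.fixture
def props():
    return ObjectProperties(name="obj", description="test object")


@pytest.fixture(scope="session")
def space():
    return AtlasSpace(
        identifier="toy:atlas/space/0",
        name="test space",
        dimensions=(100, 100, 100),
        resolution=0.05,
        orientation="RAS",
    )


def random_object(rng: np.random.Generator, kind: str | None = None):
    """One random valid geometric object of the requested (or random) kind."""
    kinds = ("point", "sphere", "lineString", "cylinder", "polygon", "polyhedron", "atlasMesh")
    kind = kind or kinds[rng.integers(len(kinds))]
    props = ObjectProperties(
        name=f"rnd-{rng.integers(1_000_000)}", description="randomized object"
    )
    center = rng.uniform(20, 80, size=3)
    if kind == "point":
        n = int(rng.integers(1, 6))
        return Point(tuple(tuple(map(float, center + rng.normal(0, 3, 3))) for _ in range(n)), props)
    if kind == "sphere":
        return Sphere(tuple(map(float, center)), float(rng.uniform(0.5, 5)), props)
    if kind == "lineString":
        n = int(rng.integers(2, 6))
        pts = center + np.cumsum(rng.uniform(0.5, 2, size=(n, 3)), axis=0)
        return LineString(tuple(tuple(map(float, p)) for p in pts), props)
    if kind == "cylinder":
        n = int(rng.integers(2, 4))
        pts = center + np.cumsum(rng.uniform(0.5, 3, size=(n, 3)), axis=0)
        return Cylinder(tuple(tuple(map(float, p)) for p in pts), float(rng.uniform(0.3, 2)), props)
    if kind == "polygon":
        # planar convex ring: random frame, random radii around a circle
        u, v = _random_frame(rng)
        n = int(rng.integers(3, 8))
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n))
        rad = rng.uniform(2, 8)
        pts = [center + rad * (np.cos(a) * u + np.sin(a) * v) for a in ang]
        return Polygon(tuple(tuple(map(float, p)) for p in pts), props)
    if kind == "polyhedron":
        E = rng.uniform(-6, 6, size=(3, 3))
        while abs(np.linalg.det(E)) < 1.0:
            E = rng.uniform(-6, 6, size=(3, 3))
        poly = volume_to_polyhedron(center, E)
        return Polyhedron(poly.vertices, poly.faces, props)
    return AtlasMeshRef(f"toy:region/{int(rng.integers(8)):03d}", "Synthetic area", props)


def _random_frame(rng):
    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    helper = np.array([1.0, 0, 0]) if abs(w[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def random_collection(rng: np.random.Generator, space: AtlasSpace) -> LocareCollection:
    n = int(rng.integers(0, 6))
    return LocareCollection(
        version=DIALECT_VERSION,
        targetAtlas=space,
        sourcePublication=(f"doi:10.0000/rnd-{rng.integers(10_000)}",),
        relatedPublications=("doi:10.0000/related",) if rng.random() < 0.3 else None,
        linkedURI="https://example.org/viewer" if rng.random() < 0.3 else None,
        objects=tuple(random_object(rng) for _ in range(n)),
    )
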