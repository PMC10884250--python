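"""Domain types for atlas spaces, geometric objects and the collection envelope.

All coordinates are continuous 0-based voxel coordinates of the target atlas
volume; radii and lengths share those units, and millimetres are obtained by
multiplying with ``AtlasSpace.resolution``. Validation is data, not
exceptions: :func:`validate_object` and :func:`validate_collection` return
lists of :class:`Violation` records so that malformed files can be reported
field by field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "AtlasSpace",
    "ObjectProperties",
    "Point",
    "Sphere",
    "LineString",
    "Cylinder",
    "Polygon",
    "Polyhedron",
    "AtlasMeshRef",
    "GeometricObject",
    "LocareCollection",
    "Violation",
    "validate_object",
    "validate_collection",
    "bounding_box",
    "OBJECT_TYPE_NAMES",
]

# Relative planarity tolerance for polygon rings: max out-of-plane distance
# must not exceed EPS_PLANE times the longest edge.
EPS_PLANE = 1e-6

# Out-of-bounds margin as a fraction of the largest atlas dimension;
# slightly-outside coordinates (e.g. skull-surface electrodes) are warnings.
BOUNDS_MARGIN_FRACTION = 0.05

#: JSON ``type`` discriminator for each variant.
OBJECT_TYPE_NAMES = (
    "point",
    "sphere",
    "lineString",
    "cylinder",
    "polygon",
    "polyhedron",
    "atlasMesh",
)

_AXIS_PAIRS = {"L": "LR", "R": "LR", "A": "AP", "P": "AP", "S": "SI", "I": "SI"}


@dataclass(frozen=True)
class Violation:
    """One validation failure: field, broken rule and offending value."""

    field: str
    rule: str
    value: object = None
    severity: str = "error"  # "error" or "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (got {self.value!r})"


@dataclass(frozen=True)
class AtlasSpace:
    """Declaration of the target atlas coordinate system.

    Parameters
    ----------
    identifier
        Opaque URI of the common coordinate space version (treated as a
        string; never resolved against any service).
    name
        Human-readable atlas name.
    dimensions
        Voxel counts per axis (three positive integers).
    resolution
        Isotropic voxel size in millimetres per voxel.
    orientation
        Three-letter axis code, one letter per axis drawn from the pairs
        L/R, A/P, S/I with no axis pair repeated (e.g. ``"RAS"``, ``"LIP"``).
    origin
        Coordinate triplet of the anatomical origin in continuous voxel
        units.
    """

    identifier: str
    name: str
    dimensions: tuple[int, int, int]
    resolution: float
    orientation: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> list[Violation]:
        v: list[Violation] = []
        if not self.identifier:
            v.append(Violation("targetAtlas.identifier", "empty", self.identifier))
        dims = tuple(self.dimensions)
        if len(dims) != 3 or any(
            (not _is_finite_number(d)) or int(d) != d or d < 1 for d in dims
        ):
            v.append(Violation("targetAtlas.dimensions", "three integers >= 1", dims))
        if not _is_finite_number(self.resolution) or self.resolution <= 0:
            v.append(Violation("targetAtlas.resolution", "must be > 0", self.resolution))
        v.extend(_check_orientation(self.orientation))
        if not _is_triplet(self.origin):
            v.append(Violation("targetAtlas.origin", "not a finite triplet", self.origin))
        return v


def _check_orientation(code: str) -> list[Violation]:
    if not isinstance(code, str) or len(code) != 3:
        return [Violation("targetAtlas.orientation", "must be a 3-letter code", code)]
    pairs = []
    for ch in code.upper():
        pair = _AXIS_PAIRS.get(ch)
        if pair is None:
            return [Violation("targetAtlas.orientation", f"unknown axis letter {ch!r}", code)]
        pairs.append(pair)
    if len(set(pairs)) != 3:
        return [Violation("targetAtlas.orientation", "repeated axis pair", code)]
    return []


@dataclass(frozen=True)
class ObjectProperties:
    """Provenance carried by every geometric object.

    ``name`` identifies the subject/file/file-group; ``description`` states
    what the geometry represents; ``linkedURI`` optionally points at the
    original data resource (opaque string).
    """

    name: str
    description: str
    linkedURI: Optional[str] = None
    extra: dict = field(default_factory=dict, compare=True, hash=False)

    def validate(self) -> list[Violation]:
        v = []
        if not isinstance(self.name, str) or not self.name:
            v.append(Violation("name", "empty", self.name))
        if not isinstance(self.description, str) or not self.description:
            v.append(Violation("description", "empty", self.description))
        return v


@dataclass(frozen=True)
class Point:
    """One or more coordinate triplets representing a group of POIs."""

    coordinates: tuple[tuple[float, float, float], ...]
    properties: ObjectProperties

    type_name = "point"


@dataclass(frozen=True)
class Sphere:
    """A centroid plus radius, e.g. an electrode or injection-site extent."""

    centroid: tuple[float, float, float]
    radius: float
    properties: ObjectProperties

    type_name = "sphere"


@dataclass(frozen=True)
class LineString:
    """Ordered polyline of two or more distinct consecutive vertices."""

    coordinates: tuple[tuple[float, float, float], ...]
    properties: ObjectProperties

    type_name = "lineString"


@dataclass(frozen=True)
class Cylinder:
    """A line-string axis swept by a circular cross-section of given radius."""

    axis: tuple[tuple[float, float, float], ...]
    radius: float
    properties: ObjectProperties

    type_name = "cylinder"


@dataclass(frozen=True)
class Polygon:
    """A planar ring of three or more corners; first vertex not repeated."""

    coordinates: tuple[tuple[float, float, float], ...]
    properties: ObjectProperties

    type_name = "polygon"


@dataclass(frozen=True)
class Polyhedron:
    """Closed oriented surface given by vertices and polygonal faces."""

    vertices: tuple[tuple[float, float, float], ...]
    faces: tuple[tuple[int, ...], ...]
    properties: ObjectProperties

    type_name = "polyhedron"


@dataclass(frozen=True)
class AtlasMeshRef:
    """Reference to a named atlas parcellation region by URI.

    The geometry lives in the atlas release, not in the file; spatial
    operations resolve ``parcellationEntityVersion`` through a caller-supplied
    region-mesh lookup.
    """

    parcellationEntityVersion: str
    regionName: str
    properties: ObjectProperties

    type_name = "atlasMesh"


GeometricObject = Union[
    Point, Sphere, LineString, Cylinder, Polygon, Polyhedron, AtlasMeshRef
]


@dataclass(frozen=True)
class LocareCollection:
    """File-level envelope binding objects to an atlas space and sources."""

    version: str
    targetAtlas: AtlasSpace
    sourcePublication: tuple[str, ...]
    objects: tuple[GeometricObject, ...] = ()
    relatedPublications: Optional[tuple[str, ...]] = None
    linkedURI: Optional[str] = None


# ---------------------------------------------------------------------------
# validation helpers


def _is_finite_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and math.isfinite(x)


def _is_triplet(t) -> bool:
    try:
        return len(t) == 3 and all(_is_finite_number(c) for c in t)
    except TypeError:
        return False


def _check_triplets(coords, fieldname: str, min_count: int) -> list[Violation]:
    v: list[Violation] = []
    try:
        n = len(coords)
    except TypeError:
        return [Violation(fieldname, "not a sequence of triplets", coords)]
    if n < min_count:
        word = "two" if min_count == 2 else str(min_count)
        v.append(Violation(fieldname, f"fewer than {word} triplets", n))
    for i, t in enumerate(coords):
        if not _is_triplet(t):
            v.append(Violation(f"{fieldname}[{i}]", "not a finite triplet", t))
    return v


def _check_distinct_consecutive(coords, fieldname: str) -> list[Violation]:
    v = []
    for i in range(len(coords) - 1):
        if _is_triplet(coords[i]) and _is_triplet(coords[i + 1]):
            if tuple(coords[i]) == tuple(coords[i + 1]):
                v.append(
                    Violation(
                        f"{fieldname}[{i}]",
                        "consecutive duplicate vertex (zero-length segment)",
                        tuple(coords[i]),
                    )
                )
    return v


def _check_polygon_geometry(coords) -> list[Violation]:
    """Planarity within EPS_PLANE x longest edge, and no self-intersection."""
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    v: list[Violation] = []
    edges = pts - np.roll(pts, 1, axis=0)
    longest = float(np.max(np.linalg.norm(edges, axis=1)))
    if longest == 0.0:
        return [Violation("coordinates", "degenerate ring (zero extent)", n)]
    centered = pts - pts.mean(axis=0)
    # best-fit plane normal = smallest singular vector
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    out_of_plane = float(np.max(np.abs(centered @ normal)))
    if out_of_plane > EPS_PLANE * longest:
        v.append(
            Violation(
                "coordinates",
                "vertices not coplanar within tolerance",
                out_of_plane / longest,
            )
        )
        return v  # 2D intersection test meaningless off-plane
    # project to the plane and test ring simplicity
    basis = vt[:2]
    p2 = centered @ basis.T
    if _ring_self_intersects(p2):
        v.append(Violation("coordinates", "ring self-intersects in its plane", n))
    return v


def _segments_properly_intersect(a, b, c, d) -> bool:
    def cross(o, p, q):
        return (p[0] - o[0]) * (q[1] - o[1]) - (p[1] - o[1]) * (q[0] - o[0])

    d1, d2 = cross(c, d, a), cross(c, d, b)
    d3, d4 = cross(a, b, c), cross(a, b, d)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _ring_self_intersects(p2: np.ndarray) -> bool:
    n = len(p2)
    for i in range(n):
        a, b = p2[i], p2[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # adjacent edges share a vertex
            c, d = p2[j], p2[(j + 1) % n]
            if _segments_properly_intersect(a, b, c, d):
                return True
    return False


def _check_polyhedron_topology(vertices, faces) -> list[Violation]:
    """Closed + consistently oriented: each directed edge used exactly once."""
    v: list[Violation] = []
    nv = len(vertices)
    if nv < 4:
        v.append(Violation("vertices", "fewer than 4 vertices", nv))
    directed: dict[tuple[int, int], int] = {}
    for fi, f in enumerate(faces):
        if len(f) < 3:
            v.append(Violation(f"faces[{fi}]", "face with fewer than 3 indices", len(f)))
            continue
        bad = [i for i in f if not (isinstance(i, (int, np.integer)) and 0 <= i < nv)]
        if bad:
            v.append(Violation(f"faces[{fi}]", "vertex index out of range", bad))
            continue
        for k in range(len(f)):
            e = (int(f[k]), int(f[(k + 1) % len(f)]))
            directed[e] = directed.get(e, 0) + 1
    if v:
        return v
    # closure: every undirected edge on exactly 2 faces, once per direction
    for (a, b), cnt in directed.items():
        if cnt != 1 or directed.get((b, a), 0) != 1:
            v.append(
                Violation(
                    "faces",
                    "surface not closed or inconsistently oriented",
                    (a, b),
                )
            )
            return v
    vol = _signed_volume(np.asarray(vertices, float), faces)
    if vol <= 0:
        if abs(vol) > 0:
            v.append(Violation("faces", "faces oriented inward (negative volume)", vol))
        else:
            v.append(Violation("vertices", "enclosed volume is zero", vol))
    return v


def _signed_volume(verts: np.ndarray, faces) -> float:
    """Divergence-theorem signed volume over fan-triangulated faces."""
    total = 0.0
    for f in faces:
        for k in range(1, len(f) - 1):
            a, b, c = verts[f[0]], verts[f[k]], verts[f[k + 1]]
            total += np.dot(a, np.cross(b, c))
    return float(total) / 6.0


# ---------------------------------------------------------------------------
# public operations


def validate_object(obj: GeometricObject) -> list[Violation]:
    """Check one geometric object against the dialect's type invariants.

    Returns an empty list iff the object is valid. Violations are plain
    data (field, rule, value) and never exceptions, so a file full of
    problems can be reported in one pass.
    """
    v: list[Violation] = []
    if isinstance(obj, Point):
        v += _check_triplets(obj.coordinates, "coordinates", 1)
    elif isinstance(obj, Sphere):
        if not _is_triplet(obj.centroid):
            v.append(Violation("centroid", "not a finite triplet", obj.centroid))
        if not _is_finite_number(obj.radius) or obj.radius <= 0:
            v.append(Violation("radius", "must be > 0", obj.radius))
    elif isinstance(obj, LineString):
        v += _check_triplets(obj.coordinates, "coordinates", 2)
        v += _check_distinct_consecutive(obj.coordinates, "coordinates")
    elif isinstance(obj, Cylinder):
        v += _check_triplets(obj.axis, "axis", 2)
        v += _check_distinct_consecutive(obj.axis, "axis")
        if not _is_finite_number(obj.radius) or obj.radius <= 0:
            v.append(Violation("radius", "must be > 0", obj.radius))
    elif isinstance(obj, Polygon):
        v += _check_triplets(obj.coordinates, "coordinates", 3)
        if not v:
            v += _check_polygon_geometry(obj.coordinates)
    elif isinstance(obj, Polyhedron):
        tv = _check_triplets(obj.vertices, "vertices", 4)
        v += tv
        if not tv:
            v += _check_polyhedron_topology(obj.vertices, obj.faces)
    elif isinstance(obj, AtlasMeshRef):
        if not obj.parcellationEntityVersion:
            v.append(
                Violation(
                    "parcellationEntityVersion", "empty", obj.parcellationEntityVersion
                )
            )
    else:
        v.append(Violation("type", "unknown object variant", type(obj).__name__))
        return v
    v += obj.properties.validate()
    return v


def object_coordinates(obj: GeometricObject) -> np.ndarray:
    """All coordinate triplets carried by a coordinate-bearing object."""
    if isinstance(obj, Point) or isinstance(obj, LineString):
        return np.asarray(obj.coordinates, float).reshape(-1, 3)
    if isinstance(obj, Sphere):
        return np.asarray([obj.centroid], float)
    if isinstance(obj, Cylinder):
        return np.asarray(obj.axis, float).reshape(-1, 3)
    if isinstance(obj, Polygon):
        return np.asarray(obj.coordinates, float).reshape(-1, 3)
    if isinstance(obj, Polyhedron):
        return np.asarray(obj.vertices, float).reshape(-1, 3)
    raise TypeError(f"{type(obj).__name__} carries no coordinates")


def validate_collection(c: LocareCollection) -> list[Violation]:
    """Envelope + per-object validation, objects tagged by index.

    Coordinates outside the atlas volume (beyond a margin of
    ``BOUNDS_MARGIN_FRACTION x max(dimensions)``) produce *warnings*, not
    errors: slightly-outside data such as skull-surface electrodes are
    legitimate.
    """
    v: list[Violation] = []
    if not isinstance(c.version, str) or not c.version:
        v.append(Violation("version", "missing or empty", c.version))
    v += c.targetAtlas.validate()
    if not c.sourcePublication or len(c.sourcePublication) == 0:
        v.append(Violation("sourcePublication", "empty", c.sourcePublication))
    dims = np.asarray(c.targetAtlas.dimensions, float)
    margin = BOUNDS_MARGIN_FRACTION * float(np.max(dims)) if dims.size == 3 else 0.0
    for i, obj in enumerate(c.objects):
        for viol in validate_object(obj):
            v.append(
                Violation(
                    f"objects[{i}].{viol.field}", viol.rule, viol.value, viol.severity
                )
            )
        if not isinstance(obj, AtlasMeshRef) and not any(
            viol.severity == "error" and viol.field.startswith(f"objects[{i}]")
            for viol in v
        ):
            coords = object_coordinates(obj)
            lo, hi = -margin, dims + margin
            if np.any(coords < lo) or np.any(coords >= hi + 1e-12):
                v.append(
                    Violation(
                        f"objects[{i}].coordinates",
                        "outside atlas bounds (within margin policy)",
                        None,
                        severity="warning",
                    )
                )
    return v


def bounding_box(
    obj: GeometricObject, atlas_meshes: Optional[dict] = None
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Smallest axis-aligned box containing the object.

    Spheres expand the centroid by the radius; cylinders take the exact
    axis-aligned box of the capsule union of their segments (each segment
    endpoint padded by the radius in every axis direction, which is exact
    for a spherically-capped tube). Atlas-mesh references require
    ``atlas_meshes``, a mapping from region URI to a mesh-bearing object
    with ``vertices``.
    """
    if isinstance(obj, AtlasMeshRef):
        if not atlas_meshes or obj.parcellationEntityVersion not in atlas_meshes:
            raise KeyError(
                f"mesh-not-found: {obj.parcellationEntityVersion!r} has no resolved mesh"
            )
        mesh = atlas_meshes[obj.parcellationEntityVersion]
        verts = np.asarray(mesh.mesh.vertices if hasattr(mesh, "mesh") else mesh.vertices, float)
        return tuple(verts.min(axis=0)), tuple(verts.max(axis=0))
    if isinstance(obj, Sphere):
        c = np.asarray(obj.centroid, float)
        return tuple(c - obj.radius), tuple(c + obj.radius)
    if isinstance(obj, Cylinder):
        pts = np.asarray(obj.axis, float)
        return tuple(pts.min(axis=0) - obj.radius), tuple(pts.max(axis=0) + obj.radius)
    coords = object_coordinates(obj)
    return tuple(coords.min(axis=0)), tuple(coords.max(axis=0))
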