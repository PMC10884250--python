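"""Converters from registration-tool outputs and POI tables to geometric objects.

Three families of inputs are covered:

* **Section anchoring records** (QuickNII-style): each registered 2D section
  is located in 3D atlas space by three vectors — ``o`` (the image's
  top-left corner), ``u`` (horizontal edge) and ``v`` (vertical edge) — so
  the four section corners are ``o``, ``o+u``, ``o+u+v`` and ``o+v``, and
  any pixel maps into atlas space by bilinear combination of ``u``/``v``.
* **Centroid exports** (Nutil-style): per-object centroids from a
  segmentation workflow become point objects, optionally grouped by region
  label.
* **Stereotaxic coordinates**: bregma-referenced millimetre coordinates are
  brought into atlas voxel space through a landmark-estimated affine
  transform (ordinary least squares over ``>=4`` non-coplanar landmark
  pairs).

File dialects (documented stand-ins mirroring the tools' flat-key layouts):
anchoring JSON is an array of ``{"filename", "ox","oy","oz", "ux","uy","uz",
"vx","vy","vz", "width", "height"}``; centroid files are JSON arrays of
``{"objectId", "x", "y", "z", ["region"]}`` or CSV with those columns;
landmark CSV has a header line declaring units and axis convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core_model import (
    AtlasMeshRef,
    Cylinder,
    GeometricObject,
    LineString,
    ObjectProperties,
    Point,
    Polygon,
    Polyhedron,
    Sphere,
)

__all__ = [
    "QuickNIIAnchoring",
    "CentroidRecord",
    "LandmarkPair",
    "AffineTransform",
    "quicknii_to_polygon",
    "quicknii_pixel_to_atlas",
    "nutil_to_points",
    "pois_to_spheres",
    "track_to_cylinder",
    "volume_to_polyhedron",
    "estimate_affine",
    "apply_affine",
    "read_anchoring_json",
    "read_centroids_json",
]


@dataclass(frozen=True)
class QuickNIIAnchoring:
    """One registered 2D section: o/u/v vectors plus pixel dimensions."""

    sectionId: str
    o: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    imageWidth: int
    imageHeight: int

    def validate(self) -> list[str]:
        problems = []
        cross = np.cross(np.asarray(self.u, float), np.asarray(self.v, float))
        if np.linalg.norm(cross) == 0.0:
            problems.append("degenerate-anchoring: u and v are parallel or zero")
        if self.imageWidth <= 0 or self.imageHeight <= 0:
            problems.append("image dimensions must be positive")
        return problems


@dataclass(frozen=True)
class CentroidRecord:
    """One segmented object's centroid in atlas voxel space."""

    objectId: str
    centroid: tuple[float, float, float]
    regionLabel: Optional[str] = None


@dataclass(frozen=True)
class LandmarkPair:
    """Corresponding landmark: stereotaxic mm (bregma origin) -> atlas voxels."""

    source: tuple[float, float, float]
    target: tuple[float, float, float]


@dataclass(frozen=True)
class AffineTransform:
    """3x3 linear part + translation, with the fit's RMS residual."""

    matrix: np.ndarray
    translation: np.ndarray
    rmsResidual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return pts @ self.matrix.T + self.translation

    @property
    def radius_scale(self) -> float:
        """Isotropic length scale: cbrt of |det M| (volume-preserving)."""
        return float(np.cbrt(abs(np.linalg.det(self.matrix))))

    @property
    def anisotropy(self) -> float:
        """Ratio of largest to smallest singular value, minus 1."""
        s = np.linalg.svd(self.matrix, compute_uv=False)
        return float(s[0] / s[-1] - 1.0)


# ---------------------------------------------------------------------------
# section anchoring


def quicknii_to_polygon(a: QuickNIIAnchoring) -> Polygon:
    """Four-corner polygon of a registered section plane.

    Corners are computed by vector addition — ``o``, ``o+u``, ``o+u+v``,
    ``o+v`` — giving a simple (non-self-intersecting) ring that is exactly
    planar by construction. Degenerate anchorings (``u x v = 0``) raise
    ``ValueError('degenerate-anchoring')``.
    """
    problems = a.validate()
    if problems:
        raise ValueError(problems[0])
    o = np.asarray(a.o, float)
    u = np.asarray(a.u, float)
    v = np.asarray(a.v, float)
    ring = (tuple(o), tuple(o + u), tuple(o + u + v), tuple(o + v))
    return Polygon(
        ring,
        ObjectProperties(
            name=a.sectionId,
            description=f"Section plane from anchoring record {a.sectionId}",
        ),
    )


def quicknii_pixel_to_atlas(
    a: QuickNIIAnchoring, px: Sequence[float]
) -> tuple[float, float, float]:
    """Map an image pixel to atlas coordinates.

    Pixel (0,0) is the image top-left; the pixel grid is normalized by
    width/height so (width, height) lands exactly on ``o+u+v``. Pixels
    outside the image bounds raise ``ValueError`` (no extrapolation).
    """
    x, y = float(px[0]), float(px[1])
    if not (0 <= x <= a.imageWidth and 0 <= y <= a.imageHeight):
        raise ValueError(
            f"pixel ({x}, {y}) outside image bounds "
            f"[0, {a.imageWidth}] x [0, {a.imageHeight}]"
        )
    o = np.asarray(a.o, float)
    u = np.asarray(a.u, float)
    v = np.asarray(a.v, float)
    p = o + (x / a.imageWidth) * u + (y / a.imageHeight) * v
    return (float(p[0]), float(p[1]), float(p[2]))


# ---------------------------------------------------------------------------
# centroid exports


def nutil_to_points(
    records: Sequence[CentroidRecord], group_by: Optional[str] = None
) -> list[Point]:
    """Centroid records -> point objects, one per group.

    ``group_by=None`` concatenates everything into a single multi-point
    object; ``group_by="regionLabel"`` emits one object per distinct label
    (groups ordered by first appearance). Empty input raises
    ``ValueError('no-records')``.
    """
    if not records:
        raise ValueError("no-records: empty centroid input")
    if group_by is None:
        coords = tuple(tuple(r.centroid) for r in records)
        return [
            Point(
                coords,
                ObjectProperties(
                    name="centroids", description="Nutil centroid export"
                ),
            )
        ]
    if group_by != "regionLabel":
        raise ValueError(f"unknown group_by {group_by!r}")
    groups: dict[str, list] = {}
    for r in records:
        key = r.regionLabel if r.regionLabel is not None else ""
        groups.setdefault(key, []).append(tuple(r.centroid))
    return [
        Point(
            tuple(coords),
            ObjectProperties(name=key or "unlabeled", description="Nutil centroid export"),
        )
        for key, coords in groups.items()
    ]


# ---------------------------------------------------------------------------
# POIs


def pois_to_spheres(
    centers: Sequence[Sequence[float]],
    radius: Union[float, Sequence[float]],
    name_prefix: str = "poi",
    description: str = "POI with known radius",
) -> list[Sphere]:
    """One sphere per POI center, order preserved.

    ``radius`` is a single value shared by all centers or a per-center
    list of matching length; non-positive radii raise ``ValueError``
    naming the offending index.
    """
    centers = [tuple(float(x) for x in c) for c in centers]
    if np.ndim(radius) == 0:
        radii = [float(radius)] * len(centers)
    else:
        radii = [float(r) for r in radius]
        if len(radii) != len(centers):
            raise ValueError(
                f"per-point radius list length {len(radii)} != {len(centers)} centers"
            )
    for i, r in enumerate(radii):
        if not (r > 0) or not math.isfinite(r):
            raise ValueError(f"radius[{i}] must be > 0, got {r}")
    return [
        Sphere(c, r, ObjectProperties(name=f"{name_prefix}-{i}", description=description))
        for i, (c, r) in enumerate(zip(centers, radii))
    ]


def track_to_cylinder(
    vertices: Sequence[Sequence[float]],
    radius: Optional[float] = None,
    name: str = "track",
    description: str = "electrode track",
) -> Union[Cylinder, LineString]:
    """An electrode track as a cylinder (radius known) or line string.

    Vertex order is preserved (entry -> tip). Fewer than two vertices, or
    a non-positive radius, raise ``ValueError``.
    """
    verts = tuple(tuple(float(x) for x in v) for v in vertices)
    if len(verts) < 2:
        raise ValueError(f"track needs >= 2 vertices, got {len(verts)}")
    props = ObjectProperties(name=name, description=description)
    if radius is None:
        return LineString(verts, props)
    if not (radius > 0):
        raise ValueError(f"radius must be > 0, got {radius}")
    return Cylinder(verts, float(radius), props)


# ---------------------------------------------------------------------------
# 3D volumes


# Unit-cube corner order: binary (bx, by, bz); faces listed with outward
# orientation for a right-handed edge triple.
_BOX_FACES = (
    (0, 2, 3, 1),  # z = 0
    (4, 5, 7, 6),  # z = 1
    (0, 1, 5, 4),  # y = 0
    (2, 6, 7, 3),  # y = 1
    (0, 4, 6, 2),  # x = 0
    (1, 3, 7, 5),  # x = 1
)


def volume_to_polyhedron(
    origin: Sequence[float],
    edges: Sequence[Sequence[float]],
    name: str = "volume",
    description: str = "3D image volume",
) -> Polyhedron:
    """Parallelepiped from an origin corner and three edge vectors.

    The eight vertices are ``origin + sum(b_i * edge_i)`` over the binary
    corners; the six quadrilateral faces are consistently outward-oriented,
    so the enclosed volume equals ``|det[edges]|``. Linearly dependent
    edges raise ``ValueError('degenerate-volume')``.
    """
    o = np.asarray(origin, float)
    E = np.asarray(edges, float).reshape(3, 3)
    det = float(np.linalg.det(E))
    if abs(det) < 1e-12 * max(1.0, float(np.abs(E).max()) ** 3):
        raise ValueError("degenerate-volume: edge vectors are linearly dependent")
    # corner index i in 0..7 encodes bits (bx, by, bz) = (i&1, (i>>1)&1, (i>>2)&1)
    corners = [
        tuple(o + (i & 1) * E[0] + ((i >> 1) & 1) * E[1] + ((i >> 2) & 1) * E[2])
        for i in range(8)
    ]
    faces = _BOX_FACES if det > 0 else tuple(tuple(reversed(f)) for f in _BOX_FACES)
    return Polyhedron(
        tuple(corners), faces, ObjectProperties(name=name, description=description)
    )


# ---------------------------------------------------------------------------
# landmark affine registration


def estimate_affine(pairs: Sequence[LandmarkPair]) -> AffineTransform:
    """Least-squares affine transform from >=4 landmark pairs.

    Solves ``min sum ||target - (M @ source + t)||^2`` by ordinary least
    squares on the homogeneous design matrix. With exactly four
    non-coplanar pairs the fit is exact. Coplanar or rank-deficient source
    configurations raise ``ValueError('rank-deficient-landmarks')``.
    """
    if len(pairs) < 4:
        raise ValueError(f"rank-deficient-landmarks: need >= 4 pairs, got {len(pairs)}")
    S = np.asarray([p.source for p in pairs], float)
    T = np.asarray([p.target for p in pairs], float)
    A = np.hstack([S, np.ones((len(S), 1))])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, float(np.abs(A).max()))) < 4:
        raise ValueError("rank-deficient-landmarks: source points are coplanar")
    X, *_ = np.linalg.lstsq(A, T, rcond=None)
    M = X[:3].T
    t = X[3]
    resid = T - (S @ M.T + t)
    # per-component RMS: an unbiased-ish estimate of isotropic landmark noise
    rms = float(np.sqrt(np.mean(resid**2)))
    return AffineTransform(M, t, rms)


def apply_affine(T: AffineTransform, obj: GeometricObject) -> GeometricObject:
    """Map a coordinate-bearing object through an affine transform.

    Every coordinate triplet becomes ``M @ x + t``; radii scale by
    ``cbrt|det M|`` (the volume-preserving isotropic approximation — when
    the transform's anisotropy exceeds 1% the scaled radius is only an
    approximation, noted in the object description). Atlas-mesh references
    carry no coordinates and raise ``TypeError('not-transformable')``.
    """
    if isinstance(obj, AtlasMeshRef):
        raise TypeError("not-transformable: atlasMesh carries no coordinates")

    def warp(coords):
        return tuple(tuple(map(float, T(np.asarray(c, float)))) for c in coords)

    props = obj.properties
    if T.anisotropy > 0.01 and isinstance(obj, (Sphere, Cylinder)):
        props = ObjectProperties(
            name=props.name,
            description=props.description
            + " [radius approximated under anisotropic transform]",
            linkedURI=props.linkedURI,
            extra=props.extra,
        )
    if isinstance(obj, Point):
        return Point(warp(obj.coordinates), props)
    if isinstance(obj, Sphere):
        (c,) = warp([obj.centroid])
        return Sphere(c, obj.radius * T.radius_scale, props)
    if isinstance(obj, LineString):
        return LineString(warp(obj.coordinates), props)
    if isinstance(obj, Cylinder):
        return Cylinder(warp(obj.axis), obj.radius * T.radius_scale, props)
    if isinstance(obj, Polygon):
        return Polygon(warp(obj.coordinates), props)
    if isinstance(obj, Polyhedron):
        faces = obj.faces
        if np.linalg.det(T.matrix) < 0:  # reflection flips orientation
            faces = tuple(tuple(reversed(f)) for f in faces)
        return Polyhedron(warp(obj.vertices), faces, props)
    raise TypeError(f"unsupported object {type(obj).__name__}")


# ---------------------------------------------------------------------------
# file dialect readers


def read_anchoring_json(text: str) -> list[QuickNIIAnchoring]:
    """Parse the flat-key anchoring JSON dialect (array of sections)."""
    data = json.loads(text)
    out = []
    for rec in data:
        out.append(
            QuickNIIAnchoring(
                sectionId=rec["filename"],
                o=(float(rec["ox"]), float(rec["oy"]), float(rec["oz"])),
                u=(float(rec["ux"]), float(rec["uy"]), float(rec["uz"])),
                v=(float(rec["vx"]), float(rec["vy"]), float(rec["vz"])),
                imageWidth=int(rec["width"]),
                imageHeight=int(rec["height"]),
            )
        )
    return out


def read_centroids_json(text: str) -> list[CentroidRecord]:
    """Parse the centroid JSON dialect (array of objectId/x/y/z[/region])."""
    data = json.loads(text)
    return [
        CentroidRecord(
            objectId=str(rec["objectId"]),
            centroid=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
            regionLabel=rec.get("region"),
        )
        for rec in data
    ]
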