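"""Spatial predicates between geometric objects and atlas region meshes.

The containment primitive is ray casting with the odd-crossing rule against
a closed triangulated region surface. Robustness near edges and vertices is
handled by re-randomization: if any ray-triangle hit lands within ``1e-9``
(barycentric) of an edge, the ray is re-drawn in a fresh random direction
from a seeded generator, so results are deterministic for a fixed seed and
terminate with probability 1.

Overlap fractions between solid objects and regions are Monte-Carlo
estimates: sample the object's interior uniformly, count the fraction of
samples inside the region mesh, and report a binomial standard error.
Point and line-string objects use vertex containment (line strings are
densified to at most 0.5 voxel spacing first).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core_model import (
    AtlasMeshRef,
    Cylinder,
    GeometricObject,
    LineString,
    LocareCollection,
    Point,
    Polygon,
    Polyhedron,
    Sphere,
    bounding_box,
)
from .geometry import TriangleMesh, contains, mesh_volume, sample_volume

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMesh",
    "OverlapResult",
    "Hit",
    "point_in_mesh",
    "points_in_mesh",
    "object_region_overlap",
    "assign_points_to_regions",
    "query_collections",
    "load_region_mesh_obj",
    "load_region_mesh_json",
]

DEFAULT_N_SAMPLES = 10_000
DEFAULT_SEED = 0
_EDGE_EPS = 1e-9
_DENSIFY_SPACING = 0.5  # voxels, line-string vertex densification


@dataclass(frozen=True)
class RegionMesh:
    """One atlas parcellation region as a closed triangulated surface."""

    regionId: str
    regionName: str
    mesh: TriangleMesh

    def validate(self) -> list[str]:
        problems = []
        if not self.mesh.is_closed():
            problems.append("mesh-not-closed")
        elif mesh_volume(self.mesh) <= 0:
            problems.append("non-positive volume")
        return problems


@dataclass(frozen=True)
class OverlapResult:
    """Monte-Carlo overlap between an object and a region.

    ``relation`` is ``"contained"`` when every sample lies inside,
    ``"disjoint"`` when none does, otherwise ``"intersects"``.
    ``fractionInside`` carries a binomial standard error in ``stdError``.
    """

    relation: str
    fractionInside: float
    stdError: float
    nSamples: int
    seed: int


@dataclass(frozen=True)
class Hit:
    """One query result: which object of which collection matched, and how."""

    collectionIndex: int
    objectIndex: int
    name: str
    relation: str
    fractionInside: Optional[float] = None
    distance: Optional[float] = None


# ---------------------------------------------------------------------------
# ray casting


def _ray_crossings(origin: np.ndarray, direction: np.ndarray, mesh: TriangleMesh):
    """Moller-Trumbore over all triangles; returns (count, ok).

    ``ok`` is False when any forward hit is within ``_EDGE_EPS`` of a
    triangle edge in barycentric coordinates (the caller then re-draws the
    ray direction).
    """
    v = mesh.vertices
    t = mesh.triangles
    a = v[t[:, 0]]
    e1 = v[t[:, 1]] - a
    e2 = v[t[:, 2]] - a
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    parallel = np.abs(det) < 1e-14
    det_safe = np.where(parallel, 1.0, det)
    tvec = origin - a
    u = np.einsum("ij,ij->i", tvec, pvec) / det_safe
    qvec = np.cross(tvec, e1)
    w = (qvec @ direction) / det_safe
    dist = np.einsum("ij,ij->i", e2, qvec) / det_safe
    hit = (~parallel) & (u >= -_EDGE_EPS) & (w >= -_EDGE_EPS) & (u + w <= 1.0 + _EDGE_EPS) & (dist > 0)
    if not np.any(hit):
        return 0, True
    u_h, w_h = u[hit], w[hit]
    near_edge = (
        (u_h < _EDGE_EPS)
        | (w_h < _EDGE_EPS)
        | (u_h + w_h > 1.0 - _EDGE_EPS)
        | (np.abs(dist[hit]) < _EDGE_EPS)
    )
    if np.any(near_edge):
        return 0, False
    return int(np.count_nonzero(hit)), True


def points_in_mesh(
    pts: np.ndarray, mesh: TriangleMesh, seed: int = DEFAULT_SEED
) -> np.ndarray:
    """Odd-crossing containment test for an array of points.

    Raises ``ValueError('mesh-not-closed')`` on an open surface.
    """
    if not mesh.is_closed():
        raise ValueError("mesh-not-closed")
    pts = np.asarray(pts, float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    out = np.zeros(len(pts), bool)
    outside = (pts < lo).any(axis=1) | (pts > hi).any(axis=1)
    for i, p in enumerate(pts):
        if outside[i]:
            continue
        direction = _random_unit(rng)
        for _ in range(64):
            count, ok = _ray_crossings(p, direction, mesh)
            if ok:
                out[i] = count % 2 == 1
                break
            direction = _random_unit(rng)
        else:  # pragma: no cover - probability ~0
            raise RuntimeError("ray re-randomization did not converge")
    return out


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def point_in_mesh(p: Sequence[float], m: RegionMesh, seed: int = DEFAULT_SEED) -> bool:
    """True iff ``p`` lies inside the region's closed surface."""
    return bool(points_in_mesh(np.asarray(p, float)[None, :], m.mesh, seed=seed)[0])


# ---------------------------------------------------------------------------
# overlap


def _densify_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    out = [pts[0]]
    for i in range(len(pts) - 1):
        seg = pts[i + 1] - pts[i]
        L = float(np.linalg.norm(seg))
        k = max(1, int(math.ceil(L / spacing)))
        for j in range(1, k + 1):
            out.append(pts[i] + seg * (j / k))
    return np.asarray(out)


def _object_probe_points(
    obj: GeometricObject, n: int, seed: int, atlas_meshes: Optional[dict]
) -> np.ndarray:
    if isinstance(obj, Point):
        return np.asarray(obj.coordinates, float)
    if isinstance(obj, LineString):
        return _densify_polyline(np.asarray(obj.coordinates, float), _DENSIFY_SPACING)
    if isinstance(obj, Polygon):
        # sample the planar patch by fan-triangle area weighting
        pts = np.asarray(obj.coordinates, float)
        rng = np.random.default_rng(seed)
        tris = [(pts[0], pts[i], pts[i + 1]) for i in range(1, len(pts) - 1)]
        areas = np.array([0.5 * np.linalg.norm(np.cross(b - a, c - a)) for a, b, c in tris])
        if areas.sum() == 0:
            return pts
        picks = rng.choice(len(tris), size=n, p=areas / areas.sum())
        r1 = np.sqrt(rng.uniform(size=n))
        r2 = rng.uniform(size=n)
        out = np.empty((n, 3))
        for i, k in enumerate(picks):
            a, b, c = tris[k]
            out[i] = (1 - r1[i]) * a + r1[i] * (1 - r2[i]) * b + r1[i] * r2[i] * c
        return out
    return sample_volume(obj, n, seed=seed, atlas_meshes=atlas_meshes)


def object_region_overlap(
    obj: GeometricObject,
    m: RegionMesh,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
    atlas_meshes: Optional[dict] = None,
) -> OverlapResult:
    """Monte-Carlo overlap fraction between an object and a region mesh.

    Solids are sampled uniformly in their interior (``n`` samples);
    point/line-string objects use their (densified) vertices. The result is
    deterministic for fixed ``(n, seed)``.
    """
    if isinstance(obj, AtlasMeshRef):
        ref_mesh = (
            atlas_meshes.get(obj.parcellationEntityVersion) if atlas_meshes else None
        )
        if ref_mesh is None:
            raise KeyError(f"mesh-not-found: {obj.parcellationEntityVersion!r}")
        probe = _object_probe_points(
            Polyhedron_from_mesh(ref_mesh.mesh if hasattr(ref_mesh, "mesh") else ref_mesh),
            n,
            seed,
            atlas_meshes,
        )
    else:
        probe = _object_probe_points(obj, n, seed, atlas_meshes)
    inside = points_in_mesh(probe, m.mesh, seed=seed)
    k = int(inside.sum())
    n_eff = len(probe)
    frac = k / n_eff
    se = math.sqrt(frac * (1.0 - frac) / n_eff) if n_eff else 0.0
    if k == n_eff and n_eff > 0:
        relation = "contained"
    elif k == 0:
        relation = "disjoint"
    else:
        relation = "intersects"
    return OverlapResult(relation, frac, se, n_eff, seed)


def Polyhedron_from_mesh(mesh: TriangleMesh) -> Polyhedron:
    """Wrap a triangle mesh as a polyhedron object for sampling purposes."""
    from .core_model import ObjectProperties

    return Polyhedron(
        tuple(tuple(map(float, v)) for v in mesh.vertices),
        tuple(tuple(map(int, t)) for t in mesh.triangles),
        ObjectProperties(name="mesh", description="resolved atlas mesh"),
    )


# ---------------------------------------------------------------------------
# region assignment


def assign_points_to_regions(
    pts: Point, atlas: Sequence[RegionMesh], seed: int = DEFAULT_SEED
) -> tuple[list[tuple[tuple[float, float, float], Optional[str]]], dict]:
    """Label each triplet of a point object with its containing region.

    Regions are assumed pairwise non-overlapping; a point inside several
    (numerically possible on shared boundaries) is assigned to the
    lexicographically lowest ``regionId`` with a logged warning. Returns
    the per-point labels and a count per region (``None`` key for
    unassigned points).
    """
    regions = sorted(atlas, key=lambda r: r.regionId)
    coords = np.asarray(pts.coordinates, float)
    labels: list[Optional[str]] = [None] * len(coords)
    membership = np.zeros((len(coords), len(regions)), bool)
    for j, r in enumerate(regions):
        membership[:, j] = points_in_mesh(coords, r.mesh, seed=seed)
    for i in range(len(coords)):
        hits = np.nonzero(membership[i])[0]
        if len(hits) > 1:
            logger.warning(
                "point %s inside %d regions; assigned to %s",
                tuple(coords[i]),
                len(hits),
                regions[hits[0]].regionId,
            )
        if len(hits) >= 1:
            labels[i] = regions[hits[0]].regionId
    counts: dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return [ (tuple(c), lab) for c, lab in zip(coords, labels) ], counts


# ---------------------------------------------------------------------------
# collection query engine


def _boxes_intersect(a, b) -> bool:
    (alo, ahi), (blo, bhi) = a, b
    return all(alo[i] <= bhi[i] and blo[i] <= ahi[i] for i in range(3))


def _object_min_distance(obj: GeometricObject, p: np.ndarray) -> float:
    """Distance from a point to the object (0 when inside a solid)."""
    from .core_model import object_coordinates

    if isinstance(obj, Sphere):
        return max(0.0, float(np.linalg.norm(np.asarray(obj.centroid) - p)) - obj.radius)
    if isinstance(obj, Cylinder):
        axis = np.asarray(obj.axis, float)
        best = math.inf
        for i in range(len(axis) - 1):
            ab = axis[i + 1] - axis[i]
            t = float(np.clip((p - axis[i]) @ ab / (ab @ ab), 0.0, 1.0))
            best = min(best, float(np.linalg.norm(p - (axis[i] + t * ab))))
        return max(0.0, best - obj.radius)
    if isinstance(obj, LineString):
        axis = np.asarray(obj.coordinates, float)
        best = math.inf
        for i in range(len(axis) - 1):
            ab = axis[i + 1] - axis[i]
            t = float(np.clip((p - axis[i]) @ ab / (ab @ ab), 0.0, 1.0))
            best = min(best, float(np.linalg.norm(p - (axis[i] + t * ab))))
        return best
    coords = object_coordinates(obj)
    return float(np.min(np.linalg.norm(coords - p, axis=1)))


def query_collections(
    docs: Sequence[LocareCollection],
    target: Union[RegionMesh, tuple, dict],
    n: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
    atlas_meshes: Optional[dict] = None,
    use_prefilter: bool = True,
) -> list[Hit]:
    """Find every object in ``docs`` that matches a spatial target.

    ``target`` is one of:

    * a :class:`RegionMesh` — objects intersecting/contained in the region;
    * an ROI box ``((lo_x, lo_y, lo_z), (hi_x, hi_y, hi_z))`` — objects whose
      geometry intersects the box;
    * ``{"point": (x, y, z), "distance": d}`` — objects within distance ``d``.

    All collections must share one target-atlas identifier; a mismatch
    raises ``ValueError('atlas-mismatch')``. Results are sorted by
    collection then object index. Atlas-mesh objects hit a region target
    iff their ``parcellationEntityVersion`` equals the target region id or
    their resolved meshes overlap.
    """
    ids = {d.targetAtlas.identifier for d in docs}
    if len(ids) > 1:
        a, b = sorted(ids)[:2]
        raise ValueError(f"atlas-mismatch: {a!r} vs {b!r}")

    if isinstance(target, RegionMesh):
        tgt_box = (
            tuple(target.mesh.vertices.min(axis=0)),
            tuple(target.mesh.vertices.max(axis=0)),
        )
    elif isinstance(target, dict):
        p = np.asarray(target["point"], float)
        d = float(target["distance"])
        tgt_box = (tuple(p - d), tuple(p + d))
    else:
        tgt_box = (tuple(map(float, target[0])), tuple(map(float, target[1])))

    hits: list[Hit] = []
    for ci, doc in enumerate(docs):
        for oi, obj in enumerate(doc.objects):
            if isinstance(obj, AtlasMeshRef):
                if isinstance(target, RegionMesh):
                    if obj.parcellationEntityVersion == target.regionId:
                        hits.append(Hit(ci, oi, obj.properties.name, "matched-region", 1.0))
                        continue
                    if atlas_meshes and obj.parcellationEntityVersion in atlas_meshes:
                        res = object_region_overlap(obj, target, n, seed, atlas_meshes)
                        if res.relation != "disjoint":
                            hits.append(
                                Hit(ci, oi, obj.properties.name, res.relation, res.fractionInside)
                            )
                continue
            box = bounding_box(obj)
            if use_prefilter and not _boxes_intersect(box, tgt_box):
                continue
            if isinstance(target, RegionMesh):
                res = object_region_overlap(obj, target, n, seed, atlas_meshes)
                if res.relation != "disjoint":
                    hits.append(
                        Hit(ci, oi, obj.properties.name, res.relation, res.fractionInside)
                    )
            elif isinstance(target, dict):
                p = np.asarray(target["point"], float)
                dist = _object_min_distance(obj, p)
                if dist <= float(target["distance"]):
                    hits.append(Hit(ci, oi, obj.properties.name, "within-distance", None, dist))
            else:
                if _boxes_intersect(box, tgt_box):
                    hits.append(Hit(ci, oi, obj.properties.name, "intersects-box"))
    hits.sort(key=lambda h: (h.collectionIndex, h.objectIndex))
    return hits


# ---------------------------------------------------------------------------
# region-mesh file readers


def load_region_mesh_obj(text: str, regionId: str, regionName: str = "") -> RegionMesh:
    """Read a triangulated region surface from Wavefront OBJ text."""
    verts, tris = [], []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append(tuple(float(x) for x in parts[1:4]))
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            for k in range(1, len(idx) - 1):
                tris.append((idx[0], idx[k], idx[k + 1]))
    return RegionMesh(regionId, regionName or regionId, TriangleMesh(np.asarray(verts), np.asarray(tris)))


def load_region_mesh_json(text: str, regionId: str, regionName: str = "") -> RegionMesh:
    """Read the JSON mesh form ``{"vertices": [...], "triangles": [...]}``."""
    d = json.loads(text)
    return RegionMesh(
        regionId,
        regionName or d.get("regionName", regionId),
        TriangleMesh(np.asarray(d["vertices"], float), np.asarray(d["triangles"], int)),
    )
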