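"""Deterministic toy atlas and use-case generators.

Everything here is synthetic: a toy atlas whose "regions" are axis-aligned
boxes partitioning a sub-volume (so exact containment oracles exist), a
matching three-level terminology tree, and nine use-case scenarios that
mirror the kinds of location documentation seen in practice — injection
sites, registered section images, region terms, electrode montages, tracks,
extracted cells, somata, imaging fields of view and linear arrays. Each
use-case emits the raw input files of the relevant converter dialect AND
the ground-truth collection the conversion pipeline must reproduce, so
every route is testable end-to-end without downloading real atlas data.

Realistic anatomy is deliberately out of scope: box regions make
containment exact, which is what correctness testing needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_model import (
    AtlasSpace,
    LocareCollection,
    ObjectProperties,
    Point,
    Polyhedron,
)
from .converters import (
    QuickNIIAnchoring,
    nutil_to_points,
    pois_to_spheres,
    quicknii_to_polygon,
    track_to_cylinder,
    volume_to_polyhedron,
)
from .geometry import TriangleMesh
from .semantic_mapping import (
    SemanticAnnotation,
    load_terminology,
    make_atlas_mesh_object,
    TerminologyNode,
)
from .spatial_query import RegionMesh

__all__ = ["SyntheticAtlas", "make_atlas", "make_use_case", "box_mesh", "USE_CASES"]

USE_CASES = "ABCDEFGHI"

_DIALECT = "locare-kit/1.0"


@dataclass(frozen=True)
class SyntheticAtlas:
    """Toy atlas: space + disjoint box regions + matching terminology."""

    space: AtlasSpace
    regions: tuple[RegionMesh, ...]
    terminology: TerminologyNode
    terminology_records: tuple[dict, ...]
    region_bounds: dict  # regionId -> (lo, hi) numpy arrays


def box_mesh(lo, hi) -> TriangleMesh:
    """Closed outward-oriented 12-triangle mesh of an axis-aligned box."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    poly = volume_to_polyhedron(lo, np.diag(hi - lo), name="box", description="box")
    verts = np.asarray(poly.vertices)
    tris = []
    for f in poly.faces:
        for k in range(1, len(f) - 1):
            tris.append((f[0], f[k], f[k + 1]))
    return TriangleMesh(verts, np.asarray(tris, int))


def make_atlas(n_regions: int = 8, dims=(100, 100, 100), seed: int = 0) -> SyntheticAtlas:
    """Toy atlas with ``n_regions`` disjoint box regions and a terminology.

    Regions partition a grid inside the central 80% of the volume. The
    terminology has one root, two mid-level groups (anterior/posterior by
    grid position) and one leaf per region, each leaf carrying at least one
    synonym. Deterministic for a fixed seed. Raises ``ValueError`` when
    ``n_regions`` exceeds the grid capacity (one voxel minimum per cell).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    dims = tuple(int(d) for d in dims)
    g = 1
    while g**3 < n_regions:
        g += 1
    inner_lo = np.asarray(dims, float) * 0.1
    inner_hi = np.asarray(dims, float) * 0.9
    cell = (inner_hi - inner_lo) / g
    if np.any(cell < 1.0):
        raise ValueError(
            f"n_regions={n_regions} exceeds grid capacity for dims {dims}"
        )
    space = AtlasSpace(
        identifier=f"toy:atlas/space/{seed}",
        name="Synthetic box atlas",
        dimensions=dims,
        resolution=0.039,
        orientation="RAS",
        origin=(0.0, 0.0, 0.0),
    )
    regions = []
    bounds = {}
    records = [{"id": "toy:region/root", "name": "Whole brain", "synonyms": ["brain"]}]
    mids = [
        {"id": "toy:region/anterior", "name": "Anterior group", "synonyms": ["rostral group"], "parent": "toy:region/root"},
        {"id": "toy:region/posterior", "name": "Posterior group", "synonyms": ["caudal group"], "parent": "toy:region/root"},
    ]
    records += mids
    k = 0
    for iz in range(g):
        for iy in range(g):
            for ix in range(g):
                if k >= n_regions:
                    break
                lo = inner_lo + cell * np.array([ix, iy, iz])
                hi = lo + cell
                rid = f"toy:region/{k:03d}"
                name = f"Synthetic area {k}"
                regions.append(RegionMesh(rid, name, box_mesh(lo, hi)))
                bounds[rid] = (lo, hi)
                parent = mids[0]["id"] if iy < g / 2 else mids[1]["id"]
                records.append(
                    {
                        "id": rid,
                        "name": name,
                        "synonyms": [f"area {k}", f"SA{k}"],
                        "parent": parent,
                    }
                )
                k += 1
    terminology = load_terminology(records)
    return SyntheticAtlas(
        space=space,
        regions=tuple(regions),
        terminology=terminology,
        terminology_records=tuple(records),
        region_bounds=bounds,
    )


def _envelope(atlas: SyntheticAtlas, objects, case: str) -> LocareCollection:
    return LocareCollection(
        version=_DIALECT,
        targetAtlas=atlas.space,
        sourcePublication=(f"doi:10.0000/synthetic-use-case-{case}",),
        objects=tuple(objects),
    )


def _region_center(atlas: SyntheticAtlas, idx: int = 0) -> np.ndarray:
    rid = atlas.regions[idx % len(atlas.regions)].regionId
    lo, hi = atlas.region_bounds[rid]
    return (lo + hi) / 2.0


def make_use_case(case: str, atlas: SyntheticAtlas, seed: int = 0):
    """One of nine synthetic scenarios, keyed ``"A"``..``"I"``.

    Returns ``(input_files, expected)`` where ``input_files`` maps file
    names to text contents in the converter dialects, and ``expected`` is
    the ground-truth :class:`LocareCollection` the conversion pipeline must
    reproduce bit-exactly. Scenarios:

    A. injection-site core and shell: two concentric spheres
    B. registered 2D section: anchoring record -> four-corner polygon
    C. region term only: semantic mapping -> atlas-mesh object
    D. epidural electrode montage: 17 spheres
    E. electrode track with known radius: cylinder
    F. extracted labeled cells: centroid export -> multi-point object
    G. single soma: one-triplet point
    H. imaging field of view x depth: eight-corner polyhedron
    I. linear array, 16 recording sites: 16-vertex line string
    """
    case = case.upper()
    if case not in USE_CASES:
        raise ValueError(f"unknown use case {case!r}; expected one of {USE_CASES}")
    rng = np.random.default_rng(seed * 16 + ord(case) - ord("A"))
    dims = np.asarray(atlas.space.dimensions, float)

    if case == "A":
        center = _region_center(atlas, 0)
        r_core, r_shell = 2.0, 5.0
        table = {
            "center": list(map(float, center)),
            "radii": [r_core, r_shell],
            "labels": ["core", "shell"],
        }
        spheres = pois_to_spheres(
            [center, center],
            [r_core, r_shell],
            name_prefix="injection",
            description="Injection site core/shell sphere",
        )
        return {"case_A_injection.json": json.dumps(table, indent=2)}, _envelope(
            atlas, spheres, case
        )

    if case == "B":
        o = _region_center(atlas, 1) - np.array([20.0, 0.0, 10.0])
        anchoring = QuickNIIAnchoring(
            sectionId="section_042",
            o=tuple(map(float, o)),
            u=(40.0, 0.0, 0.0),
            v=(0.0, 0.0, 20.0),
            imageWidth=1024,
            imageHeight=512,
        )
        rec = {
            "filename": anchoring.sectionId,
            "ox": anchoring.o[0], "oy": anchoring.o[1], "oz": anchoring.o[2],
            "ux": anchoring.u[0], "uy": anchoring.u[1], "uz": anchoring.u[2],
            "vx": anchoring.v[0], "vy": anchoring.v[1], "vz": anchoring.v[2],
            "width": anchoring.imageWidth, "height": anchoring.imageHeight,
        }
        poly = quicknii_to_polygon(anchoring)
        return {"case_B_anchoring.json": json.dumps([rec], indent=2)}, _envelope(
            atlas, [poly], case
        )

    if case == "C":
        node_name = atlas.regions[2 % len(atlas.regions)].regionName
        ann = SemanticAnnotation(
            granularity="matched",
            coverage="full",
            confidence="high",
            rationale=f"Term {node_name!r} taken directly from the target terminology",
        )
        obj = make_atlas_mesh_object(
            atlas.regions[2 % len(atlas.regions)].regionId, atlas.terminology, ann
        )
        return {"case_C_term.json": json.dumps({"term": node_name}, indent=2)}, _envelope(
            atlas, [obj], case
        )

    if case == "D":
        # 17 epidural electrodes on a jittered grid near the volume top
        centers = []
        for i in range(17):
            gx, gy = i % 5, i // 5
            centers.append(
                (
                    float(dims[0] * 0.25 + gx * dims[0] * 0.1 + rng.uniform(-1, 1)),
                    float(dims[1] * 0.3 + gy * dims[1] * 0.1 + rng.uniform(-1, 1)),
                    float(dims[2] * 0.92),
                )
            )
        rows = [
            {"objectId": f"el{i:02d}", "x": c[0], "y": c[1], "z": c[2], "radius": 1.25}
            for i, c in enumerate(centers)
        ]
        spheres = pois_to_spheres(
            centers, 1.25, name_prefix="electrode", description="Epidural electrode"
        )
        return {"case_D_montage.json": json.dumps(rows, indent=2)}, _envelope(
            atlas, spheres, case
        )

    if case == "E":
        entry = _region_center(atlas, 3) + np.array([0.0, 0.0, 25.0])
        tip = _region_center(atlas, 3)
        cyl = track_to_cylinder(
            [tuple(map(float, entry)), tuple(map(float, tip))],
            radius=0.4,
            name="probe-1",
            description="Annotated electrode track",
        )
        table = {"vertices": [list(map(float, entry)), list(map(float, tip))], "radius": 0.4}
        return {"case_E_track.json": json.dumps(table, indent=2)}, _envelope(
            atlas, [cyl], case
        )

    if case == "F":
        # extracted labeled cells scattered inside two regions
        rows = []
        for j, ridx in enumerate((0, 1)):
            rid = atlas.regions[ridx % len(atlas.regions)].regionId
            lo, hi = atlas.region_bounds[rid]
            pts = rng.uniform(lo + 0.5, hi - 0.5, size=(25, 3))
            for i, p in enumerate(pts):
                rows.append(
                    {
                        "objectId": f"cell{j}_{i:03d}",
                        "x": float(p[0]),
                        "y": float(p[1]),
                        "z": float(p[2]),
                    }
                )
        from .converters import read_centroids_json

        text = json.dumps(rows, indent=2)
        points = nutil_to_points(read_centroids_json(text), group_by=None)
        return {"case_F_centroids.json": text}, _envelope(atlas, points, case)

    if case == "G":
        soma = _region_center(atlas, 4) + rng.uniform(-2, 2, size=3)
        obj = Point(
            (tuple(map(float, soma)),),
            ObjectProperties(name="neuron-1", description="Soma position of reconstructed neuron"),
        )
        return {
            "case_G_soma.json": json.dumps({"x": soma[0], "y": soma[1], "z": soma[2]}, indent=2)
        }, _envelope(atlas, [obj], case)

    if case == "H":
        origin = _region_center(atlas, 5) - np.array([8.0, 6.0, 0.0])
        edges = ((16.0, 0.0, 0.0), (0.0, 12.0, 0.0), (0.0, 0.0, -7.0))
        poly = volume_to_polyhedron(
            tuple(map(float, origin)),
            edges,
            name="fov-1",
            description="Imaging field of view with depth",
        )
        table = {"origin": list(map(float, origin)), "edges": [list(e) for e in edges]}
        return {"case_H_fov.json": json.dumps(table, indent=2)}, _envelope(
            atlas, [poly], case
        )

    # case I: linear array with 16 recording sites along the electrode
    entry = _region_center(atlas, 6) + np.array([0.0, 0.0, 30.0])
    tip = _region_center(atlas, 6)
    sites = [entry + (tip - entry) * (i / 15.0) for i in range(16)]
    ls = track_to_cylinder(
        [tuple(map(float, s)) for s in sites],
        radius=None,
        name="array-1",
        description="Linear electrode array, 16 recording sites",
    )
    table = {"vertices": [list(map(float, s)) for s in sites]}
    return {"case_I_array.json": json.dumps(table, indent=2)}, _envelope(
        atlas, [ls], case
    )
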