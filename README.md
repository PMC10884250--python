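# locarekit

A validating library and command-line tool for representing **where in the
brain** a neuroscience data set was acquired, as geometric objects in a
declared 3D reference-atlas coordinate space.

Most published physiology, imaging and histology data come with *location
documentation* — stereotaxic coordinates, registered section images, or just
a region name — that is hard to search or co-visualize across studies.
locarekit makes that documentation computable by expressing it in a
GeoJSON-style JSON dialect (`locare-kit/1.0`): a collection envelope that
declares the target atlas space (dimensions, isotropic resolution,
orientation code, origin) and source publications, holding any number of
seven geometric object types:

| type | geometry | typical use |
|---|---|---|
| `point` | ≥1 coordinate triplet | cell somata, extracted cell positions |
| `sphere` | centroid + radius *r* | electrodes, injection-site core/shell |
| `lineString` | ≥2 ordered triplets | electrode track, linear array sites |
| `cylinder` | line-string axis + *r* | electrode track with known radius |
| `polygon` | ≥3 coplanar corners | the plane of a registered 2D section |
| `polyhedron` | vertices + closed faces | imaging field of view × depth |
| `atlasMesh` | region URI | "recorded in region X" (semantic route) |

All coordinates are continuous 0-based voxel coordinates of the target atlas
volume; millimetres are `value × resolution`.

On top of the format the package provides:

* **Converters** for the three routes from raw documentation to objects —
  POI tables (`pois_to_spheres`, `track_to_cylinder`), registered images
  (section anchoring vectors **o**, **u**, **v** → four-corner polygons via
  `quicknii_to_polygon`, with pixel-to-atlas mapping
  `p(x, y) = o + (x/W)·u + (y/H)·v`; 3D volumes → eight-corner
  parallelepipeds whose enclosed volume is `|det[e₁ e₂ e₃]|`), and
  centroid exports (`nutil_to_points`). Stereotaxic millimetre coordinates
  are brought into atlas space by landmark least squares:
  `min_{M,t} Σᵢ ‖yᵢ − (M xᵢ + t)‖²` (`estimate_affine` / `apply_affine`).
* **A geometry engine**: analytic measures, watertight tessellation
  (icosphere subdivision for spheres, capped tubes for cylinders),
  divergence-theorem mesh volumes, and seeded uniform interior sampling.
* **Spatial queries** against atlas region meshes: ray-casting
  point-in-mesh with the odd-crossing rule, Monte-Carlo overlap fractions
  with binomial standard errors, per-region point assignment, and a
  collection-level query engine (region / ROI box / distance-to-point).
* **Semantic mapping**: resolve free-text region terms against an atlas
  terminology tree (exact > synonym > normalized > substring) and build
  annotated `atlasMesh` objects with granularity/coverage/confidence
  consistency checks.
* **Synthetic fixtures**: a deterministic toy atlas (box regions + matching
  terminology) and nine end-to-end scenarios covering every route.

## Worked example

```sh
locare demo --out demo --seed 0
```

```
case A: 2 objects, 0 violations
case B: 1 objects, 0 violations
case C: 1 objects, 0 violations
case D: 17 objects, 0 violations
case E: 1 objects, 0 violations
case F: 1 objects, 0 violations
case G: 1 objects, 0 violations
case H: 1 objects, 0 violations
case I: 1 objects, 0 violations
query against 'Synthetic area 0': 3 hits
demo complete: 0 violations
```

Case A is an injection site (2 concentric spheres for core and shell),
case D an epidural electrode montage (17 spheres), case F extracted
immunopositive cells (one multi-point object). The query reports the three
objects overlapping the first toy region: both injection spheres and the
cell point cloud. `demo/` now holds each scenario's raw input file, its
converted `.locare.json` collection, the toy region meshes and terminology,
and viewer exports; reruns at the same seed are byte-identical.

```sh
locare validate demo                # -> 9 files validated, 0 invalid
locare query demo --region-mesh demo/meshes/000.json --n-samples 2000
locare export demo/case_A.locare.json --format obj --out spheres.obj
locare schemas --out schemas/       # the 8 JSON-Schema documents
```

Library use mirrors the CLI:

```python
from locarekit import parse_locare, write_locare
from locarekit.converters import QuickNIIAnchoring, quicknii_to_polygon

a = QuickNIIAnchoring("s42", o=(10, 5, 60), u=(40, 0, 0), v=(0, 0, -20),
                      imageWidth=1024, imageHeight=512)
poly = quicknii_to_polygon(a)
poly.coordinates
# ((10, 5, 60), (50, 5, 60), (50, 5, 40), (10, 5, 40))
```

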