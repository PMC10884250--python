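# Methods

## The representation

A `locare-kit/1.0` document is a collection envelope binding geometric
objects to one atlas coordinate space. The envelope requires a dialect
`version`, a `targetAtlas` block (opaque space identifier URI, voxel
`dimensions`, isotropic `resolution` in mm/voxel, a three-letter
`orientation` code drawn one letter each from the L/R, A/P and S/I axis
pairs, and an `origin` triplet) and at least one `sourcePublication`
persistent identifier; `relatedPublications` and `linkedURI` are optional.
Each object requires a `type` discriminator, its geometry fields, and
`name`/`description` provenance (plus optional `linkedURI`); unknown extra
fields are preserved on round-trip but carry no semantics.

**Units.** All coordinates, radii and lengths are continuous 0-based voxel
coordinates of the target atlas volume. The atlas viewers this format
targets operate in voxel space, and no universal physical-unit convention
exists across atlases, so the unit contract is declared in the file itself
through `targetAtlas.resolution` rather than assumed. Anisotropic voxels
are out of scope (a single scalar resolution).

**Object invariants.** Points carry a *list* of triplets (an object groups
one biological entity set — e.g. all extracted cells of one section — not
one coordinate). Line strings and cylinder axes reject consecutive
duplicate vertices because zero-length segments break direction-dependent
geometry. Polygon rings are stored open (first vertex not repeated), must
be planar within a relative tolerance of 1e-6 × the longest edge (anchoring
output is exactly planar; the tolerance only absorbs float noise) and
non-self-intersecting in their plane. Polyhedra must be closed and
consistently oriented — every directed edge used exactly once — with
positive enclosed volume. Coordinates outside the atlas volume are
*warnings*, not errors, up to a margin of 5% of the largest dimension:
slightly-outside data such as skull-surface electrodes are legitimate.

**Validation is data.** `validate_object`/`validate_collection` return
violation records (field, rule, offending value) rather than raising, so a
malformed file is reported in one pass. Parsing validates twice: against
the emitted JSON-Schema documents (structural), then against the in-memory
invariants (geometric). The schema documents are standard draft-07 JSON
Schema restricted to a small keyword subset, and the package ships its own
checker for exactly that subset, so external validators and the built-in
path accept the same documents.

## Converters

**Section anchoring.** A registered 2D section is located by vectors
`o` (top-left corner), `u` (horizontal edge) and `v` (vertical edge). The
polygon ring is `[o, o+u, o+u+v, o+v]` — ring order rather than raster
order, so the ring is simple. Pixel mapping uses a corner-anchored
continuous convention, `p(x, y) = o + (x/W)u + (y/H)v` with (0,0) at the
image top-left: the tools' sub-pixel convention is not documented, and this
choice makes the four corner identities exact. No extrapolation outside
the image bounds.

**Volumes.** A 3D image footprint is the parallelepiped
`{origin + Σ bᵢ eᵢ}`, eight vertices and six outward-oriented quads;
orientation flips when `det[e] < 0` so the enclosed volume is always
positive and equals `|det[e]|`.

**Landmark registration.** Stereotaxic (bregma-referenced, mm) coordinates
map to atlas voxels through an affine fit to ≥4 non-coplanar landmark
pairs, solved by least squares on the homogeneous design matrix. The
reported `rmsResidual` is the per-component RMS of the target residuals, a
direct estimate of isotropic landmark noise σ. Radii transform by
`∛|det M|` — the volume-preserving isotropic approximation; when the
transform's singular-value anisotropy exceeds 1% the object description is
tagged so downstream users know the radius is approximate. Translation
tables between specific surgical atlases are user-supplied data, not
bundled.

## Geometry engine

Sphere tessellation subdivides an icosahedron (no pole clustering;
subdivision depth chosen so the chord deviation ≤ tol × radius). Cylinders
with multi-segment axes are unions of flat-capped circular tubes; joint
overlap volumes are double-counted and not subtracted — electrode tracks
are near-straight, and exact swept volumes would be disproportionate
machinery. The containment predicate, the tessellation and the
`πr²·length` measure all use the same flat-capped model; only the bounding
box uses the (slightly larger) capsule box, which is conservative and
therefore safe for prefiltering and rejection sampling. Mesh volumes use
the divergence theorem over oriented triangles. Interior sampling is
rejection sampling from the bounding box against the object's own
containment predicate — simple and exactly consistent with it — with a
seeded generator (`numpy.random.default_rng`); the worst acceptance rate
among the solids is the sphere's π/6.

## Spatial queries

Point-in-mesh uses ray casting with the odd-crossing rule. Robustness near
edges/vertices comes from re-randomization: a hit within 1e-9 (barycentric)
of a triangle edge discards the ray and draws a fresh random direction from
the seeded generator, which terminates with probability 1 and is
deterministic for a fixed seed. Overlap between a solid object and a
region is a Monte-Carlo estimate — `n` uniform interior samples, fraction
inside, binomial standard error; `relation` is `contained` when all samples
are inside, `disjoint` when none are. Point objects use their vertices;
line strings are densified to ≤0.5 voxel spacing first (exact segment–mesh
intersection is future work). Defaults: n = 10⁴ samples, seed = 0, both
surfaced in the CLI. Boundary points falling in several abutting regions
are assigned to the lexicographically lowest region id with a logged
warning. The collection query engine prefilters on axis-aligned bounding
boxes before refinement; the prefilter is conservative by construction and
is additionally property-tested to discard no true hit.

## Semantic mapping

Term resolution normalizes by lowercasing, stripping punctuation and
collapsing whitespace — no stemming, since anatomical nomenclature is
irregular enough that false merges are worse than misses. Ranking is
exact name > synonym > normalized > unique substring; multiple substring
candidates are all returned and flagged ambiguous. The final choice of
term — trading specificity against confidence — is deliberately left to
the user; the module enforces only annotation consistency (substituting an
ancestor of an exact match must be annotated `granularity="coarser"`).
Accuracy judgments are free text: they are not machine-checkable.

## Synthetic fixtures

The toy atlas partitions the central 80% of a 100³ voxel volume into
disjoint axis-aligned box regions (default 8) with a three-level
terminology (root, two mid-level groups, leaves with synonyms). Boxes are
used because exact containment oracles exist for them; anatomical realism
is irrelevant to correctness testing, so passing tests demonstrate
correctness of the geometry and plumbing, not robustness to the thin,
curved, high-genus surfaces of real parcellations. The nine scenarios fix
the study conditions: 2 concentric injection spheres (core r=2, shell r=5
voxels), one anchored section, one semantic term, 17 epidural electrode
spheres (r=1.25 voxels ≈ 0.05 mm electrode radius at 0.039 mm/voxel), one
cylinder track, 50 extracted cells, one soma, one 16×12×7-voxel imaging
field of view, and a 16-site linear array. Shipped fixtures use seed 0;
the generator API is parameterized.

## Problem sizes and numerical choices

The test suite and acceptance script use: 10⁴ random points for the
convex sign-test agreement check; 10⁴ Monte-Carlo samples (seed 0) for the
half-ball overlap fraction, asserted within 3 binomial standard errors of
0.5; 100 replicates at σ = 0.1 for the affine residual band [0.5σ, 1.5σ];
200 randomized collections for round-trip identity; 300 random solids for
the bounding-box/tessellation property (chord tolerance 0.05); and demo
queries at 400–2000 samples. Parallelepiped volumes are asserted to
1e-12 relative against the determinant; noiseless affine recovery to 1e-9.

## Known limitations

* Mesh-based region assignment only; no label-volume (voxel image) path.
* No boolean solid geometry: cylinder joints double-count, polygon
  "overlap" uses surface sampling.
* Region meshes are trusted to be closed and pairwise disjoint; the query
  engine does not repair meshes.
* URIs (atlas spaces, parcellation entities) are opaque strings, never
  resolved against a live service.
* No nonlinear refinement of section anchorings; the affine landmark path
  assumes rigid+shear relations between coordinate frames.
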