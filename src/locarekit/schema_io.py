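"""Reading, writing and schema validation of the ``locare-kit/1.0`` dialect.

The on-disk form is a GeoJSON-style JSON document: a collection envelope
(``version``, ``targetAtlas``, ``sourcePublication``, optional
``relatedPublications``/``linkedURI``) holding an ``objects`` array whose
members carry a ``type`` discriminator from the seven geometric variants.
Writing is deterministic (fixed key order, shortest round-trip float
serialization) so that identical collections produce byte-identical files.

The dialect schemas are emitted as standard JSON-Schema (draft-07 subset)
documents for external validators; :func:`validate_against_schema` is a
small built-in checker for exactly the subset those schemas use.
"""

from __future__ import annotations

import json
from typing import Any, Optional

from .core_model import (
    AtlasMeshRef,
    AtlasSpace,
    Cylinder,
    GeometricObject,
    LineString,
    LocareCollection,
    ObjectProperties,
    Point,
    Polygon,
    Polyhedron,
    Sphere,
    Violation,
    validate_collection,
)

__all__ = [
    "LocareError",
    "LocareParseError",
    "LocareValidationError",
    "parse_locare",
    "write_locare",
    "emit_dialect_schemas",
    "validate_against_schema",
    "collection_to_json_obj",
]

DIALECT_VERSION = "locare-kit/1.0"


class LocareError(Exception):
    """Base class for dialect I/O errors."""


class LocareParseError(LocareError):
    """JSON syntax error, with line/column from the decoder."""

    def __init__(self, msg: str, line: int, column: int):
        super().__init__(f"parse error at line {line}, column {column}: {msg}")
        self.line = line
        self.column = column


class LocareValidationError(LocareError):
    """Schema or invariant violation; ``errors`` lists JSON-pointer paths."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"{path}: {msg}" for path, msg in self.errors)
        super().__init__(f"invalid document: {lines}")


# ---------------------------------------------------------------------------
# JSON-schema emission

_TRIPLET = {
    "type": "array",
    "items": {"type": "number"},
    "minItems": 3,
    "maxItems": 3,
}

_COMMON_PROPS = {
    "name": {"type": "string", "minLength": 1},
    "description": {"type": "string", "minLength": 1},
    "linkedURI": {"type": "string"},
}


def _object_schema(type_name: str, specific: dict, required: list[str]) -> dict:
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": f"locare-kit/1.0/{type_name}.schema.json",
        "title": type_name,
        "type": "object",
        "properties": {
            "type": {"const": type_name},
            **specific,
            **_COMMON_PROPS,
        },
        "required": ["type", *required, "name", "description"],
    }


def emit_dialect_schemas() -> dict[str, dict]:
    """One JSON-Schema document per object type plus the collection envelope.

    Returns a mapping of eight schema names (the seven ``type``
    discriminators and ``"locareCollection"``) to JSON-Schema dicts. Every
    object schema requires ``type`` and ``coordinates`` except ``atlasMesh``,
    which requires ``parcellationEntityVersion``.
    """
    coords_many = {"type": "array", "items": _TRIPLET, "minItems": 1}
    schemas = {
        "point": _object_schema("point", {"coordinates": coords_many}, ["coordinates"]),
        "sphere": _object_schema(
            "sphere",
            {"coordinates": _TRIPLET, "radius": {"type": "number", "exclusiveMinimum": 0}},
            ["coordinates", "radius"],
        ),
        "lineString": _object_schema(
            "lineString",
            {"coordinates": {"type": "array", "items": _TRIPLET, "minItems": 2}},
            ["coordinates"],
        ),
        "cylinder": _object_schema(
            "cylinder",
            {
                "coordinates": {"type": "array", "items": _TRIPLET, "minItems": 2},
                "radius": {"type": "number", "exclusiveMinimum": 0},
            },
            ["coordinates", "radius"],
        ),
        "polygon": _object_schema(
            "polygon",
            {"coordinates": {"type": "array", "items": _TRIPLET, "minItems": 3}},
            ["coordinates"],
        ),
        "polyhedron": _object_schema(
            "polyhedron",
            {
                "coordinates": {"type": "array", "items": _TRIPLET, "minItems": 4},
                "faces": {
                    "type": "array",
                    "items": {
                        "type": "array",
                        "items": {"type": "integer", "minimum": 0},
                        "minItems": 3,
                    },
                    "minItems": 4,
                },
            },
            ["coordinates", "faces"],
        ),
        "atlasMesh": _object_schema(
            "atlasMesh",
            {
                "parcellationEntityVersion": {"type": "string", "minLength": 1},
                "regionName": {"type": "string"},
            },
            ["parcellationEntityVersion"],
        ),
    }
    schemas["locareCollection"] = {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": "locare-kit/1.0/locareCollection.schema.json",
        "title": "locareCollection",
        "type": "object",
        "properties": {
            "version": {"type": "string", "minLength": 1},
            "targetAtlas": {
                "type": "object",
                "properties": {
                    "identifier": {"type": "string", "minLength": 1},
                    "name": {"type": "string"},
                    "dimensions": {
                        "type": "array",
                        "items": {"type": "integer", "minimum": 1},
                        "minItems": 3,
                        "maxItems": 3,
                    },
                    "resolution": {"type": "number", "exclusiveMinimum": 0},
                    "orientation": {"type": "string", "minLength": 3, "maxLength": 3},
                    "origin": _TRIPLET,
                },
                "required": [
                    "identifier",
                    "dimensions",
                    "resolution",
                    "orientation",
                ],
            },
            "sourcePublication": {
                "type": "array",
                "items": {"type": "string", "minLength": 1},
                "minItems": 1,
            },
            "relatedPublications": {"type": "array", "items": {"type": "string"}},
            "linkedURI": {"type": "string"},
            "objects": {"type": "array", "items": {"type": "object"}},
        },
        "required": ["version", "targetAtlas", "sourcePublication", "objects"],
    }
    return schemas


# ---------------------------------------------------------------------------
# built-in validator for the subset of JSON Schema the dialect uses


def validate_against_schema(
    instance: Any, schema: dict, path: str = ""
) -> list[tuple[str, str]]:
    """Validate ``instance`` against a dialect schema document.

    Covers the keywords the emitted schemas use: ``type``, ``const``,
    ``required``, ``properties``, ``items``, ``minItems``, ``maxItems``,
    ``minLength``, ``maxLength``, ``minimum``, ``exclusiveMinimum``.
    Returns a list of ``(json_pointer, message)`` pairs, empty iff valid.
    """
    errs: list[tuple[str, str]] = []
    t = schema.get("type")
    if t is not None and not _type_ok(instance, t):
        return [(path or "/", f"expected {t}, got {type(instance).__name__}")]
    if "const" in schema and instance != schema["const"]:
        errs.append((path or "/", f"expected constant {schema['const']!r}"))
    if isinstance(instance, str):
        if "minLength" in schema and len(instance) < schema["minLength"]:
            errs.append((path or "/", f"shorter than {schema['minLength']}"))
        if "maxLength" in schema and len(instance) > schema["maxLength"]:
            errs.append((path or "/", f"longer than {schema['maxLength']}"))
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            errs.append((path or "/", f"less than minimum {schema['minimum']}"))
        if "exclusiveMinimum" in schema and instance <= schema["exclusiveMinimum"]:
            errs.append((path or "/", f"not greater than {schema['exclusiveMinimum']}"))
    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            errs.append((path or "/", f"fewer than {schema['minItems']} items"))
        if "maxItems" in schema and len(instance) > schema["maxItems"]:
            errs.append((path or "/", f"more than {schema['maxItems']} items"))
        item_schema = schema.get("items")
        if isinstance(item_schema, dict):
            for i, item in enumerate(instance):
                errs += validate_against_schema(item, item_schema, f"{path}/{i}")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                errs.append((f"{path}/{req}", "required property missing"))
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errs += validate_against_schema(instance[key], sub, f"{path}/{key}")
    return errs


def _type_ok(instance: Any, t: str) -> bool:
    if t == "object":
        return isinstance(instance, dict)
    if t == "array":
        return isinstance(instance, list)
    if t == "string":
        return isinstance(instance, str)
    if t == "number":
        return isinstance(instance, (int, float)) and not isinstance(instance, bool)
    if t == "integer":
        return (
            isinstance(instance, int) and not isinstance(instance, bool)
        ) or (isinstance(instance, float) and instance.is_integer())
    if t == "boolean":
        return isinstance(instance, bool)
    return True


# ---------------------------------------------------------------------------
# parsing

_KNOWN_OBJECT_KEYS = {
    "type",
    "coordinates",
    "radius",
    "faces",
    "parcellationEntityVersion",
    "regionName",
    "name",
    "description",
    "linkedURI",
}


def _props_from_json(d: dict) -> ObjectProperties:
    extra = {k: v for k, v in d.items() if k not in _KNOWN_OBJECT_KEYS}
    return ObjectProperties(
        name=d.get("name", ""),
        description=d.get("description", ""),
        linkedURI=d.get("linkedURI"),
        extra=extra,
    )


def _triplet(x) -> tuple[float, float, float]:
    return (float(x[0]), float(x[1]), float(x[2]))


def _triplets(xs) -> tuple:
    return tuple(_triplet(x) for x in xs)


def _object_from_json(d: dict) -> GeometricObject:
    t = d["type"]
    props = _props_from_json(d)
    if t == "point":
        return Point(_triplets(d["coordinates"]), props)
    if t == "sphere":
        return Sphere(_triplet(d["coordinates"]), float(d["radius"]), props)
    if t == "lineString":
        return LineString(_triplets(d["coordinates"]), props)
    if t == "cylinder":
        return Cylinder(_triplets(d["coordinates"]), float(d["radius"]), props)
    if t == "polygon":
        return Polygon(_triplets(d["coordinates"]), props)
    if t == "polyhedron":
        return Polyhedron(
            _triplets(d["coordinates"]),
            tuple(tuple(int(i) for i in f) for f in d["faces"]),
            props,
        )
    if t == "atlasMesh":
        return AtlasMeshRef(
            d["parcellationEntityVersion"], d.get("regionName", ""), props
        )
    raise LocareValidationError([("/type", f"unknown-type: {t!r}")])


def parse_locare(text: str) -> LocareCollection:
    """Parse and validate a LocareJSON document string.

    Raises :class:`LocareParseError` on malformed JSON (with line/column),
    :class:`LocareValidationError` when the document fails the dialect
    schemas or the in-memory invariants, listing JSON-pointer paths.
    """
    try:
        tree = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LocareParseError(exc.msg, exc.lineno, exc.colno) from None

    schemas = emit_dialect_schemas()
    errors = validate_against_schema(tree, schemas["locareCollection"])
    if errors:
        raise LocareValidationError(errors)

    for i, od in enumerate(tree.get("objects", [])):
        t = od.get("type")
        if t not in schemas:
            raise LocareValidationError(
                [(f"/objects/{i}/type", f"unknown-type: {t!r}")]
            )
        obj_errors = validate_against_schema(od, schemas[t], f"/objects/{i}")
        if obj_errors:
            raise LocareValidationError(obj_errors)

    ta = tree["targetAtlas"]
    space = AtlasSpace(
        identifier=ta["identifier"],
        name=ta.get("name", ""),
        dimensions=tuple(int(d) for d in ta["dimensions"]),
        resolution=float(ta["resolution"]),
        orientation=ta["orientation"],
        origin=_triplet(ta.get("origin", (0.0, 0.0, 0.0))),
    )
    collection = LocareCollection(
        version=tree["version"],
        targetAtlas=space,
        sourcePublication=tuple(tree["sourcePublication"]),
        relatedPublications=(
            tuple(tree["relatedPublications"])
            if tree.get("relatedPublications") is not None
            else None
        ),
        linkedURI=tree.get("linkedURI"),
        objects=tuple(_object_from_json(od) for od in tree["objects"]),
    )
    violations = [v for v in validate_collection(collection) if v.severity == "error"]
    if violations:
        raise LocareValidationError(
            [(f"/{v.field.replace('.', '/').replace('[', '/').replace(']', '')}", v.rule) for v in violations]
        )
    return collection


# ---------------------------------------------------------------------------
# writing


def _object_to_json(obj: GeometricObject) -> dict:
    d: dict[str, Any] = {"type": obj.type_name}
    if isinstance(obj, Point) or isinstance(obj, LineString) or isinstance(obj, Polygon):
        d["coordinates"] = [list(t) for t in obj.coordinates]
    elif isinstance(obj, Sphere):
        d["coordinates"] = list(obj.centroid)
        d["radius"] = obj.radius
    elif isinstance(obj, Cylinder):
        d["coordinates"] = [list(t) for t in obj.axis]
        d["radius"] = obj.radius
    elif isinstance(obj, Polyhedron):
        d["coordinates"] = [list(t) for t in obj.vertices]
        d["faces"] = [list(f) for f in obj.faces]
    elif isinstance(obj, AtlasMeshRef):
        d["parcellationEntityVersion"] = obj.parcellationEntityVersion
        if obj.regionName:
            d["regionName"] = obj.regionName
    p = obj.properties
    d["name"] = p.name
    d["description"] = p.description
    if p.linkedURI is not None:
        d["linkedURI"] = p.linkedURI
    for k in sorted(p.extra):
        d[k] = p.extra[k]
    return d


def collection_to_json_obj(c: LocareCollection) -> dict:
    """The JSON tree for a collection, keys in the documented fixed order."""
    d: dict[str, Any] = {
        "version": c.version,
        "targetAtlas": {
            "identifier": c.targetAtlas.identifier,
            "name": c.targetAtlas.name,
            "dimensions": [int(x) for x in c.targetAtlas.dimensions],
            "resolution": c.targetAtlas.resolution,
            "orientation": c.targetAtlas.orientation,
            "origin": list(c.targetAtlas.origin),
        },
        "sourcePublication": list(c.sourcePublication),
    }
    if c.relatedPublications is not None:
        d["relatedPublications"] = list(c.relatedPublications)
    if c.linkedURI is not None:
        d["linkedURI"] = c.linkedURI
    d["objects"] = [_object_to_json(o) for o in c.objects]
    return d


def write_locare(c: LocareCollection) -> str:
    """Serialize a valid collection deterministically.

    Key order is fixed, floats use Python's shortest round-trip ``repr``,
    and two calls on equal collections yield byte-identical strings.
    Refuses (with the violation list) when the collection fails
    :func:`~locarekit.core_model.validate_collection`.
    """
    violations = [v for v in validate_collection(c) if v.severity == "error"]
    if violations:
        raise LocareValidationError([(v.field, v.rule) for v in violations])
    return json.dumps(collection_to_json_obj(c), indent=2, ensure_ascii=False)
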