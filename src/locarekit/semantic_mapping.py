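"""Resolve region terms against a target-atlas terminology and build
atlas-mesh objects with semantic annotations.

The semantic route handles data whose only location documentation is a
textual region name. The module does the computable part: rank candidate
terms from the target-atlas terminology (exact name > synonym > normalized
> unique substring), and attach an annotation describing how well the
chosen term represents the original sampling location (granularity,
coverage, specificity, confidence). The judgment-laden choice between
candidates — the specificity-versus-confidence trade-off — is deliberately
left to the user; the module only ranks and enforces annotation
consistency (e.g. substituting a parent term must not claim finer
granularity).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .core_model import AtlasMeshRef, ObjectProperties

__all__ = [
    "TerminologyNode",
    "SemanticAnnotation",
    "Match",
    "load_terminology",
    "resolve_term",
    "make_atlas_mesh_object",
]

GRANULARITY = ("finer", "matched", "coarser")
COVERAGE = ("partial", "full", "exceeds")
CONFIDENCE = ("high", "medium", "low")

_MATCH_RANK = {"exact": 0, "synonym": 1, "normalized": 2, "substring": 3}


@dataclass
class TerminologyNode:
    """One region term in the atlas terminology tree."""

    regionId: str
    name: str
    synonyms: tuple[str, ...] = ()
    parentId: Optional[str] = None
    children: list["TerminologyNode"] = field(default_factory=list)


@dataclass(frozen=True)
class SemanticAnnotation:
    """How well the chosen atlas term represents the original location.

    ``granularity``: is the chosen term finer, matched or coarser than the
    originally reported one. ``coverage``: does the term cover the sampled
    location partially, fully, or does it exceed it. ``specificity`` and
    ``rationale`` are free text (accuracy judgments are not
    machine-checkable and live in the rationale). ``confidence`` is the
    annotator's confidence in the mapping.
    """

    granularity: str
    coverage: str
    confidence: str
    specificity: str = ""
    rationale: str = ""

    def validate(self) -> list[str]:
        problems = []
        if self.granularity not in GRANULARITY:
            problems.append(f"granularity must be one of {GRANULARITY}")
        if self.coverage not in COVERAGE:
            problems.append(f"coverage must be one of {COVERAGE}")
        if self.confidence not in CONFIDENCE:
            problems.append(f"confidence must be one of {CONFIDENCE}")
        return problems


@dataclass(frozen=True)
class Match:
    """One candidate term: region id, how it matched, and its tree path."""

    regionId: str
    matchType: str  # exact | synonym | normalized | substring
    path: tuple[str, ...]  # root-to-node region ids
    name: str
    ambiguous: bool = False


class TerminologyError(ValueError):
    """Malformed terminology: cycle, duplicate id, or multiple roots."""


def load_terminology(text_or_list) -> TerminologyNode:
    """Build and validate the terminology tree from the flat JSON dialect.

    Input is a JSON array (or already-parsed list) of
    ``{"id", "name", "synonyms": [...], "parent"}`` records; exactly one
    record has no parent (the root). Duplicate ids, unknown parents,
    cycles and forests raise :class:`TerminologyError` ('bad-terminology').
    """
    records = json.loads(text_or_list) if isinstance(text_or_list, str) else text_or_list
    nodes: dict[str, TerminologyNode] = {}
    for rec in records:
        rid = rec["id"]
        if rid in nodes:
            raise TerminologyError(f"bad-terminology: duplicate id {rid!r}")
        nodes[rid] = TerminologyNode(
            regionId=rid,
            name=rec["name"],
            synonyms=tuple(rec.get("synonyms", ())),
            parentId=rec.get("parent"),
        )
    roots = []
    for node in nodes.values():
        if node.parentId is None:
            roots.append(node)
        else:
            if node.parentId not in nodes:
                raise TerminologyError(
                    f"bad-terminology: unknown parent {node.parentId!r} of {node.regionId!r}"
                )
            nodes[node.parentId].children.append(node)
    if len(roots) != 1:
        raise TerminologyError(f"bad-terminology: {len(roots)} roots, need exactly 1")
    # cycle check: every node must reach the root
    for node in nodes.values():
        seen = set()
        cur = node
        while cur.parentId is not None:
            if cur.regionId in seen:
                raise TerminologyError(f"bad-terminology: cycle at {cur.regionId!r}")
            seen.add(cur.regionId)
            cur = nodes[cur.parentId]
    return roots[0]


def _walk(root: TerminologyNode):
    stack = [(root, (root.regionId,))]
    while stack:
        node, path = stack.pop()
        yield node, path
        for child in sorted(node.children, key=lambda c: c.regionId, reverse=True):
            stack.append((child, path + (child.regionId,)))


def _normalize(s: str) -> str:
    # lowercase, strip punctuation/hyphens, collapse whitespace; no stemming
    s = re.sub(r"[^\w\s]|_", " ", s.lower())
    return re.sub(r"\s+", " ", s).strip()


def resolve_term(query: str, terminology: TerminologyNode) -> list[Match]:
    """Rank candidate terminology nodes for a free-text region term.

    Match classes, best first: exact name, synonym, case/punctuation-
    normalized name or synonym, unique substring of a normalized name.
    Ties within a class are ordered by tree path. Substring candidates
    matching more than one node are all returned and flagged ambiguous.
    An empty result means the caller must substitute a coarser term
    manually.
    """
    if not query:
        raise ValueError("empty query")
    nq = _normalize(query)
    found: dict[str, tuple[int, Match]] = {}

    def record(node, path, mtype):
        rank = _MATCH_RANK[mtype]
        prev = found.get(node.regionId)
        if prev is None or rank < prev[0]:
            found[node.regionId] = (
                rank,
                Match(node.regionId, mtype, path, node.name),
            )

    for node, path in _walk(terminology):
        if query == node.name:
            record(node, path, "exact")
        elif query in node.synonyms:
            record(node, path, "synonym")
        elif nq == _normalize(node.name) or nq in (_normalize(s) for s in node.synonyms):
            record(node, path, "normalized")
        elif nq and nq in _normalize(node.name):
            record(node, path, "substring")

    matches = sorted(found.values(), key=lambda rm: (rm[0], rm[1].path))
    result = [m for _, m in matches]
    n_sub = sum(1 for m in result if m.matchType == "substring")
    if n_sub > 1:
        result = [
            Match(m.regionId, m.matchType, m.path, m.name, ambiguous=(m.matchType == "substring"))
            for m in result
        ]
    return result


def _find_node(root: TerminologyNode, regionId: str):
    for node, path in _walk(root):
        if node.regionId == regionId:
            return node, path
    return None, None


def make_atlas_mesh_object(
    regionId: str,
    terminology: TerminologyNode,
    annotation: SemanticAnnotation,
    original_query: Optional[str] = None,
    name: Optional[str] = None,
) -> AtlasMeshRef:
    """Build an atlas-mesh object for a chosen terminology region.

    The annotation is stored in the object's extra fields (so it survives
    round-trip serialization). When ``original_query`` is given and the
    chosen region is a strict ancestor of an exact match for that query,
    the annotation must say ``granularity="coarser"`` — a parent-term
    substitution cannot claim a finer or matched granularity.
    Unknown region ids raise ``KeyError('unknown-region')``.
    """
    problems = annotation.validate()
    if problems:
        raise ValueError("; ".join(problems))
    node, path = _find_node(terminology, regionId)
    if node is None:
        raise KeyError(f"unknown-region: {regionId!r}")
    if original_query is not None:
        for m in resolve_term(original_query, terminology):
            if m.matchType != "exact":
                continue
            # chosen region strictly above the exact match in the tree?
            if regionId in m.path[:-1] and annotation.granularity != "coarser":
                raise ValueError(
                    f"inconsistent annotation: {regionId!r} is an ancestor of the "
                    f"exact match {m.regionId!r}; granularity must be 'coarser'"
                )
    return AtlasMeshRef(
        parcellationEntityVersion=node.regionId,
        regionName=node.name,
        properties=ObjectProperties(
            name=name or node.name,
            description=annotation.rationale or f"Semantic mapping to {node.name}",
            extra={
                "annotation": {
                    "granularity": annotation.granularity,
                    "coverage": annotation.coverage,
                    "confidence": annotation.confidence,
                    "specificity": annotation.specificity,
                    "rationale": annotation.rationale,
                }
            },
        ),
    )
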