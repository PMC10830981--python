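"""Shared knowledge-graph data model.

A knowledge graph here is the tuple G = (E, R, T, C, D): a set of entities E,
a set of relation labels R, a list of weighted triples T of the form
(head, relation, tail, weight), a partial map C from entities to category
labels and a partial map D from entities to free-text descriptions.  The
other modules (tabular builder, image builder, gene-tree explainer) all emit
this structure, so validation and serialization live in one place.

Serialization dialects
----------------------
* GraphML (via networkx): nodes carry ``category`` and ``description``
  attributes, edges carry ``relation`` and ``weight``; the full relation
  vocabulary is kept as a graph-level attribute so relations unused by any
  triple survive a round trip.
* JSON: ``{"entities": [...], "relations": [...], "triples":
  [[head, rel, tail, weight], ...], "categories": {...},
  "descriptions": {...}}``.

Both are round-trip safe up to triple ordering.
"""

from __future__ import annotations

import io
import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

_FORMATS = ("graphml", "json")


class GraphFormatError(ValueError):
    """Unknown serialization format requested."""


class GraphParseError(ValueError):
    """Malformed serialized document."""


class InvalidGraphError(ValueError):
    """Graph failed invariant validation; carries the violation list."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "graph failed validation:\n" + "\n".join(f"- {v}" for v in violations)
        )


@dataclass
class KnowledgeGraph:
    """Entities, relation labels, weighted triples, categories, descriptions.

    Triples are kept as an ordered list for reproducible output files, but
    equality is order-insensitive (two graphs with the same triple multiset
    are equal).  Entity identifiers are opaque strings.
    """

    entities: set[str] = field(default_factory=set)
    relations: set[str] = field(default_factory=set)
    triples: list[tuple[str, str, str, float]] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.relations == other.relations
            and sorted(self.triples) == sorted(other.triples)
            and self.categories == other.categories
            and self.descriptions == other.descriptions
        )


def validate(graph: KnowledgeGraph) -> list[str]:
    """Check all graph invariants; return one message per violation.

    Never raises: an empty list means the graph is valid.
    """
    violations: list[str] = []
    for idx, triple in enumerate(graph.triples):
        try:
            head, rel, tail, weight = triple
        except (TypeError, ValueError):
            violations.append(f"triple #{idx} is not a (head, rel, tail, weight) 4-tuple: {triple!r}")
            continue
        if head not in graph.entities:
            violations.append(f"triple #{idx}: head {head!r} is not in entities")
        if tail not in graph.entities:
            violations.append(f"triple #{idx}: tail {tail!r} is not in entities")
        if rel not in graph.relations:
            violations.append(f"triple #{idx}: relation {rel!r} is not in relations")
        if not isinstance(weight, (int, float)) or not math.isfinite(weight):
            violations.append(
                f"triple #{idx} ({head!r}, {rel!r}, {tail!r}): weight {weight!r} is not finite"
            )
    for name, mapping in (("categories", graph.categories), ("descriptions", graph.descriptions)):
        extra = set(mapping) - graph.entities
        for ent in sorted(extra):
            violations.append(f"{name} key {ent!r} is not in entities")
    return violations


def write_graph(graph: KnowledgeGraph, format: str = "graphml") -> str:
    """Serialize a valid graph to text in the named dialect.

    Raises :class:`InvalidGraphError` if the graph fails :func:`validate`.
    """
    if format not in _FORMATS:
        raise GraphFormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
    violations = validate(graph)
    if violations:
        raise InvalidGraphError(violations)
    if format == "json":
        doc = {
            "entities": sorted(graph.entities),
            "relations": sorted(graph.relations),
            "triples": [[h, r, t, w] for h, r, t, w in graph.triples],
            "categories": dict(sorted(graph.categories.items())),
            "descriptions": dict(sorted(graph.descriptions.items())),
        }
        return json.dumps(doc, indent=2, sort_keys=False)
    g = nx.MultiDiGraph()
    g.graph["relations"] = json.dumps(sorted(map(str, graph.relations)))
    for ent in sorted(graph.entities):
        attrs = {}
        if ent in graph.categories:
            attrs["category"] = str(graph.categories[ent])
        if ent in graph.descriptions:
            attrs["description"] = str(graph.descriptions[ent])
        g.add_node(str(ent), **attrs)
    for h, r, t, w in graph.triples:
        g.add_edge(str(h), str(t), relation=str(r), weight=float(w))
    buf = io.BytesIO()
    nx.write_graphml(g, buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")


def read_graph(text: str, format: str = "graphml") -> KnowledgeGraph:
    """Parse a serialized graph; the result always passes :func:`validate`.

    A GraphML edge without a ``weight`` attribute (or a JSON triple with only
    three elements) gets weight 1.0 with a logged warning, so externally
    produced files remain usable.
    """
    if format not in _FORMATS:
        raise GraphFormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "json":
        return _read_json(text)
    return _read_graphml(text)


def _read_json(text: str) -> KnowledgeGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GraphParseError(f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise GraphParseError("JSON document is not an object")
    triples: list[tuple[str, str, str, float]] = []
    for raw in doc.get("triples", []):
        if len(raw) == 3:
            logger.warning("triple %r has no weight; defaulting to 1.0", raw)
            h, r, t = raw
            w = 1.0
        elif len(raw) == 4:
            h, r, t, w = raw
        else:
            raise GraphParseError(f"triple {raw!r} does not have 3 or 4 elements")
        triples.append((str(h), str(r), str(t), float(w)))
    graph = KnowledgeGraph(
        entities=set(map(str, doc.get("entities", []))),
        relations=set(map(str, doc.get("relations", []))),
        triples=triples,
        categories={str(k): str(v) for k, v in doc.get("categories", {}).items()},
        descriptions={str(k): str(v) for k, v in doc.get("descriptions", {}).items()},
    )
    violations = validate(graph)
    if violations:
        raise GraphParseError("parsed graph is invalid: " + "; ".join(violations))
    return graph


def _read_graphml(text: str) -> KnowledgeGraph:
    try:
        g = nx.parse_graphml(text, node_type=str, force_multigraph=True)
    except ET.ParseError as exc:
        raise GraphParseError(f"malformed GraphML at line {exc.position[0]}, column {exc.position[1]}") from exc
    except (nx.NetworkXError, KeyError) as exc:
        raise GraphParseError(f"malformed GraphML: {exc}") from exc
    entities = set(g.nodes())
    categories = {}
    descriptions = {}
    for node, attrs in g.nodes(data=True):
        if "category" in attrs:
            categories[node] = str(attrs["category"])
        if "description" in attrs:
            descriptions[node] = str(attrs["description"])
    triples = []
    relations: set[str] = set()
    if "relations" in g.graph:
        relations |= set(json.loads(g.graph["relations"]))
    for h, t, attrs in g.edges(data=True):
        rel = str(attrs.get("relation", "related_to"))
        if "weight" in attrs:
            w = float(attrs["weight"])
        else:
            logger.warning("edge %r->%r has no weight attribute; defaulting to 1.0", h, t)
            w = 1.0
        triples.append((h, rel, t, w))
        relations.add(rel)
    graph = KnowledgeGraph(
        entities=entities,
        relations=relations,
        triples=triples,
        categories=categories,
        descriptions=descriptions,
    )
    violations = validate(graph)
    if violations:
        raise GraphParseError("parsed graph is invalid: " + "; ".join(violations))
    return graph
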