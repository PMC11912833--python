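"""Ontology data model, OBO / OBO-Graph-JSON readers and writers, closures.

The in-memory substrate for everything else in the package: terms identified
by CURIEs, typed edges (``is_a``, ``part_of``, ...), and reflexive-transitive
closure queries over selected edge types.  Closure over ``{is_a, part_of}``
treats mixed chains as ancestry (property-chain semantics:
``is_a ∘ part_of → part_of`` and ``part_of ∘ is_a → part_of``), which is the
single ancestry semantics used by the structural reasoner: an aortic valve
that is part of the heart contributes the heart to its ancestry.

Only a pragmatic subset of each exchange format is supported: OBO flat files
restricted to ``[Term]`` stanzas (id, name, def, synonym, is_a, relationship,
is_obsolete; unknown tags are preserved as opaque annotations) and the
nodes/edges dialect of OBO-Graph-JSON.  Dangling references are recorded and
reported, not silently dropped; a strict flag turns them into hard errors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from functools import total_ordering
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ParseError, UnknownTermError, ValidationError

__all__ = [
    "Curie",
    "OntologyTerm",
    "OntologyEdge",
    "OntologyGraph",
    "ValidationReport",
    "IS_A",
    "PART_OF",
    "OCCURS_IN",
    "HAS_PART",
    "CHARACTERISTIC_OF",
    "CHARACTERISTIC_OF_PART_OF",
    "TOWARDS",
    "HAS_MODIFIER",
    "HAS_ROLE",
    "parse_obo",
    "write_obo",
    "parse_obograph_json",
    "write_obograph_json",
    "load_graph",
    "save_graph",
]

# Built-in predicate vocabulary (OBO relationship shorthand names).
IS_A = "is_a"
PART_OF = "part_of"
OCCURS_IN = "occurs_in"
HAS_PART = "has_part"
CHARACTERISTIC_OF = "characteristic_of"
CHARACTERISTIC_OF_PART_OF = "characteristic_of_part_of"
TOWARDS = "towards"
HAS_MODIFIER = "has_modifier"
HAS_ROLE = "has_role"

BUILTIN_PREDICATES = frozenset(
    {
        IS_A,
        PART_OF,
        OCCURS_IN,
        HAS_PART,
        CHARACTERISTIC_OF,
        CHARACTERISTIC_OF_PART_OF,
        TOWARDS,
        HAS_MODIFIER,
        HAS_ROLE,
    }
)

_CURIE_RE = re.compile(r"^(?P<prefix>[A-Za-z_][A-Za-z0-9_.]*):(?P<local>\S+)$")


@total_ordering
@dataclass(frozen=True)
class Curie:
    """A compact identifier ``prefix:local_id``.

    Comparison and hashing are case-sensitive on the rendered form, so CURIEs
    sort and deduplicate exactly as their string rendering would.
    """

    prefix: str
    local_id: str

    @classmethod
    def parse(cls, text: "str | Curie") -> "Curie":
        if isinstance(text, Curie):
            return text
        m = _CURIE_RE.match(text.strip())
        if not m:
            raise ParseError(f"not a CURIE: {text!r}")
        return cls(m.group("prefix"), m.group("local"))

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __lt__(self, other: "Curie") -> bool:
        return str(self) < str(other)


def as_curie(value: str | Curie) -> Curie:
    """Coerce a string or Curie to a Curie."""
    return Curie.parse(value)


@dataclass(frozen=True)
class OntologyTerm:
    id: Curie
    label: str = ""
    text_definition: str | None = None
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope tag)
    obsolete: bool = False
    # Unknown OBO tags, preserved verbatim for round-tripping.
    annotations: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class OntologyEdge:
    subject: Curie
    predicate: str  # builtin shorthand or a rendered CURIE
    object: Curie


@dataclass
class ValidationReport:
    """Summary of referential problems found in a graph."""

    dangling: list[OntologyEdge] = field(default_factory=list)
    duplicate_ids: list[Curie] = field(default_factory=list)
    unlabeled: list[Curie] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.dangling or self.duplicate_ids or self.unlabeled)

    def summary(self) -> str:
        parts = []
        if self.dangling:
            refs = ", ".join(f"{e.subject}-[{e.predicate}]->{e.object}" for e in self.dangling[:10])
            parts.append(f"{len(self.dangling)} dangling reference(s): {refs}")
        if self.duplicate_ids:
            parts.append(f"duplicate ids: {', '.join(map(str, self.duplicate_ids))}")
        if self.unlabeled:
            parts.append(f"unlabeled non-obsolete terms: {', '.join(map(str, self.unlabeled))}")
        return "; ".join(parts) if parts else "ok"


class OntologyGraph:
    """Terms plus typed edges, with closure queries.

    Edges run child -> parent (subject -> object), so "closure" means the
    ancestor set of the start term.
    """

    def __init__(self, ontology_id: str = "", version: str = ""):
        self.ontology_id = ontology_id
        self.version = version
        self.terms: dict[Curie, OntologyTerm] = {}
        self.edges: list[OntologyEdge] = []
        self._adjacency_cache: dict = {}

    # -- construction -----------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        self.terms[term.id] = term
        self._adjacency_cache.clear()

    def add_edge(self, subject: str | Curie, predicate: str, object: str | Curie) -> None:
        self.edges.append(OntologyEdge(as_curie(subject), predicate, as_curie(object)))
        self._adjacency_cache.clear()

    def update(self, other: "OntologyGraph") -> None:
        """Merge another graph's terms and edges into this one."""
        for t in other.terms.values():
            self.terms[t.id] = t
        self.edges.extend(other.edges)
        self._adjacency_cache.clear()

    # -- lookup -----------------------------------------------------------

    def __contains__(self, curie: str | Curie) -> bool:
        return as_curie(curie) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, curie: str | Curie) -> OntologyTerm:
        c = as_curie(curie)
        try:
            return self.terms[c]
        except KeyError:
            raise UnknownTermError(f"unknown term id: {c}") from None

    def label(self, curie: str | Curie) -> str:
        return self.term(curie).label

    def label_map(self) -> dict[Curie, str]:
        return {c: t.label for c, t in self.terms.items()}

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        for e in self.edges:
            if e.subject not in self.terms or e.object not in self.terms:
                report.dangling.append(e)
        for c, t in self.terms.items():
            if not t.obsolete and not t.label:
                report.unlabeled.append(c)
        return report

    # -- closures ---------------------------------------------------------

    def _adjacency(self, predicates: frozenset[str], include_obsolete: bool) -> dict[Curie, list[Curie]]:
        key = (predicates, include_obsolete)
        adj = self._adjacency_cache.get(key)
        if adj is None:
            adj = {}
            for e in self.edges:
                if e.predicate not in predicates:
                    continue
                if e.subject not in self.terms or e.object not in self.terms:
                    continue  # dangling: reported by validate(), excluded here
                if not include_obsolete and (
                    self.terms[e.subject].obsolete or self.terms[e.object].obsolete
                ):
                    continue
                adj.setdefault(e.subject, []).append(e.object)
            self._adjacency_cache[key] = adj
        return adj

    def closure(
        self,
        start: str | Curie,
        predicates: Iterable[str] = (IS_A,),
        reflexive: bool = True,
        include_obsolete: bool = False,
    ) -> set[Curie]:
        """Reflexive-transitive closure (ancestors) of ``start`` over the
        union of the requested edge types.

        Mixed is_a/part_of chains count as ancestry when both predicates are
        requested.  Obsolete terms are excluded unless ``include_obsolete``.
        """
        start = as_curie(start)
        if start not in self.terms:
            raise UnknownTermError(f"unknown term id: {start}")
        adj = self._adjacency(frozenset(predicates), include_obsolete)
        out: set[Curie] = {start} if reflexive else set()
        stack = [start]
        seen = {start}
        while stack:
            node = stack.pop()
            for parent in adj.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    out.add(parent)
                    stack.append(parent)
        return out

    def descendants(
        self,
        start: str | Curie,
        predicates: Iterable[str] = (IS_A,),
        reflexive: bool = True,
        include_obsolete: bool = False,
    ) -> set[Curie]:
        """Inverse closure: all terms whose closure contains ``start``."""
        start = as_curie(start)
        if start not in self.terms:
            raise UnknownTermError(f"unknown term id: {start}")
        adj = self._adjacency(frozenset(predicates), include_obsolete)
        children: dict[Curie, list[Curie]] = {}
        for sub, parents in adj.items():
            for p in parents:
                children.setdefault(p, []).append(sub)
        out: set[Curie] = {start} if reflexive else set()
        stack = [start]
        seen = {start}
        while stack:
            node = stack.pop()
            for child in children.get(node, ()):
                if child not in seen:
                    seen.add(child)
                    out.add(child)
                    stack.append(child)
        return out

    def roots(self, predicate: str = IS_A) -> list[Curie]:
        """Non-obsolete terms with no outgoing edge of ``predicate``."""
        with_parent = {
            e.subject
            for e in self.edges
            if e.predicate == predicate and e.object in self.terms
        }
        return sorted(
            c for c, t in self.terms.items() if not t.obsolete and c not in with_parent
        )

    def to_networkx(self, predicates: Iterable[str] | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        preds = None if predicates is None else frozenset(predicates)
        for c in self.terms:
            g.add_node(c)
        for e in self.edges:
            if preds is None or e.predicate in preds:
                if e.subject in self.terms and e.object in self.terms:
                    g.add_edge(e.subject, e.object, predicate=e.predicate)
        return g

    def assert_acyclic(self) -> None:
        """is_a and part_of edge sets must each be acyclic."""
        for pred in (IS_A, PART_OF):
            g = self.to_networkx([pred])
            if not nx.is_directed_acyclic_graph(g):
                cycle = nx.find_cycle(g)
                raise ValidationError(f"{pred} cycle detected: {cycle}")

    def copy(self) -> "OntologyGraph":
        g = OntologyGraph(self.ontology_id, self.version)
        g.terms = dict(self.terms)
        g.edges = list(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.ontology_id == other.ontology_id
            and self.version == other.version
            and self.terms == other.terms
            and sorted(self.edges, key=_edge_key) == sorted(other.edges, key=_edge_key)
        )


def _edge_key(e: OntologyEdge) -> tuple[str, str, str]:
    return (str(e.subject), e.predicate, str(e.object))


# ---------------------------------------------------------------------------
# OBO flat file subset
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')
_DEF_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _strip_comment(line: str) -> str:
    # OBO comments start with unescaped '!'
    out = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "\\" and i + 1 < len(line):
            out.append(line[i : i + 2])
            i += 2
            continue
        if ch == "!":
            break
        out.append(ch)
        i += 1
    return "".join(out).strip()


def parse_obo(text: str, strict: bool = False) -> OntologyGraph:
    """Parse an OBO flat file ([Term] stanzas only) into an OntologyGraph.

    A stanza without an ``id`` tag is a hard error naming the stanza ordinal.
    References to undeclared ids are kept as edges and reported by
    ``validate()``; with ``strict=True`` they raise instead.
    """
    graph = OntologyGraph()
    lines = text.splitlines()
    i = 0
    # Header (everything before the first stanza)
    while i < len(lines) and not lines[i].startswith("["):
        line = _strip_comment(lines[i])
        if line.startswith("ontology:"):
            graph.ontology_id = line.split(":", 1)[1].strip()
        elif line.startswith("data-version:"):
            graph.version = line.split(":", 1)[1].strip()
        i += 1

    stanza_ordinal = 0
    while i < len(lines):
        header = lines[i].strip()
        i += 1
        body: list[tuple[str, str]] = []
        while i < len(lines) and not lines[i].startswith("["):
            line = _strip_comment(lines[i])
            i += 1
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"malformed tag line in stanza {stanza_ordinal + 1}: {line!r}")
            tag, value = line.split(":", 1)
            body.append((tag.strip(), value.strip()))
        if header != "[Term]":
            continue  # [Typedef] etc. are outside the supported subset
        stanza_ordinal += 1
        tags = dict()  # first-wins for singular tags
        term_id = None
        label = ""
        definition = None
        synonyms: list[tuple[str, str]] = []
        obsolete = False
        annotations: list[tuple[str, str]] = []
        edges: list[tuple[str, str]] = []
        for tag, value in body:
            if tag == "id":
                term_id = Curie.parse(value)
            elif tag == "name":
                label = value
            elif tag == "def":
                m = _DEF_RE.match(value)
                if not m:
                    raise ParseError(f"malformed def in stanza {stanza_ordinal}: {value!r}")
                definition = _unescape(m.group("text"))
            elif tag == "synonym":
                m = _SYNONYM_RE.match(value)
                if not m:
                    raise ParseError(f"malformed synonym in stanza {stanza_ordinal}: {value!r}")
                synonyms.append((_unescape(m.group("text")), m.group("scope") or "RELATED"))
            elif tag == "is_a":
                edges.append((IS_A, value))
            elif tag == "relationship":
                parts = value.split(None, 1)
                if len(parts) != 2:
                    raise ParseError(
                        f"malformed relationship in stanza {stanza_ordinal}: {value!r}"
                    )
                edges.append((parts[0], parts[1]))
            elif tag == "is_obsolete":
                obsolete = value.lower() == "true"
            else:
                annotations.append((tag, value))
        if term_id is None:
            raise ParseError(f"[Term] stanza {stanza_ordinal} has no id tag")
        graph.add_term(
            OntologyTerm(
                id=term_id,
                label=label,
                text_definition=definition,
                synonyms=tuple(synonyms),
                obsolete=obsolete,
                annotations=tuple(annotations),
            )
        )
        for pred, target in edges:
            graph.add_edge(term_id, pred, Curie.parse(target))

    if strict:
        report = graph.validate()
        if report.dangling:
            raise ValidationError(f"dangling references: {report.summary()}")
    return graph


def write_obo(graph: OntologyGraph) -> str:
    """Serialize the supported OBO subset deterministically (terms sorted by
    id, tags in canonical order)."""
    out: list[str] = ["format-version: 1.2"]
    if graph.version:
        out.append(f"data-version: {graph.version}")
    if graph.ontology_id:
        out.append(f"ontology: {graph.ontology_id}")
    edges_by_subject: dict[Curie, list[OntologyEdge]] = {}
    for e in graph.edges:
        edges_by_subject.setdefault(e.subject, []).append(e)
    for curie in sorted(graph.terms):
        t = graph.terms[curie]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {t.id}")
        if t.label:
            out.append(f"name: {t.label}")
        if t.text_definition is not None:
            out.append(f'def: "{_escape(t.text_definition)}" []')
        for syn_text, scope in t.synonyms:
            out.append(f'synonym: "{_escape(syn_text)}" {scope} []')
        for tag, value in t.annotations:
            out.append(f"{tag}: {value}")
        if t.obsolete:
            out.append("is_obsolete: true")
        for e in sorted(edges_by_subject.get(curie, []), key=_edge_key):
            if e.predicate == IS_A:
                out.append(f"is_a: {e.object}")
            else:
                out.append(f"relationship: {e.predicate} {e.object}")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# OBO-Graph-JSON (nodes/edges dialect)
# ---------------------------------------------------------------------------


def write_obograph_json(graph: OntologyGraph) -> str:
    """Serialize to the OBO-Graph-JSON nodes/edges dialect, deterministically
    (sorted nodes and edges, sorted keys)."""
    nodes = []
    for curie in sorted(graph.terms):
        t = graph.terms[curie]
        meta: dict = {}
        if t.text_definition is not None:
            meta["definition"] = {"val": t.text_definition}
        if t.synonyms:
            meta["synonyms"] = [
                {"pred": scope, "val": text} for text, scope in t.synonyms
            ]
        if t.obsolete:
            meta["deprecated"] = True
        if t.annotations:
            meta["basicPropertyValues"] = [
                {"pred": tag, "val": value} for tag, value in t.annotations
            ]
        node: dict = {"id": str(t.id), "lbl": t.label, "type": "CLASS"}
        if meta:
            node["meta"] = meta
        nodes.append(node)
    edges = [
        {"sub": str(e.subject), "pred": e.predicate, "obj": str(e.object)}
        for e in sorted(graph.edges, key=_edge_key)
    ]
    doc = {
        "graphs": [
            {
                "id": graph.ontology_id,
                "meta": {"version": graph.version},
                "nodes": nodes,
                "edges": edges,
            }
        ]
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def parse_obograph_json(text: str, strict: bool = False) -> OntologyGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    graphs = doc.get("graphs", [])
    if not graphs:
        return OntologyGraph()
    g = graphs[0]
    graph = OntologyGraph(g.get("id", ""), (g.get("meta") or {}).get("version", ""))
    for node in g.get("nodes", []):
        if "id" not in node:
            raise ParseError("node without id in OBO-Graph-JSON document")
        meta = node.get("meta") or {}
        synonyms = tuple(
            (s["val"], s.get("pred", "RELATED")) for s in meta.get("synonyms", [])
        )
        annotations = tuple(
            (p["pred"], p["val"]) for p in meta.get("basicPropertyValues", [])
        )
        definition = meta.get("definition", {}).get("val") if meta.get("definition") else None
        graph.add_term(
            OntologyTerm(
                id=Curie.parse(node["id"]),
                label=node.get("lbl", ""),
                text_definition=definition,
                synonyms=synonyms,
                obsolete=bool(meta.get("deprecated", False)),
                annotations=annotations,
            )
        )
    for edge in g.get("edges", []):
        graph.add_edge(Curie.parse(edge["sub"]), edge["pred"], Curie.parse(edge["obj"]))
    if strict:
        report = graph.validate()
        if report.dangling:
            raise ValidationError(f"dangling references: {report.summary()}")
    return graph


# ---------------------------------------------------------------------------
# File-level helpers (format by extension)
# ---------------------------------------------------------------------------


def load_graph(path: str, strict: bool = False) -> OntologyGraph:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return parse_obograph_json(text, strict=strict)
    if str(path).endswith(".obo"):
        return parse_obo(text, strict=strict)
    raise ParseError(f"unrecognized ontology file extension: {path}")


def save_graph(graph: OntologyGraph, path: str) -> None:
    if str(path).endswith(".json"):
        text = write_obograph_json(graph)
    elif str(path).endswith(".obo"):
        text = write_obo(graph)
    else:
        raise ParseError(f"unrecognized ontology file extension: {path}")
    from .cli_util import atomic_write_text

    atomic_write_text(path, text)
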