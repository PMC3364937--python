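"""Gene Ontology DAG: parsing, subsumption queries, cross-release term sharing.

The ontology is a rooted directed acyclic graph per namespace (biological_process,
molecular_function, cellular_component). Terms are related by typed child->parent
edges; only the true-path relations ``is_a`` and ``part_of`` propagate
annotations, and ``part_of`` edges that cross a namespace boundary do not
propagate (the three ontologies are analyzed separately). Other relation types
(``regulates`` etc.) are parsed and kept but never traversed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import obonet
from lxml import etree

PROPAGATING_RELATIONS = frozenset({"is_a", "part_of"})
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_TERM_ID = re.compile(r"GO:\d{7}$")


class OntologyError(Exception):
    """Structural problem in an ontology (cycle, dangling parent, bad stanza)."""


class UnknownTermError(KeyError):
    """A term identifier that cannot be resolved in the graph."""


@dataclass
class OntologyGraph:
    """In-memory GO DAG.

    ``parents`` maps a term to its set of ``(parent, relation)`` edges;
    ``alt_ids`` maps merged/secondary identifiers to their canonical term.
    Obsolete terms are kept (flagged), never dropped.
    """

    terms: set[str] = field(default_factory=set)
    name: dict[str, str] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    _ancestors: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _descendants: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _children: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False
    )

    # -- identifier resolution -------------------------------------------------

    def resolve(self, term: str) -> str:
        """Return the canonical identifier for ``term`` (follows alt_id merges)."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def resolve_or_none(self, term: str) -> str | None:
        try:
            return self.resolve(term)
        except UnknownTermError:
            return None

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_ids

    # -- DAG queries -----------------------------------------------------------

    def _propagating_parents(self, term: str) -> Iterable[str]:
        ns = self.namespace.get(term)
        for parent, rel in self.parents.get(term, ()):
            if rel == "is_a":
                yield parent
            elif rel == "part_of" and self.namespace.get(parent) == ns:
                yield parent

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive closure of ``term`` over propagating relations."""
        term = self.resolve(term)
        if term in self.obsolete:
            raise OntologyError(f"ancestors() of obsolete term {term}")
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        # iterative DFS with memoisation; the graph is acyclic by validation
        out: set[str] = {term}
        stack = list(self._propagating_parents(term))
        while stack:
            p = stack.pop()
            if p in out:
                continue
            hit = self._ancestors.get(p)
            if hit is not None:
                out |= hit
            else:
                out.add(p)
                stack.extend(self._propagating_parents(p))
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def _child_index(self) -> dict[str, set[str]]:
        if self._children is None:
            idx: dict[str, set[str]] = {t: set() for t in self.terms}
            for child in self.terms:
                for parent in self._propagating_parents(child):
                    idx.setdefault(parent, set()).add(child)
            self._children = idx
        return self._children

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive-transitive closure in the child direction."""
        term = self.resolve(term)
        if term in self.obsolete:
            raise OntologyError(f"descendants() of obsolete term {term}")
        cached = self._descendants.get(term)
        if cached is not None:
            return cached
        idx = self._child_index()
        out: set[str] = {term}
        stack = list(idx.get(term, ()))
        while stack:
            c = stack.pop()
            if c in out:
                continue
            out.add(c)
            stack.extend(idx.get(c, ()))
        result = frozenset(out)
        self._descendants[term] = result
        return result

    def roots(self) -> dict[str, str]:
        """Map namespace -> root term (non-obsolete term without propagating parents)."""
        out: dict[str, str] = {}
        for t in self.terms:
            if t in self.obsolete:
                continue
            if not any(True for _ in self._propagating_parents(t)):
                ns = self.namespace[t]
                if ns in out:
                    raise OntologyError(
                        f"namespace {ns} has multiple roots: {out[ns]}, {t}"
                    )
                out[ns] = t
        return out

    # -- validation ------------------------------------------------------------

    def validate(self) -> None:
        """Enforce structural invariants; raise :class:`OntologyError` on violation."""
        dangling = sorted(
            p
            for t in self.terms
            for p, _rel in self.parents.get(t, ())
            if p not in self.terms
        )
        if dangling:
            raise OntologyError(
                "dangling parent references: " + ", ".join(sorted(set(dangling)))
            )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms:
            for p in self._propagating_parents(t):
                g.add_edge(t, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise OntologyError(f"cycle over propagating relations: {path}")
        bad_ns = [
            t
            for t in self.terms
            if t not in self.obsolete and self.namespace.get(t) not in NAMESPACES
        ]
        if bad_ns:
            raise OntologyError(f"terms with missing/unknown namespace: {bad_ns[:5]}")
        roots = self.roots()
        for t in self.terms:
            if t in self.obsolete:
                continue
            root = roots.get(self.namespace[t])
            if root is None or root not in self.ancestors(t):
                raise OntologyError(
                    f"term {t} cannot reach its namespace root over propagating relations"
                )


# -- parsing -------------------------------------------------------------------


def _graph_from_obonet(net: nx.MultiDiGraph) -> OntologyGraph:
    g = OntologyGraph()
    for node, data in net.nodes(data=True):
        if not data:
            # node that only ever appeared as an edge target
            continue
        g.terms.add(node)
        g.name[node] = data.get("name", "")
        if "namespace" in data:
            g.namespace[node] = data["namespace"]
        if str(data.get("is_obsolete", "")).lower() == "true":
            g.obsolete.add(node)
        for alt in data.get("alt_id", []):
            g.alt_ids[alt] = node
        edges: set[tuple[str, str]] = set()
        for parent in data.get("is_a", []):
            edges.add((parent, "is_a"))
        for relationship in data.get("relationship", []):
            rel, _, target = relationship.partition(" ")
            edges.add((target.strip(), rel))
        g.parents[node] = edges
    return g


def _parse_obo_flat(stream: TextIO) -> OntologyGraph:
    try:
        net = obonet.read_obo(stream, ignore_obsolete=False)
    except ValueError as exc:
        raise OntologyError(f"malformed OBO stanza: {exc}") from exc
    return _graph_from_obonet(net)


def _parse_obo_xml(stream: TextIO) -> OntologyGraph:
    data = stream.read()
    if isinstance(data, str):
        data = data.encode()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise OntologyError(f"malformed OBO-XML: {exc}") from exc
    g = OntologyGraph()
    for term in root.iter("term"):
        tid = term.findtext("id")
        if tid is None:
            raise OntologyError("OBO-XML term element without <id>")
        g.terms.add(tid)
        g.name[tid] = term.findtext("name", default="")
        ns = term.findtext("namespace")
        if ns:
            g.namespace[tid] = ns
        if term.findtext("is_obsolete") in ("1", "true"):
            g.obsolete.add(tid)
        for alt in term.findall("alt_id"):
            if alt.text:
                g.alt_ids[alt.text] = tid
        edges: set[tuple[str, str]] = set()
        for isa in term.findall("is_a"):
            if isa.text:
                edges.add((isa.text, "is_a"))
        for rel in term.findall("relationship"):
            rtype = rel.findtext("type")
            to = rel.findtext("to")
            if rtype and to:
                edges.add((to, rtype))
        g.parents[tid] = edges
    return g


def parse_ontology(
    source: str | TextIO, dialect: str = "obo-flat", validate: bool = True
) -> OntologyGraph:
    """Parse an ontology file into an :class:`OntologyGraph`.

    Parameters
    ----------
    source:
        Path or open text stream.
    dialect:
        ``"obo-flat"`` (OBO 1.2 stanza format) or ``"obo-xml"``.
    validate:
        Check acyclicity, dangling references and root reachability.
    """
    if dialect not in ("obo-flat", "obo-xml"):
        raise ValueError(f"unknown ontology dialect: {dialect!r}")
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        g = _parse_obo_flat(source) if dialect == "obo-flat" else _parse_obo_xml(source)
    finally:
        if close:
            source.close()
    if validate:
        g.validate()
    return g


def write_obo(graph: OntologyGraph, dest: str | TextIO) -> None:
    """Serialize a graph as an OBO 1.2 flat file (terms sorted by identifier)."""
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        dest.write("format-version: 1.2\nontology: go\n")
        alt_by_term: dict[str, list[str]] = {}
        for alt, canon in graph.alt_ids.items():
            alt_by_term.setdefault(canon, []).append(alt)
        for term in sorted(graph.terms):
            dest.write(f"\n[Term]\nid: {term}\n")
            dest.write(f"name: {graph.name.get(term, '')}\n")
            if term in graph.namespace:
                dest.write(f"namespace: {graph.namespace[term]}\n")
            for alt in sorted(alt_by_term.get(term, ())):
                dest.write(f"alt_id: {alt}\n")
            for parent, rel in sorted(graph.parents.get(term, ())):
                if rel == "is_a":
                    dest.write(f"is_a: {parent}\n")
                else:
                    dest.write(f"relationship: {rel} {parent}\n")
            if term in graph.obsolete:
                dest.write("is_obsolete: true\n")
    finally:
        if close:
            dest.close()


def shared_terms(graph_old: OntologyGraph, graph_new: OntologyGraph) -> set[str]:
    """Terms usable across a release pair.

    A term is shared when it is non-obsolete in the old graph and resolves
    (possibly through an ``alt_id`` merge) to a non-obsolete term of the new
    graph. Returned identifiers are canonical in ``graph_new``; all per-term
    outputs of a release comparison are restricted to this set.
    """
    out: set[str] = set()
    for t in graph_old.terms:
        if t in graph_old.obsolete:
            continue
        canon = graph_new.resolve_or_none(t)
        if canon is not None and canon not in graph_new.obsolete:
            out.add(canon)
    return out
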