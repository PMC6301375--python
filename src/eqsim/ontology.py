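"""Ontology graphs, a narrow OBO flat-file reader, and structural subsumption.

The graph substrate is a :class:`networkx.DiGraph` of ``is_a`` edges
(child -> parent) plus a separate set of typed relationship edges
(``part_of`` etc.).  Subsumption over post-composed class expressions is
computed with a small structural rule set — the EL-style fragment that
existential restrictions and intersections over an acyclic terminology
require:

R1  Named(x) is subsumed by Named(y) iff y is reachable from x through
    ``is_a`` edges (reflexive-transitive).
R2  Some(p, F) is subsumed by Some(p, F') for every superclass F' of F.
R3  And(c1..ck) is subsumed by every superclass of every conjunct, and by
    itself.
R4  If p is transitive, Some(p, Some(p, F)) is subsumed by Some(p, F') for
    every superclass F' of F (applied to fixpoint).

Named-class equivalence axioms and property hierarchies are deliberately
out of this fragment; ``intersection_of``/``equivalent_to`` OBO lines are
ignored with a warning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, TextIO, Tuple, Union

import networkx as nx

from .expressions import And, ClassExpression, Named, Some, TermId

logger = logging.getLogger(__name__)


class OntologyError(Exception):
    """Base error for ontology loading and lookup problems."""


class OboParseError(OntologyError):
    """Malformed OBO content; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class CycleError(OntologyError):
    pass


@dataclass
class ClassInfo:
    label: str = ""
    synonyms: List[str] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class PropertyInfo:
    transitive: bool = False


class OntologyGraph:
    """Named classes with typed edges; the substrate for subsumption.

    ``is_a`` edges live in ``self.isa`` (networkx DiGraph, child -> parent);
    other relationships in ``rel_edges`` as (subject, property, object).
    """

    def __init__(self):
        self.classes: Dict[TermId, ClassInfo] = {}
        self.isa = nx.DiGraph()
        self.rel_edges: Set[Tuple[TermId, str, TermId]] = set()
        self.properties: Dict[str, PropertyInfo] = {}
        self._anc_cache: Dict[TermId, frozenset] = {}
        self._super_cache: Dict[str, frozenset] = {}
        self._label_index: Optional[Dict[str, List[TermId]]] = None
        self._syn_index: Optional[Dict[str, List[TermId]]] = None

    # -- construction -----------------------------------------------------

    def add_class(self, term: TermId, label: str = "", synonyms=(), obsolete=False):
        self.classes[term] = ClassInfo(label, list(synonyms), obsolete)
        self.isa.add_node(term)
        self._invalidate()

    def add_isa(self, child: TermId, parent: TermId):
        self.isa.add_edge(child, parent)
        self._invalidate()

    def add_property(self, name: str, transitive: bool = False):
        self.properties[name] = PropertyInfo(transitive)

    def add_relationship(self, subject: TermId, prop: str, obj: TermId):
        self.rel_edges.add((subject, prop, obj))

    def _invalidate(self):
        self._anc_cache.clear()
        self._super_cache.clear()
        self._label_index = None
        self._syn_index = None

    def check(self):
        """Validate structural invariants; raise on violation."""
        for child, parent in self.isa.edges():
            for t in (child, parent):
                if t not in self.classes:
                    raise OntologyError(f"is_a edge endpoint {t.render()} is not a declared class")
        for s, p, o in self.rel_edges:
            if s not in self.classes or o not in self.classes:
                raise OntologyError(f"relationship endpoint missing for ({s.render()} {p} {o.render()})")
            if p not in self.properties:
                raise OntologyError(f"relationship property {p!r} is not declared")
        try:
            cycle = nx.find_cycle(self.isa)
        except nx.NetworkXNoCycle:
            return
        member = cycle[0][0]
        raise CycleError(f"is_a cycle detected involving {member.render()}")

    # -- lookups -----------------------------------------------------------

    def is_transitive(self, prop: str) -> bool:
        info = self.properties.get(prop)
        return bool(info and info.transitive)

    def non_obsolete(self) -> List[TermId]:
        return [t for t, c in self.classes.items() if not c.obsolete]

    def ancestors(self, term: TermId) -> frozenset:
        """Reflexive-transitive is_a closure, restricted to non-obsolete classes."""
        if term not in self.classes:
            raise OntologyError(f"unknown term {term.render()}")
        if self.classes[term].obsolete:
            raise OntologyError(f"term {term.render()} is obsolete and excluded from subsumption")
        cached = self._anc_cache.get(term)
        if cached is None:
            up = nx.descendants(self.isa, term)  # edges point child -> parent
            cached = frozenset(
                t for t in (up | {term}) if not self.classes[t].obsolete
            )
            self._anc_cache[term] = cached
        return cached

    def descendants_of(self, term: TermId) -> frozenset:
        """Reflexive set of non-obsolete classes subsumed by ``term``."""
        if term not in self.classes:
            raise OntologyError(f"unknown term {term.render()}")
        down = nx.ancestors(self.isa, term)
        return frozenset(t for t in (down | {term}) if not self.classes[t].obsolete)

    def resolve_label(self, text: str) -> TermId:
        """Resolve a quoted label: exact label match first, then synonym;
        ambiguity or no match is an error listing near-matches."""
        if self._label_index is None:
            self._label_index = {}
            self._syn_index = {}
            for t, info in self.classes.items():
                if info.label:
                    self._label_index.setdefault(info.label, []).append(t)
                for s in info.synonyms:
                    self._syn_index.setdefault(s, []).append(t)
        hits = self._label_index.get(text, [])
        if not hits:
            hits = self._syn_index.get(text, [])
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise OntologyError(
                f"label {text!r} is ambiguous: " + ", ".join(t.render() for t in sorted(hits))
            )
        import difflib

        near = difflib.get_close_matches(text, list(self._label_index) + list(self._syn_index), n=3)
        hint = f" (near matches: {', '.join(near)})" if near else ""
        raise OntologyError(f"label {text!r} does not resolve{hint}")


# ---------------------------------------------------------------------------
# OBO reading / writing
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _strip_comment(value: str) -> str:
    # OBO trailing comments start with ' ! '
    idx = value.find("!")
    if idx >= 0:
        value = value[:idx]
    return value.strip()


def parse_obo(document: Union[str, TextIO]) -> OntologyGraph:
    """Read the [Term]/[Typedef] fragment of an OBO 1.2/1.4 flat file.

    Honored tags: id, name, synonym, is_a, relationship, is_obsolete,
    is_transitive.  ``intersection_of`` and ``equivalent_to`` lines are
    ignored with a warning.  Obsolete terms are kept but flagged.
    """
    if isinstance(document, str):
        document = io.StringIO(document)

    graph = OntologyGraph()
    pending_isa: List[Tuple[TermId, str, int]] = []
    pending_rel: List[Tuple[TermId, str, str, int]] = []

    stanza: Optional[str] = None  # None (header), 'Term', 'Typedef', or other
    cur: Dict[str, object] = {}
    cur_line = 0

    def flush():
        if stanza == "Term":
            if "id" not in cur:
                raise OboParseError("[Term] stanza without id tag", cur_line)
            term = TermId.parse(str(cur["id"]))
            graph.add_class(
                term,
                label=str(cur.get("name", "")),
                synonyms=cur.get("synonyms", []),
                obsolete=bool(cur.get("obsolete", False)),
            )
            for parent, line in cur.get("is_a", []):
                pending_isa.append((term, parent, line))
            for prop, target, line in cur.get("rels", []):
                pending_rel.append((term, prop, target, line))
        elif stanza == "Typedef":
            if "id" not in cur:
                raise OboParseError("[Typedef] stanza without id tag", cur_line)
            graph.add_property(str(cur["id"]), transitive=bool(cur.get("transitive", False)))

    for lineno, raw in enumerate(document, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.strip().endswith("]"):
                raise OboParseError(f"malformed stanza header {line!r}", lineno)
            flush()
            stanza = line.strip()[1:-1]
            cur = {}
            cur_line = lineno
            continue
        if stanza is None:
            continue  # header tags (format-version etc.)
        if stanza not in ("Term", "Typedef"):
            continue
        tag, sep, value = line.partition(":")
        if not sep:
            raise OboParseError(f"malformed tag line {line!r}", lineno)
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            v = _strip_comment(value)
            try:
                TermId.parse(v) if stanza == "Term" else None
            except ValueError:
                raise OboParseError(f"malformed id {v!r}", lineno)
            cur["id"] = v
        elif tag == "name":
            cur["name"] = _strip_comment(value)
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(f"malformed synonym line {value!r}", lineno)
            cur.setdefault("synonyms", []).append(m.group("text").replace('\\"', '"'))
        elif tag == "is_a":
            cur.setdefault("is_a", []).append((_strip_comment(value), lineno))
        elif tag == "relationship":
            v = _strip_comment(value)
            parts = v.split()
            if len(parts) != 2:
                raise OboParseError(f"malformed relationship line {v!r}", lineno)
            cur.setdefault("rels", []).append((parts[0], parts[1], lineno))
        elif tag == "is_obsolete":
            cur["obsolete"] = _strip_comment(value).lower() == "true"
        elif tag == "is_transitive":
            cur["transitive"] = _strip_comment(value).lower() == "true"
        elif tag in ("intersection_of", "equivalent_to"):
            logger.warning("ignoring %s line %d (outside the supported fragment)", tag, lineno)
        # all other tags ignored silently

    flush()

    for child, parent_s, line in pending_isa:
        try:
            parent = TermId.parse(parent_s)
        except ValueError:
            raise OboParseError(f"malformed is_a target {parent_s!r}", line)
        if parent not in graph.classes:
            raise OntologyError(f"is_a target {parent_s} of {child.render()} is not declared")
        graph.add_isa(child, parent)
    for subj, prop, target_s, line in pending_rel:
        try:
            target = TermId.parse(target_s)
        except ValueError:
            raise OboParseError(f"malformed relationship target {target_s!r}", line)
        if target not in graph.classes:
            raise OntologyError(f"relationship target {target_s} of {subj.render()} is not declared")
        if prop not in graph.properties:
            # OBO files routinely use properties defined upstream; declare
            # implicitly, non-transitive, so validation still has a record.
            graph.add_property(prop, transitive=(prop == "part_of"))
        graph.add_relationship(subj, prop, target)

    # part_of is transitive in the anatomy/spatial ontologies this tool
    # targets; honor an explicit declaration but default accordingly.
    if "part_of" in graph.properties and not graph.properties["part_of"].transitive:
        graph.properties["part_of"].transitive = True

    graph.check()
    return graph


def write_obo(graph: OntologyGraph, stream: TextIO):
    """Serialize the supported fragment back to OBO text (stable order)."""
    stream.write("format-version: 1.2\n")
    for name in sorted(graph.properties):
        stream.write(f"\n[Typedef]\nid: {name}\nname: {name}\n")
        if graph.properties[name].transitive:
            stream.write("is_transitive: true\n")
    rels: Dict[TermId, List[Tuple[str, TermId]]] = {}
    for s, p, o in graph.rel_edges:
        rels.setdefault(s, []).append((p, o))
    for term in sorted(graph.classes, key=lambda t: t.render()):
        info = graph.classes[term]
        stream.write(f"\n[Term]\nid: {term.render()}\n")
        if info.label:
            stream.write(f"name: {info.label}\n")
        for syn in info.synonyms:
            stream.write(f'synonym: "{syn}" EXACT []\n')
        for parent in sorted(graph.isa.successors(term), key=lambda t: t.render()):
            stream.write(f"is_a: {parent.render()}\n")
        for p, o in sorted(rels.get(term, []), key=lambda po: (po[0], po[1].render())):
            stream.write(f"relationship: {p} {o.render()}\n")
        if info.obsolete:
            stream.write("is_obsolete: true\n")


# ---------------------------------------------------------------------------
# Merge and augmentation
# ---------------------------------------------------------------------------


def merge_ontologies(graphs: List[OntologyGraph]) -> OntologyGraph:
    """Set-union of classes and edges; first graph wins on label conflicts."""
    if not graphs:
        raise ValueError("merge_ontologies requires at least one graph")
    merged = OntologyGraph()
    for g in graphs:
        for term, info in g.classes.items():
            if term in merged.classes:
                existing = merged.classes[term]
                if info.label and existing.label and info.label != existing.label:
                    logger.warning(
                        "label conflict for %s: keeping %r, dropping %r",
                        term.render(), existing.label, info.label,
                    )
                elif info.label and not existing.label:
                    existing.label = info.label
                for s in info.synonyms:
                    if s not in existing.synonyms:
                        existing.synonyms.append(s)
                existing.obsolete = existing.obsolete or info.obsolete
            else:
                merged.add_class(term, info.label, list(info.synonyms), info.obsolete)
        for name, pinfo in g.properties.items():
            if name in merged.properties:
                merged.properties[name].transitive |= pinfo.transitive
            else:
                merged.add_property(name, pinfo.transitive)
        for child, parent in g.isa.edges():
            merged.add_isa(child, parent)
        merged.rel_edges |= g.rel_edges
    merged.check()
    return merged


def augment_with_existentials(graph: OntologyGraph, properties: List[str]) -> Set[ClassExpression]:
    """The existential vocabulary {``(op some U)``} over every non-obsolete
    class U and each listed object property.

    This is the set of expression-level subsumers the subsumption rules can
    produce; the graph itself is not mutated.
    """
    for p in properties:
        if p not in graph.properties:
            raise OntologyError(f"property {p!r} is not declared in the graph")
    return {
        Some(p, Named(u))
        for u in graph.non_obsolete()
        for p in properties
    }


# ---------------------------------------------------------------------------
# Structural subsumption
# ---------------------------------------------------------------------------


def superclasses(graph: OntologyGraph, expr: ClassExpression) -> frozenset:
    """Reflexive set of structural subsumers of ``expr`` (rules R1-R4)."""
    key = expr.render()
    cached = graph._super_cache.get(key)
    if cached is not None:
        return cached

    if isinstance(expr, Named):
        result = frozenset(Named(t) for t in graph.ancestors(expr.term))
    elif isinstance(expr, Some):
        fillers = superclasses(graph, expr.filler)
        out = {Some(expr.property, f) for f in fillers}
        if graph.is_transitive(expr.property):
            # R4: collapse nested (p some (p some F)) one level per pass,
            # to fixpoint.
            frontier = set(out)
            while frontier:
                new = set()
                for e in frontier:
                    inner = e.filler
                    if isinstance(inner, Some) and inner.property == expr.property:
                        for g in superclasses(graph, inner.filler):
                            cand = Some(expr.property, g)
                            if cand not in out:
                                new.add(cand)
                out |= new
                frontier = new
        result = frozenset(out)
    elif isinstance(expr, And):
        out = {expr}
        for c in expr.conjuncts:
            out |= superclasses(graph, c)
        result = frozenset(out)
    else:  # pragma: no cover
        raise TypeError(f"not a class expression: {expr!r}")

    graph._super_cache[key] = result
    return result


def is_subsumed_by(graph: OntologyGraph, sub: ClassExpression, sup: ClassExpression) -> bool:
    """True iff ``sup`` structurally subsumes ``sub`` (reflexive)."""
    return sup in superclasses(graph, sub)
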