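"""Subsumer-set assembly for EQ annotations.

Each complete EQ annotation is treated as a node in an ad hoc phenotype
ontology.  Its subsumers come from two families:

* combinatorial E-Q-RE triples: the cross-product of the component
  superclass sets (a memory-saving alternative to materializing the full
  cross-product ontology), and
* superclasses of the annotation's class expression
  ``Q and (inheres_in some E) [and (towards some RE)]``.

The two families are kept distinguishable: a bare quality superclass
counted inside a triple and the same quality appearing as an expression
superclass are distinct subsumer nodes.  Set-based metrics (Jaccard)
therefore count them separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional, Tuple

from .expressions import And, ClassExpression, Named, Some, intersection_of
from .model import EQAnnotation
from .ontology import OntologyGraph, superclasses

INHERES_IN = "inheres_in"
TOWARDS = "towards"

Triple = Tuple[ClassExpression, ClassExpression, Optional[ClassExpression]]
# Tagged subsumer element: ("t", rendered E, Q, RE-or-None) or ("x", rendering)
Element = Tuple


class IncompleteEQError(ValueError):
    """Raised when a subsumer/metric operation receives an incomplete EQ.

    Callers must route incomplete annotations to the zero-score rule at
    the character-state level instead."""


def eq_to_class_expression(eq: EQAnnotation) -> ClassExpression:
    """The OWL-style class expression of an EQ annotation:
    ``Q and (inheres_in some E)`` plus ``(towards some RE)`` if present."""
    if not eq.complete or eq.entity is None or eq.quality is None:
        raise IncompleteEQError("cannot build a class expression for an incomplete EQ")
    conjuncts = [eq.quality, Some(INHERES_IN, eq.entity)]
    if eq.related_entity is not None:
        conjuncts.append(Some(TOWARDS, eq.related_entity))
    return intersection_of(conjuncts)


@dataclass(frozen=True)
class SubsumerSet:
    """All subsumers of one EQ annotation.

    ``triples`` is the combinatorial E-Q-RE family; ``expr_supers`` the
    class-expression family.  ``universe`` is their tagged disjoint union,
    keyed by canonical renderings, which is what the set metrics count.
    """

    triples: FrozenSet[Triple]
    expr_supers: FrozenSet[ClassExpression]
    owner: EQAnnotation

    @property
    def universe(self) -> FrozenSet[Element]:
        return self._universe()

    def _universe(self):
        if not hasattr(self, "_universe_cache"):
            tagged = {
                ("t", e.render(), q.render(), r.render() if r is not None else None)
                for (e, q, r) in self.triples
            } | {("x", x.render()) for x in self.expr_supers}
            object.__setattr__(self, "_universe_cache", frozenset(tagged))
        return self._universe_cache

    @property
    def size(self) -> int:
        return len(self.triples) + len(self.expr_supers)

    def identity_triple(self) -> Triple:
        return (self.owner.entity, self.owner.quality, self.owner.related_entity)

    def render_lines(self):
        """Sorted human-readable lines (for --dump-subsumers and diffing)."""
        lines = []
        for (e, q, r) in self.triples:
            parts = [e.render(), q.render()] + ([r.render()] if r is not None else [])
            lines.append("TRIPLE\t" + " | ".join(parts))
        for x in self.expr_supers:
            lines.append("EXPR\t" + x.render())
        return sorted(lines)


def subsumers(eq: EQAnnotation, graph: OntologyGraph) -> SubsumerSet:
    """Assemble the subsumer set of a complete EQ annotation.

    With SE/SQ/SR the reflexive superclass sets of the components:
    triples = SE x SQ x SR (SR = {absent} when there is no related
    entity), and expr_supers = the structural superclasses of the
    combined class expression.
    """
    if not eq.complete or eq.entity is None or eq.quality is None:
        raise IncompleteEQError("subsumers of an incomplete EQ are undefined")

    cache = getattr(graph, "_subsumer_cache", None)
    if cache is None:
        cache = {}
        graph._subsumer_cache = cache
    key = eq.render_key()
    hit = cache.get(key)
    if hit is not None:
        return hit

    se = superclasses(graph, eq.entity)
    sq = superclasses(graph, eq.quality)
    if eq.related_entity is not None:
        sr = superclasses(graph, eq.related_entity)
        triples = frozenset((e, q, r) for e in se for q in sq for r in sr)
    else:
        triples = frozenset((e, q, None) for e in se for q in sq)
    expr = eq_to_class_expression(eq)
    expr_supers = superclasses(graph, expr)
    result = SubsumerSet(triples=triples, expr_supers=expr_supers, owner=eq)
    cache[key] = result
    return result
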