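"""Class-expression AST for post-composed ontology terms.

Post-compositions combine named ontology classes with existential
restrictions (``part_of some X``) and intersections, e.g. the entity
"gland that is part of the lateral region of the pelvis" is written

    (gland and (part_of some (lateral_region and (part_of some pelvis))))

Expressions are immutable and canonical: intersections are flattened,
deduplicated and sorted by rendered form, so structurally equal
expressions compare (and hash) equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Tuple, Union


@total_ordering
@dataclass(frozen=True)
class TermId:
    """A CURIE-style ontology class identifier, e.g. ``UBERON:0000033``.

    Identity is the rendered ``PREFIX:LOCAL`` form, case-sensitive.
    """

    prefix: str
    local_id: str

    @classmethod
    def parse(cls, curie: str) -> "TermId":
        prefix, sep, local = curie.partition(":")
        if not sep or not prefix or not local:
            raise ValueError(f"not a CURIE: {curie!r}")
        return cls(prefix, local)

    def render(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def __lt__(self, other: "TermId") -> bool:
        return self.render() < other.render()


class ClassExpression:
    """Base class for :class:`Named`, :class:`Some` and :class:`And`."""

    __slots__ = ()

    def render(self) -> str:
        raise NotImplementedError

    def term_ids(self) -> Iterable[TermId]:
        """All named-class identifiers mentioned in the expression."""
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}<{self.render()}>"


@dataclass(frozen=True, repr=False)
class Named(ClassExpression):
    term: TermId

    def render(self) -> str:
        return self.term.render()

    def term_ids(self):
        yield self.term


@dataclass(frozen=True, repr=False)
class Some(ClassExpression):
    """Existential restriction ``(property some filler)``."""

    property: str
    filler: ClassExpression

    def render(self) -> str:
        return f"({self.property} some {self.filler.render()})"

    def term_ids(self):
        yield from self.filler.term_ids()


@dataclass(frozen=True, repr=False)
class And(ClassExpression):
    """Intersection of two or more conjuncts, stored flattened and sorted."""

    conjuncts: Tuple[ClassExpression, ...]

    def __post_init__(self):
        flat = []
        for c in self.conjuncts:
            if isinstance(c, And):
                flat.extend(c.conjuncts)
            else:
                flat.append(c)
        seen = {}
        for c in flat:
            seen[c.render()] = c
        ordered = tuple(seen[k] for k in sorted(seen))
        if len(ordered) < 2:
            raise ValueError("And requires at least 2 distinct conjuncts")
        object.__setattr__(self, "conjuncts", ordered)

    def render(self) -> str:
        return "(" + " and ".join(c.render() for c in self.conjuncts) + ")"

    def term_ids(self):
        for c in self.conjuncts:
            yield from c.term_ids()


def intersection_of(exprs: Iterable[ClassExpression]) -> ClassExpression:
    """Canonical intersection; collapses to the single conjunct if only one
    distinct expression remains after flattening."""
    flat = []
    for e in exprs:
        if isinstance(e, And):
            flat.extend(e.conjuncts)
        else:
            flat.append(e)
    uniq = {e.render(): e for e in flat}
    if not uniq:
        raise ValueError("empty intersection")
    if len(uniq) == 1:
        return next(iter(uniq.values()))
    return And(tuple(uniq.values()))


Expr = Union[Named, Some, And]
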