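"""EQ annotations, character states, annotation sources, and their TSV format.

An EQ annotation describes a phenotype as an Entity (an anatomical
structure) bearing a Quality (a phenotypic attribute), optionally relative
to a Related Entity (e.g. "nasal bone" / "in contact with" / "prefrontal
bone").  Each component is either a single ontology term or a
post-composed class expression written in a small textual grammar:

    expr := atom | "(" expr ("and" expr)+ ")" | "(" PROP "some" expr ")"
    atom := CURIE | 'quoted label'

Quoted labels resolve through the working ontology (exact label first,
then synonym; ambiguity is an error).

Annotation sources are flat TSV tables, one row per EQ, with columns
study, character_id, state_id, character_text, state_text, entity,
quality, related_entity (blank related_entity = absent).  Rows sharing a
(study, character_id, state_id) key accumulate multiple EQ annotations on
the same character state.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, TextIO, Tuple

from .expressions import ClassExpression, Named, Some, TermId, intersection_of
from .ontology import OntologyError, OntologyGraph

REQUIRED_COLUMNS = [
    "study", "character_id", "state_id",
    "character_text", "state_text",
    "entity", "quality", "related_entity",
]

StateKey = Tuple[str, str, str]


class ExpressionParseError(ValueError):
    pass


@dataclass(frozen=True)
class EQAnnotation:
    """Entity / Quality / optional Related-Entity triple.

    ``complete`` is False when a component failed to resolve against the
    working ontology (or is missing); the raw texts are preserved so that
    incomplete annotations can still be reported and re-serialized.
    Incomplete annotations force a zero similarity score on their state.
    """

    entity: Optional[ClassExpression]
    quality: Optional[ClassExpression]
    related_entity: Optional[ClassExpression] = None
    complete: bool = True
    raw_entity: str = ""
    raw_quality: str = ""
    raw_related_entity: str = ""

    def render_key(self) -> str:
        """Canonical rendering used as the EQ node identity in a corpus."""
        if not self.complete:
            raise ValueError("incomplete EQ has no canonical rendering")
        parts = [self.entity.render(), self.quality.render()]
        if self.related_entity is not None:
            parts.append(self.related_entity.render())
        return " | ".join(parts)


@dataclass
class CharacterState:
    study: str
    character_id: str
    state_id: str
    character_text: str = ""
    state_text: str = ""
    annotations: List[EQAnnotation] = field(default_factory=list)

    @property
    def key(self) -> StateKey:
        return (self.study, self.character_id, self.state_id)


@dataclass
class AnnotationSource:
    """A set of character states annotated by one curator/tool/round."""

    source_id: str
    round: Optional[str] = None
    ontology_id: Optional[str] = None
    states: Dict[StateKey, CharacterState] = field(default_factory=dict)

    def add(self, state: CharacterState):
        if state.key in self.states:
            raise ValueError(f"duplicate state key {state.key}")
        self.states[state.key] = state

    def all_annotations(self) -> Iterable[EQAnnotation]:
        for state in self.states.values():
            yield from state.annotations


# ---------------------------------------------------------------------------
# Post-composition grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|'(?:[^'\\]|\\.)*'|[^\s()]+")
_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")


def _tokenize(text: str) -> List[str]:
    tokens = _TOKEN_RE.findall(text)
    if "".join(tokens).replace("'", "") and not tokens:
        raise ExpressionParseError(f"cannot tokenize {text!r}")
    return tokens


def parse_expression(text: str, graph: OntologyGraph) -> ClassExpression:
    """Parse a post-composition string into a canonical class expression."""
    tokens = _tokenize(text.strip())
    if not tokens:
        raise ExpressionParseError("empty expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        if pos >= len(tokens):
            raise ExpressionParseError(f"unexpected end of expression in {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def atom(tok: str) -> ClassExpression:
        if tok.startswith("'") and tok.endswith("'") and len(tok) >= 2:
            label = tok[1:-1].replace("\\'", "'")
            return Named(graph.resolve_label(label))
        if _CURIE_RE.match(tok):
            term = TermId.parse(tok)
            if term not in graph.classes:
                raise OntologyError(f"unknown term {tok}")
            return Named(term)
        raise ExpressionParseError(f"cannot parse atom {tok!r} in {text!r}")

    def expr() -> ClassExpression:
        tok = take()
        if tok != "(":
            if tok == ")":
                raise ExpressionParseError(f"unexpected ')' in {text!r}")
            return atom(tok)
        first = take()
        if first != "(" and peek() == "some":
            # existential restriction: ( PROP some expr )
            prop = first
            # inheres_in/towards are built into the EQ-to-expression
            # transform and need no ontology declaration
            if prop not in graph.properties and prop not in ("inheres_in", "towards"):
                raise ExpressionParseError(f"unknown property {prop!r} in {text!r}")
            take()  # 'some'
            filler = expr()
            if take() != ")":
                raise ExpressionParseError(f"expected ')' in {text!r}")
            return Some(prop, filler)
        # intersection: ( expr ("and" expr)+ )
        pos_rewind(first)
        conjuncts = [expr()]
        while True:
            tok = take()
            if tok == ")":
                break
            if tok != "and":
                raise ExpressionParseError(f"expected 'and' or ')', got {tok!r} in {text!r}")
            conjuncts.append(expr())
        if len(conjuncts) < 2:
            raise ExpressionParseError(f"intersection needs >= 2 conjuncts in {text!r}")
        return intersection_of(conjuncts)

    def pos_rewind(tok: str):
        nonlocal pos
        pos -= 1
        assert tokens[pos] == tok

    result = expr()
    if pos != len(tokens):
        raise ExpressionParseError(f"trailing tokens {tokens[pos:]} in {text!r}")
    return result


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def _parse_component(text: str, graph: OntologyGraph):
    """Returns (expression or None, ok flag)."""
    text = text.strip()
    if not text:
        return None, True
    try:
        return parse_expression(text, graph), True
    except (ExpressionParseError, OntologyError, ValueError):
        return None, False


def read_annotations(table: TextIO, graph: OntologyGraph, source_id: str = "source") -> AnnotationSource:
    """Read an annotation TSV into an :class:`AnnotationSource`.

    Rows whose entity/quality/related-entity fail to parse or resolve yield
    incomplete annotations with the raw text preserved, rather than being
    dropped: downstream scoring needs to see them to apply the zero rule.
    """
    reader = csv.DictReader(table, delimiter="\t")
    if reader.fieldnames is None:
        raise ValueError("empty annotation table")
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ValueError(f"annotation table missing mandatory columns: {missing}")

    source = AnnotationSource(source_id=source_id)
    for row in reader:
        key = (row["study"], row["character_id"], row["state_id"])
        state = source.states.get(key)
        if state is None:
            state = CharacterState(
                study=key[0], character_id=key[1], state_id=key[2],
                character_text=row.get("character_text", "") or "",
                state_text=row.get("state_text", "") or "",
            )
            source.states[key] = state

        e_raw = (row.get("entity") or "").strip()
        q_raw = (row.get("quality") or "").strip()
        r_raw = (row.get("related_entity") or "").strip()
        if not e_raw and not q_raw and not r_raw:
            continue  # row declares an unannotated state

        entity, e_ok = _parse_component(e_raw, graph)
        quality, q_ok = _parse_component(q_raw, graph)
        rel, r_ok = _parse_component(r_raw, graph)
        complete = bool(entity and quality and e_ok and q_ok and r_ok)
        state.annotations.append(EQAnnotation(
            entity=entity, quality=quality, related_entity=rel,
            complete=complete,
            raw_entity=e_raw, raw_quality=q_raw, raw_related_entity=r_raw,
        ))
    return source


def write_annotations(source: AnnotationSource, stream: TextIO):
    """Serialize a source back to the TSV dialect (stable state order)."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(REQUIRED_COLUMNS)
    for key in sorted(source.states):
        state = source.states[key]
        if not state.annotations:
            writer.writerow([state.study, state.character_id, state.state_id,
                             state.character_text, state.state_text, "", "", ""])
        for eq in state.annotations:
            e = eq.entity.render() if eq.entity is not None else eq.raw_entity
            q = eq.quality.render() if eq.quality is not None else eq.raw_quality
            r = eq.related_entity.render() if eq.related_entity is not None else eq.raw_related_entity
            writer.writerow([state.study, state.character_id, state.state_id,
                             state.character_text, state.state_text, e, q, r])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

RELATIONAL_Q_WITHOUT_RE = "RELATIONAL_Q_WITHOUT_RE"
INCOMPLETE_EQ = "INCOMPLETE_EQ"
EMPTY_STATE = "EMPTY_STATE"
OBSOLETE_TERM = "OBSOLETE_TERM"


@dataclass(frozen=True)
class ValidationIssue:
    state_key: StateKey
    code: str
    message: str


def validate(source: AnnotationSource, graph: OntologyGraph,
             relational_qualities: Set[TermId] = frozenset()) -> List[ValidationIssue]:
    """Check curation conventions; never raises on content.

    A relational quality (e.g. 'in contact with') requires a related
    entity.  A quality counts as relational if the term itself or any of
    its is_a ancestors is in ``relational_qualities``.
    """
    issues: List[ValidationIssue] = []
    for key in sorted(source.states):
        state = source.states[key]
        if not state.annotations:
            issues.append(ValidationIssue(key, EMPTY_STATE, "state has no EQ annotations"))
            continue
        for eq in state.annotations:
            if not eq.complete:
                issues.append(ValidationIssue(
                    key, INCOMPLETE_EQ,
                    f"incomplete EQ (entity={eq.raw_entity!r}, quality={eq.raw_quality!r})"))
                continue
            for expr in (eq.entity, eq.quality, eq.related_entity):
                if expr is None:
                    continue
                for term in expr.term_ids():
                    info = graph.classes.get(term)
                    if info is not None and info.obsolete:
                        issues.append(ValidationIssue(
                            key, OBSOLETE_TERM, f"uses obsolete term {term.render()}"))
            if relational_qualities and isinstance(eq.quality, Named) and eq.related_entity is None:
                anc = {n.term for n in _named_ancestors(graph, eq.quality)}
                if anc & set(relational_qualities):
                    issues.append(ValidationIssue(
                        key, RELATIONAL_Q_WITHOUT_RE,
                        f"relational quality {eq.quality.render()} lacks a related entity"))
    return issues


def _named_ancestors(graph: OntologyGraph, named: Named):
    from .ontology import superclasses
    return [s for s in superclasses(graph, named) if isinstance(s, Named)]
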