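"""Ontology-aware similarity metrics for EQ annotations.

Four metrics, all on [0, 1]:

* ``JSIM`` — Jaccard similarity of two annotations' subsumer sets,
  |S1 ∩ S2| / |S1 ∪ S2|.
* ``IN``  — normalized information content of the least common subsumer
  (LCS) of two annotations, where IC of a node N is
  I(N) = -log( sum of annotation frequencies of everything N subsumes /
  corpus total ) and In = I / Imax with Imax = -log(1/total).
* ``PP`` / ``PR`` — partial precision and recall: directional state-level
  scores averaging each test (resp. reference) annotation's best Jaccard
  match on the other side, admitting partial credit for semantically
  close annotations.

Aggregation follows a two-level scheme: a character-state score is the
best match (maximum) over all pairwise EQ comparisons between the two
sources' annotations of that state (PP/PR are computed at state level
directly), and a source-level score is the arithmetic mean over shared
character states.  A state containing an incomplete EQ on either side, or
no EQs at all, scores 0 on every metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .expressions import And, ClassExpression, Some, intersection_of
from .model import AnnotationSource, CharacterState, EQAnnotation, StateKey
from .ontology import OntologyGraph, superclasses
from .subsumers import (INHERES_IN, TOWARDS, IncompleteEQError, SubsumerSet,
                        subsumers)

logger = logging.getLogger(__name__)

PP = "PP"
PR = "PR"
JSIM = "JSIM"
IN = "IN"
METRICS = (PP, PR, JSIM, IN)


# ---------------------------------------------------------------------------
# Annotation corpus and information content
# ---------------------------------------------------------------------------


@dataclass
class AnnotationCorpus:
    """Frequency map from canonical EQ renderings to annotation counts."""

    counts: Dict[str, int] = field(default_factory=dict)
    exemplars: Dict[str, EQAnnotation] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, eq: EQAnnotation, n: int = 1):
        key = eq.render_key()
        self.counts[key] = self.counts.get(key, 0) + n
        self.exemplars.setdefault(key, eq)


def build_corpus(sources: Sequence[AnnotationSource]) -> AnnotationCorpus:
    """Count every complete EQ annotation across all provided sources.

    Incomplete annotations carry no resolvable EQ node and are excluded
    from the frequency map (they still zero out their states in scoring).
    """
    if not sources:
        raise ValueError("build_corpus requires at least one source")
    corpus = AnnotationCorpus()
    for src in sources:
        for eq in src.all_annotations():
            if eq.complete:
                corpus.add(eq)
    return corpus


def _decompose_identity_expression(expr: ClassExpression):
    """Map an identity-shaped expression ``Q and (inheres_in some E)
    [and (towards some RE)]`` back to its (E, Q, RE) combination, or None
    if the expression does not have that shape."""
    if not isinstance(expr, And):
        return None
    entities, relateds, rest = [], [], []
    for c in expr.conjuncts:
        if isinstance(c, Some) and c.property == INHERES_IN:
            entities.append(c.filler)
        elif isinstance(c, Some) and c.property == TOWARDS:
            relateds.append(c.filler)
        else:
            rest.append(c)
    if len(entities) != 1 or len(relateds) > 1 or not rest:
        return None
    quality = rest[0] if len(rest) == 1 else intersection_of(rest)
    related = relateds[0] if relateds else None
    return (entities[0], quality, related)


def _element_subsumes_eq(element, target: SubsumerSet) -> bool:
    """Does a subsumer element (triple or expression) subsume the EQ whose
    subsumer set is ``target``?

    Identity-shaped expressions denote the same class as their E-Q-RE
    combination, so they are decomposed before the membership test —
    without this, an expression node would only ever subsume its own EQ.
    """
    kind, payload = element
    if kind == "t":
        return payload in target.triples
    triple = _decompose_identity_expression(payload)
    if triple is not None:
        return triple in target.triples
    return payload in target.expr_supers


def _corpus_subsumer_sets(corpus: AnnotationCorpus, graph: OntologyGraph):
    cache = getattr(corpus, "_ss_cache", None)
    if cache is None or cache[0] is not graph:
        cache = (graph, [(subsumers(eq, graph), corpus.counts[key])
                         for key, eq in corpus.exemplars.items()])
        corpus._ss_cache = cache
    return cache[1]


def _element_ic(element, corpus: AnnotationCorpus, graph: OntologyGraph) -> Tuple[float, float]:
    total = corpus.total
    if total <= 0:
        raise ValueError("information content requires a non-empty corpus")
    key = element[0] + "|" + str(element[1:] if element[0] == "t" else element[1].render())
    ic_cache = getattr(corpus, "_ic_cache", None)
    if ic_cache is None or getattr(corpus, "_ic_graph", None) is not graph:
        ic_cache = {}
        corpus._ic_cache = ic_cache
        corpus._ic_graph = graph
    if key in ic_cache:
        return ic_cache[key]

    freq = 0
    for ss, count in _corpus_subsumer_sets(corpus, graph):
        if _element_subsumes_eq(element, ss):
            freq += count
    imax = math.log(total)
    if freq == 0:
        logger.info("node subsumes no annotated EQ; assigning maximal IC")
        result = (imax, 1.0)
    elif freq >= total:
        result = (0.0, 0.0)  # p = 1: the node subsumes the whole corpus
    else:
        p = freq / total
        i = -math.log(p)
        result = (i, (i / imax) if imax > 0 else 0.0)
    ic_cache[key] = result
    return result


def information_content(node: Union[EQAnnotation, str], corpus: AnnotationCorpus,
                        graph: OntologyGraph) -> Tuple[float, float]:
    """(I, In) of an EQ node: I = -log p, p = subsumed annotation frequency
    over the corpus total; In = I / Imax with Imax = -log(1/total).

    ``node`` is an :class:`EQAnnotation` or a canonical rendering present
    in the corpus.  The node is identified with its E-Q-RE combination for
    the frequency sum (the node subsumes every corpus EQ whose component
    superclasses include its components).
    """
    if isinstance(node, str):
        eq = corpus.exemplars.get(node)
        if eq is None:
            raise KeyError(f"EQ rendering not in corpus: {node!r}")
    else:
        eq = node
    if not eq.complete:
        raise IncompleteEQError("information content of an incomplete EQ is undefined")
    element = ("t", (eq.entity, eq.quality, eq.related_entity))
    return _element_ic(element, corpus, graph)


# ---------------------------------------------------------------------------
# Pairwise metrics
# ---------------------------------------------------------------------------


def jaccard(eq1: EQAnnotation, eq2: EQAnnotation, graph: OntologyGraph) -> float:
    """Jaccard similarity of the two annotations' subsumer universes
    (combinatorial triples and expression superclasses, counted as
    distinct families)."""
    if not (eq1.complete and eq2.complete):
        raise IncompleteEQError("Jaccard similarity of an incomplete EQ is undefined")
    u1 = subsumers(eq1, graph).universe
    u2 = subsumers(eq2, graph).universe
    union = len(u1 | u2)
    if union == 0:  # pragma: no cover - complete EQs always have subsumers
        return 0.0
    return len(u1 & u2) / union


def _minimal(elements: Iterable[ClassExpression], graph: OntologyGraph) -> List[ClassExpression]:
    """Elements of a set that do not strictly subsume another element."""
    elems = list(elements)
    out = []
    for a in elems:
        strict_over_some = False
        for b in elems:
            if a is b or a == b:
                continue
            if a in superclasses(graph, b):
                strict_over_some = True
                break
        if not strict_over_some:
            out.append(a)
    return out


def lcs_similarity(eq1: EQAnnotation, eq2: EQAnnotation, corpus: AnnotationCorpus,
                   graph: OntologyGraph) -> float:
    """Normalized IC of the least common subsumer of two EQ nodes.

    Common subsumers are the intersection of the two subsumer universes;
    LCS candidates are those that do not strictly subsume another common
    subsumer; among candidates the one with the highest I wins (ties
    broken lexicographically on rendering).  No common subsumer -> 0.
    """
    if not (eq1.complete and eq2.complete):
        raise IncompleteEQError("LCS similarity of an incomplete EQ is undefined")
    ss1 = subsumers(eq1, graph)
    ss2 = subsumers(eq2, graph)
    common_triples = ss1.triples & ss2.triples
    common_exprs = ss1.expr_supers & ss2.expr_supers
    if not common_triples and not common_exprs:
        return 0.0

    candidates = []
    if common_triples:
        # Minimal triples = componentwise product of minimal components.
        es = {t[0] for t in common_triples}
        qs = {t[1] for t in common_triples}
        with_re = any(t[2] is not None for t in common_triples)
        if with_re:
            rs = {t[2] for t in common_triples if t[2] is not None}
            min_r = _minimal(rs, graph)
        prod = []
        for e in _minimal(es, graph):
            for q in _minimal(qs, graph):
                if with_re:
                    prod.extend((e, q, r) for r in min_r)
                if any(t == (e, q, None) for t in common_triples):
                    prod.append((e, q, None))
        candidates.extend(("t", t) for t in prod if t in common_triples)
        if not candidates:
            # Fall back to the exact definition when the product heuristic
            # misses (mixed-arity common sets).
            for t in common_triples:
                dominated = False
                for u in common_triples:
                    if t != u and _triple_subsumes(t, u, graph):
                        dominated = True
                        break
                if not dominated:
                    candidates.append(("t", t))
    candidates.extend(("x", x) for x in _minimal(common_exprs, graph))

    best = None
    for cand in candidates:
        i, i_n = _element_ic(cand, corpus, graph)
        render = ("|".join(c.render() if c is not None else "-" for c in cand[1])
                  if cand[0] == "t" else cand[1].render())
        score = (i, render)
        if best is None or i > best[0] or (i == best[0] and render < best[1]):
            best = (i, render, i_n)
    return best[2]


def _triple_subsumes(a, b, graph) -> bool:
    if (a[2] is None) != (b[2] is None):
        return False
    if a[0] not in superclasses(graph, b[0]) or a[1] not in superclasses(graph, b[1]):
        return False
    return a[2] is None or a[2] in superclasses(graph, b[2])


def partial_scores(ref_eqs: Sequence[EQAnnotation], test_eqs: Sequence[EQAnnotation],
                   graph: OntologyGraph) -> Tuple[float, float]:
    """Partial precision and recall between two EQ lists.

    PP = mean over test annotations of their best Jaccard match in the
    reference list; PR = mean over reference annotations of their best
    match in the test list.  Directional: (ref, test) order matters.
    """
    if not ref_eqs or not test_eqs:
        raise ValueError("partial_scores requires non-empty EQ lists")
    sims = [[jaccard(r, t, graph) for t in test_eqs] for r in ref_eqs]
    pp = sum(max(sims[i][j] for i in range(len(ref_eqs)))
             for j in range(len(test_eqs))) / len(test_eqs)
    pr = sum(max(row) for row in sims) / len(ref_eqs)
    return pp, pr


# ---------------------------------------------------------------------------
# State- and source-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class StateScore:
    state_key: StateKey
    metric: str
    value: float
    n_ref_eqs: int
    n_test_eqs: int
    zeroed_for_incompleteness: bool = False


def state_similarity(ref_state: CharacterState, test_state: CharacterState,
                     metric: str, graph: OntologyGraph,
                     corpus: Optional[AnnotationCorpus] = None) -> StateScore:
    """Best-match similarity of two annotations of the same character state.

    JSIM/IN take the maximum pairwise score across all ref x test EQ
    pairs; PP/PR are the partial precision/recall of the two lists.  A
    state with no EQs, or containing an incomplete EQ on either side,
    scores 0 with the ``zeroed_for_incompleteness`` flag set.
    """
    if ref_state.key != test_state.key:
        raise ValueError(f"state keys differ: {ref_state.key} vs {test_state.key}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == IN and corpus is None:
        raise ValueError("IN requires an annotation corpus")

    n_ref = len(ref_state.annotations)
    n_test = len(test_state.annotations)
    incomplete = (any(not eq.complete for eq in ref_state.annotations)
                  or any(not eq.complete for eq in test_state.annotations))
    if incomplete or n_ref == 0 or n_test == 0:
        return StateScore(ref_state.key, metric, 0.0, n_ref, n_test,
                          zeroed_for_incompleteness=True)

    if metric in (PP, PR):
        pp, pr = partial_scores(ref_state.annotations, test_state.annotations, graph)
        value = pp if metric == PP else pr
    elif metric == JSIM:
        value = max(jaccard(r, t, graph)
                    for r in ref_state.annotations for t in test_state.annotations)
    else:  # IN
        value = max(lcs_similarity(r, t, corpus, graph)
                    for r in ref_state.annotations for t in test_state.annotations)
    return StateScore(ref_state.key, metric, value, n_ref, n_test)


@dataclass
class SourceComparison:
    """Mean and per-state scores for one ordered source pair and metric."""

    ref_id: str
    test_id: str
    metric: str
    mean: float
    per_state: List[StateScore]
    only_ref_keys: List[StateKey] = field(default_factory=list)
    only_test_keys: List[StateKey] = field(default_factory=list)

    @property
    def sem(self) -> float:
        n = len(self.per_state)
        if n < 2:
            return 0.0
        vals = [s.value for s in self.per_state]
        m = self.mean
        return math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1) / n)


def source_similarity(ref: AnnotationSource, test: AnnotationSource, metric: str,
                      graph: OntologyGraph, corpus: Optional[AnnotationCorpus] = None,
                      empty_policy: str = "zero") -> SourceComparison:
    """Mean best-match similarity over the character states shared by two
    sources.  States present in only one source are excluded from the mean
    and reported in ``only_ref_keys`` / ``only_test_keys``.

    ``empty_policy``: "zero" (default) scores a shared state with an empty
    annotation list on either side as 0; "skip" excludes such states from
    the mean.
    """
    shared = sorted(set(ref.states) & set(test.states))
    if not shared:
        raise ValueError(f"sources {ref.source_id!r} and {test.source_id!r} share no state keys")
    only_ref = sorted(set(ref.states) - set(test.states))
    only_test = sorted(set(test.states) - set(ref.states))
    if only_ref or only_test:
        logger.info("excluding %d ref-only and %d test-only states from the mean",
                    len(only_ref), len(only_test))

    per_state = []
    for key in shared:
        r, t = ref.states[key], test.states[key]
        if empty_policy == "skip" and (not r.annotations or not t.annotations):
            continue
        per_state.append(state_similarity(r, t, metric, graph, corpus))
    mean = sum(s.value for s in per_state) / len(per_state) if per_state else float("nan")
    return SourceComparison(ref.source_id, test.source_id, metric, mean,
                            per_state, only_ref, only_test)
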