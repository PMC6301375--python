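"""Independent brute-force reference implementations used only by tests.

Deliberately naive and structured differently from the library:
named-class reachability comes from boolean adjacency-matrix closure,
expression subsumers from plain recursion with explicit rewriting, and
all metrics from direct enumeration over rendered-string sets.  The only
concession to runtime is that one :class:`Oracle` instance computes the
matrix closure once for its graph.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def named_closure(graph):
    """dict term -> frozenset of reflexive-transitive is_a ancestors,
    via boolean matrix powers (non-obsolete classes only)."""
    terms = [t for t in sorted(graph.classes, key=lambda x: x.render())
             if not graph.classes[t].obsolete]
    idx = {t: i for i, t in enumerate(terms)}
    n = len(terms)
    adj = np.eye(n, dtype=bool)
    for child, parent in graph.isa.edges():
        if child in idx and parent in idx:
            adj[idx[child], idx[parent]] = True
    prev = np.zeros_like(adj)
    while (prev != adj).any():
        prev = adj
        adj = adj | (adj @ adj)
    return {t: frozenset(terms[j] for j in np.nonzero(adj[idx[t]])[0]) for t in terms}


class Oracle:
    """Brute-force metric evaluator bound to one ontology graph."""

    def __init__(self, graph):
        self.graph = graph
        self.closure = named_closure(graph)
        self._supers_memo = {}

    # -- subsumption -----------------------------------------------------

    def supers(self, expr):
        """Set of superclass expressions of a class expression."""
        from eqsim.expressions import And, Named, Some

        key = expr.render()
        if key in self._supers_memo:
            return self._supers_memo[key]
        if isinstance(expr, Named):
            out = {Named(t) for t in self.closure[expr.term]}
        elif isinstance(expr, Some):
            out = set()
            todo = [Some(expr.property, f) for f in self.supers(expr.filler)]
            while todo:
                cand = todo.pop()
                if cand in out:
                    continue
                out.add(cand)
                if self.graph.is_transitive(expr.property):
                    inner = cand.filler
                    if isinstance(inner, Some) and inner.property == expr.property:
                        todo.extend(Some(expr.property, g)
                                    for g in self.supers(inner.filler))
        elif isinstance(expr, And):
            out = {expr}
            for c in expr.conjuncts:
                out |= self.supers(c)
        else:
            raise TypeError(expr)
        self._supers_memo[key] = out
        return out

    def super_renderings(self, expr):
        return {s.render() for s in self.supers(expr)}

    def universe(self, eq):
        """Tagged rendered subsumer elements of one complete EQ."""
        from eqsim.expressions import Some, intersection_of

        se = self.super_renderings(eq.entity)
        sq = self.super_renderings(eq.quality)
        out = set()
        if eq.related_entity is not None:
            sr = self.super_renderings(eq.related_entity)
            for e, q, r in product(sorted(se), sorted(sq), sorted(sr)):
                out.add(("t", e, q, r))
        else:
            for e, q in product(sorted(se), sorted(sq)):
                out.add(("t", e, q, None))
        conjuncts = [eq.quality, Some("inheres_in", eq.entity)]
        if eq.related_entity is not None:
            conjuncts.append(Some("towards", eq.related_entity))
        for s in self.super_renderings(intersection_of(conjuncts)):
            out.add(("x", s))
        return out

    # -- metrics -----------------------------------------------------------

    def jaccard(self, eq1, eq2):
        u1, u2 = self.universe(eq1), self.universe(eq2)
        return len(u1 & u2) / len(u1 | u2)

    def partial_scores(self, ref_eqs, test_eqs):
        pp = sum(max(self.jaccard(r, t) for r in ref_eqs)
                 for t in test_eqs) / len(test_eqs)
        pr = sum(max(self.jaccard(r, t) for t in test_eqs)
                 for r in ref_eqs) / len(ref_eqs)
        return pp, pr

    def _element_subsumes(self, element, eq):
        """Semantic test: identity-shaped expressions equal their triple."""
        from eqsim.expressions import And, Some, intersection_of
        from eqsim.model import parse_expression

        universe = self.universe(eq)
        if element[0] == "t":
            return element in universe
        expr = parse_expression(element[1], self.graph)
        if isinstance(expr, And):
            entities = [c.filler for c in expr.conjuncts
                        if isinstance(c, Some) and c.property == "inheres_in"]
            relateds = [c.filler for c in expr.conjuncts
                        if isinstance(c, Some) and c.property == "towards"]
            rest = [c for c in expr.conjuncts
                    if not (isinstance(c, Some) and c.property in ("inheres_in", "towards"))]
            if len(entities) == 1 and len(relateds) <= 1 and rest:
                q = rest[0] if len(rest) == 1 else intersection_of(rest)
                r = relateds[0].render() if relateds else None
                return ("t", entities[0].render(), q.render(), r) in universe
        return ("x", element[1]) in universe

    def element_ic(self, element, corpus_eqs):
        total = sum(c for _, c in corpus_eqs)
        freq = sum(c for m, c in corpus_eqs if self._element_subsumes(element, m))
        imax = math.log(total)
        if freq == 0:
            return imax, 1.0
        i = -math.log(freq / total)
        return i, (i / imax if imax > 0 else 0.0)

    def information_content(self, eq, corpus_eqs):
        element = ("t", eq.entity.render(), eq.quality.render(),
                   eq.related_entity.render() if eq.related_entity is not None else None)
        return self.element_ic(element, corpus_eqs)

    def _strictly_subsumes(self, a, b):
        from eqsim.model import parse_expression

        if a == b or a[0] != b[0]:
            return False
        if a[0] == "x":
            return a[1] in self.super_renderings(parse_expression(b[1], self.graph))
        if (a[3] is None) != (b[3] is None):
            return False
        for ax, bx in zip(a[1:], b[1:]):
            if ax is None:
                continue
            if ax not in self.super_renderings(parse_expression(bx, self.graph)):
                return False
        return True

    def lcs_similarity(self, eq1, eq2, corpus_eqs):
        common = self.universe(eq1) & self.universe(eq2)
        if not common:
            return 0.0
        candidates = [c for c in common
                      if not any(self._strictly_subsumes(c, d) for d in common)]
        best = None
        for cand in candidates:
            i, i_n = self.element_ic(cand, corpus_eqs)
            render = "|".join(str(x) for x in cand[1:])
            if best is None or i > best[0] or (i == best[0] and render < best[1]):
                best = (i, render, i_n)
        return best[2]


# -- module-level conveniences (fresh Oracle per call; used by unit tests) --


def expr_superclasses(graph, expr):
    return Oracle(graph).super_renderings(expr)


def subsumer_universe(graph, eq):
    return Oracle(graph).universe(eq)


def jaccard(graph, eq1, eq2):
    return Oracle(graph).jaccard(eq1, eq2)


def partial_scores(graph, ref_eqs, test_eqs):
    return Oracle(graph).partial_scores(ref_eqs, test_eqs)


def information_content(graph, eq, corpus_eqs):
    return Oracle(graph).information_content(eq, corpus_eqs)


def element_ic(graph, element, corpus_eqs):
    return Oracle(graph).element_ic(element, corpus_eqs)


def lcs_similarity(graph, eq1, eq2, corpus_eqs):
    return Oracle(graph).lcs_similarity(eq1, eq2, corpus_eqs)
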