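"""Seeded synthetic ontologies and annotation-source pairs.

The generator emulates the documented ways two curators diverge when
annotating the same character states against the same ontologies:

* ``exact``        — identical EQ choices;
* ``subsumption``  — a component replaced by one of its ancestors or
                     descendants (a more general/specific term);
* ``sibling``      — a component replaced by a term sharing a parent;
* ``unrelated``    — every component replaced by a term from a disjoint
                     branch (minimal ancestor overlap);
* ``recompose``    — an entity re-expressed as a post-composition over
                     ``part_of`` (e.g. a named gland vs
                     "gland and part_of some pelvis");
* ``missing``      — one annotation dropped by the second curator;
* ``incomplete``   — one annotation contains an unresolvable term.

Ontologies are rooted DAGs over a synthetic namespace with an anatomy
branch (entities) and an attribute branch (qualities) under the root,
plus transitive ``part_of`` edges.  One master seed fans out to
independent per-state streams, so enlarging a study never perturbs
earlier states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .expressions import And, ClassExpression, Named, Some, TermId, intersection_of
from .model import AnnotationSource, CharacterState, EQAnnotation
from .ontology import OntologyGraph

MODES = ("exact", "subsumption", "sibling", "unrelated",
         "recompose", "missing", "incomplete")


@dataclass(frozen=True)
class DivergenceProfile:
    """Per-state probabilities of each divergence mode.

    Probabilities must sum to at most 1; the remainder is added to
    ``p_exact``.  The defaults are illustrative, not estimates of any
    particular curation team: roughly a quarter of states match exactly,
    related-term substitutions dominate the rest, and small fractions of
    states suffer dropped or unresolvable annotations.
    """

    p_exact: float = 0.26
    p_subsumption: float = 0.30
    p_sibling: float = 0.16
    p_unrelated: float = 0.08
    p_recompose: float = 0.10
    p_missing: float = 0.05
    p_incomplete: float = 0.05
    seed: int = 0

    def probabilities(self) -> np.ndarray:
        p = np.array([self.p_exact, self.p_subsumption, self.p_sibling,
                      self.p_unrelated, self.p_recompose, self.p_missing,
                      self.p_incomplete], dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("divergence probabilities must lie in [0, 1]")
        s = p.sum()
        if s > 1 + 1e-9:
            raise ValueError(f"divergence probabilities sum to {s} > 1")
        p[0] += max(0.0, 1.0 - s)
        return p / p.sum()


def gen_ontology(n_classes: int, max_parents: int = 2, seed: int = 0,
                 prefix: str = "SYN", p_part_of: float = 0.1) -> OntologyGraph:
    """A seeded rooted DAG ontology.

    The root has two children anchoring an anatomy branch and an
    attribute branch; every further class attaches below one of them with
    1..max_parents parents.  A ``part_of`` property (transitive) is
    declared and a fraction of classes get a part_of edge.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    graph = OntologyGraph()
    graph.add_property("part_of", transitive=True)

    terms = [TermId(prefix, f"{i:07d}") for i in range(n_classes)]
    graph.add_class(terms[0], label="synthetic root")
    branch_labels = {1: "anatomical structure", 2: "quality attribute"}
    for i in range(1, n_classes):
        graph.add_class(terms[i], label=branch_labels.get(i, f"synthetic class {i}"))
        if i <= 2:
            parents = [0]
        else:
            # attach below non-root classes, keeping the two branches;
            # parents drawn among earlier classes for acyclicity
            k = int(rng.integers(1, max_parents + 1))
            pool = np.arange(1, i)
            parents = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        for p in parents:
            graph.add_isa(terms[i], terms[p])
    for i in range(3, n_classes):
        if rng.random() < p_part_of:
            target = int(rng.integers(1, i))
            graph.add_relationship(terms[i], "part_of", terms[target])
    graph.check()
    return graph


# ---------------------------------------------------------------------------
# Source-pair generation
# ---------------------------------------------------------------------------


def _pools(graph: OntologyGraph) -> Tuple[List[TermId], List[TermId]]:
    """Entity and quality term pools.

    With a single root the pools are the subtrees of its first two
    children; a merged multi-component graph uses the first component's
    classes as entities and the second's as qualities."""
    roots = sorted((t for t in graph.classes
                    if graph.isa.out_degree(t) == 0 and not graph.classes[t].obsolete),
                   key=lambda t: t.render())
    if len(roots) >= 2:
        e_pool = sorted(graph.descendants_of(roots[0]) - {roots[0]}) or [roots[0]]
        q_pool = sorted(graph.descendants_of(roots[1]) - {roots[1]}) or [roots[1]]
        return list(e_pool), list(q_pool)
    root = roots[0]
    children = sorted(graph.isa.predecessors(root), key=lambda t: t.render())
    if len(children) < 2:
        raise ValueError("ontology needs at least two branches under the root")
    e_pool = sorted(graph.descendants_of(children[0]))
    q_pool = sorted(graph.descendants_of(children[1]) - set(e_pool))
    if not q_pool:
        raise ValueError("quality branch is empty")
    return list(e_pool), list(q_pool)


def _pick(rng, items):
    return items[int(rng.integers(0, len(items)))]


def _related_terms(graph, term, kind: str) -> List[TermId]:
    if kind == "subsumption":
        # one is_a step in either direction: the "broader/narrower term"
        # choice two curators most plausibly disagree by
        parents = set(graph.isa.successors(term))
        children = set(graph.isa.predecessors(term))
        return sorted((parents | children) - {term})
    if kind == "sibling":
        sibs = set()
        for parent in graph.isa.successors(term):
            sibs |= set(graph.isa.predecessors(parent))
        return sorted(sibs - {term})
    raise ValueError(kind)


def _unrelated_terms(graph, term, pool) -> List[TermId]:
    """Pool terms with minimal ancestor overlap with ``term`` (0 on a
    multi-component graph; only shared global roots otherwise)."""
    anc = graph.ancestors(term)
    overlaps = {}
    for cand in pool:
        if cand == term:
            continue
        overlaps[cand] = len(graph.ancestors(cand) & anc)
    if not overlaps:
        return []
    best = min(overlaps.values())
    return sorted(c for c, v in overlaps.items() if v == best)


def _replace_named(eq: EQAnnotation, which: str, new: ClassExpression) -> EQAnnotation:
    return dc_replace(eq, **{which: new})


def gen_source_pair(graph: OntologyGraph, n_states: int,
                    profile: DivergenceProfile,
                    p_related_entity: float = 0.2,
                    ) -> Tuple[AnnotationSource, AnnotationSource, Dict]:
    """A reference source, a divergent test source, and per-state truth.

    The reference curator gives each state 1-3 complete EQ annotations
    (entity and quality drawn from the two branches; some states get a
    related entity).  One divergence mode is drawn per state from the
    profile and applied to every annotation of that state.  Truth labels
    map state keys to the applied mode.
    """
    if len(graph.classes) < 5:
        raise ValueError("graph too small for annotation sampling")
    probs = profile.probabilities()
    e_pool, q_pool = _pools(graph)
    master = np.random.SeedSequence(profile.seed)
    state_seeds = master.spawn(n_states)

    ref = AnnotationSource(source_id="REF")
    test = AnnotationSource(source_id="TEST")
    truth: Dict = {}

    for s_idx in range(n_states):
        rng = np.random.default_rng(state_seeds[s_idx])
        key = ("synthetic", f"c{s_idx + 1}", "s1")
        mode = MODES[int(rng.choice(len(MODES), p=probs))]
        truth[key] = mode

        n_eq = int(rng.integers(1, 4))
        ref_eqs = []
        for _ in range(n_eq):
            e = Named(_pick(rng, e_pool))
            q = Named(_pick(rng, q_pool))
            re_ = Named(_pick(rng, e_pool)) if rng.random() < p_related_entity else None
            ref_eqs.append(EQAnnotation(entity=e, quality=q, related_entity=re_))

        test_eqs = [_diverge(eq, mode, graph, rng, e_pool, q_pool) for eq in ref_eqs]
        if mode == "missing":
            drop = int(rng.integers(0, len(test_eqs)))
            test_eqs = [eq for i, eq in enumerate(test_eqs) if i != drop]
        elif mode == "incomplete":
            idx = int(rng.integers(0, len(test_eqs)))
            broken = test_eqs[idx]
            test_eqs[idx] = EQAnnotation(
                entity=None, quality=broken.quality, related_entity=broken.related_entity,
                complete=False, raw_entity=f"UNRESOLVED:{s_idx:05d}")

        ref.add(CharacterState(*key, character_text=f"character {s_idx + 1}",
                               state_text="state 1", annotations=ref_eqs))
        test.add(CharacterState(*key, character_text=f"character {s_idx + 1}",
                                state_text="state 1", annotations=list(test_eqs)))
    return ref, test, truth


def _diverge(eq: EQAnnotation, mode: str, graph: OntologyGraph, rng,
             e_pool, q_pool) -> EQAnnotation:
    if mode in ("exact", "missing", "incomplete"):
        return eq

    components = [("entity", e_pool), ("quality", q_pool)]
    if eq.related_entity is not None:
        components.append(("related_entity", e_pool))

    if mode == "unrelated":
        # candidates come from the combined pool: on a merged
        # multi-component graph the minimal-overlap terms sit in the other
        # component, giving annotations with no shared subsumers at all
        combined = list(e_pool) + list(q_pool)
        out = eq
        for which, _pool in components:
            term = getattr(eq, which).term
            cands = _unrelated_terms(graph, term, combined)
            if cands:
                out = _replace_named(out, which, Named(_pick(rng, cands)))
        return out

    if mode == "recompose":
        # re-express the entity as (parent and part_of some X)
        term = eq.entity.term
        parents = sorted(graph.isa.successors(term), key=lambda t: t.render())
        parents = [p for p in parents if not graph.classes[p].obsolete]
        if not parents:
            return eq
        parent = _pick(rng, parents)
        anchors = sorted(graph.ancestors(term) - {term, parent}) or [parent]
        anchor = _pick(rng, anchors)
        recomposed = intersection_of([Named(parent), Some("part_of", Named(anchor))])
        return _replace_named(eq, "entity", recomposed)

    # subsumption / sibling: replace one randomly chosen component,
    # trying the other components, then the other related-term kind, and
    # finally an unrelated in-pool term, so a divergent mode never
    # silently returns an identical annotation
    order = list(rng.permutation(len(components)))
    kinds = [mode, ("sibling" if mode == "subsumption" else "subsumption")]
    for kind in kinds:
        for idx in order:
            which, pool = components[idx]
            term = getattr(eq, which).term
            cands = [t for t in _related_terms(graph, term, kind) if t in set(pool)]
            if cands:
                return _replace_named(eq, which, Named(_pick(rng, cands)))
    which, pool = components[order[0]]
    cands = [t for t in pool if t != getattr(eq, which).term]
    if cands:
        return _replace_named(eq, which, Named(_pick(rng, cands)))
    return eq


def write_truth(truth: Dict, stream):
    stream.write("study\tcharacter_id\tstate_id\tmode\n")
    for key in sorted(truth):
        stream.write("\t".join(key) + f"\t{truth[key]}\n")
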