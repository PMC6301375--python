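"""Subsumer sets and Jaccard similarity for two fin phenotypes.

Builds a ten-term anatomy/quality ontology, annotates "pectoral fin,
increased size" and "pelvic fin, increased size", and shows how the
subsumer machinery sees them.
"""

import io

from eqsim import EQAnnotation, Named, TermId, jaccard, parse_obo, subsumers

OBO = """\
[Typedef]
id: part_of
is_transitive: true

[Term]
id: A:1
name: anatomical structure

[Term]
id: A:2
name: fin
is_a: A:1

[Term]
id: A:3
name: pectoral fin
is_a: A:2

[Term]
id: A:4
name: pelvic fin
is_a: A:2

[Term]
id: Q:1
name: quality

[Term]
id: Q:2
name: size
is_a: Q:1

[Term]
id: Q:3
name: increased size
is_a: Q:2
"""

graph = parse_obo(io.StringIO(OBO))

def eq(entity, quality):
    return EQAnnotation(entity=Named(TermId.parse(entity)),
                        quality=Named(TermId.parse(quality)))

pectoral = eq("A:3", "Q:3")
pelvic = eq("A:4", "Q:3")

ss = subsumers(pectoral, graph)
print(f"E-Q combination subsumers : {len(ss.triples)}")
print(f"expression superclasses   : {len(ss.expr_supers)}")
print(f"total subsumers           : {ss.size}")
# 3 entity ancestors x 3 quality ancestors = 9 combinations, plus the
# class expression, its 3 bare quality supers and 3 inheres_in supers.

j = jaccard(pectoral, pelvic, graph)
print(f"Jsim(pectoral fin, pelvic fin | increased size) = {j:.4f}")
# The two phenotypes share every subsumer that generalizes the fin to
# its ancestors, and differ only in the leaf entity: Jsim ~ 0.52,
# i.e. the annotations are closely related but not identical.
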