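"""Information content and LCS similarity on a two-leaf corpus.

Annotation corpus: the phenotype "B bears q" is annotated 3 times, the
sibling "C bears q" once.  Rarer nodes carry more information.
"""

import io
import math

from eqsim import (AnnotationCorpus, EQAnnotation, Named, TermId,
                   information_content, lcs_similarity, parse_obo)

OBO = """\
[Term]
id: T:1
name: root

[Term]
id: T:2
name: b
is_a: T:1

[Term]
id: T:3
name: c
is_a: T:1

[Term]
id: Q:1
name: q
"""

graph = parse_obo(io.StringIO(OBO))

def eq(entity):
    return EQAnnotation(entity=Named(TermId.parse(entity)),
                        quality=Named(TermId.parse("Q:1")))

corpus = AnnotationCorpus()
corpus.add(eq("T:2"), 3)
corpus.add(eq("T:3"), 1)

for name, node in [("B", eq("T:2")), ("C", eq("T:3")), ("root", eq("T:1"))]:
    i, i_n = information_content(node, corpus, graph)
    print(f"I({name}) = {i:.4f} nats, In({name}) = {i_n:.4f}")
# In(B) = log(4/3)/log(4) ~ 0.2075: B covers 3 of 4 annotations, so it is
# only mildly informative.  In(C) = 1: C pins down a single annotation.
# The root subsumes everything: In = 0.

print(f"LCS similarity of B and C: {lcs_similarity(eq('T:2'), eq('T:3'), corpus, graph):.4f}")
# Their least common subsumer is the root-level phenotype, which subsumes
# the whole corpus, so the pair shares no information (score 0).
assert math.isclose(information_content(eq('T:2'), corpus, graph)[1],
                    math.log(4 / 3) / math.log(4))
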