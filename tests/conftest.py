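import io

import pytest

from eqsim import EQAnnotation, Named, TermId, parse_obo

TOY_OBO = """\
format-version: 1.2

[Typedef]
id: part_of
is_transitive: true

[Typedef]
id: inheres_in

[Typedef]
id: towards

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
id: A:5
name: pelvis
is_a: A:1

[Term]
id: A:6
name: gland
is_a: A:1

[Term]
id: A:7
name: lateral region
is_a: A:1

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
synonym: "enlarged" EXACT []

[Term]
id: Q:4
name: decreased size
is_a: Q:2

[Term]
id: Q:5
name: in contact with
is_a: Q:1
"""


def term(curie: str) -> Named:
    return Named(TermId.parse(curie))


def make_eq(entity: str, quality: str, related: str = None) -> EQAnnotation:
    return EQAnnotation(
        entity=term(entity), quality=term(quality),
        related_entity=term(related) if related else None)


@pytest.fixture(scope="session")
def toy_graph():
    """Small anatomy/quality ontology used across metric tests."""
    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture()
def fin_size_eq():
    return make_eq("A:3", "Q:3")
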