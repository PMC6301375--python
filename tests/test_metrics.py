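"""Similarity metrics: Jaccard, information content, LCS, partial
precision/recall, and the two-level best-match/mean aggregation."""

import io
import math

import pytest

from eqsim import (IN, JSIM, PP, PR, AnnotationSource, CharacterState,
                   EQAnnotation, build_corpus, information_content, jaccard,
                   lcs_similarity, parse_obo, partial_scores, source_similarity,
                   state_similarity)
from eqsim.metrics import AnnotationCorpus
from eqsim.subsumers import IncompleteEQError
from eqsim.synth import DivergenceProfile, gen_ontology, gen_source_pair

from . import _oracle
from .conftest import make_eq, term

DISJOINT_OBO = """\
[Term]
id: L:1

[Term]
id: L:2
is_a: L:1

[Term]
id: L:3
is_a: L:1

[Term]
id: R:1

[Term]
id: R:2
is_a: R:1

[Term]
id: R:3
is_a: R:1
"""


def state(key, *eqs):
    return CharacterState(*key, annotations=list(eqs))


def source(source_id, *states):
    src = AnnotationSource(source_id=source_id)
    for s in states:
        src.add(s)
    return src


def toy_corpus(graph):
    """f(EQ(pectoral fin, increased size)) = 3, f(EQ(pelvic fin, ...)) = 1,
    plus one gland annotation so the fin subtree is not the whole corpus."""
    corpus = AnnotationCorpus()
    corpus.add(make_eq("A:3", "Q:3"), 3)
    corpus.add(make_eq("A:4", "Q:3"), 1)
    corpus.add(make_eq("A:6", "Q:4"), 1)
    return corpus


class TestJaccard:
    def test_identity_is_one(self, toy_graph, fin_size_eq):
        assert jaccard(fin_size_eq, make_eq("A:3", "Q:3"), toy_graph) == 1.0

    def test_disjoint_components_score_zero(self):
        g = parse_obo(io.StringIO(DISJOINT_OBO))
        eq1 = make_eq("L:2", "L:3")
        eq2 = make_eq("R:2", "R:3")
        assert jaccard(eq1, eq2, g) == 0.0

    def test_sibling_fins_match_enumeration_oracle(self, toy_graph):
        eq1 = make_eq("A:3", "Q:3")
        eq2 = make_eq("A:4", "Q:3")
        got = jaccard(eq1, eq2, toy_graph)
        assert got == pytest.approx(_oracle.jaccard(toy_graph, eq1, eq2), abs=1e-15)
        assert 0.5 < got < 0.65

    def test_symmetric_and_bounded(self, toy_graph):
        eqs = [make_eq("A:3", "Q:3"), make_eq("A:4", "Q:4"),
               make_eq("A:6", "Q:3", "A:5"), make_eq("A:2", "Q:2")]
        for a in eqs:
            for b in eqs:
                j = jaccard(a, b, toy_graph)
                assert 0.0 <= j <= 1.0
                assert j == jaccard(b, a, toy_graph)
                if a == b:
                    assert j == 1.0

    def test_incomplete_eq_is_error(self, toy_graph, fin_size_eq):
        broken = EQAnnotation(entity=term("A:3"), quality=None, complete=False)
        with pytest.raises(IncompleteEQError):
            jaccard(fin_size_eq, broken, toy_graph)


class TestInformationContent:
    def test_root_node_has_zero_ic(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        i, i_n = information_content(make_eq("A:1", "Q:1"), corpus, toy_graph)
        assert i == pytest.approx(0.0)
        assert i_n == pytest.approx(0.0)

    def test_frequency_one_node_has_maximal_ic(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        _, i_n = information_content(make_eq("A:4", "Q:3"), corpus, toy_graph)
        assert i_n == pytest.approx(1.0)

    def test_two_leaf_worked_example(self, toy_graph):
        """f(B)=3, f(C)=1 under a shared root: In(B) = log(4/3)/log(4)."""
        corpus = AnnotationCorpus()
        corpus.add(make_eq("A:3", "Q:3"), 3)
        corpus.add(make_eq("A:4", "Q:3"), 1)
        i, i_n = information_content(make_eq("A:3", "Q:3"), corpus, toy_graph)
        assert i == pytest.approx(math.log(4 / 3), abs=1e-12)
        assert i_n == pytest.approx(math.log(4 / 3) / math.log(4), abs=1e-12)
        assert i_n == pytest.approx(0.2075, abs=5e-4)

    def test_node_subsuming_nothing_gets_in_of_one(self, toy_graph):
        corpus = AnnotationCorpus()
        corpus.add(make_eq("A:3", "Q:3"), 2)
        _, i_n = information_content(make_eq("A:5", "Q:4"), corpus, toy_graph)
        assert i_n == 1.0

    def test_anti_monotone_along_subsumption(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        chain = [make_eq("A:3", "Q:3"), make_eq("A:2", "Q:2"), make_eq("A:1", "Q:1")]
        ics = [information_content(eq, corpus, toy_graph)[0] for eq in chain]
        assert ics[0] >= ics[1] >= ics[2]

    def test_matches_direct_oracle(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        corpus_eqs = [(corpus.exemplars[k], corpus.counts[k]) for k in sorted(corpus.counts)]
        for key in sorted(corpus.counts):
            got = information_content(key, corpus, toy_graph)
            want = _oracle.information_content(toy_graph, corpus.exemplars[key], corpus_eqs)
            assert got == pytest.approx(want, abs=1e-12)


class TestLcsSimilarity:
    def test_self_lcs_equals_own_in(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        for key in sorted(corpus.counts):
            eq = corpus.exemplars[key]
            assert lcs_similarity(eq, eq, corpus, toy_graph) == pytest.approx(
                information_content(eq, corpus, toy_graph)[1], abs=1e-12)

    def test_sibling_lcs_is_parent_in(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        got = lcs_similarity(make_eq("A:3", "Q:3"), make_eq("A:4", "Q:3"),
                             corpus, toy_graph)
        # minimal common subsumers all cover exactly the two fin EQs: p = 4/5
        assert got == pytest.approx(math.log(5 / 4) / math.log(5), abs=1e-12)

    def test_no_common_subsumer_scores_zero(self):
        g = parse_obo(io.StringIO(DISJOINT_OBO))
        corpus = AnnotationCorpus()
        corpus.add(make_eq("L:2", "L:3"), 1)
        corpus.add(make_eq("R:2", "R:3"), 1)
        assert lcs_similarity(make_eq("L:2", "L:3"), make_eq("R:2", "R:3"),
                              corpus, g) == 0.0

    def test_matches_brute_force_oracle(self, toy_graph):
        corpus = toy_corpus(toy_graph)
        corpus_eqs = [(corpus.exemplars[k], corpus.counts[k]) for k in sorted(corpus.counts)]
        pairs = [(make_eq("A:3", "Q:3"), make_eq("A:4", "Q:4")),
                 (make_eq("A:3", "Q:3"), make_eq("A:6", "Q:4")),
                 (make_eq("A:2", "Q:2"), make_eq("A:4", "Q:3"))]
        for a, b in pairs:
            got = lcs_similarity(a, b, corpus, toy_graph)
            want = _oracle.lcs_similarity(toy_graph, a, b, corpus_eqs)
            assert got == pytest.approx(want, abs=1e-12)


class TestPartialScores:
    def test_identical_singletons(self, toy_graph, fin_size_eq):
        assert partial_scores([fin_size_eq], [make_eq("A:3", "Q:3")], toy_graph) \
            == (1.0, 1.0)

    def test_extra_test_annotation_dilutes_precision(self, toy_graph):
        a, b = make_eq("A:3", "Q:3"), make_eq("A:4", "Q:3")
        j_star = jaccard(a, b, toy_graph)
        pp, pr = partial_scores([a], [a, b], toy_graph)
        assert pr == pytest.approx(1.0)
        assert pp == pytest.approx((1 + j_star) / 2, abs=1e-12)

    def test_duality_mirror(self, toy_graph):
        a, b = make_eq("A:3", "Q:3"), make_eq("A:4", "Q:3")
        j_star = jaccard(a, b, toy_graph)
        pp, pr = partial_scores([a, b], [a], toy_graph)
        assert pp == pytest.approx(1.0)
        assert pr == pytest.approx((1 + j_star) / 2, abs=1e-12)

    def test_duality_exact_on_generated_pairs(self):
        graph = gen_ontology(40, seed=11)
        ref, test, _ = gen_source_pair(graph, 30, DivergenceProfile(seed=11))
        for key in ref.states:
            r = [e for e in ref.states[key].annotations if e.complete]
            t = [e for e in test.states[key].annotations if e.complete]
            if not r or not t:
                continue
            pp_rt, pr_rt = partial_scores(r, t, graph)
            pp_tr, pr_tr = partial_scores(t, r, graph)
            assert pp_rt == pr_tr
            assert pr_rt == pp_tr

    def test_pr_non_decreasing_pp_decreasing_with_unmatched_addition(self):
        g = parse_obo(io.StringIO(DISJOINT_OBO))
        a = make_eq("L:2", "L:3")
        unmatched = make_eq("R:2", "R:3")
        pp1, pr1 = partial_scores([a], [a], g)
        pp2, pr2 = partial_scores([a], [a, unmatched], g)
        assert pr2 >= pr1
        assert pp2 < pp1

    def test_empty_list_is_error(self, toy_graph, fin_size_eq):
        with pytest.raises(ValueError):
            partial_scores([], [fin_size_eq], toy_graph)


class TestStateAndSourceAggregation:
    def test_same_single_eq_scores_one(self, toy_graph):
        key = ("s", "c1", "s1")
        score = state_similarity(state(key, make_eq("A:3", "Q:3")),
                                 state(key, make_eq("A:3", "Q:3")), JSIM, toy_graph)
        assert score.value == 1.0 and not score.zeroed_for_incompleteness

    def test_incomplete_eq_zeroes_state(self, toy_graph):
        key = ("s", "c1", "s1")
        broken = EQAnnotation(entity=None, quality=term("Q:3"), complete=False,
                              raw_entity="NOPE:1")
        for metric in (PP, PR, JSIM):
            score = state_similarity(state(key, make_eq("A:3", "Q:3")),
                                     state(key, make_eq("A:3", "Q:3"), broken),
                                     metric, toy_graph)
            assert score.value == 0.0
            assert score.zeroed_for_incompleteness

    def test_best_match_is_max_over_all_pairs(self, toy_graph):
        key = ("s", "c1", "s1")
        refs = [make_eq("A:3", "Q:3"), make_eq("A:4", "Q:4"), make_eq("A:6", "Q:3")]
        tests = [make_eq("A:4", "Q:3"), make_eq("A:5", "Q:4")]
        score = state_similarity(state(key, *refs), state(key, *tests), JSIM, toy_graph)
        expected = max(jaccard(r, t, toy_graph) for r in refs for t in tests)
        assert score.value == expected
        assert (score.n_ref_eqs, score.n_test_eqs) == (3, 2)

    def test_key_mismatch_is_error(self, toy_graph):
        with pytest.raises(ValueError):
            state_similarity(state(("s", "c1", "s1"), make_eq("A:3", "Q:3")),
                             state(("s", "c1", "s2"), make_eq("A:3", "Q:3")),
                             JSIM, toy_graph)

    def test_source_self_similarity_is_one(self, toy_graph):
        src = source("C1",
                     state(("s", "c1", "s1"), make_eq("A:3", "Q:3")),
                     state(("s", "c1", "s2"), make_eq("A:4", "Q:4"), make_eq("A:6", "Q:3")))
        corpus = build_corpus([src])
        for metric in (PP, PR, JSIM, IN):
            comp = source_similarity(src, src, metric, toy_graph, corpus)
            assert comp.mean == pytest.approx(1.0)

    def test_mean_of_one_and_zero_states(self, toy_graph):
        g = parse_obo(io.StringIO(DISJOINT_OBO))
        k1, k2 = ("s", "c1", "s1"), ("s", "c2", "s1")
        ref = source("R", state(k1, make_eq("L:2", "L:3")), state(k2, make_eq("L:2", "L:3")))
        tst = source("T", state(k1, make_eq("L:2", "L:3")), state(k2, make_eq("R:2", "R:3")))
        comp = source_similarity(ref, tst, JSIM, g)
        assert comp.mean == pytest.approx(0.5)

    def test_one_sided_states_excluded_but_reported(self, toy_graph):
        k1, k2 = ("s", "c1", "s1"), ("s", "c2", "s1")
        ref = source("R", state(k1, make_eq("A:3", "Q:3")), state(k2, make_eq("A:4", "Q:4")))
        tst = source("T", state(k1, make_eq("A:3", "Q:3")))
        comp = source_similarity(ref, tst, JSIM, toy_graph)
        assert comp.mean == 1.0
        assert comp.only_ref_keys == [k2]

    def test_no_shared_keys_is_error(self, toy_graph):
        ref = source("R", state(("s", "c1", "s1"), make_eq("A:3", "Q:3")))
        tst = source("T", state(("s", "c9", "s1"), make_eq("A:3", "Q:3")))
        with pytest.raises(ValueError):
            source_similarity(ref, tst, JSIM, toy_graph)


class TestBuildCorpus:
    def test_single_annotation(self, toy_graph):
        src = source("C1", state(("s", "c1", "s1"), make_eq("A:3", "Q:3")))
        corpus = build_corpus([src])
        assert corpus.total == 1

    def test_same_eq_across_sources_counts_thrice(self, toy_graph):
        srcs = [source(f"C{i}", state(("s", "c1", "s1"), make_eq("A:3", "Q:3")))
                for i in range(3)]
        corpus = build_corpus(srcs)
        assert corpus.counts[make_eq("A:3", "Q:3").render_key()] == 3

    def test_total_is_additive_over_sources(self, toy_graph):
        srcs = []
        for i in range(4):
            srcs.append(source(
                f"C{i}",
                state(("s", "c1", "s1"), make_eq("A:3", "Q:3"), make_eq("A:4", "Q:4"))))
        assert build_corpus(srcs).total == 8

    def test_incomplete_annotations_not_counted(self, toy_graph):
        broken = EQAnnotation(entity=None, quality=term("Q:3"), complete=False)
        src = source("C1", state(("s", "c1", "s1"), make_eq("A:3", "Q:3"), broken))
        assert build_corpus([src]).total == 1
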