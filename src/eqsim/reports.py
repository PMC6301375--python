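"""Deterministic TSV report writing for source comparisons.

Reports are byte-identical across runs for identical inputs: state keys
are sorted lexicographically and floats are printed with a fixed format.
Summaries carry two standard errors of the mean alongside each mean, the
error-bar convention used when plotting these scores.
"""

from __future__ import annotations

from typing import List, Sequence, TextIO

from .metrics import SourceComparison

_FLOAT = "{:.6f}"


def write_per_state(comparisons: Sequence[SourceComparison], stream: TextIO):
    """One row per (source pair, state, metric)."""
    stream.write("ref\ttest\tstudy\tcharacter_id\tstate_id\tmetric\tvalue\t"
                 "n_ref_eqs\tn_test_eqs\tzeroed_for_incompleteness\n")
    for comp in comparisons:
        for score in sorted(comp.per_state, key=lambda s: s.state_key):
            stream.write("\t".join([
                comp.ref_id, comp.test_id, *score.state_key, score.metric,
                _FLOAT.format(score.value), str(score.n_ref_eqs),
                str(score.n_test_eqs), str(int(score.zeroed_for_incompleteness)),
            ]) + "\n")


def write_summary(comparisons: Sequence[SourceComparison], stream: TextIO):
    """One row per (source pair, metric) with mean, SEM and 2*SEM."""
    stream.write("ref\ttest\tmetric\tmean\tsem\ttwo_sem\tn_states\t"
                 "n_zeroed\tn_only_ref\tn_only_test\n")
    for comp in comparisons:
        n_zeroed = sum(1 for s in comp.per_state if s.zeroed_for_incompleteness)
        stream.write("\t".join([
            comp.ref_id, comp.test_id, comp.metric,
            _FLOAT.format(comp.mean), _FLOAT.format(comp.sem),
            _FLOAT.format(2 * comp.sem), str(len(comp.per_state)),
            str(n_zeroed), str(len(comp.only_ref_keys)), str(len(comp.only_test_keys)),
        ]) + "\n")
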