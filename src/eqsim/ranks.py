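"""Rank-preference statistics for annotation-source surveys, and the paired
Wilcoxon signed-rank harness used to compare per-state score vectors.

A survey presents each observation (e.g. one character state shown to a
study author) with t annotation sources to rank 1..t by preference.  Two
chi-square statistics summarize the resulting rank table:

* Anderson's A tests whether the full distribution of ranks departs from
  uniform (every source receiving every rank equally often);
* Friedman's F tests whether the mean ranks of the sources differ.

Both are referred to chi-square null distributions (df (t-1)^2 and t-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RankTable:
    """Observations x sources rank assignments.

    Each row of ``ranks`` is a permutation of 1..t assigning a rank to
    every source; ``counts()`` gives the t x t matrix O with O[i, j] =
    number of times source i received rank j+1.
    """

    sources: List[str]
    ranks: np.ndarray  # shape (n, t), integer ranks 1..t

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=float)
        n, t = self.ranks.shape
        if t != len(self.sources):
            raise ValueError("rank matrix width does not match the source list")
        if t < 2 or n < 1:
            raise ValueError("need at least 2 sources and 1 observation")
        expected = np.arange(1, t + 1, dtype=float)
        for row in self.ranks:
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(f"row {row} is not a permutation of 1..{t}")

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @property
    def t(self) -> int:
        return self.ranks.shape[1]

    def counts(self) -> np.ndarray:
        t = self.t
        o = np.zeros((t, t))
        for row in self.ranks:
            for i, r in enumerate(row):
                o[i, int(round(r)) - 1] += 1
        return o

    def mean_ranks(self) -> np.ndarray:
        return self.ranks.mean(axis=0)

    @classmethod
    def from_records(cls, records: Sequence[Tuple[str, str, float]],
                     allow_ties: bool = False) -> "RankTable":
        """Build from long-format (observation_id, source, rank) records.

        Observations with missing sources are dropped (surveys may be
        ragged when respondents skip items); with ``allow_ties`` tied
        ranks are converted to mid-ranks with a warning, otherwise they
        are an error.
        """
        sources = sorted({s for _, s, _ in records})
        by_obs: dict = {}
        for obs, src, rank in records:
            by_obs.setdefault(obs, {})[src] = float(rank)
        rows = []
        dropped = 0
        for obs in sorted(by_obs):
            row = by_obs[obs]
            if set(row) != set(sources):
                dropped += 1
                continue
            vals = [row[s] for s in sources]
            if sorted(vals) != list(range(1, len(sources) + 1)):
                if not allow_ties:
                    raise ValueError(f"observation {obs!r} has tied or invalid ranks {vals}")
                logger.warning("observation %r: converting tied ranks to mid-ranks", obs)
                vals = list(stats.rankdata(vals))
            rows.append(vals)
        if dropped:
            logger.warning("dropped %d incomplete observations", dropped)
        if not rows:
            raise ValueError("no complete ranking observations")
        table = cls.__new__(cls)
        table.sources = sources
        table.ranks = np.asarray(rows, dtype=float)
        return table


def anderson_a(table: RankTable) -> Tuple[float, int, float]:
    """Anderson's statistic A = ((t-1)/t) * sum_ij (O_ij - n/t)^2 / (n/t),
    with df = (t-1)^2 and an upper-tail chi-square p-value."""
    o = table.counts()
    n, t = table.n, table.t
    expected = n / t
    a = (t - 1) / t * float(((o - expected) ** 2 / expected).sum())
    df = (t - 1) ** 2
    return a, df, float(stats.chi2.sf(a, df))


def friedman_f(table: RankTable) -> Tuple[float, int, float]:
    """Friedman's statistic F = 12 / (n t (t+1)) * sum_i (R_i - n(t+1)/2)^2
    with R_i the rank sum of source i, df = t-1, chi-square p-value."""
    o = table.counts()
    n, t = table.n, table.t
    j = np.arange(1, t + 1)
    r = (o * j).sum(axis=1)
    f = 12.0 / (n * t * (t + 1)) * float(((r - n * (t + 1) / 2.0) ** 2).sum())
    df = t - 1
    return f, df, float(stats.chi2.sf(f, df))


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 25


def paired_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are handled by the Pratt convention (they enter the
    ranking of |d| but are excluded from the rank sums).  The null
    distribution is exact (dynamic program over signed rank sums,
    supporting mid-rank ties) when at most 25 nonzero differences remain,
    and a normal approximation with continuity correction above that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_signed_rank requires equal-length 1-d vectors")
    if a.size < 1:
        raise ValueError("empty input")
    d = a - b
    nonzero = d != 0
    m = int(nonzero.sum())
    if m == 0:
        logger.info("all paired differences are zero; p = 1")
        return 1.0

    ranks = stats.rankdata(np.abs(d))  # zeros included in the ranking (Pratt)
    w_plus = float(ranks[d > 0].sum())
    nz_ranks = ranks[nonzero]

    if m <= _EXACT_LIMIT:
        return _exact_two_sided(w_plus, nz_ranks)

    n = d.size
    z = n - m  # number of zeros
    mean = (n * (n + 1) - z * (z + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - z * (z + 1) * (2 * z + 1)) / 24.0
    _, tie_counts = np.unique(ranks[nonzero], return_counts=True)
    var -= float((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    corr = 0.5 * np.sign(diff)
    zstat = (diff - corr) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(zstat))))


def _exact_two_sided(w_plus: float, nz_ranks: np.ndarray) -> float:
    """Exact null distribution of W+ by dynamic programming.

    Ranks are doubled so mid-ranks become integers; each nonzero rank is
    included in W+ with probability 1/2 under the null."""
    doubled = np.rint(2 * nz_ranks).astype(int)
    max_sum = int(doubled.sum())
    dist = np.zeros(max_sum + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:max_sum + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = float(dist[:w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons
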