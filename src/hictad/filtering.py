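"""Statistical filtering of false-positive boundary calls.

At a genuine TAD boundary the contacts *within* the flanking regions are
systematically stronger than the contacts *across* the boundary.  For each
candidate bin ``i`` we collect three multisets from the contact matrix with
a half-window of ``w`` bins (default 5):

* ``U`` — contacts among the ``w`` upstream bins ``[i-w, i-1]``
  (strict upper triangle, diagonal self-contacts excluded),
* ``D`` — likewise among the downstream bins ``[i+1, i+w]``,
* ``R`` — all ``w x w`` contacts between the upstream and downstream bins,

and run a one-sided Wilcoxon rank-sum (Mann-Whitney) test of
``U ∪ D`` stochastically greater than ``R``.  Candidates whose p-value
exceeds alpha (default .05) are filtered out.  Candidates too close to a
chromosome end for the test are kept with a missing p-value: the classifier
already vouched for them and the test is merely unavailable there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .hic_io import ContactMatrix

#: below this size of the smaller sample the exact permutation null is used
EXACT_MIN_N = 8


@dataclass
class FilterStats:
    bin: int
    U: np.ndarray
    D: np.ndarray
    R: np.ndarray
    p_value: float | None = None
    kept: bool = True

    @property
    def testable(self) -> bool:
        return len(self.U) > 0 and len(self.D) > 0 and len(self.R) > 0


def boundary_stats(m: ContactMatrix, i: int, w: int = 5) -> FilterStats:
    """Collect the within/cross contact multisets around candidate bin ``i``.

    Windows are truncated at chromosome ends; with fewer than 2 bins on
    either side the statistics are marked untestable (empty multisets).
    """
    if w < 2:
        raise ValueError("window half-width w must be >= 2")
    n = m.n_bins
    up = np.arange(max(0, i - w), i)
    down = np.arange(i + 1, min(n, i + w + 1))
    if len(up) < 2 or len(down) < 2:
        return FilterStats(bin=i, U=np.empty(0), D=np.empty(0), R=np.empty(0))
    iu = np.triu_indices(len(up), k=1)
    U = m.values[np.ix_(up, up)][iu]
    idn = np.triu_indices(len(down), k=1)
    D = m.values[np.ix_(down, down)][idn]
    R = m.values[np.ix_(up, down)].ravel()
    return FilterStats(bin=i, U=U, D=D, R=R)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact one-sided p = P(rank sum of a >= observed) by enumerating every
    assignment of the pooled midranks to a subset of size |a|."""
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    na = len(a)
    observed = ranks[:na].sum()
    total = math.comb(len(pooled), na)
    hits = sum(1 for combo in combinations(ranks, na)
               if sum(combo) >= observed - 1e-9)
    return hits / total


def rank_sum_p(sample_a, sample_b, alternative: str = "a_greater") -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: a stochastically > b.

    Ties are handled by midranks.  When the smaller sample has at least
    ``EXACT_MIN_N`` observations the tie-corrected normal approximation with
    continuity correction is used; otherwise the permutation null is
    enumerated exactly.  A degenerate pooled sample (every value identical)
    carries no evidence either way and returns 0.5.
    """
    if alternative != "a_greater":
        raise ValueError("only the 'a_greater' alternative is supported")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.5
    if min(a.size, b.size) >= EXACT_MIN_N:
        res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        return float(res.pvalue)
    return _exact_rank_sum_p(a, b)


def filter_boundaries(m: ContactMatrix, candidates, w: int = 5,
                      alpha: float = 0.05, bh: bool = False
                      ) -> tuple[list[int], list[FilterStats]]:
    """Keep candidate boundaries whose one-sided rank-sum p-value is <= alpha.

    ``bh=True`` applies a Benjamini-Hochberg correction across the testable
    candidates before thresholding.  Untestable edge candidates are always
    kept, with ``p_value`` recorded as None.
    """
    all_stats: list[FilterStats] = []
    for i in sorted(candidates):
        s = boundary_stats(m, int(i), w=w)
        if s.testable:
            s.p_value = rank_sum_p(np.concatenate([s.U, s.D]), s.R)
        all_stats.append(s)

    testable = [s for s in all_stats if s.p_value is not None]
    if bh and testable:
        ps = np.array([s.p_value for s in testable])
        order = np.argsort(ps, kind="stable")
        m_tests = len(ps)
        adj = np.empty(m_tests)
        running = 1.0
        for rank_idx in range(m_tests - 1, -1, -1):
            k = order[rank_idx]
            running = min(running, ps[k] * m_tests / (rank_idx + 1))
            adj[k] = running
        for s, p_adj in zip(testable, adj):
            s.kept = bool(p_adj <= alpha)
    else:
        for s in testable:
            s.kept = bool(s.p_value <= alpha)

    kept = [s.bin for s in all_stats if s.kept]
    return kept, all_stats
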