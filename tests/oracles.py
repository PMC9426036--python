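"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: timing is checked
against an explicit per-copy mutation event-list simulation, and the
statistical tests against full enumeration / scipy closed forms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def lineage_multiplicity_counts(
    rng: np.random.Generator,
    rate: float,
    gd_time: float,
    state: str = "2+2",
) -> tuple[int, int]:
    """Event-list simulation of clock-like accrual with doubling at gd_time.

    Each chromosome copy is an explicit set of mutation ids; doubling
    duplicates copies (state '2+1' duplicates only one of the two).
    Returns (n1, n2): counts of multiplicity-1 and multiplicity-2
    mutations at the end of unit mutational time.
    """
    if state == "2+2":
        n_pre_copies = 2
        duplicated = (0, 1)
    elif state == "2+0":
        n_pre_copies = 1
        duplicated = (0,)
    elif state == "2+1":
        n_pre_copies = 2
        duplicated = (0,)
    else:
        raise ValueError(state)

    next_id = itertools.count()
    copies: list[set[int]] = []
    for _ in range(n_pre_copies):
        n_mut = rng.poisson(rate * gd_time)
        copies.append({next(next_id) for _ in range(n_mut)})
    # doubling: duplicate the designated copies with their mutations
    for idx in duplicated:
        copies.append(set(copies[idx]))
    for copy in copies:
        n_mut = rng.poisson(rate * (1.0 - gd_time))
        copy.update(next(next_id) for _ in range(n_mut))

    all_ids = set().union(*copies)
    n1 = n2 = 0
    for mut in all_ids:
        mult = sum(mut in c for c in copies)
        if mult == 1:
            n1 += 1
        elif mult == 2:
            n2 += 1
    return n1, n2


def fisher_2x2_closed_form(table) -> float:
    """Two-sided 2x2 Fisher p from the hypergeometric closed form."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9)))


def wilcoxon_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every rank assignment."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in x)
    n1 = len(x)
    all_ranks = list(range(1, len(combined) + 1))
    ws = [sum(comb) for comb in itertools.combinations(all_ranks, n1)]
    total = len(ws)
    cdf = sum(1 for w in ws if w <= w_obs) / total
    sf = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2.0 * min(cdf, sf))
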