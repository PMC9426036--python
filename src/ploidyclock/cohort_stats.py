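"""Cohort-level statistics.

* :func:`fisher_exact` — two-sided Fisher exact test. 2x2 tables are
  solved by exact integer hypergeometric enumeration; r x c tables with
  grand total <= 200 by full enumeration over margin-fixed tables; larger
  tables by seeded Monte-Carlo sampling from the fixed-margin null
  (Patefield algorithm via :func:`scipy.stats.random_table`). The method
  used is always recorded.
* :func:`wilcoxon_rank_sum` — two-sided rank-sum test, exact null by
  enumeration for combined n <= 20 without ties, normal approximation
  with tie and continuity correction otherwise.
* :func:`call_arm_events` / :func:`arm_frequency_comparison` — arm-level
  gain/loss calling against the sample's rounded ploidy baseline, with
  per-arm Fisher tests and Bonferroni correction over all tests run.
* :func:`count_high_breakage` — per-chromosome breakpoint counts (after
  merging adjacent same-state segments) and the number of chromosomes at
  or above the breakage threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genome import arm_intervals
from .io_formats import Segment

MC_THRESHOLD_TOTAL = 200
MC_DEFAULT_DRAWS = 100_000
# Full r x c enumeration is abandoned in favour of Monte Carlo past this
# many candidate tables (keeps worst-case 3x3/total-200 inputs bounded).
ENUMERATION_CAP = 2_000_000
HIGH_BREAKAGE_K = 10
_REL_TOL = 1e-10


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, ...], ...]
    p_value: float
    odds_ratio: float | None
    method: str  # "exact_enumeration" | "monte_carlo"
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of x in the combined sample
    p_value: float
    method: str  # "exact_enumeration" | "normal_approximation"


@dataclass(frozen=True)
class ArmEvent:
    sample_id: str
    arm: str
    call: str  # "gain" | "loss" | "neutral"
    supporting_fraction: float


@dataclass(frozen=True)
class ArmTestResult:
    arm: str
    event: str
    result: ContingencyResult
    p_corrected: float


@dataclass(frozen=True)
class BreakageSummary:
    sample_id: str
    breakpoints: dict[str, int]
    high_breakage_count: int
    k: int


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency table must contain integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr.astype(int)


def _fisher_2x2(arr: np.ndarray) -> tuple[float, float]:
    """Two-sided 2x2 Fisher p by integer hypergeometric enumeration.

    All table probabilities share the denominator C(N, c1), so tables are
    compared by exact integer numerators: no floating-point tie tolerance
    is needed.
    """
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n_total = a + b + c + d
    r1, c1 = a + b, a + c
    if n_total == 0:
        return 1.0, float("nan")
    lo = max(0, r1 + c1 - n_total)
    hi = min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(n_total - r1, c1 - k)
               for k in range(lo, hi + 1)}
    w_obs = weights[a]
    numerator = sum(w for w in weights.values() if w <= w_obs)
    p = numerator / math.comb(n_total, c1)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return min(p, 1.0), odds


def _table_logprob(arr: np.ndarray, lf: np.ndarray) -> float:
    # log P(table | margins) = sum(log r_i!) + sum(log c_j!) - log N! - sum(log n_ij!)
    r = arr.sum(axis=1)
    c = arr.sum(axis=0)
    return float(lf[r].sum() + lf[c].sum() - lf[arr.sum()] - lf[arr].sum())


def _enumerate_tables(row_sums, col_sums, cap):
    """Yield all non-negative integer tables with the given margins.

    Raises OverflowError when more than ``cap`` tables would be visited.
    """
    n_rows = len(row_sums)
    n_cols = len(col_sums)
    table = np.zeros((n_rows, n_cols), dtype=int)
    count = 0

    def fill_row(i, remaining_cols):
        nonlocal count
        if i == n_rows - 1:
            if all(r >= 0 for r in remaining_cols) and sum(remaining_cols) == row_sums[i]:
                table[i, :] = remaining_cols
                count += 1
                if count > cap:
                    raise OverflowError
                yield table
            return
        yield from fill_cell(i, 0, row_sums[i], remaining_cols)

    def fill_cell(i, j, row_left, remaining_cols):
        if j == n_cols - 1:
            if 0 <= row_left <= remaining_cols[j]:
                table[i, j] = row_left
                new_cols = list(remaining_cols)
                new_cols[j] -= row_left
                yield from fill_row(i + 1, new_cols)
            return
        for v in range(min(row_left, remaining_cols[j]) + 1):
            table[i, j] = v
            new_cols = list(remaining_cols)
            new_cols[j] -= v
            yield from fill_cell(i, j + 1, row_left - v, new_cols)

    yield from fill_row(0, list(col_sums))


def _fisher_rxc_enumeration(arr: np.ndarray, cap: int = ENUMERATION_CAP) -> float:
    n_total = int(arr.sum())
    lf = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_total + 1)))])
    logp_obs = _table_logprob(arr, lf)
    row_sums = [int(v) for v in arr.sum(axis=1)]
    col_sums = [int(v) for v in arr.sum(axis=0)]
    total_logp = []
    hit_logp = []
    for table in _enumerate_tables(row_sums, col_sums, cap):
        lp = _table_logprob(table, lf)
        total_logp.append(lp)
        if lp <= logp_obs + _REL_TOL:
            hit_logp.append(lp)
    # normalise within the enumerated set (sums to 1 analytically; the
    # explicit normalisation absorbs float error)
    total = np.logaddexp.reduce(total_logp)
    p = float(np.exp(np.logaddexp.reduce(hit_logp) - total))
    return min(p, 1.0)


def _fisher_monte_carlo(
    arr: np.ndarray, n_draws: int, seed: int
) -> tuple[float, int]:
    n_total = int(arr.sum())
    lf = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_total + 1)))])
    logp_obs = _table_logprob(arr, lf)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(arr.sum(axis=1), arr.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng).astype(int)
    hits = 0
    for t in draws:
        if _table_logprob(t, lf) <= logp_obs + _REL_TOL:
            hits += 1
    return (hits + 1) / (n_draws + 1), n_draws


def fisher_exact(
    table,
    n_permutations: int = MC_DEFAULT_DRAWS,
    seed: int = 0,
    enumeration_cap: int = ENUMERATION_CAP,
) -> ContingencyResult:
    """Two-sided Fisher exact test on an r x c count table.

    Two-sided p-value: total probability of all margin-fixed tables at
    most as probable as the observed one.
    """
    arr = _validate_table(table)
    table_tuple = tuple(tuple(int(v) for v in row) for row in arr)
    if arr.shape == (2, 2):
        p, odds = _fisher_2x2(arr)
        return ContingencyResult(table_tuple, p, odds, "exact_enumeration")
    if int(arr.sum()) <= MC_THRESHOLD_TOTAL:
        try:
            p = _fisher_rxc_enumeration(arr, cap=enumeration_cap)
            return ContingencyResult(table_tuple, p, None, "exact_enumeration")
        except OverflowError:
            pass  # too many tables; fall through to Monte Carlo
    p, n_done = _fisher_monte_carlo(arr, n_permutations, seed)
    return ContingencyResult(
        table_tuple, p, None, "monte_carlo", n_permutations=n_done, seed=seed
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> RankSumResult:
    """Two-sided two-sample rank-sum test.

    The statistic is the rank sum of ``x`` in the combined sample. Exact
    null distribution (full enumeration over rank assignments) is used
    for combined n <= ``exact_max_n`` without ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[: len(x)].sum())
    n1, n2 = len(x), len(y)
    n = n1 + n2
    has_ties = len(np.unique(combined)) < n

    if n <= exact_max_n and not has_ties:
        # Exact: distribution of the rank sum over all C(n, n1) subsets,
        # computed by dynamic programming over rank inclusion.
        max_w = n1 * n + 1
        counts = np.zeros((n1 + 1, max_w), dtype=float)
        counts[0, 0] = 1.0
        for rank in range(1, n + 1):
            for k in range(min(rank, n1), 0, -1):
                counts[k, rank:] += counts[k - 1, :-rank] if rank else counts[k - 1, :]
        dist = counts[n1]
        total = dist.sum()
        w_int = int(round(w))
        cdf = dist[: w_int + 1].sum() / total
        sf = dist[w_int:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return RankSumResult(statistic=w, p_value=p, method="exact_enumeration")

    mean_w = n1 * (n + 1) / 2.0
    tie_counts = np.unique(combined, return_counts=True)[1]
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return RankSumResult(statistic=w, p_value=1.0, method="normal_approximation")
    z = (w - mean_w - math.copysign(0.5, w - mean_w)) / math.sqrt(var_w)
    if abs(w - mean_w) <= 0.5:
        z = 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankSumResult(statistic=w, p_value=p, method="normal_approximation")


def merge_adjacent_segments(segments: Sequence[Segment]) -> list[Segment]:
    """Merge contiguous same-chromosome segments with identical copy state."""
    merged: list[Segment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (
            merged
            and merged[-1].chrom == seg.chrom
            and merged[-1].state == seg.state
            and merged[-1].end + 1 == seg.start
        ):
            prev = merged.pop()
            seg = Segment(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=prev.start,
                end=seg.end,
                n_major=prev.n_major,
                n_minor=prev.n_minor,
            )
        merged.append(seg)
    return merged


def count_high_breakage(
    segments: Sequence[Segment], k: int = HIGH_BREAKAGE_K
) -> BreakageSummary:
    """Per-chromosome breakpoint counts (segments - 1 after adjacency merge)
    and the number of chromosomes with >= k breakpoints."""
    sample_id = segments[0].sample_id if segments else "unknown"
    merged = merge_adjacent_segments(segments)
    per_chrom: dict[str, int] = {}
    for seg in merged:
        per_chrom[seg.chrom] = per_chrom.get(seg.chrom, 0) + 1
    breakpoints = {chrom: n - 1 for chrom, n in per_chrom.items()}
    high = sum(1 for bp in breakpoints.values() if bp >= k)
    return BreakageSummary(
        sample_id=sample_id, breakpoints=breakpoints, high_breakage_count=high, k=k
    )


def call_arm_events(
    segments: Sequence[Segment],
    gd: bool,
    min_fraction: float = 0.5,
) -> list[ArmEvent]:
    """Call per-arm gains/losses against the rounded ploidy baseline.

    An arm is called gained (lost) when at least ``min_fraction`` of the
    arm's length carries total copy number above (below) the baseline —
    2 in diploid genomes, 4 with genome doubling.
    """
    baseline = 4 if gd else 2
    sample_id = segments[0].sample_id if segments else "unknown"
    arms = arm_intervals()
    known_chroms = {chrom for chrom, _, _ in arms.values()}
    for seg in segments:
        if seg.chrom not in known_chroms:
            raise KeyError(
                f"chromosome {seg.chrom!r} missing from the arm-boundary table"
            )
    events: list[ArmEvent] = []
    for arm, (chrom, arm_start, arm_end) in arms.items():
        arm_len = arm_end - arm_start + 1
        gained = lost = 0
        for seg in segments:
            if seg.chrom != chrom:
                continue
            overlap = min(seg.end, arm_end) - max(seg.start, arm_start) + 1
            if overlap <= 0:
                continue
            if seg.total_cn > baseline:
                gained += overlap
            elif seg.total_cn < baseline:
                lost += overlap
        gain_frac = gained / arm_len
        loss_frac = lost / arm_len
        if gain_frac >= min_fraction and gain_frac >= loss_frac:
            events.append(ArmEvent(sample_id, arm, "gain", gain_frac))
        elif loss_frac >= min_fraction:
            events.append(ArmEvent(sample_id, arm, "loss", loss_frac))
        else:
            events.append(
                ArmEvent(sample_id, arm, "neutral", max(gain_frac, loss_frac))
            )
    return events


def arm_frequency_comparison(
    events_by_sample: Mapping[str, Sequence[ArmEvent]],
    group_by_sample: Mapping[str, str],
    event_types: Sequence[str] = ("gain", "loss"),
    seed: int = 0,
) -> list[ArmTestResult]:
    """Per-arm, per-event-type Fisher tests of event presence across groups,
    Bonferroni-corrected by the number of tests performed."""
    groups = sorted(set(group_by_sample.values()))
    if len(groups) < 2:
        raise ValueError("arm comparison requires at least two groups")
    arms = sorted({e.arm for evs in events_by_sample.values() for e in evs})
    results: list[ArmTestResult] = []
    raw: list[tuple[str, str, ContingencyResult]] = []
    for arm in arms:
        for event in event_types:
            table = np.zeros((2, len(groups)), dtype=int)
            for sample_id, events in events_by_sample.items():
                group_idx = groups.index(group_by_sample[sample_id])
                has_event = any(e.arm == arm and e.call == event for e in events)
                table[0 if has_event else 1, group_idx] += 1
            raw.append((arm, event, fisher_exact(table, seed=seed)))
    n_tests = len(raw)
    for arm, event, res in raw:
        results.append(
            ArmTestResult(
                arm=arm,
                event=event,
                result=res,
                p_corrected=min(1.0, res.p_value * n_tests),
            )
        )
    return results
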