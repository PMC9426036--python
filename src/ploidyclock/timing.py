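"""Molecular-clock timing of genome doubling.

For an SNV with variant allele fraction ``f`` inside a segment of total
copy number ``n_t`` in a tumour of purity ``rho``, the expected VAF of a
mutation present on ``m`` chromosome copies is

    f = m * rho / (rho * n_t + 2 * (1 - rho))

so the raw multiplicity estimate is the inversion

    m_raw = f * (rho * n_t + 2 * (1 - rho)) / rho

hard-assigned by rounding and clamping to [1, n_major].

In timing-informative copy states, pre-doubling mutations sit on two
copies (m=2) and post-doubling ones on one (m=1). With clock-like
accrual at a constant per-copy rate, the fraction of mutational time
elapsed before doubling is

    2+2 and 2+0 segments:  pi = 2*n2 / (2*n2 + n1)
    2+1 segments:          pi = 3*n2 / (2*n2 + n1)   (clamped to [0, 1])

where n1/n2 count multiplicity-1/2 SNVs in the segment. The per-sample
estimate pools 2+2 and 2+0 segments (both created simultaneously by the
doubling) by SNV-count-weighted mean; 2+1 segments are computed but
excluded from the aggregate unless requested, since their gains need not
be synchronous with the doubling. The bootstrap interval resamples SNVs
within segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import Segment, SNVRecord

logger = logging.getLogger(__name__)

MIN_SNVS_PER_SEGMENT = 10
MIN_SNVS_PER_SAMPLE = 50

TIMEABLE_STATES = ((2, 2), (2, 0))
OPTIONAL_STATES = ((2, 1),)


@dataclass(frozen=True)
class MultiplicityEstimate:
    snv: SNVRecord
    m_raw: float
    m: int
    n_t: int
    n_major: int


@dataclass(frozen=True)
class SegmentTiming:
    segment: Segment
    n1: int
    n2: int
    pi: float | None  # None => uninformative (too few SNVs)


@dataclass(frozen=True)
class TimingEstimate:
    """Aggregated GD timing for one sample; ``pi`` is None if untimeable."""

    sample_id: str
    pi: float | None
    ci_low: float | None
    ci_high: float | None
    n_segments: int
    n_snvs: int
    segment_timings: tuple[SegmentTiming, ...]
    reason: str | None = None

    @property
    def timeable(self) -> bool:
        return self.pi is not None


def estimate_multiplicity(
    snv: SNVRecord, seg: Segment, purity: float
) -> MultiplicityEstimate:
    """Invert the VAF model to a hard-assigned integer multiplicity."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} not in (0, 1]")
    if snv.chrom != seg.chrom or not (seg.start <= snv.pos <= seg.end):
        raise ValueError(
            f"SNV {snv.chrom}:{snv.pos} does not lie in segment"
            f" {seg.chrom}:{seg.start}-{seg.end}"
        )
    n_t = seg.total_cn
    m_raw = snv.vaf * (purity * n_t + 2.0 * (1.0 - purity)) / purity
    m = int(np.clip(round(m_raw), 1, max(seg.n_major, 1)))
    return MultiplicityEstimate(snv=snv, m_raw=m_raw, m=m, n_t=n_t, n_major=seg.n_major)


def assign_snvs_to_segments(
    snvs: Sequence[SNVRecord], segments: Sequence[Segment]
) -> tuple[list[tuple[SNVRecord, Segment]], int]:
    """Match each SNV to its containing segment; unmatched SNVs are dropped.

    Returns the (snv, segment) pairs and the count of excluded SNVs.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    starts = {}
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        starts[chrom] = np.array([s.start for s in segs])
    pairs: list[tuple[SNVRecord, Segment]] = []
    n_excluded = 0
    for snv in snvs:
        segs = by_chrom.get(snv.chrom)
        if not segs:
            n_excluded += 1
            continue
        idx = int(np.searchsorted(starts[snv.chrom], snv.pos, side="right")) - 1
        if idx >= 0 and segs[idx].start <= snv.pos <= segs[idx].end:
            pairs.append((snv, segs[idx]))
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("assign_snvs_to_segments: %d SNVs outside segments", n_excluded)
    return pairs, n_excluded


def time_segment(
    n1: int,
    n2: int,
    state: tuple[int, int],
    min_snvs: int = MIN_SNVS_PER_SEGMENT,
) -> float | None:
    """Per-segment GD time from multiplicity-1/2 counts; None if uninformative."""
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if state not in TIMEABLE_STATES + OPTIONAL_STATES:
        raise ValueError(f"state {state} is not timing-informative")
    if n1 + n2 < min_snvs:
        return None
    numerator = 2.0 * n2 if state in TIMEABLE_STATES else 3.0 * n2
    pi = numerator / (2.0 * n2 + n1)
    return float(np.clip(pi, 0.0, 1.0))


def _aggregate(timings: Sequence[SegmentTiming]) -> float:
    weights = np.array([t.n1 + t.n2 for t in timings], dtype=float)
    pis = np.array([t.pi for t in timings], dtype=float)
    return float(np.average(pis, weights=weights))


def time_genome_doubling(
    snvs: Sequence[SNVRecord],
    segments: Sequence[Segment],
    purity: float,
    n_boot: int = 200,
    seed: int = 0,
    include_2plus1: bool = False,
    min_snvs_segment: int = MIN_SNVS_PER_SEGMENT,
    min_snvs_sample: int = MIN_SNVS_PER_SAMPLE,
) -> TimingEstimate:
    """Aggregate GD timing for one (GD-called) sample with bootstrap CI.

    Samples without informative segments or with fewer than
    ``min_snvs_sample`` informative SNVs are returned as explicitly
    untimeable (``pi is None`` with a reason), never as a noisy number.
    """
    sample_id = snvs[0].sample_id if snvs else "unknown"
    states = TIMEABLE_STATES + (OPTIONAL_STATES if include_2plus1 else ())
    aggregate_states = states if include_2plus1 else TIMEABLE_STATES

    pairs, _ = assign_snvs_to_segments(snvs, segments)
    mult_by_seg: dict[Segment, list[int]] = {}
    for snv, seg in pairs:
        if seg.state in states:
            est = estimate_multiplicity(snv, seg, purity)
            mult_by_seg.setdefault(seg, []).append(est.m)

    seg_timings: list[SegmentTiming] = []
    for seg, mults in sorted(
        mult_by_seg.items(), key=lambda kv: (kv[0].chrom, kv[0].start)
    ):
        n1 = sum(1 for m in mults if m == 1)
        n2 = sum(1 for m in mults if m == 2)
        pi = time_segment(n1, n2, seg.state, min_snvs=min_snvs_segment)
        seg_timings.append(SegmentTiming(segment=seg, n1=n1, n2=n2, pi=pi))

    informative = [
        t
        for t in seg_timings
        if t.pi is not None and t.segment.state in aggregate_states
    ]
    n_snvs = sum(t.n1 + t.n2 for t in informative)
    if not informative or n_snvs < min_snvs_sample:
        reason = (
            "no timing-informative segments"
            if not informative
            else f"only {n_snvs} informative SNVs (< {min_snvs_sample})"
        )
        return TimingEstimate(
            sample_id=sample_id,
            pi=None,
            ci_low=None,
            ci_high=None,
            n_segments=len(informative),
            n_snvs=n_snvs,
            segment_timings=tuple(seg_timings),
            reason=reason,
        )

    pi_hat = _aggregate(informative)

    # Bootstrap: resample SNV multiplicity labels within each segment.
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    ns = np.array([t.n1 + t.n2 for t in informative])
    p2 = np.array([t.n2 / (t.n1 + t.n2) for t in informative])
    is_21 = np.array([t.segment.state == (2, 1) for t in informative])
    for b in range(n_boot):
        n2_b = rng.binomial(ns, p2)
        n1_b = ns - n2_b
        num = np.where(is_21, 3.0, 2.0) * n2_b
        pis_b = np.clip(num / np.maximum(2.0 * n2_b + n1_b, 1e-12), 0.0, 1.0)
        boot[b] = np.average(pis_b, weights=ns)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    return TimingEstimate(
        sample_id=sample_id,
        pi=pi_hat,
        ci_low=float(min(ci_low, pi_hat)),
        ci_high=float(max(ci_high, pi_hat)),
        n_segments=len(informative),
        n_snvs=n_snvs,
        segment_timings=tuple(seg_timings),
    )
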