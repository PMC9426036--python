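"""Copy-state classification, LOH fraction, ploidy, and the amplification rule.

Copy states are classified into four categories from the allele-specific
(major, minor) copy numbers:

* ``diploid`` — 1+1
* ``gain``    — 2+1 (trisomy) or 2+2 (tetrasomy)
* ``cnLOH``   — 2+0 (copy-neutral loss of heterozygosity)
* ``other``   — every remaining state

All genome fractions (LOH fraction, ploidy, class lengths) are length-
weighted over autosomal segments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .genome import AUTOSOMES
from .io_formats import Segment


class CopyStateClass(str, Enum):
    DIPLOID = "diploid"
    GAIN = "gain"
    CNLOH = "cnLOH"
    OTHER = "other"


@dataclass
class PloidyProfile:
    """Per-sample genome summary.

    ``ploidy`` is the length-weighted mean total copy number; ``major_ploidy``
    the length-weighted mean major-allele copy number (the genome-doubling
    clustering feature: robust to haploidisation, which lowers total ploidy
    but not major-allele ploidy); ``loh_fraction`` the fraction of autosomal
    length with minor allele 0. The ``gd``/``hp`` flags are filled in by the
    caller module and default to ``None`` (not yet called).
    """

    sample_id: str
    ploidy: float
    major_ploidy: float
    loh_fraction: float
    class_lengths: dict[CopyStateClass, int] = field(default_factory=dict)
    total_length: int = 0
    hp: bool | None = None
    gd: bool | None = None


def classify_segment(seg: Segment) -> CopyStateClass:
    """Map a segment's (major, minor) state to its copy-state class."""
    state = seg.state
    if state == (1, 1):
        return CopyStateClass.DIPLOID
    if state in ((2, 1), (2, 2)):
        return CopyStateClass.GAIN
    if state == (2, 0):
        return CopyStateClass.CNLOH
    return CopyStateClass.OTHER


def _autosomal(segments: Iterable[Segment]) -> list[Segment]:
    return [s for s in segments if s.chrom in AUTOSOMES]


def loh_fraction(segments: Sequence[Segment]) -> float:
    """Length fraction of the autosomal segmented genome with minor allele 0."""
    segs = _autosomal(segments)
    if not segs:
        raise ValueError("loh_fraction requires at least one autosomal segment")
    total = sum(s.length for s in segs)
    loh = sum(s.length for s in segs if s.n_minor == 0)
    return loh / total


def sample_ploidy(segments: Sequence[Segment]) -> float:
    """Length-weighted mean total copy number over autosomal segments."""
    segs = _autosomal(segments)
    if not segs:
        raise ValueError("sample_ploidy requires at least one autosomal segment")
    total = sum(s.length for s in segs)
    return sum(s.total_cn * s.length for s in segs) / total


def major_ploidy(segments: Sequence[Segment]) -> float:
    """Length-weighted mean major-allele copy number (GD clustering feature)."""
    segs = _autosomal(segments)
    if not segs:
        raise ValueError("major_ploidy requires at least one autosomal segment")
    total = sum(s.length for s in segs)
    return sum(s.n_major * s.length for s in segs) / total


def class_lengths(segments: Sequence[Segment]) -> dict[CopyStateClass, int]:
    lengths = {cls: 0 for cls in CopyStateClass}
    for seg in _autosomal(segments):
        lengths[classify_segment(seg)] += seg.length
    return lengths


def is_amplified(total_cn: int, gd: bool) -> bool:
    """Amplification rule: total copy >= 5 in diploid genomes, >= 9 with GD."""
    if total_cn < 0:
        raise ValueError("total_cn must be non-negative")
    return total_cn >= (9 if gd else 5)


def build_ploidy_profile(sample_id: str, segments: Sequence[Segment]) -> PloidyProfile:
    """Compute the per-sample :class:`PloidyProfile` (GD/HP flags unset)."""
    segs = _autosomal(segments)
    lengths = class_lengths(segs)
    return PloidyProfile(
        sample_id=sample_id,
        ploidy=sample_ploidy(segs),
        major_ploidy=major_ploidy(segs),
        loh_fraction=loh_fraction(segs),
        class_lengths=lengths,
        total_length=sum(s.length for s in segs),
    )


def build_profiles(
    segments_by_sample: Mapping[str, Sequence[Segment]]
) -> list[PloidyProfile]:
    return [
        build_ploidy_profile(sample_id, segs)
        for sample_id, segs in segments_by_sample.items()
    ]
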