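"""Shared data model and readers/writers for the standard tabular formats.

Conventions used throughout the package:

* all genomic coordinates are 1-based inclusive (Battenberg/VCF style);
* chromosome names are normalised by stripping a leading ``chr``;
* segment tables are tab-separated with configurable column aliases so
  that Battenberg's native header (``startpos``/``endpos``/``nMajor``/
  ``nMinor``) is accepted out of the box;
* SNVs come from VCF 4.x with per-sample ``AD`` (allelic depth) and
  ``DP`` fields; indels and multiallelic records are skipped with a
  logged count, never decomposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .genome import normalise_chrom

logger = logging.getLogger(__name__)

GRADES = ("ACT/G1", "G2/3", "DD")
IDH_GROUPS = ("IDH1", "IDH2", "IDHwt", "unknown")
TERT_STATUSES = ("mutant", "wildtype", "unknown")


class SegmentTableError(ValueError):
    """Raised when a segment table violates the data-model invariants."""


class VcfFormatError(ValueError):
    """Raised when a VCF record lacks the required depth fields."""


class MetadataError(ValueError):
    """Raised for invalid sample-metadata values."""


@dataclass(frozen=True, order=True)
class Segment:
    """One allele-specific copy-number interval of one sample.

    ``start``/``end`` are 1-based inclusive; ``n_major >= n_minor >= 0``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SegmentTableError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}"
                " has end < start"
            )
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise SegmentTableError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}"
                f" has invalid copy numbers {self.n_major}+{self.n_minor}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_cn(self) -> int:
        return self.n_major + self.n_minor

    @property
    def state(self) -> tuple[int, int]:
        return (self.n_major, self.n_minor)


@dataclass(frozen=True)
class SNVRecord:
    """A somatic single-nucleotide variant with read support."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.alt_reads < 0 or self.alt_reads > self.depth:
            raise ValueError(
                f"SNV {self.sample_id} {self.chrom}:{self.pos} has invalid"
                f" read counts alt={self.alt_reads} depth={self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical/technical metadata."""

    sample_id: str
    grade: str = "G2/3"
    idh_group: str = "unknown"
    tert_status: str = "unknown"
    purity: float = 1.0
    age: float | None = None
    size: float | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise MetadataError(f"{self.sample_id}: unknown grade {self.grade!r}")
        if self.idh_group not in IDH_GROUPS:
            raise MetadataError(
                f"{self.sample_id}: unknown IDH group {self.idh_group!r}"
            )
        if self.tert_status not in TERT_STATUSES:
            raise MetadataError(
                f"{self.sample_id}: unknown TERT status {self.tert_status!r}"
            )
        if not (0.0 < self.purity <= 1.0):
            raise MetadataError(
                f"{self.sample_id}: purity {self.purity} not in (0, 1]"
            )


# Stable cohort-table column order; boolean flags are serialised as 0/1.
COHORT_COLUMNS = (
    "sample_id",
    "grade",
    "idh_group",
    "tert_status",
    "purity",
    "gd",
    "hp",
    "loh_fraction",
    "ploidy",
    "high_breakage_count",
    "idh_label",
    "tert_label",
)
_COHORT_BOOL = ("gd", "hp")
_COHORT_FLOAT = ("purity", "loh_fraction", "ploidy")
_COHORT_INT = ("high_breakage_count",)


@dataclass
class CohortTable:
    """Samples x (group labels, genomic flags) table.

    A thin validated wrapper around a :class:`pandas.DataFrame` with the
    fixed column set :data:`COHORT_COLUMNS`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.df = self.df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        if self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.equals(other.df)


_DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample", "samplename"),
    "chrom": ("chrom", "chr", "chromosome"),
    "start": ("startpos", "start"),
    "end": ("endpos", "end"),
    "n_major": ("nmajor", "n_major", "major", "nmaj1_a"),
    "n_minor": ("nminor", "n_minor", "minor", "nmin1_a"),
}


def _resolve_columns(
    columns: Sequence[str], aliases: Mapping[str, Sequence[str]] | None
) -> dict[str, str]:
    lookup = {c.lower(): c for c in columns}
    merged = dict(_DEFAULT_ALIASES)
    if aliases:
        for key, names in aliases.items():
            merged[key] = tuple(names) + merged.get(key, ())
    resolved = {}
    for key, names in merged.items():
        for name in names:
            if name.lower() in lookup:
                resolved[key] = lookup[name.lower()]
                break
        else:
            raise SegmentTableError(
                f"segment table missing a column for {key!r}"
                f" (accepted: {list(names)})"
            )
    return resolved


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (99, chrom)


def read_segments(
    path: str | Path,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[Segment]]:
    """Read a tab-separated allele-specific segment table.

    Returns segments grouped by sample, sorted by chromosome and start.
    Raises :class:`SegmentTableError` on overlapping segments or invalid
    copy numbers, naming the offending sample and chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(df.columns, aliases)
    segments: dict[str, list[Segment]] = {}
    for _, row in df.iterrows():
        seg = Segment(
            sample_id=str(row[cols["sample_id"]]),
            chrom=normalise_chrom(row[cols["chrom"]]),
            start=int(row[cols["start"]]),
            end=int(row[cols["end"]]),
            n_major=int(row[cols["n_major"]]),
            n_minor=int(row[cols["n_minor"]]),
        )
        segments.setdefault(seg.sample_id, []).append(seg)
    for sample_id, segs in segments.items():
        segs.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
        validate_segments(segs)
    return segments


def validate_segments(segments: Sequence[Segment]) -> None:
    """Check the sortedness/non-overlap invariant of one sample's segments."""
    for prev, cur in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and cur.start <= prev.end:
            raise SegmentTableError(
                f"overlapping segments for sample {cur.sample_id}"
                f" on chromosome {cur.chrom}:"
                f" {prev.start}-{prev.end} and {cur.start}-{cur.end}"
            )


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    """Write segments as a Battenberg-style TSV (native header names)."""
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_major, s.n_minor)
        for s in segments
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "startpos", "endpos", "nMajor", "nMinor"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_snvs(path: str | Path) -> list[SNVRecord]:
    """Read biallelic SNVs from a VCF 4.x file (or every ``*.vcf`` in a dir).

    One :class:`SNVRecord` is emitted per sample column carrying a
    non-missing AD entry with positive depth. Indels and multiallelic
    records are skipped; the number skipped is logged.
    """
    path = Path(path)
    if path.is_dir():
        records: list[SNVRecord] = []
        for vcf_path in sorted(path.glob("*.vcf")):
            records.extend(read_snvs(vcf_path))
        return records

    records = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or alts[0] not in "ACGT"
            ):
                n_skipped += 1
                continue
            for sample_name, call in rec.samples.items():
                if "AD" not in call or call["AD"] is None:
                    raise VcfFormatError(
                        f"record {rec.chrom}:{rec.pos} sample {sample_name}"
                        " lacks the AD field"
                    )
                ad = call["AD"]
                if ad is None or any(a is None for a in ad):
                    continue  # missing genotype for this sample
                alt_reads = int(ad[1])
                depth = call.get("DP")
                if depth is None:
                    depth = int(sum(ad))
                depth = int(depth)
                if depth <= 0:
                    continue
                records.append(
                    SNVRecord(
                        sample_id=sample_name,
                        chrom=normalise_chrom(rec.chrom),
                        pos=int(rec.pos),
                        ref=rec.ref,
                        alt=alts[0],
                        alt_reads=alt_reads,
                        depth=depth,
                    )
                )
    if n_skipped:
        logger.info("read_snvs(%s): skipped %d non-SNV/multiallelic records",
                    path, n_skipped)
    return records


def group_snvs(snvs: Iterable[SNVRecord]) -> dict[str, list[SNVRecord]]:
    grouped: dict[str, list[SNVRecord]] = {}
    for snv in snvs:
        grouped.setdefault(snv.sample_id, []).append(snv)
    return grouped


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample-metadata CSV (documented header, see README)."""
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise MetadataError("metadata CSV must have a 'sample_id' column")
    metas: dict[str, SampleMeta] = {}
    valid = {f.name for f in fields(SampleMeta)}
    for _, row in df.iterrows():
        kwargs: dict = {}
        for key, value in row.items():
            if key not in valid or pd.isna(value):
                continue
            if key == "purity":
                kwargs[key] = float(value)
            elif key in ("age", "size"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        meta = SampleMeta(**kwargs)
        if meta.sample_id in metas:
            raise MetadataError(f"duplicate sample id {meta.sample_id}")
        metas[meta.sample_id] = meta
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "grade": m.grade,
                "idh_group": m.idh_group,
                "tert_status": m.tert_status,
                "purity": m.purity,
                "age": m.age,
                "size": m.size,
                "outcome": m.outcome,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write the cohort table as TSV with a stable column order.

    Round-trips losslessly through :func:`read_cohort_table` (bit-exact
    integers/booleans; floats via repr, exact to well below 1e-12).
    """
    df = table.df.copy()
    for col in _COHORT_BOOL:
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        df = pd.DataFrame(columns=list(COHORT_COLUMNS))
    for col in _COHORT_BOOL:
        df[col] = df[col].map(lambda v: bool(int(v))) if len(df) else df[col].astype(bool)
    for col in _COHORT_FLOAT:
        df[col] = df[col].astype(float)
    for col in _COHORT_INT:
        df[col] = df[col].astype(int) if len(df) else df[col]
    for col in ("idh_label", "tert_label"):
        df[col] = df[col].where(pd.notna(df[col]), None) if len(df) else df[col]
    return CohortTable(df)
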