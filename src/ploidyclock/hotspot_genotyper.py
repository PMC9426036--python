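"""Driver hotspot genotyping: IDH1/IDH2 grouping and TERT promoter status.

Samples are genotyped by exact (chrom, pos, ref, alt) matching of their
SNVs against a hotspot table; no fuzzy or consequence-based matching is
performed. A versioned GRCh38 table covering IDH1 R132, IDH2 R172, and
the TERT promoter positions (C228T at g.1295113 and C250T) ships as
package data; users may supply their own table for other builds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome import normalise_chrom
from .io_formats import SNVRecord


class HotspotTableError(ValueError):
    """Raised for malformed hotspot tables (e.g. duplicate keys)."""


@dataclass(frozen=True)
class HotspotDef:
    gene: str
    label: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]


@dataclass(frozen=True)
class DriverGenotype:
    """Per-sample driver call.

    ``idh_group`` is IDHwt iff no IDH hotspot matched (``idh_label`` is
    then None); ``conflict`` is set when hotspots from both IDH1 and
    IDH2 matched, in which case the group follows the higher-VAF match.
    """

    sample_id: str
    idh_group: str  # "IDH1" | "IDH2" | "IDHwt"
    idh_label: str | None
    tert_status: str  # "mutant" | "wildtype"
    tert_label: str | None
    conflict: bool = False


def load_hotspots(path: str | Path | None = None) -> list[HotspotDef]:
    """Load a hotspot TSV (gene, label, chrom, pos, ref, alts); default bundled."""
    if path is None:
        text = (
            resources.files("ploidyclock.data")
            .joinpath("hotspots_grch38.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    hotspots: list[HotspotDef] = []
    seen_keys: set[tuple[str, int, str]] = set()
    labels: set[tuple[str, str]] = set()
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        hs = HotspotDef(
            gene=row["gene"],
            label=row["label"],
            chrom=normalise_chrom(row["chrom"]),
            pos=int(row["pos"]),
            ref=row["ref"],
            alts=tuple(row["alts"].split(",")),
        )
        for alt in hs.alts:
            key = (hs.chrom, hs.pos, alt)
            if key in seen_keys:
                raise HotspotTableError(f"duplicate hotspot key {key}")
            seen_keys.add(key)
        if (hs.gene, hs.label) in labels:
            raise HotspotTableError(f"duplicate label {hs.label} for {hs.gene}")
        labels.add((hs.gene, hs.label))
        hotspots.append(hs)
    return hotspots


def _match(snv: SNVRecord, hotspots: Sequence[HotspotDef]) -> HotspotDef | None:
    for hs in hotspots:
        if (
            snv.chrom == hs.chrom
            and snv.pos == hs.pos
            and snv.ref == hs.ref
            and snv.alt in hs.alts
        ):
            return hs
    return None


def genotype_sample(
    snvs: Sequence[SNVRecord],
    hotspots: Sequence[HotspotDef] | None = None,
    sample_id: str | None = None,
) -> DriverGenotype:
    """Genotype one sample's SNVs against the hotspot table.

    A pure function of the (snv set, hotspot table): VCF record order
    never changes the output.
    """
    if hotspots is None:
        hotspots = load_hotspots()
    if sample_id is None:
        sample_id = snvs[0].sample_id if snvs else "unknown"

    idh_matches: list[tuple[HotspotDef, SNVRecord]] = []
    tert_matches: list[tuple[HotspotDef, SNVRecord]] = []
    for snv in snvs:
        hs = _match(snv, hotspots)
        if hs is None:
            continue
        if hs.gene in ("IDH1", "IDH2"):
            idh_matches.append((hs, snv))
        elif hs.gene == "TERT":
            tert_matches.append((hs, snv))

    genes = {hs.gene for hs, _ in idh_matches}
    conflict = "IDH1" in genes and "IDH2" in genes
    if idh_matches:
        # deterministic: highest VAF wins, ties broken by coordinates
        hs, _ = max(
            idh_matches, key=lambda pair: (pair[1].vaf, -pair[1].pos, pair[0].label)
        )
        idh_group, idh_label = hs.gene, hs.label
    else:
        idh_group, idh_label = "IDHwt", None

    if tert_matches:
        hs, _ = max(tert_matches, key=lambda pair: pair[1].vaf)
        tert_status, tert_label = "mutant", hs.label
    else:
        tert_status, tert_label = "wildtype", None

    return DriverGenotype(
        sample_id=sample_id,
        idh_group=idh_group,
        idh_label=idh_label,
        tert_status=tert_status,
        tert_label=tert_label,
        conflict=conflict,
    )


def genotype_cohort(
    snvs_by_sample: Mapping[str, Sequence[SNVRecord]],
    hotspots: Sequence[HotspotDef] | None = None,
    overrides: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, DriverGenotype]:
    """Genotype every sample; ``overrides`` (orthogonal-assay results)
    take precedence over the WGS-derived call, field by field."""
    if hotspots is None:
        hotspots = load_hotspots()
    genotypes: dict[str, DriverGenotype] = {}
    for sample_id, snvs in snvs_by_sample.items():
        gt = genotype_sample(snvs, hotspots, sample_id=sample_id)
        if overrides and sample_id in overrides:
            ov = overrides[sample_id]
            gt = DriverGenotype(
                sample_id=sample_id,
                idh_group=ov.get("idh_group", gt.idh_group),
                idh_label=ov.get("idh_label", gt.idh_label),
                tert_status=ov.get("tert_status", gt.tert_status),
                tert_label=ov.get("tert_label", gt.tert_label),
                conflict=gt.conflict,
            )
        genotypes[sample_id] = gt
    return genotypes
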