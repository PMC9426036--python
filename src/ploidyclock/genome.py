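"""Bundled GRCh38 autosome coordinates.

All genome-fraction denominators in this package are computed over
autosomes 1-22 only; sex chromosomes are excluded throughout. Arm
boundaries are defined by approximate centromere midpoints: the p arm
spans ``1..cen_mid`` and the q arm ``cen_mid+1..length`` (1-based
inclusive coordinates).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


def normalise_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; '23' is left untouched (not an alias)."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@lru_cache(maxsize=1)
def _arm_table() -> dict[str, tuple[int, int]]:
    text = (
        resources.files("ploidyclock.data").joinpath("arms_grch38.tsv").read_text()
    )
    table: dict[str, tuple[int, int]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        table[row["chrom"]] = (int(row["length"]), int(row["cen_mid"]))
    return table


def chrom_lengths() -> dict[str, int]:
    """Chromosome name -> length (bp) for autosomes 1-22."""
    return {c: lc[0] for c, lc in _arm_table().items()}


@lru_cache(maxsize=1)
def total_autosome_length() -> int:
    return sum(lc[0] for lc in _arm_table().values())


@lru_cache(maxsize=1)
def arm_intervals() -> dict[str, tuple[str, int, int]]:
    """Arm name (e.g. '15q') -> (chrom, start, end), 1-based inclusive."""
    arms: dict[str, tuple[str, int, int]] = {}
    for chrom, (length, cen) in _arm_table().items():
        arms[f"{chrom}p"] = (chrom, 1, cen)
        arms[f"{chrom}q"] = (chrom, cen + 1, length)
    return arms


def arm_length(arm: str) -> int:
    chrom, start, end = arm_intervals()[arm]
    return end - start + 1
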