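"""Synthetic tumour-genome generator with known ground truth.

Generative model (per sample, autosomes 1-22, GRCh38 lengths):

1. The genome starts 1+1 everywhere. Mutational time is normalised to
   ``T = 1``.
2. Haploidisation (optional): at ``hp_time`` (default 0), whole
   chromosomes — chosen in seeded random order — are set to 1+0 until at
   least ``hp_fraction`` of the autosomal genome is LOH.
3. SNVs accrue on each allele copy as a Poisson process at rate
   ``mutation_rate`` per Mb per unit time.
4. Genome doubling (optional): at time ``gd_time`` every allele copy
   number doubles. SNVs acquired before doubling end up on two copies
   (multiplicity 2); later ones on one copy (multiplicity 1).
5. Arm-level events (optional, default off): at the end of mutational
   time each arm independently loses or gains one copy with the
   configured probability. SNVs falling in arm-altered segments are
   dropped from the output (their multiplicities are ambiguous); arm
   events are intended for copy-number statistics tests and are best
   combined with ``mutation_rate = 0``.
6. The observed VAF of a multiplicity-``m`` SNV in a segment of total
   copy ``n_t`` at purity ``rho`` is ``m*rho / (rho*n_t + 2*(1-rho))``;
   read depths are Poisson around ``depth`` and alt counts binomial. In
   ``infinite_depth`` mode, depth is fixed and alt = round(depth * f)
   (deterministic, for exact-inversion tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import genome
from .io_formats import (
    SampleMeta,
    Segment,
    SNVRecord,
    write_metadata,
    write_segments,
)

_BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated tumour (or one cohort group)."""

    purity: float = 1.0
    depth: float = 80.0
    mutation_rate: float = 0.05  # SNVs per Mb per allele copy per unit time
    gd_time: float | None = None  # in [0, 1]; None => no genome doubling
    hp_fraction: float = 0.0  # target LOH genome fraction, in [0, 1)
    hp_time: float = 0.0  # when haploidisation happens (before GD)
    arm_loss_probs: dict[str, float] = field(default_factory=dict)
    arm_gain_probs: dict[str, float] = field(default_factory=dict)
    infinite_depth: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise SimulationConfigError(f"purity {self.purity} not in (0, 1]")
        if not (0.0 <= self.hp_fraction < 1.0):
            raise SimulationConfigError(
                f"hp_fraction {self.hp_fraction} not in [0, 1)"
            )
        if self.gd_time is not None and not (0.0 <= self.gd_time <= 1.0):
            raise SimulationConfigError(f"gd_time {self.gd_time} not in [0, 1]")
        if self.hp_fraction > 0.0 and self.gd_time is None:
            raise SimulationConfigError(
                "hp_fraction > 0 requires gd_time (haploidisation is always"
                " followed by genome doubling in this model)"
            )
        if self.gd_time is not None and self.hp_time > self.gd_time:
            raise SimulationConfigError("hp_time must not exceed gd_time")
        if self.mutation_rate < 0 or self.depth <= 0:
            raise SimulationConfigError("mutation_rate >= 0 and depth > 0 required")


@dataclass
class TruthRecord:
    """Ground truth of one simulated tumour, for recovery tests."""

    sample_id: str
    gd: bool
    hp: bool
    gd_time: float | None
    loh_fraction: float
    ploidy: float
    snv_multiplicity: dict[tuple[str, int], int] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a label, sample count, and shared configuration."""

    label: str
    n: int
    config: SimulationConfig
    grade: str = "G2/3"
    idh_group: str = "unknown"
    tert_status: str = "unknown"


def _choose_hp_chromosomes(
    rng: np.random.Generator, hp_fraction: float
) -> set[str]:
    lengths = genome.chrom_lengths()
    total = genome.total_autosome_length()
    order = list(genome.AUTOSOMES)
    rng.shuffle(order)
    chosen: set[str] = set()
    loh = 0
    for chrom in order:
        if loh >= hp_fraction * total:
            break
        chosen.add(chrom)
        loh += lengths[chrom]
    return chosen


def _simulate_segment_snvs(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    chrom: str,
    start: int,
    end: int,
    pre_state: tuple[int, int],
    final_state: tuple[int, int],
) -> tuple[list[SNVRecord], dict[tuple[str, int], int]]:
    """Draw the SNVs of one segment; (counts are Poisson per copy class)."""
    length_mb = (end - start + 1) / 1e6
    mu = config.mutation_rate
    pre_copies = sum(pre_state)
    if config.gd_time is None:
        n_m2 = 0
        n_m1 = rng.poisson(mu * length_mb * pre_copies * 1.0)
    else:
        gd = config.gd_time
        n_m2 = rng.poisson(mu * length_mb * pre_copies * gd)
        n_m1 = rng.poisson(mu * length_mb * 2 * pre_copies * (1.0 - gd))
    n_t = sum(final_state)
    records: list[SNVRecord] = []
    truth: dict[tuple[str, int], int] = {}
    multiplicities = np.concatenate(
        [np.full(n_m2, 2, dtype=int), np.ones(n_m1, dtype=int)]
    )
    if len(multiplicities) == 0:
        return records, truth
    positions = rng.integers(start, end + 1, size=len(multiplicities))
    positions, keep = np.unique(positions, return_index=True)
    multiplicities = multiplicities[keep]
    rho = config.purity
    denom = rho * n_t + 2.0 * (1.0 - rho)
    for pos, m in zip(positions, multiplicities):
        f = m * rho / denom
        if config.infinite_depth:
            depth = int(round(config.depth))
            alt = int(round(depth * f))
        else:
            depth = int(rng.poisson(config.depth))
            if depth == 0:
                continue
            alt = int(rng.binomial(depth, min(f, 1.0)))
        ref_idx = rng.integers(0, 4)
        alt_idx = (ref_idx + rng.integers(1, 4)) % 4
        records.append(
            SNVRecord(
                sample_id=sample_id,
                chrom=chrom,
                pos=int(pos),
                ref=str(_BASES[ref_idx]),
                alt=str(_BASES[alt_idx]),
                alt_reads=alt,
                depth=depth,
            )
        )
        truth[(chrom, int(pos))] = int(m)
    return records, truth


def simulate_tumour(
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
) -> tuple[list[Segment], list[SNVRecord], TruthRecord]:
    """Simulate one tumour genome; returns (segments, snvs, truth)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = genome.chrom_lengths()
    arms = genome.arm_intervals()
    gd = config.gd_time is not None

    hp_chroms = (
        _choose_hp_chromosomes(rng, config.hp_fraction)
        if config.hp_fraction > 0
        else set()
    )

    # per-chromosome pre-GD and final (pre-arm-event) states
    pre_states: dict[str, tuple[int, int]] = {}
    final_states: dict[str, tuple[int, int]] = {}
    for chrom in genome.AUTOSOMES:
        pre = (1, 0) if chrom in hp_chroms else (1, 1)
        pre_states[chrom] = pre
        final_states[chrom] = (2 * pre[0], 2 * pre[1]) if gd else pre

    # arm events (applied at the end of mutational time)
    arm_states: dict[str, tuple[int, int] | None] = {}
    any_arm_events = False
    for arm, (chrom, _, _) in arms.items():
        state = final_states[chrom]
        p_loss = config.arm_loss_probs.get(arm, 0.0)
        p_gain = config.arm_gain_probs.get(arm, 0.0)
        u = rng.random() if (p_loss > 0 or p_gain > 0) else 1.0
        if u < p_loss:
            if state[1] > 0:
                state = (state[0], state[1] - 1)
            elif state[0] > 1:
                state = (state[0] - 1, state[1])
            arm_states[arm] = state
            any_arm_events = True
        elif u < p_loss + p_gain:
            arm_states[arm] = (state[0] + 1, state[1])
            any_arm_events = True
        else:
            arm_states[arm] = None

    segments: list[Segment] = []
    snvs: list[SNVRecord] = []
    truth_mult: dict[tuple[str, int], int] = {}
    for chrom in genome.AUTOSOMES:
        chrom_len = lengths[chrom]
        p_arm, q_arm = f"{chrom}p", f"{chrom}q"
        split = any_arm_events and (
            arm_states[p_arm] is not None or arm_states[q_arm] is not None
        )
        if split:
            cen = arms[p_arm][2]
            pieces = [(1, cen, arm_states[p_arm]), (cen + 1, chrom_len, arm_states[q_arm])]
        else:
            pieces = [(1, chrom_len, None)]
        for start, end, altered in pieces:
            state = altered if altered is not None else final_states[chrom]
            segments.append(
                Segment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_major=state[0],
                    n_minor=state[1],
                )
            )
            if config.mutation_rate > 0 and altered is None:
                recs, tr = _simulate_segment_snvs(
                    rng,
                    config,
                    sample_id,
                    chrom,
                    start,
                    end,
                    pre_states[chrom],
                    final_states[chrom],
                )
                snvs.extend(recs)
                truth_mult.update(tr)

    total = genome.total_autosome_length()
    loh_len = sum(s.length for s in segments if s.n_minor == 0)
    ploidy = sum(s.total_cn * s.length for s in segments) / total
    truth = TruthRecord(
        sample_id=sample_id,
        gd=gd,
        hp=config.hp_fraction > 0,
        gd_time=config.gd_time,
        loh_fraction=loh_len / total,
        ploidy=ploidy,
        snv_multiplicity=truth_mult,
    )
    return segments, snvs, truth


_VCF_HEADER_TOP = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_vcf(snvs: Sequence[SNVRecord], path: str | Path, sample_id: str) -> None:
    """Write one sample's SNVs as a minimal single-sample VCF 4.2."""
    lengths = genome.chrom_lengths()
    lines = [_VCF_HEADER_TOP]
    for chrom in genome.AUTOSOMES:
        lines.append(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
    )

    def sort_key(s: SNVRecord):
        return (genome.AUTOSOMES.index(s.chrom), s.pos)

    for snv in sorted(snvs, key=sort_key):
        ref_reads = snv.depth - snv.alt_reads
        lines.append(
            f"{snv.chrom}\t{snv.pos}\t.\t{snv.ref}\t{snv.alt}\t.\tPASS\t.\t"
            f"AD:DP\t{ref_reads},{snv.alt_reads}:{snv.depth}\n"
        )
    Path(path).write_text("".join(lines))


def simulate_cohort(
    groups: Sequence[GroupSpec],
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[dict[str, tuple[list[Segment], list[SNVRecord], SampleMeta]], list[TruthRecord]]:
    """Simulate a group-structured cohort; optionally write the io formats.

    With ``outdir`` set, writes ``segments.tsv``, ``metadata.csv``,
    ``truth.json`` and one VCF per sample under ``outdir/vcf/``. Outputs
    are deterministic (byte-identical) for a given (groups, seed).
    """
    if not groups:
        raise SimulationConfigError("at least one group is required")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise SimulationConfigError("duplicate group labels")

    samples: dict[str, tuple[list[Segment], list[SNVRecord], SampleMeta]] = {}
    truths: list[TruthRecord] = []
    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(sum(g.n for g in groups))
    i = 0
    for group in groups:
        if group.n == 0:
            warnings.warn(f"group {group.label!r} has n=0 and is omitted")
            continue
        for j in range(group.n):
            sample_id = f"{group.label}_{j:03d}"
            if sample_id in samples:
                raise SimulationConfigError(f"duplicate sample id {sample_id}")
            rng = np.random.default_rng(child_seeds[i])
            i += 1
            segments, snvs, truth = simulate_tumour(
                group.config, rng, sample_id=sample_id
            )
            meta = SampleMeta(
                sample_id=sample_id,
                grade=group.grade,
                idh_group=group.idh_group,
                tert_status=group.tert_status,
                purity=group.config.purity,
            )
            samples[sample_id] = (segments, snvs, meta)
            truths.append(truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "vcf").mkdir(exist_ok=True)
        all_segments = [s for segs, _, _ in samples.values() for s in segs]
        write_segments(all_segments, outdir / "segments.tsv")
        write_metadata([m for _, _, m in samples.values()], outdir / "metadata.csv")
        for sample_id, (_, snvs, _) in samples.items():
            write_vcf(snvs, outdir / "vcf" / f"{sample_id}.vcf", sample_id)
        _write_truth_json(truths, outdir / "truth.json")
    return samples, truths


def _write_truth_json(truths: Sequence[TruthRecord], path: Path) -> None:
    import json

    payload = [
        {
            "sample_id": t.sample_id,
            "gd": t.gd,
            "hp": t.hp,
            "gd_time": t.gd_time,
            "loh_fraction": t.loh_fraction,
            "ploidy": t.ploidy,
            "snv_multiplicity": {
                f"{chrom}:{pos}": m for (chrom, pos), m in t.snv_multiplicity.items()
            },
        }
        for t in truths
    ]
    path.write_text(json.dumps(payload, indent=1))
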