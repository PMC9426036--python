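from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ploidyclock import SimulationConfig, Segment, simulate_tumour


def make_segment(
    chrom="1",
    start=1,
    end=1_000_000,
    n_major=1,
    n_minor=1,
    sample_id="S1",
) -> Segment:
    return Segment(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        n_major=n_major,
        n_minor=n_minor,
    )


def uniform_genome(state: tuple[int, int], sample_id: str = "S1") -> list[Segment]:
    """A whole-autosome genome with one copy state everywhere."""
    from ploidyclock.genome import AUTOSOMES, chrom_lengths

    lengths = chrom_lengths()
    return [
        make_segment(
            chrom=c,
            start=1,
            end=lengths[c],
            n_major=state[0],
            n_minor=state[1],
            sample_id=sample_id,
        )
        for c in AUTOSOMES
    ]


@pytest.fixture
def diploid_tumour():
    cfg = SimulationConfig(purity=1.0, depth=60, mutation_rate=0.01)
    return simulate_tumour(cfg, seed=11, sample_id="DIP")


@pytest.fixture
def gd_tumour():
    cfg = SimulationConfig(purity=0.8, depth=80, mutation_rate=0.1, gd_time=0.5)
    return simulate_tumour(cfg, seed=17, sample_id="GD")


@pytest.fixture
def hp_gd_tumour():
    cfg = SimulationConfig(
        purity=0.8, depth=80, mutation_rate=0.05, gd_time=0.5, hp_fraction=0.6
    )
    return simulate_tumour(cfg, seed=23, sample_id="HPGD")
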