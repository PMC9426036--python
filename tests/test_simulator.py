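from __future__ import annotations

import numpy as np
import pytest

from oracles import lineage_multiplicity_counts
from ploidyclock import (
    GroupSpec,
    SimulationConfig,
    read_metadata,
    read_segments,
    read_snvs,
    simulate_cohort,
    simulate_tumour,
)
from ploidyclock.genome import AUTOSOMES, chrom_lengths, total_autosome_length
from ploidyclock.simulator import SimulationConfigError


class TestConfigValidation:
    def test_hp_requires_gd(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(hp_fraction=0.5)

    def test_hp_fraction_bounds(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(hp_fraction=1.0, gd_time=0.5)

    def test_gd_time_bounds(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(gd_time=1.5)

    def test_purity_bounds(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(purity=0.0)


class TestSimulateTumour:
    def test_null_model(self):
        cfg = SimulationConfig(purity=1.0, mutation_rate=0.02)
        segs, snvs, truth = simulate_tumour(cfg, seed=1)
        assert all(s.state == (1, 1) for s in segs)
        assert truth.ploidy == 2.0
        assert not truth.gd and not truth.hp
        assert all(m == 1 for m in truth.snv_multiplicity.values())

    def test_length_conservation(self, gd_tumour, hp_gd_tumour):
        for segs, _, _ in (gd_tumour, hp_gd_tumour):
            assert sum(s.length for s in segs) == total_autosome_length()

    def test_hp_gd_structure(self, hp_gd_tumour):
        segs, _, truth = hp_gd_tumour
        assert truth.loh_fraction >= 0.6
        assert {s.state for s in segs} == {(2, 0), (2, 2)}
        assert truth.ploidy < 4.0

    def test_multiplicity_fraction_closed_form(self):
        """At gd_time=0.5, one third of SNVs carry multiplicity 2."""
        cfg = SimulationConfig(purity=1.0, depth=100, mutation_rate=0.3, gd_time=0.5)
        _, _, truth = simulate_tumour(cfg, seed=8)
        mults = np.array(list(truth.snv_multiplicity.values()))
        frac_m2 = (mults == 2).mean()
        se = np.sqrt(frac_m2 * (1 - frac_m2) / len(mults))
        assert abs(frac_m2 - 1 / 3) <= max(3 * se, 0.02)

    def test_multiplicity_fraction_matches_lineage_oracle(self):
        """Generated multiplicity mix agrees with the event-list oracle."""
        rng = np.random.default_rng(12)
        n1, n2 = lineage_multiplicity_counts(rng, rate=50_000.0, gd_time=0.5)
        oracle_frac = n2 / (n1 + n2)
        assert abs(oracle_frac - 1 / 3) < 0.02

    def test_exact_vaf_inversion_noise_free(self):
        cfg = SimulationConfig(purity=1.0, depth=100, mutation_rate=0.05,
                               gd_time=0.3, infinite_depth=True)
        segs, snvs, truth = simulate_tumour(cfg, seed=4)
        seg_by_chrom = {s.chrom: s for s in segs}
        for rec in snvs:
            n_t = seg_by_chrom[rec.chrom].total_cn
            m = rec.vaf * n_t
            assert m == pytest.approx(round(m), abs=1e-6)
            assert round(m) == truth.snv_multiplicity[(rec.chrom, rec.pos)]

    def test_expected_snv_count(self):
        """Mean SNV count per segment matches mu * L_Mb * copy-time integral."""
        cfg = SimulationConfig(purity=1.0, depth=50, mutation_rate=0.02, gd_time=0.25)
        n_reps = 200
        counts = np.zeros(n_reps)
        for i in range(n_reps):
            _, snvs, _ = simulate_tumour(cfg, seed=1000 + i)
            counts[i] = sum(1 for s in snvs if s.chrom == "22")
        length_mb = chrom_lengths()["22"] / 1e6
        expected = 0.02 * length_mb * (2 * 0.25 + 4 * 0.75)
        se = np.sqrt(expected / n_reps)  # Poisson
        assert abs(counts.mean() - expected) <= 3 * se

    def test_seed_determinism_in_memory(self):
        cfg = SimulationConfig(purity=0.7, depth=60, mutation_rate=0.05, gd_time=0.4)
        out_a = simulate_tumour(cfg, seed=99)
        out_b = simulate_tumour(cfg, seed=99)
        assert out_a[0] == out_b[0]
        assert out_a[1] == out_b[1]
        assert out_a[2].snv_multiplicity == out_b[2].snv_multiplicity


class TestSimulateCohort:
    GROUPS = [
        GroupSpec("dip", 5, SimulationConfig(purity=0.9, depth=40, mutation_rate=0.01),
                  idh_group="IDH1"),
        GroupSpec("gd", 5, SimulationConfig(purity=0.9, depth=40, mutation_rate=0.01,
                                            gd_time=0.5), idh_group="IDHwt"),
    ]

    def test_truth_matches_group_spec(self):
        samples, truths = simulate_cohort(self.GROUPS, seed=7)
        assert len(samples) == 10
        for truth in truths:
            assert truth.gd == truth.sample_id.startswith("gd")

    def test_files_round_trip(self, tmp_path):
        simulate_cohort(self.GROUPS, seed=7, outdir=tmp_path)
        segs = read_segments(tmp_path / "segments.tsv")
        metas = read_metadata(tmp_path / "metadata.csv")
        snvs = read_snvs(tmp_path / "vcf")
        assert set(segs) == set(metas)
        assert len(segs) == 10
        assert metas["dip_000"].idh_group == "IDH1"
        assert {s.sample_id for s in snvs} <= set(metas)

    def test_byte_identical_given_seed(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(self.GROUPS, seed=7, outdir=a)
        simulate_cohort(self.GROUPS, seed=7, outdir=b)
        for rel in ["segments.tsv", "metadata.csv", "truth.json"] + [
            f"vcf/{p.name}" for p in sorted((a / "vcf").glob("*.vcf"))
        ]:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(self.GROUPS, seed=7, outdir=a)
        simulate_cohort(self.GROUPS, seed=8, outdir=b)
        assert (a / "segments.tsv").read_bytes() != (b / "segments.tsv").read_bytes() or (
            a / "vcf/dip_000.vcf"
        ).read_bytes() != (b / "vcf/dip_000.vcf").read_bytes()

    def test_empty_group_warned_and_omitted(self):
        groups = self.GROUPS + [GroupSpec("empty", 0, SimulationConfig())]
        with pytest.warns(UserWarning, match="empty"):
            samples, _ = simulate_cohort(groups, seed=1)
        assert len(samples) == 10

    def test_duplicate_group_labels_rejected(self):
        groups = [self.GROUPS[0], self.GROUPS[0]]
        with pytest.raises(SimulationConfigError):
            simulate_cohort(groups, seed=1)


class TestArmEvents:
    def test_arm_loss_applied(self):
        cfg = SimulationConfig(purity=1.0, mutation_rate=0.0,
                               arm_loss_probs={"15q": 1.0})
        segs, _, _ = simulate_tumour(cfg, seed=2)
        chr15 = [s for s in segs if s.chrom == "15"]
        assert len(chr15) == 2
        assert chr15[1].state == (1, 0)
        assert chr15[0].state == (1, 1)
        assert sum(s.length for s in segs) == total_autosome_length()

    def test_arm_gain_on_gd_background(self):
        cfg = SimulationConfig(purity=1.0, mutation_rate=0.0, gd_time=0.5,
                               arm_gain_probs={"19p": 1.0})
        segs, _, _ = simulate_tumour(cfg, seed=2)
        chr19 = {("p" if s.start == 1 else "q"): s for s in segs if s.chrom == "19"}
        assert chr19["p"].state == (3, 2)
        assert chr19["q"].state == (2, 2)
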