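# ploidyclock

A toolkit for analysing tumour genome evolution from allele-specific
copy-number segments and somatic SNV calls:

- **Copy-state classification** — segments are classed as `diploid` (1+1),
  `gain` (2+1, 2+2), `cnLOH` (2+0), or `other`; per-sample LOH fraction and
  length-weighted ploidy; amplification rule (total copy ≥ 5, or ≥ 9 in
  genome-doubled samples).
- **Genome-doubling (GD) calling** — a seeded 1-D Gaussian-mixture EM with
  BIC model selection over the per-sample *major-allele* ploidy (robust to
  haploidisation), with a threshold fallback for cohorts under 10 samples.
- **Partial-haploidisation (HP) calling** — LOH fraction strictly > 50%.
- **Molecular-clock timing of GD** — SNV multiplicities are inverted from
  VAF, purity, and segment copy number; the fraction of mutational time
  before doubling is estimated per timing-informative segment
  (π = 2·n₂/(2·n₂+n₁) in 2+2/2+0, 3·n₂/(2·n₂+n₁) in 2+1) and pooled with
  a seeded bootstrap interval.
- **Hotspot genotyping** — IDH1 R132 / IDH2 R172 / TERT promoter status by
  exact coordinate matching against a bundled (GRCh38) or user hotspot table.
- **Cohort statistics** — exact Fisher tests (2×2 integer-exact
  enumeration, full r×c enumeration for totals ≤ 200, seeded Monte Carlo
  beyond), rank-sum tests (exact for combined n ≤ 20 without ties),
  arm-level gain/loss calling with Bonferroni-corrected frequency
  comparisons, and the per-chromosome high-breakage statistic.
- **Simulator** — synthetic tumours with known haploidisation/doubling
  history, clock-like SNV accrual, purity dilution, and binomial read
  noise, emitting the same segment-TSV/VCF/metadata-CSV formats the
  pipeline reads, plus a full ground-truth record for recovery tests.

All coordinates are 1-based inclusive; genome fractions are computed over
autosomes 1–22 only.

## CLI

```sh
ploidyclock simulate --config config.yaml --seed 1 --outdir sim/
ploidyclock classify --segments sim/segments.tsv --out states.tsv
ploidyclock call-gd --segments sim/segments.tsv --out gd.tsv
ploidyclock time-gd --segments sim/segments.tsv --vcf sim/vcf --meta sim/metadata.csv --out timing.tsv
ploidyclock hotspots --vcf sim/vcf --out hotspots.csv
ploidyclock cohort-stats --cohort sim/metadata.csv --segments sim/segments.tsv --out stats/
```

A simulation config lists cohort groups:

```yaml
groups:
  - {label: dip, n: 25, purity: 0.8, depth: 80, mutation_rate: 0.01}
  - {label: gd,  n: 15, purity: 0.8, depth: 80, mutation_rate: 0.01, gd_time: 0.5}
  - {label: hpgd, n: 10, purity: 0.8, depth: 80, mutation_rate: 0.01,
     gd_time: 0.5, hp_fraction: 0.6, idh_group: IDHwt}
```

## File formats

- **Segments**: TSV with columns `sample_id, chrom, startpos, endpos,
  nMajor, nMinor` (Battenberg-style aliases accepted; `chr` prefixes
  stripped).
- **SNVs**: VCF 4.2 with per-sample `AD`/`DP` FORMAT fields; a directory
  of per-sample `*.vcf` files is also accepted. Indels and multiallelic
  records are skipped.
- **Metadata**: CSV with `sample_id, grade, idh_group, tert_status,
  purity` and optional `age, size, outcome`.

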