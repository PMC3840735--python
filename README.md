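# snpdemog

Conservation-genomics analyses of diploid biallelic SNP panels, built for
small, often endangered, populations genotyped on medium-density arrays
(tens of samples, tens of thousands of markers): local livestock breeds,
wild relatives, zoo or rescue populations. From one genotype panel with
population labels it derives population structure, inbreeding and
demographic history:

- **Quality control** — PLINK text/binary input, sex-chromosome removal,
  per-locus missingness filter, and per-population MAF and exact
  Hardy-Weinberg filters ahead of LD analysis.
- **Differentiation** — Weir & Cockerham's θ (Fst), Nei's (1972) standard
  genetic distance, and individual allele-sharing distances (ASD) with a
  PHYLIP writer for external tree building.
- **Linkage disequilibrium** — two-locus haplotype frequencies by
  maximum-likelihood EM from unphased genotypes; signed r and r² for all
  pairs within 3 Mbp; per-chromosome summaries and decay profiles.
- **Persistence of phase** — Pearson correlation of signed r between
  populations in 100-kbp distance bins; high correlation at long range
  indicates recent common ancestry.
- **Effective population size** — from the drift-recombination balance
  `r² = 1/(4·Ne·c + 1)`, inverted per 1-Mb genome bin with the bin's
  recombination distance `c` from a cM/Mb map, so `Ne = (1/4c)(1/r² − 1)`;
  each bin also dates its estimate at `T = 1/(2c)` generations ago, turning
  the binned genome into an Ne trajectory through time.
- **Runs of homozygosity** — per-individual maximal homozygous runs
  (≥10 kbp, ≥20 homozygous SNPs, ≤1 heterozygote inside, ≤1 Mb gaps,
  ≥1 SNP/Mb), length classes, and genome-fraction inbreeding summaries.
- **Synthetic data** — a forward Wright-Fisher simulator (diploid, Poisson
  recombination, epochs, splits, admixture pulses, planted autozygous
  tracts) so every stage is testable against a known truth.

## Worked example

```python
from snpdemog import (DemographyConfig, simulate_wright_fisher, apply_ld_qc,
                      pairwise_ld, chromosome_ld_summary, bin_genome, current_ne,
                      detect_roh_all, summarize_roh)

cfg = DemographyConfig(
    epochs=[(300, 100)], n_chromosomes=5, chromosome_length_bp=5_000_000,
    recombination_cm_per_mb=1.0, n_snps=2_500, sample_size=25, seed=7,
)
panel, rmap, truth = simulate_wright_fisher(cfg)
qc = apply_ld_qc(panel, "P1", maf_min=0.05, hwe_p_min=0.001)
ld = pairwise_ld(qc, max_distance_bp=3_000_000)
print(chromosome_ld_summary(ld).round(3).to_string(index=False))
est = current_ne(bin_genome(ld, rmap), sample_size=25)
print(f"current Ne = {est.mean_ne:.0f} +/- {est.sd_ne:.0f} over {est.n_bins} bins")
summary = summarize_roh(detect_roh_all(panel), panel)
pop = summary.per_population.iloc[0]
print(f"ROH: mean {pop['mean_n_roh']:.1f} runs/individual, "
      f"{100*pop['mean_fraction_genome']:.1f}% of the genome")
```

prints

```
chromosome  mean_r2  sd_r2  n_pairs
         1    0.500  0.338      861
         2    0.293  0.334     7957
         3    0.421  0.390     2396
         4    0.296  0.334     9759
         5    0.722  0.269      202
     Total    0.321  0.347    21175
current Ne = 55 +/- 57 over 20 bins
ROH: mean 4.6 runs/individual, 40.7% of the genome
```

The simulated population had a true size of 100 diploids: mean r² of ~0.32
within 3 Mbp is the LD a population that small maintains; inverting it bin
by bin recovers Ne to the right order (the across-bin SD is honest about how
noisy per-bin inversion is at 25 samples — apply the `correct_sample_size`
option to remove the sampling contribution to r²), and ~40% of the genome in
homozygous runs is the expected autozygosity after 300 generations at that
size.

## Command line

```bash
snpdemog simulate --out fixtures --seed 7      # synthetic PLINK fixture suite
snpdemog run --config run.yaml                 # qc -> dist -> ld -> phase -> ne -> roh -> report
snpdemog ld --config run.yaml                  # any single stage, resumable
```

`run.yaml` names the genotype input (`ped`/`map` or `bed`/`bim`/`fam`), a
recombination-map TSV (`chromosome start end cM/Mb`), an output directory
and optional parameter overrides (`plots: true` additionally writes LD-decay,
phase-persistence and Ne-trajectory figures); every stage writes plain TSVs
plus a checksummed `run_report.json`, and reruns are byte-identical.

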