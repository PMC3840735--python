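"""Parameter-recovery validation scenarios on synthetic data.

Each function runs one self-contained experiment end to end — simulate a
panel with known demography, push it through the analysis stages, and
measure how well the known quantity is recovered.  They exist so the
package's statistical behaviour can be audited reproducibly (the test suite
and the reproduction script both call them); every scenario takes a single
seed and is deterministic given it.

Scenario design notes
---------------------
* Constant-size recovery uses a 300-generation burn-in at N = 100: the
  slowest within-bin LD timescale here is ~1/(2c + 1/(2N)) ≈ 110
  generations, so 300 generations gives near-equilibrium LD while leaving
  enough founder variants segregating.  Founder site counts are chosen so
  roughly 2,000 SNPs survive drift to the analysis stage.
* The bottleneck scenario spreads per-chromosome recombination rates over
  0.05-3 cM/Mb so the 1-Mb bins probe time horizons T = 1/(2c) from a few
  tens to several thousand generations, straddling the bottleneck age.
* ROH recovery plants autozygous tracts into a fully heterozygous
  background, the designed worst case for boundary precision: every SNP
  outside a tract is a heterozygote, so any boundary overshoot is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from snpdemog.genotype_io import GenotypePanel, apply_ld_qc
from snpdemog.ld_analysis import pairwise_ld
from snpdemog.ne_estimation import bin_genome, current_ne, past_ne_trajectory
from snpdemog.phase_persistence import phase_correlation, signed_r_catalog
from snpdemog.popgen_stats import pairwise_fst
from snpdemog.roh_analysis import ROHParams, detect_roh, detect_roh_all
from snpdemog.synthetic_data import (
    DemographyConfig,
    plant_autozygous_segments,
    simulate_wright_fisher,
)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Ne recovery at constant size
# ---------------------------------------------------------------------------

def constant_size_config(seed: int) -> DemographyConfig:
    """N = 100 diploids, 20 chromosomes x 5 Mb at 1 cM/Mb, 25 sampled."""
    return DemographyConfig(
        epochs=[(300, 100)],
        n_chromosomes=20,
        chromosome_length_bp=5_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=11_000,
        sample_size=25,
        seed=seed,
    )


def ne_recovery_trial(seed: int) -> dict:
    """Estimate current Ne from one constant-size simulation.

    Uses the standard sample-size correction of r² (subtract 1/(2n)): with
    25 diploids the sampling contribution to observed r² is material, and a
    recovery experiment against a known truth should remove it.  Returns the
    across-bin Ne estimate plus the Spearman rank correlation of the (T, Ne)
    trajectory points, which should show no trend when the true size never
    changed.
    """
    panel, rmap, _ = simulate_wright_fisher(constant_size_config(seed))
    qc = apply_ld_qc(panel, "P1")
    ld = pairwise_ld(qc)
    bins = bin_genome(ld, rmap)
    est = current_ne(bins, sample_size=qc.n_samples, correct_sample_size=True)
    traj = past_ne_trajectory(bins)
    finite = traj[np.isfinite(traj["ne"])]
    rho, pval = stats.spearmanr(finite["T_generations"], finite["ne"])
    return {
        "mean_ne": est.mean_ne,
        "sd_ne": est.sd_ne,
        "n_bins": est.n_bins,
        "n_snps": panel.n_loci,
        "trend_spearman": float(rho),
        "trend_p": float(pval),
    }


# ---------------------------------------------------------------------------
# bottleneck direction
# ---------------------------------------------------------------------------

def bottleneck_config(seed: int) -> DemographyConfig:
    """N = 1000, then a drastic drop to N = 50 for the last 100 generations.

    Six high-recombination chromosomes (2.8 cM/Mb) populate the recent time
    horizons (T below the bottleneck age) and eighteen low-recombination
    chromosomes (0.2 cM/Mb) the ancestral window around T of 500-1000
    generations.  Every surviving diploid is sampled: after a bottleneck
    this severe, deep-time LD survives only in some pedigree realizations,
    so the scenario needs all the information it can get.
    """
    return DemographyConfig(
        epochs=[(150, 1000), (100, 50)],
        n_chromosomes=24,
        chromosome_length_bp=5_000_000,
        recombination_cm_per_mb=np.concatenate([np.full(6, 2.8), np.full(18, 0.2)]),
        n_snps=7_200,
        sample_size=50,
        seed=seed,
    )


def bottleneck_trial(seed: int) -> dict:
    """Recover the direction of a recent bottleneck from the Ne trajectory.

    Compares the median trajectory Ne at horizons younger than the
    bottleneck (T < 100) with the median in the ancestral window
    (T in [500, 5000]).  LD QC uses a 0.01 MAF floor: with all 50 survivors
    genotyped, rarer alleles are still well measured, and they carry the
    haplotype contrasts that distinguish surviving bottleneck lineages.
    """
    panel, rmap, _ = simulate_wright_fisher(bottleneck_config(seed))
    qc = apply_ld_qc(panel, "P1", maf_min=0.01)
    ld = pairwise_ld(qc)
    bins = bin_genome(ld, rmap)
    traj = past_ne_trajectory(bins)
    traj = traj[np.isfinite(traj["ne"])]
    recent = traj[traj["T_generations"] < 100]["ne"]
    ancient = traj[traj["T_generations"].between(500, 5000)]["ne"]
    return {
        "median_ne_recent": float(recent.median()) if len(recent) else float("nan"),
        "median_ne_ancient": float(ancient.median()) if len(ancient) else float("nan"),
        "n_recent_bins": int(len(recent)),
        "n_ancient_bins": int(len(ancient)),
        "n_snps": panel.n_loci,
    }


# ---------------------------------------------------------------------------
# ROH planted-segment recovery
# ---------------------------------------------------------------------------

def _het_background_panel(
    rng: np.random.Generator, n_samples: int, n_chrom: int, snps_per_chrom: int,
    chrom_length: int,
) -> GenotypePanel:
    positions, chroms = [], []
    for c in range(n_chrom):
        positions.append(
            np.sort(rng.choice(chrom_length, snps_per_chrom, replace=False)) + 1
        )
        chroms.append(np.full(snps_per_chrom, c + 1))
    loci = pd.DataFrame(
        {
            "locus_id": [f"m{c}_{j}" for c in range(n_chrom) for j in range(snps_per_chrom)],
            "chromosome": np.concatenate(chroms),
            "position_bp": np.concatenate(positions),
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"H{i + 1:03d}" for i in range(n_samples)],
            "population": "BG",
        }
    )
    genotypes = np.ones((n_samples, n_chrom * snps_per_chrom), dtype=np.int8)
    return GenotypePanel(loci=loci, samples=samples, genotypes=genotypes)


def roh_recovery_trial(
    seed: int, n_plantings: int = 100, het_error_rate: float = 0.01
) -> dict:
    """Plant autozygous tracts in heterozygous individuals and recover them.

    Tracts are >= 1 Mb with >= 30 SNPs.  For tracts that received at most
    one heterozygote error, recovery demands exactly one detected run whose
    boundaries sit within one inter-SNP interval of the tract ends.  Also
    checks the two degenerate cases: a fully heterozygous individual carries
    no run, a fully homozygous one carries one maximal run per chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    n_chrom, chrom_length, snps_per_chrom = 5, 5_000_000, 200
    per_sample_chrom = 2  # tract slots per sample x chromosome
    n_samples = int(np.ceil(n_plantings / (n_chrom * per_sample_chrom)))
    panel = _het_background_panel(rng, n_samples + 2, n_chrom, snps_per_chrom, chrom_length)
    chroms = panel.loci["chromosome"].to_numpy()
    positions = panel.loci["position_bp"].to_numpy()

    requests = []
    slots = [(0, 2_200_000), (2_600_000, 4_900_000)]
    k = 0
    for sid in panel.samples["sample_id"][:n_samples]:
        for chrom in range(1, n_chrom + 1):
            for lo, hi in slots:
                if k >= n_plantings:
                    break
                for _ in range(100):  # rejection-sample a tract with >= 30 SNPs
                    length = int(rng.uniform(1_000_000, 2_000_000))
                    start = int(rng.uniform(lo, hi - length))
                    end = start + length
                    inside = (chroms == chrom) & (positions >= start) & (positions <= end)
                    if inside.sum() >= 30:
                        requests.append((sid, chrom, start, end))
                        k += 1
                        break
    planted, truth = plant_autozygous_segments(
        panel, requests, het_error_rate=het_error_rate, seed=_sub_seed(seed, 7)
    )
    rohs = detect_roh_all(planted)

    n_eligible = n_recovered = n_boundary_ok = 0
    for seg in truth.planted_segments:
        if seg["n_het_errors"] > 1:
            continue
        n_eligible += 1
        sub = rohs[
            (rohs["sample_id"] == seg["sample_id"])
            & (rohs["chromosome"] == seg["chromosome"])
            & (rohs["end_bp"] >= seg["start_bp"])
            & (rohs["start_bp"] <= seg["end_bp"])
        ]
        if len(sub) != 1:
            continue
        n_recovered += 1
        run = sub.iloc[0]
        inside = (chroms == seg["chromosome"]) & (
            (positions >= seg["start_bp"]) & (positions <= seg["end_bp"])
        )
        seg_pos = positions[inside]
        start_ok = seg_pos[0] <= run["start_bp"] <= seg_pos[1]
        end_ok = seg_pos[-2] <= run["end_bp"] <= seg_pos[-1]
        if start_ok and end_ok:
            n_boundary_ok += 1

    het_sample = panel.samples["sample_id"].iloc[n_samples]  # untouched, all het
    hom_sid = panel.samples["sample_id"].iloc[n_samples + 1]
    hom_panel = planted.restrict_samples(np.ones(planted.n_samples, dtype=bool))
    hom_row = planted.samples.index[planted.samples["sample_id"] == hom_sid][0]
    hom_panel.genotypes[hom_row] = 2
    hom_runs = detect_roh(hom_panel, hom_sid)
    return {
        "n_planted": len(requests),
        "n_eligible": n_eligible,
        "recall": n_recovered / n_eligible,
        "boundary_within_one_interval": n_boundary_ok / n_eligible,
        "het_individual_n_roh": len(detect_roh(planted, het_sample)),
        "hom_individual_runs_per_chromosome": len(hom_runs) / n_chrom,
    }


# ---------------------------------------------------------------------------
# differentiation and phase persistence on a split-half null and a split
# ---------------------------------------------------------------------------

def split_half_config(seed: int) -> DemographyConfig:
    return DemographyConfig(
        epochs=[(400, 120)],
        n_chromosomes=10,
        chromosome_length_bp=3_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=2_400,
        sample_size=100,
        base_population="HALF",
        seed=seed,
    )


def split_half_panel(seed: int) -> GenotypePanel:
    """One panmictic sample of 100 relabelled as two 50-sample halves."""
    panel, _, _ = simulate_wright_fisher(split_half_config(seed))
    pops = ["HALF1"] * 50 + ["HALF2"] * (panel.n_samples - 50)
    return GenotypePanel(
        loci=panel.loci,
        samples=panel.samples.assign(population=pops),
        genotypes=panel.genotypes,
    )


def diverged_config(seed: int) -> DemographyConfig:
    return DemographyConfig(
        epochs=[(300, 150)],
        n_chromosomes=10,
        chromosome_length_bp=3_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=2_400,
        sample_size=30,
        split_events=[(180, "DIV2", 150)],
        base_population="DIV1",
        seed=seed,
    )


def phase_trial(seed: int, bin_width_bp: int = 100_000, max_distance_bp: int = 3_000_000) -> dict:
    """Phase persistence for split halves of one population versus two
    populations diverged 180 generations."""
    half = split_half_panel(seed)
    half_cats = {
        p: signed_r_catalog(apply_ld_qc(half, p), max_distance_bp=max_distance_bp)
        for p in ("HALF1", "HALF2")
    }
    same = phase_correlation(
        half_cats["HALF1"], half_cats["HALF2"],
        bin_width_bp=bin_width_bp, max_distance_bp=max_distance_bp,
    ).bins
    div_panel, _, _ = simulate_wright_fisher(diverged_config(_sub_seed(seed, 11)))
    div_cats = {
        p: signed_r_catalog(apply_ld_qc(div_panel, p), max_distance_bp=max_distance_bp)
        for p in ("DIV1", "DIV2")
    }
    div = phase_correlation(
        div_cats["DIV1"], div_cats["DIV2"],
        bin_width_bp=bin_width_bp, max_distance_bp=max_distance_bp,
    ).bins
    short_same = same[same["bin_end_bp"] <= 500_000]["pearson_r"].dropna()
    short_div = div[div["bin_end_bp"] <= 500_000]["pearson_r"].dropna()
    div_defined = div.dropna(subset=["pearson_r"])
    rho, _ = stats.spearmanr(div_defined["bin_start_bp"], div_defined["pearson_r"])
    return {
        "split_half_min_short_corr": float(short_same.min()),
        "split_half_n_short_bins": int(len(short_same)),
        "diverged_mean_short_corr": float(short_div.mean()),
        "diverged_distance_spearman": float(rho),
        "fst_split_half": pairwise_fst(half, "HALF1", "HALF2"),
    }


# ---------------------------------------------------------------------------
# chromosome-level correlation signs under two recombination regimes
# ---------------------------------------------------------------------------

def two_regime_config(seed: int) -> DemographyConfig:
    rates = [0.3] * 9 + [1.2] * 9
    return DemographyConfig(
        epochs=[(150, 100)],
        n_chromosomes=18,
        chromosome_length_bp=5_000_000,
        recombination_cm_per_mb=rates,
        n_snps=9_000,
        sample_size=25,
        seed=seed,
    )


def two_regime_trial(seed: int) -> dict:
    """Signs of the chromosome-level correlations between mean r², mean ROH
    length and recombination rate under a low/high recombination contrast."""
    from snpdemog.ld_analysis import chromosome_ld_summary
    from snpdemog.roh_analysis import chromosome_correlation_matrix

    panel, rmap, _ = simulate_wright_fisher(two_regime_config(seed))
    qc = apply_ld_qc(panel, "P1")
    ld = pairwise_ld(qc)
    summary = chromosome_ld_summary(ld)
    rohs = detect_roh_all(panel, ROHParams())
    rho, pval = chromosome_correlation_matrix(summary, rohs, rmap)
    return {
        "rho_ld_vs_roh_length": float(rho.loc["mean_r2", "mean_roh_length_bp"]),
        "rho_roh_length_vs_rate": float(
            rho.loc["mean_roh_length_bp", "rate_cm_per_mb"]
        ),
        "n_roh": int(len(rohs)),
    }
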