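"""Runs of homozygosity (ROH) and inbreeding summaries.

A run is a maximal stretch of consecutive SNPs in one individual that starts
and ends at a homozygous call, contains at most ``max_het`` heterozygous and
``max_missing`` missing calls strictly inside, and never spans an inter-SNP
gap larger than ``max_gap_bp``.  A run is emitted only if it additionally
meets the minimum physical length, minimum homozygous-SNP count and minimum
SNP density.  Runs are found by a direct scan that enumerates every maximal
window satisfying the budgets and then keeps a non-overlapping subset —
declarative and reproducible, rather than a sliding-window heuristic.

Long runs indicate recent inbreeding (few ancestral recombination events
have broken the autozygous haplotype); many short runs indicate historically
small population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import MISSING, GenotypePanel, RecombinationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """ROH calling parameters.

    Defaults: minimum 10 kbp and 20 homozygous SNPs per run, one
    heterozygote permitted inside a run, at most 2 missing calls inside,
    minimum density 1 SNP/Mb, largest permitted inter-SNP gap 1 Mb.  Runs
    longer than 100 Mbp are classed as long ROH; the 50-100 Mbp interval is
    the mid class.
    """

    min_length_bp: int = 10_000
    min_snps: int = 20
    max_het: int = 1
    max_missing: int = 2
    min_density_snp_per_mb: float = 1.0
    max_gap_bp: int = 1_000_000
    long_roh_threshold_bp: int = 100_000_000
    mid_class_bp: tuple[int, int] = (50_000_000, 100_000_000)

    def __post_init__(self) -> None:
        if min(
            self.min_length_bp,
            self.min_snps,
            self.max_gap_bp,
            self.long_roh_threshold_bp,
        ) <= 0 or self.min_density_snp_per_mb <= 0:
            raise UserInputError("ROH parameters must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise UserInputError("het/missing allowances must be non-negative")
        if self.mid_class_bp[1] != self.long_roh_threshold_bp:
            raise UserInputError(
                "mid ROH class must end at the long-ROH threshold"
            )


@dataclass(frozen=True)
class ROHRecord:
    """One homozygous run in one individual."""

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


ROH_COLUMNS = [
    "sample_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "length_bp",
    "n_snps",
    "n_het",
    "n_missing",
]


def _maximal_windows(
    geno: np.ndarray, max_het: int, max_missing: int
) -> list[tuple[int, int]]:
    """All maximal index windows with <= max_het hets and <= max_missing
    missing calls, trimmed so both ends are homozygous calls."""
    n = len(geno)
    is_het = geno == 1
    is_miss = geno == MISSING
    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    miss_cum = np.concatenate([[0], np.cumsum(is_miss)])

    def ok(l: int, r: int) -> bool:  # inclusive indices
        return (
            het_cum[r + 1] - het_cum[l] <= max_het
            and miss_cum[r + 1] - miss_cum[l] <= max_missing
        )

    windows = []
    l = 0
    prev_l = -1
    for r in range(n):
        while not ok(l, r):
            l += 1
        # [l, r] is the left-maximal window ending at r; it is right-maximal
        # iff extending to r+1 forces l to move
        if r == n - 1 or not ok(l, r + 1):
            if l != prev_l:
                windows.append((l, r))
                prev_l = l
    trimmed = []
    hom = ~(is_het | is_miss)
    for l, r in windows:
        while l <= r and not hom[l]:
            l += 1
        while r >= l and not hom[r]:
            r -= 1
        if l <= r:
            trimmed.append((l, r))
    return sorted(set(trimmed))


def detect_roh(
    panel: GenotypePanel, sample_id: str, params: ROHParams = ROHParams()
) -> list[ROHRecord]:
    """Detect ROH in one individual.

    The chromosome is first split wherever consecutive SNPs are more than
    ``max_gap_bp`` apart (runs never span such gaps); within each segment all
    maximal windows satisfying the het/missing budgets are enumerated,
    trimmed to homozygous ends, filtered by the length, SNP-count and
    density rules, and a non-overlapping subset is kept greedily from the
    left (longer window first on ties).
    """
    matches = panel.samples.index[panel.samples["sample_id"] == sample_id]
    if len(matches) == 0:
        raise UserInputError(f"sample {sample_id!r} not in panel")
    row = int(matches[0])
    geno = panel.genotypes[row]
    chroms = panel.loci["chromosome"].to_numpy()
    positions = panel.loci["position_bp"].to_numpy()

    records: list[ROHRecord] = []
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        g = geno[sel]
        # split at gaps larger than max_gap_bp
        gap_breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
        segments = np.split(np.arange(len(sel)), gap_breaks)
        candidates: list[tuple[int, int]] = []
        for seg in segments:
            if len(seg) == 0:
                continue
            offset = seg[0]
            for l, r in _maximal_windows(
                g[seg], params.max_het, params.max_missing
            ):
                candidates.append((offset + l, offset + r))
        qualified = []
        for l, r in candidates:
            n_total = r - l + 1
            n_het = int((g[l : r + 1] == 1).sum())
            n_miss = int((g[l : r + 1] == MISSING).sum())
            n_hom = n_total - n_het - n_miss
            length = int(pos[r] - pos[l] + 1)
            if n_hom < params.min_snps:
                continue
            if length < params.min_length_bp:
                continue
            if n_total / (length / 1e6) < params.min_density_snp_per_mb:
                continue
            qualified.append((l, r, n_total, n_het, n_miss, length))
        # greedy non-overlapping selection, leftmost first, longer on ties
        qualified.sort(key=lambda w: (w[0], -(w[1] - w[0])))
        last_end = -1
        for l, r, n_total, n_het, n_miss, length in qualified:
            if l <= last_end:
                continue
            records.append(
                ROHRecord(
                    sample_id=sample_id,
                    chromosome=int(chrom),
                    start_bp=int(pos[l]),
                    end_bp=int(pos[r]),
                    n_snps=n_total,
                    n_het=n_het,
                    n_missing=n_miss,
                )
            )
            last_end = r
    return records


def detect_roh_all(
    panel: GenotypePanel, params: ROHParams = ROHParams()
) -> pd.DataFrame:
    """ROH table for every sample in the panel."""
    rows = []
    for sid in panel.samples["sample_id"]:
        for rec in detect_roh(panel, sid, params):
            rows.append(
                (
                    rec.sample_id,
                    rec.chromosome,
                    rec.start_bp,
                    rec.end_bp,
                    rec.length_bp,
                    rec.n_snps,
                    rec.n_het,
                    rec.n_missing,
                )
            )
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


@dataclass
class ROHSummary:
    """Per-sample and per-population ROH aggregates.

    ``per_sample`` columns: ``sample_id, population, n_roh, total_length_bp,
    mean_length_bp, fraction_genome``.  ``per_population`` carries the means
    of those plus the proportions of individuals with at least one long
    (> 100 Mbp) or mid-class (50-100 Mbp) run.
    """

    per_sample: pd.DataFrame
    per_population: pd.DataFrame
    covered_genome_bp: int


def summarize_roh(
    rohs: pd.DataFrame, panel: GenotypePanel, params: ROHParams = ROHParams()
) -> ROHSummary:
    """Individual and population inbreeding summaries from a ROH table.

    ``fraction_genome`` uses the SNP-covered genome length (sum over
    autosomes of last minus first SNP position + 1) as denominator: the panel
    defines what is observable.
    """
    span = 0
    for _, grp in panel.loci.groupby("chromosome"):
        span += int(grp["position_bp"].max() - grp["position_bp"].min() + 1)
    if span <= 0:
        raise UserInputError("panel covers no genome span")

    lo_mid, hi_mid = params.mid_class_bp
    sample_rows = []
    for srow in panel.samples.itertuples(index=False):
        sub = rohs[rohs["sample_id"] == srow.sample_id] if len(rohs) else rohs
        n = len(sub)
        total = int(sub["length_bp"].sum()) if n else 0
        mean_len = float(sub["length_bp"].mean()) if n else 0.0
        has_long = bool((sub["length_bp"] > params.long_roh_threshold_bp).any()) if n else False
        has_mid = (
            bool(
                (
                    (sub["length_bp"] > lo_mid) & (sub["length_bp"] <= hi_mid)
                ).any()
            )
            if n
            else False
        )
        sample_rows.append(
            (
                srow.sample_id,
                srow.population,
                n,
                total,
                mean_len,
                total / span,
                has_long,
                has_mid,
            )
        )
    per_sample = pd.DataFrame(
        sample_rows,
        columns=[
            "sample_id",
            "population",
            "n_roh",
            "total_length_bp",
            "mean_length_bp",
            "fraction_genome",
            "has_long_roh",
            "has_mid_roh",
        ],
    )
    per_population = (
        per_sample.groupby("population")
        .agg(
            n_samples=("sample_id", "size"),
            mean_n_roh=("n_roh", "mean"),
            mean_total_length_bp=("total_length_bp", "mean"),
            mean_length_bp=("mean_length_bp", "mean"),
            mean_fraction_genome=("fraction_genome", "mean"),
            prop_long_roh=("has_long_roh", "mean"),
            prop_mid_roh=("has_mid_roh", "mean"),
        )
        .reset_index()
    )
    return ROHSummary(
        per_sample=per_sample.drop(columns=["has_long_roh", "has_mid_roh"]),
        per_population=per_population,
        covered_genome_bp=span,
    )


def chromosome_correlation_matrix(
    ld_summary: pd.DataFrame, rohs: pd.DataFrame, rmap: RecombinationMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of per-chromosome LD, ROH length and
    recombination rate.

    One point per chromosome: mean r² (from a chromosome LD summary), mean
    ROH length pooled over individuals, and length-weighted mean map rate.
    Returns ``(rho, p_values)`` as 3x3 DataFrames; requires at least 3
    chromosomes carrying all three quantities.
    """
    ld_rows = ld_summary[ld_summary["chromosome"] != "Total"]
    ld_by_chrom = {
        int(r.chromosome): float(r.mean_r2) for r in ld_rows.itertuples(index=False)
    }
    roh_by_chrom = (
        rohs.groupby("chromosome")["length_bp"].mean().to_dict() if len(rohs) else {}
    )
    points = []
    for chrom in sorted(ld_by_chrom):
        rate = rmap.mean_rate(chrom)
        if chrom in roh_by_chrom and not np.isnan(rate):
            points.append(
                (chrom, ld_by_chrom[chrom], float(roh_by_chrom[chrom]), rate)
            )
    if len(points) < 3:
        raise UserInputError(
            "need >= 3 chromosomes with LD, ROH and map data for correlations"
        )
    df = pd.DataFrame(
        points, columns=["chromosome", "mean_r2", "mean_roh_length_bp", "rate_cm_per_mb"]
    )
    names = ["mean_r2", "mean_roh_length_bp", "rate_cm_per_mb"]
    rho = pd.DataFrame(np.eye(3), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((3, 3)), index=names, columns=names)
    for i, a in enumerate(names):
        pval.loc[a, a] = 0.0
        for b in names[i + 1 :]:
            if df[a].std(ddof=0) == 0 or df[b].std(ddof=0) == 0:
                r, p = float("nan"), float("nan")  # constant vector
            else:
                r, p = stats.pearsonr(df[a], df[b])
            rho.loc[a, b] = rho.loc[b, a] = float(r)
            pval.loc[a, b] = pval.loc[b, a] = float(p)
    return rho, pval
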