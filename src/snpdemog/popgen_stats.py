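"""Allele-frequency differentiation and distance statistics.

Population-level statistics (Nei's 1972 standard genetic distance, Weir &
Cockerham's 1984 theta as the Fst estimator, with Nei's Gst behind a flag)
and the individual-level allele-sharing distance (ASD).  Distances are
computed on the missingness-filtered panel without MAF/HWE filters, which are
reserved for LD analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class FrequencyTable:
    """Per-locus a1 allele frequencies of one population.

    ``table`` columns: ``locus_id, chromosome, position_bp, freq_a1,
    n_alleles``.  ``freq_a1`` is NaN when every call is missing.
    """

    population: str
    table: pd.DataFrame


def allele_frequencies(panel: GenotypePanel, population: str) -> FrequencyTable:
    """a1 frequency per locus: (2·n_hom_a1 + n_het) / (2·n_non_missing)."""
    sub = panel.restrict_samples(panel.population_mask(population))
    g = sub.genotypes
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=0)
    dose = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, dose / n_alleles, np.nan)
    table = sub.loci[["locus_id", "chromosome", "position_bp"]].copy()
    table["freq_a1"] = freq
    table["n_alleles"] = n_alleles
    return FrequencyTable(population=population, table=table)


def nei_standard_distance(
    freqs_a: FrequencyTable, freqs_b: FrequencyTable
) -> float:
    """Nei's (1972) standard genetic distance D = -ln(Jab / sqrt(Ja·Jb)).

    For biallelic loci Jab is the mean over loci of ``pa·pb +
    (1-pa)(1-pb)``; Ja, Jb are the within-population homozygosities.  Loci
    with a missing frequency in either population are excluded pairwise.
    Returns ``inf`` when Jab = 0 (every locus fixed for opposite alleles).
    """
    ta, tb = freqs_a.table, freqs_b.table
    if len(ta) != len(tb) or not (ta["locus_id"].to_numpy() == tb["locus_id"].to_numpy()).all():
        raise UserInputError("frequency tables must share one locus set")
    pa = ta["freq_a1"].to_numpy(dtype=float)
    pb = tb["freq_a1"].to_numpy(dtype=float)
    ok = ~(np.isnan(pa) | np.isnan(pb))
    if not ok.any():
        raise UserInputError("no loci with defined frequencies in both populations")
    pa, pb = pa[ok], pb[ok]
    jab = float(np.mean(pa * pb + (1 - pa) * (1 - pb)))
    ja = float(np.mean(pa**2 + (1 - pa) ** 2))
    jb = float(np.mean(pb**2 + (1 - pb) ** 2))
    if jab == 0.0:
        return math.inf
    d = -math.log(jab / math.sqrt(ja * jb))
    return d if d > 0 else 0.0


def _wc_theta_components(
    g_a: np.ndarray, g_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) numerator a and denominator a+b+c
    for two populations of diploid genotypes (columns = loci)."""
    r = 2.0
    comps = []
    for g in (g_a, g_b):
        called = g != MISSING
        n = called.sum(axis=0).astype(float)  # diploid individuals
        dose = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, dose / (2 * n), np.nan)
            h = np.where(n > 0, np.where(called, g == 1, False).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    num = a
    den = a + b + c
    usable = (
        (n1 >= 1)
        & (n2 >= 1)
        & (nbar > 1)
        & ~np.isnan(pbar)
        & ~((p1 == p2) & ((p1 == 0) | (p1 == 1)))  # monomorphic across both
    )
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0)


def pairwise_fst(
    panel: GenotypePanel, pop_a: str, pop_b: str, estimator: str = "wc"
) -> float:
    """Fst between two populations.

    ``estimator='wc'`` (default) is Weir & Cockerham's theta aggregated as a
    ratio of sums over loci; ``estimator='gst'`` is Nei's Gst.  Loci
    monomorphic across both populations are skipped; the result is clamped to
    [0, 1].
    """
    mask_a = panel.population_mask(pop_a)
    mask_b = panel.population_mask(pop_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise UserInputError("each population needs at least 2 samples for Fst")
    g_a = panel.genotypes[mask_a]
    g_b = panel.genotypes[mask_b]
    if estimator == "wc":
        num, den = _wc_theta_components(g_a, g_b)
        total_den = den.sum()
        if total_den == 0:
            raise UserInputError("no polymorphic loci usable for Fst")
        theta = float(num.sum() / total_den)
        return min(max(theta, 0.0), 1.0)
    if estimator == "gst":
        freqs = []
        for g in (g_a, g_b):
            called = g != MISSING
            n_alleles = 2 * called.sum(axis=0)
            dose = np.where(called, g, 0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs.append(np.where(n_alleles > 0, dose / n_alleles, np.nan))
        p1, p2 = freqs
        ok = ~(np.isnan(p1) | np.isnan(p2))
        ok &= ~((p1 == p2) & ((p1 == 0) | (p1 == 1)))
        if not ok.any():
            raise UserInputError("no polymorphic loci usable for Fst")
        p1, p2 = p1[ok], p2[ok]
        hs = np.mean(2 * p1 * (1 - p1) / 2 + 2 * p2 * (1 - p2) / 2)
        pm = (p1 + p2) / 2
        ht = np.mean(2 * pm * (1 - pm))
        if ht == 0:
            raise UserInputError("total heterozygosity is zero")
        return min(max(float(1 - hs / ht), 0.0), 1.0)
    raise UserInputError("estimator must be 'wc' or 'gst'")


def allele_sharing_distance(panel: GenotypePanel) -> pd.DataFrame:
    """Sample-by-sample allele-sharing distance matrix.

    ASD = 1 - mean(IBS)/2 over loci where both samples are called, with IBS
    the number of shared alleles (0, 1 or 2) per locus, i.e. ``2 - |g_i -
    g_j|`` for dosage genotypes.  Pairs with no jointly called locus get NaN.
    """
    if panel.n_samples < 2:
        raise UserInputError("at least 2 samples required")
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    n = panel.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1 :])  # NaN where either is missing
        ibs = 2.0 - diff
        with np.errstate(invalid="ignore"):
            mean_ibs = np.nanmean(ibs, axis=1)
        asd = 1.0 - mean_ibs / 2.0
        dist[i, i + 1 :] = asd
        dist[i + 1 :, i] = asd
    if np.isnan(dist).any():
        logger.warning(
            "%d sample pairs share no called locus; ASD set to NaN",
            int(np.isnan(dist).sum() // 2),
        )
    ids = panel.samples["sample_id"].tolist()
    return pd.DataFrame(dist, index=ids, columns=ids)


def distance_matrix(
    panel: GenotypePanel, statistic: str = "fst", estimator: str = "wc"
) -> pd.DataFrame:
    """Symmetric population-by-population distance matrix.

    ``statistic`` is ``'fst'`` or ``'nei_D'``.
    """
    pops = panel.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    freqs = {p: allele_frequencies(panel, p) for p in pops}
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            if statistic == "fst":
                d = pairwise_fst(panel, pa, pb, estimator=estimator)
            elif statistic == "nei_D":
                d = nei_standard_distance(freqs[pa], freqs[pb])
            else:
                raise UserInputError("statistic must be 'fst' or 'nei_D'")
            mat.loc[pa, pb] = d
            mat.loc[pb, pa] = d
    return mat


def combined_distance_table(panel: GenotypePanel) -> pd.DataFrame:
    """One table with Fst below and Nei's D above the diagonal."""
    fst = distance_matrix(panel, "fst")
    nei = distance_matrix(panel, "nei_D")
    out = fst.copy()
    pops = list(out.index)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            out.loc[pa, pb] = nei.loc[pa, pb]
    return out


def write_phylip(dist: pd.DataFrame, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (names truncated to 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for name, row in dist.iterrows():
            label = f"{str(name)[:10]:<10}"
            vals = " ".join(f"{v:.6f}" for v in row.to_numpy())
            fh.write(f"{label} {vals}\n")
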