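"""Persistence of LD phase between populations.

For each pair of populations, the signed LD values r of the SNP pairs defined
in *both* populations are grouped into 100-kbp distance bins and the Pearson
correlation of the two r vectors is computed per bin.  Because r is signed,
the panel-wide allele coding set at read time is what makes the sign of a
SNP pair comparable across populations; the correlation of r² would erase
phase information.  High correlations at long distances indicate recent
common ancestry of the two populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import GenotypePanel
from snpdemog.ld_analysis import pairwise_ld

logger = logging.getLogger(__name__)


@dataclass
class PhaseCurve:
    """Per-distance-bin Pearson correlation of signed r between two
    populations.

    ``bins`` columns: ``bin_start_bp, bin_end_bp, pearson_r, n_pairs``;
    ``pearson_r`` is NaN for bins with fewer than the minimum shared pairs.
    """

    population_a: str
    population_b: str
    bins: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def signed_r_catalog(
    panel: GenotypePanel,
    population: str | None = None,
    max_distance_bp: int = 10_000_000,
    estimator: str = "em",
) -> pd.DataFrame:
    """Keyed table of signed r per SNP pair for one population.

    The catalog is built with its own distance cap (default 10 Mb, wider than
    the 3 Mb used for LD-decay summaries).  Pairs with undefined LD in this
    population are omitted.  Columns: ``chromosome, locus_i, locus_j,
    distance_bp, r``.
    """
    ld = pairwise_ld(
        panel,
        population=population,
        max_distance_bp=max_distance_bp,
        estimator=estimator,
    )
    return ld.table[["chromosome", "locus_i", "locus_j", "distance_bp", "r"]].copy()


def phase_correlation(
    cat_a: pd.DataFrame,
    cat_b: pd.DataFrame,
    bin_width_bp: int = 100_000,
    max_distance_bp: int = 10_000_000,
    min_pairs: int = 3,
    population_a: str = "A",
    population_b: str = "B",
) -> PhaseCurve:
    """Pearson correlation of signed r in consecutive distance bins.

    Only SNP pairs present in both catalogs contribute (intersection
    semantics); bins with fewer than ``min_pairs`` shared pairs are reported
    with ``pearson_r`` = NaN and their count recorded.
    """
    if bin_width_bp <= 0 or max_distance_bp <= 0:
        raise UserInputError("bin width and maximum distance must be positive")
    merged = cat_a.merge(
        cat_b,
        on=["chromosome", "locus_i", "locus_j"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    if len(merged) == 0:
        raise UserInputError("the two catalogs share no SNP pairs")
    dist = merged["distance_bp_a"].to_numpy()
    merged = merged[dist < max_distance_bp]
    n_shared = len(merged)
    logger.info(
        "%s-%s: %d shared SNP pairs within %d bp",
        population_a,
        population_b,
        n_shared,
        max_distance_bp,
    )
    k = (merged["distance_bp_a"].to_numpy() // bin_width_bp).astype(int)
    ra = merged["r_a"].to_numpy()
    rb = merged["r_b"].to_numpy()
    n_bins = max_distance_bp // bin_width_bp
    rows = []
    for b in range(n_bins):
        sel = k == b
        n = int(sel.sum())
        if n >= min_pairs and np.std(ra[sel]) > 0 and np.std(rb[sel]) > 0:
            rho = float(stats.pearsonr(ra[sel], rb[sel])[0])
        else:
            rho = float("nan")
        rows.append((b * bin_width_bp, (b + 1) * bin_width_bp, rho, n))
    bins = pd.DataFrame(
        rows, columns=["bin_start_bp", "bin_end_bp", "pearson_r", "n_pairs"]
    )
    return PhaseCurve(
        population_a=population_a,
        population_b=population_b,
        bins=bins,
        provenance={
            "bin_width_bp": bin_width_bp,
            "max_distance_bp": max_distance_bp,
            "min_pairs": min_pairs,
            "n_shared_pairs": n_shared,
        },
    )
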