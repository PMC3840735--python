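"""Effective population size from binned LD and a recombination map.

The expected squared LD between loci at recombination distance c Morgans in
a Wright-Fisher population of effective size Ne is r² = 1/(4·Ne·c + 1), so
Ne = (1/(4c))·(1/r² - 1).  Each 1-Mb genome bin contributes one estimate:
its mean r² over SNP pairs wholly inside the bin, and its recombination
distance c = rate(cM/Mb)/100 · mean pair distance(Mb).  The current-Ne
estimate is the mean ± sample SD across bins.  LD at recombination distance
c reflects drift roughly T = 1/(2c) generations ago, so low-recombination
bins probe deeper time and the per-bin (T, Ne) points form a historical Ne
trajectory; bins with c below a cutoff (default 1e-6 Morgans, approaching
the per-generation mutation rate) are excluded from the trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import RecombinationMap
from snpdemog.ld_analysis import LDTable

logger = logging.getLogger(__name__)

BIN_COLUMNS = [
    "chromosome",
    "start_bp",
    "end_bp",
    "rate_cm_per_mb",
    "mean_r2",
    "mean_pair_distance_bp",
    "c_morgans",
    "n_pairs",
]


@dataclass
class NeEstimate:
    """Across-bin mean and sample SD of the per-bin Ne estimates."""

    mean_ne: float
    sd_ne: float
    n_bins: int


def bin_genome(
    ld: LDTable, rmap: RecombinationMap, bin_size_bp: int = 1_000_000
) -> pd.DataFrame:
    """Divide chromosomes into bins and attach mean r² and c per bin.

    A SNP pair contributes to a bin only if *both* loci lie inside it
    (half-open [k·s, (k+1)·s) in 0-based coordinates).  The bin recombination
    rate is the length-weighted mean of the map windows overlapping the bin;
    c_morgans = (rate/100) · (mean pair distance in Mb).  Bins without pairs
    or without map coverage are dropped (counts logged).
    """
    if rmap.is_empty:
        raise UserInputError("recombination map is empty; Ne stages refuse to run")
    t = ld.table
    if len(t) == 0:
        raise UserInputError("empty LD table")
    bin_i = ((t["pos_i"].to_numpy() - 1) // bin_size_bp).astype(int)
    bin_j = ((t["pos_j"].to_numpy() - 1) // bin_size_bp).astype(int)
    inside = bin_i == bin_j
    n_straddle = int((~inside).sum())
    sub = t[inside].copy()
    sub["bin"] = bin_i[inside]
    rows = []
    n_no_cov = 0
    for (chrom, b), grp in sub.groupby(["chromosome", "bin"]):
        start = int(b) * bin_size_bp
        end = start + bin_size_bp
        rate, covered = rmap.rate_in_interval(int(chrom), start, end)
        if covered == 0 or np.isnan(rate):
            n_no_cov += 1
            continue
        mean_dist = float((grp["pos_j"] - grp["pos_i"]).mean())
        c = (rate / 100.0) * (mean_dist / 1e6)
        rows.append(
            (
                int(chrom),
                start,
                end,
                rate,
                float(grp["r2"].mean()),
                mean_dist,
                c,
                len(grp),
            )
        )
    logger.info(
        "binning: %d pairs straddled a bin boundary, %d bins lacked map coverage",
        n_straddle,
        n_no_cov,
    )
    if not rows:
        raise UserInputError("no usable genome bins (check map coverage and LD table)")
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def ne_from_bin(mean_r2: float, c_morgans: float) -> float:
    """Invert r² = 1/(4·Ne·c + 1): Ne = (1/(4c))·(1/r² - 1).

    Returns 0 for r² = 1 and ``inf`` for r² = 0 (such bins are excluded from
    aggregation by the callers).
    """
    if c_morgans <= 0:
        raise UserInputError("c_morgans must be positive")
    if not 0 <= mean_r2 <= 1:
        raise UserInputError("mean_r2 must be within [0, 1]")
    if mean_r2 == 0:
        return float("inf")
    return (1.0 / (4.0 * c_morgans)) * (1.0 / mean_r2 - 1.0)


def current_ne(
    bins: pd.DataFrame,
    sample_size: int | None = None,
    correct_sample_size: bool = False,
) -> NeEstimate:
    """Current Ne as mean ± sample SD of the per-bin estimates.

    If ``correct_sample_size`` is set, each bin's r² is first reduced by
    1/(2·sample_size) — the expected contribution of finite sample size to
    observed r² — floored at 1e-6; the correction is OFF by default.  Bins
    with r² = 0 or c = 0 are excluded and counted.
    """
    if len(bins) < 2:
        raise UserInputError("need at least 2 usable bins for a mean and SD")
    if sample_size is not None and sample_size < 15:
        logger.warning(
            "sample size %d < 15: Ne estimate should be treated with care",
            sample_size,
        )
    r2 = bins["mean_r2"].to_numpy(dtype=float).copy()
    if correct_sample_size:
        if not sample_size:
            raise UserInputError("sample_size required for the r² correction")
        r2 = np.maximum(r2 - 1.0 / (2.0 * sample_size), 1e-6)
    c = bins["c_morgans"].to_numpy(dtype=float)
    usable = (r2 > 0) & (c > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluded %d bins with r²=0 or c=0 from Ne", n_excluded)
    if usable.sum() < 2:
        raise UserInputError("fewer than 2 bins usable for Ne estimation")
    ne = (1.0 / (4.0 * c[usable])) * (1.0 / r2[usable] - 1.0)
    return NeEstimate(
        mean_ne=float(ne.mean()),
        sd_ne=float(np.std(ne, ddof=1)),
        n_bins=int(usable.sum()),
    )


def past_ne_trajectory(bins: pd.DataFrame, c_min: float = 1e-6) -> pd.DataFrame:
    """Historical Ne trajectory: one (T, Ne) point per bin.

    T = 1/(2c) generations; bins with c below ``c_min`` are dropped because
    the drift approximation requires c to dominate the mutation rate.
    Columns: ``T_generations, ne, chromosome, start_bp, c_morgans,
    rate_cm_per_mb``; sorted by T ascending.
    """
    c = bins["c_morgans"].to_numpy(dtype=float)
    r2 = bins["mean_r2"].to_numpy(dtype=float)
    usable = (c >= c_min) & (r2 > 0)
    if not usable.any():
        raise UserInputError(f"no bins with c >= {c_min}")
    sub = bins[usable].sort_values("rate_cm_per_mb", ascending=False)
    c = sub["c_morgans"].to_numpy(dtype=float)
    r2 = sub["mean_r2"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "T_generations": 1.0 / (2.0 * c),
            "ne": (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0),
            "chromosome": sub["chromosome"].to_numpy(),
            "start_bp": sub["start_bp"].to_numpy(),
            "c_morgans": c,
            "rate_cm_per_mb": sub["rate_cm_per_mb"].to_numpy(),
        }
    )
    return out.sort_values("T_generations", kind="stable").reset_index(drop=True)
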