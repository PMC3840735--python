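"""Linkage disequilibrium from unphased diploid genotypes.

Two-locus haplotype frequencies are estimated by maximum likelihood with an
EM algorithm: under random mating only double heterozygotes are
phase-ambiguous, so the E-step splits them between the cis (a1a1/a2a2) and
trans (a1a2/a2a1) configurations at their current expected proportions.  The
EM ascends from two deterministic starts bracketing the linkage-equilibrium
point (which is itself an EM fixed point for allele-swap-symmetric data) and
iterates until the largest haplotype-frequency change falls below 1e-9 (at
most 1000 iterations); ties between the two modes resolve to the smaller
f11, so the reported solution is deterministic.  From the converged
frequencies,
D = f11 - p·q, r = D / sqrt(p(1-p)q(1-q)) and r² = r².

A faster composite (genotype-correlation) estimator is available behind the
``estimator`` flag for exploratory work.

The EM core is vectorised over locus pairs: all within-chromosome pairs
below the distance cap are processed as one batch of 3x3 genotype count
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpdemog.errors import UndefinedLDError, UserInputError
from snpdemog.genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

EM_TOL = 1e-9
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFrequencies:
    """Converged two-locus haplotype frequencies (a1/a2 at locus 1 x 2)."""

    f11: float
    f12: float
    f21: float
    f22: float
    loglik: float
    n_iter: int

    def as_array(self) -> np.ndarray:
        return np.array([self.f11, self.f12, self.f21, self.f22])


@dataclass
class LDTable:
    """Signed r and r² for all qualifying SNP pairs of one population.

    ``table`` columns: ``chromosome, locus_i, locus_j, pos_i, pos_j,
    distance_bp, r, r2``.
    """

    population: str
    table: pd.DataFrame
    n_failed: int = 0
    provenance: dict = field(default_factory=dict)

    TABLE_COLUMNS = [
        "chromosome",
        "locus_i",
        "locus_j",
        "pos_i",
        "pos_j",
        "distance_bp",
        "r",
        "r2",
    ]


# ---------------------------------------------------------------------------
# EM core (vectorised over pairs)
# ---------------------------------------------------------------------------

def _count_tables(
    g1: np.ndarray, g2: np.ndarray
) -> np.ndarray:
    """3x3 genotype count tables for column-matched pairs.

    ``g1, g2``: (n_samples, n_pairs) int8.  Returns (n_pairs, 3, 3) counts
    over samples where both calls are non-missing; index = a1-dosage.
    """
    valid = (g1 != MISSING) & (g2 != MISSING)
    counts = np.empty((g1.shape[1], 3, 3), dtype=np.int64)
    for a in range(3):
        ga = (g1 == a) & valid
        for b in range(3):
            counts[:, a, b] = (ga & (g2 == b)).sum(axis=0)
    return counts


def _em_run(k11, k12, k21, k22, ndh, two_n, f11_init, p, q, ok, tol, max_iter):
    """One EM ascent from a given f11 start (margins are fixed at the MLE)."""
    f11 = np.where(ok, f11_init, 0.25)
    f12 = np.where(ok, p - f11_init, 0.25)
    f21 = np.where(ok, q - f11_init, 0.25)
    f22 = np.where(ok, 1 - p - q + f11_init, 0.25)
    n_iter = np.zeros(len(f11), dtype=np.int64)
    active = ok.copy()
    safe_two_n = np.where(two_n > 0, two_n, 1.0)
    for _ in range(max_iter):
        if not active.any():
            break
        cis = f11 * f22
        trans = f12 * f21
        denom = cis + trans
        pc = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), 0.5)
        new11 = (k11 + ndh * pc) / safe_two_n
        new12 = (k12 + ndh * (1 - pc)) / safe_two_n
        new21 = (k21 + ndh * (1 - pc)) / safe_two_n
        new22 = (k22 + ndh * pc) / safe_two_n
        delta = np.max(
            np.abs(np.stack([new11 - f11, new12 - f12, new21 - f21, new22 - f22])),
            axis=0,
        )
        upd = active
        f11 = np.where(upd, new11, f11)
        f12 = np.where(upd, new12, f12)
        f21 = np.where(upd, new21, f21)
        f22 = np.where(upd, new22, f22)
        n_iter[upd] += 1
        active = active & (delta >= tol)
    return f11, f12, f21, f22, n_iter


def _em_batch(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the EM on a batch of 3x3 count tables.

    The linkage-equilibrium point is an EM fixed point whenever the data are
    symmetric under an allele swap (e.g. a fully heterozygous locus), so the
    ascent is started from two small symmetric perturbations of it and the
    higher-likelihood solution kept; on an exact likelihood tie the smaller
    f11 (repulsion-side mode) is reported, a deterministic convention.

    Returns ``(freqs, loglik, n_iter, ok)`` where ``freqs`` is (n, 4) in the
    order f11, f12, f21, f22 and ``ok`` flags pairs with defined LD (both
    margins polymorphic, >= 2 informative samples).
    """
    c = counts.astype(float)
    n_ind = c.sum(axis=(1, 2))
    # known haplotype contributions (everything except double heterozygotes)
    k11 = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    k12 = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]
    k21 = 2 * c[:, 0, 2] + c[:, 0, 1] + c[:, 1, 2]
    k22 = 2 * c[:, 0, 0] + c[:, 0, 1] + c[:, 1, 0]
    ndh = c[:, 1, 1]
    two_n = 2 * n_ind
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * c[:, 2, :].sum(axis=1) + c[:, 1, :].sum(axis=1)) / two_n
        q = (2 * c[:, :, 2].sum(axis=1) + c[:, :, 1].sum(axis=1)) / two_n
    ok = (n_ind >= 2) & (p > 0) & (p < 1) & (q > 0) & (q < 1)

    le = np.where(ok, p * q, 0.25)
    lo = np.where(ok, np.maximum(0.0, p + q - 1.0), 0.0)
    hi = np.where(ok, np.minimum(p, q), 1.0)
    start_hi = le + 0.25 * (hi - le)
    start_lo = le - 0.25 * (le - lo)
    n_single_het = c[:, 2, 1] + c[:, 1, 2] + c[:, 1, 0] + c[:, 0, 1]

    runs = []
    for start in (start_lo, start_hi):
        f11, f12, f21, f22, n_iter = _em_run(
            k11, k12, k21, k22, ndh, two_n, start, p, q, ok, tol, max_iter
        )
        ll = _safe_loglik(k11, k12, k21, k22, ndh, n_single_het, f11, f12, f21, f22)
        runs.append((f11, f12, f21, f22, n_iter, ll))
    (a11, a12, a21, a22, a_it, a_ll), (b11, b12, b21, b22, b_it, b_ll) = runs
    # keep the low start unless the high start is strictly better
    take_hi = b_ll > a_ll + 1e-9
    f11 = np.where(take_hi, b11, a11)
    f12 = np.where(take_hi, b12, a12)
    f21 = np.where(take_hi, b21, a21)
    f22 = np.where(take_hi, b22, a22)
    n_iter = np.where(take_hi, b_it, a_it)
    ll = np.where(take_hi, b_ll, a_ll)
    freqs = np.stack([f11, f12, f21, f22], axis=1)
    return freqs, ll, n_iter, ok


def _safe_loglik(k11, k12, k21, k22, ndh, n_single_het, f11, f12, f21, f22):
    def term(k, f):
        with np.errstate(divide="ignore"):
            t = k * np.log(np.where(f > 0, f, 1.0))
        return np.where(k > 0, t, 0.0)

    dh = 2 * f11 * f22 + 2 * f12 * f21
    with np.errstate(divide="ignore"):
        dh_term = ndh * np.log(np.where(dh > 0, dh, 1.0))
    dh_term = np.where(ndh > 0, dh_term, 0.0)
    return (
        term(k11, f11)
        + term(k12, f12)
        + term(k21, f21)
        + term(k22, f22)
        + dh_term
        + n_single_het * np.log(2.0)
    )


def em_haplotype_frequencies(
    genotypes_i: np.ndarray, genotypes_j: np.ndarray
) -> HaplotypeFrequencies:
    """EM maximum-likelihood haplotype frequencies for one locus pair.

    Raises :class:`UndefinedLDError` if fewer than two samples carry both
    calls or either locus is monomorphic among them.
    """
    g1 = np.asarray(genotypes_i, dtype=np.int8).reshape(-1, 1)
    g2 = np.asarray(genotypes_j, dtype=np.int8).reshape(-1, 1)
    if g1.shape != g2.shape:
        raise UserInputError("genotype vectors must have equal length")
    counts = _count_tables(g1, g2)
    freqs, ll, n_iter, ok = _em_batch(counts)
    if not ok[0]:
        raise UndefinedLDError(
            "LD undefined: monomorphic locus or < 2 jointly called samples"
        )
    f = freqs[0]
    return HaplotypeFrequencies(
        f11=float(f[0]),
        f12=float(f[1]),
        f21=float(f[2]),
        f22=float(f[3]),
        loglik=float(ll[0]),
        n_iter=int(n_iter[0]),
    )


def ld_from_haplotypes(h: HaplotypeFrequencies) -> tuple[float, float]:
    """Signed r and r² from haplotype frequencies.

    D = f11 - p·q with p, q the marginal a1 frequencies; undefined when a
    margin is fixed.
    """
    p = h.f11 + h.f12
    q = h.f11 + h.f21
    if not (0 < p < 1 and 0 < q < 1):
        raise UndefinedLDError("marginal allele frequency at 0 or 1")
    d = h.f11 - p * q
    r = d / np.sqrt(p * (1 - p) * q * (1 - q))
    r = float(np.clip(r, -1.0, 1.0))
    return r, r * r


# ---------------------------------------------------------------------------
# panel-level LD
# ---------------------------------------------------------------------------

def _chromosome_pairs(
    positions: np.ndarray, max_distance_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i < j, with pos_j - pos_i strictly below the cap."""
    idx_i = []
    idx_j = []
    n = len(positions)
    hi = np.searchsorted(positions, positions + max_distance_bp, side="left")
    for i in range(n):
        j_end = hi[i]
        if j_end > i + 1:
            idx_i.append(np.full(j_end - i - 1, i))
            idx_j.append(np.arange(i + 1, j_end))
    if not idx_i:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(idx_i), np.concatenate(idx_j)


def _composite_r(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of dosage genotypes, pairwise-complete."""
    valid = (g1 != MISSING) & (g2 != MISSING)
    x = np.where(valid, g1, 0).astype(float)
    y = np.where(valid, g2, 0).astype(float)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = x.sum(axis=0) / n
        my = y.sum(axis=0) / n
        sxy = (x * y * valid).sum(axis=0) / n - mx * my
        sxx = (x * x * valid).sum(axis=0) / n - mx * mx
        syy = (y * y * valid).sum(axis=0) / n - my * my
        r = sxy / np.sqrt(sxx * syy)
    ok = (n >= 2) & (sxx > 0) & (syy > 0)
    return np.clip(np.where(ok, r, np.nan), -1, 1), ok


def pairwise_ld(
    panel: GenotypePanel,
    population: str | None = None,
    max_distance_bp: int = 3_000_000,
    estimator: str = "em",
    block_size: int = 200_000,
) -> LDTable:
    """Signed r and r² for all same-chromosome pairs closer than the cap.

    The panel is expected to have passed per-population QC already; if
    ``population`` is given the panel is restricted to it first.  Pairs where
    the estimator is undefined (monomorphic margin among jointly called
    samples) are skipped and counted in ``n_failed``.
    """
    if max_distance_bp <= 0:
        raise UserInputError("max_distance_bp must be positive")
    if estimator not in ("em", "composite"):
        raise UserInputError("estimator must be 'em' or 'composite'")
    if population is not None and set(panel.samples["population"]) != {population}:
        panel = panel.restrict_samples(panel.population_mask(population))
    label = population if population is not None else "all"
    g = panel.genotypes
    chroms = panel.loci["chromosome"].to_numpy()
    positions = panel.loci["position_bp"].to_numpy()
    locus_ids = panel.loci["locus_id"].to_numpy()

    frames = []
    n_failed = 0
    if panel.n_samples == 0:
        logger.warning("population %s has no samples after QC; empty LD table", label)
    else:
        for chrom in np.unique(chroms):
            sel = np.flatnonzero(chroms == chrom)
            pos_c = positions[sel]
            ii, jj = _chromosome_pairs(pos_c, max_distance_bp)
            for start in range(0, len(ii), block_size):
                bi = ii[start : start + block_size]
                bj = jj[start : start + block_size]
                g1 = g[:, sel[bi]]
                g2 = g[:, sel[bj]]
                if estimator == "em":
                    counts = _count_tables(g1, g2)
                    freqs, _ll, _it, ok = _em_batch(counts)
                    f11, f12, f21 = freqs[:, 0], freqs[:, 1], freqs[:, 2]
                    p = f11 + f12
                    q = f11 + f21
                    ok &= (p > 0) & (p < 1) & (q > 0) & (q < 1)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = (f11 - p * q) / np.sqrt(p * (1 - p) * q * (1 - q))
                    r = np.clip(r, -1, 1)
                else:
                    r, ok = _composite_r(g1, g2)
                n_failed += int((~ok).sum())
                keep = np.asarray(ok, dtype=bool)
                if not keep.any():
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "chromosome": chrom,
                            "locus_i": locus_ids[sel[bi[keep]]],
                            "locus_j": locus_ids[sel[bj[keep]]],
                            "pos_i": pos_c[bi[keep]],
                            "pos_j": pos_c[bj[keep]],
                            "distance_bp": pos_c[bj[keep]] - pos_c[bi[keep]],
                            "r": r[keep],
                            "r2": r[keep] ** 2,
                        }
                    )
                )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=LDTable.TABLE_COLUMNS)
        logger.warning("no SNP pairs retained for population %s", label)
    if n_failed:
        logger.info(
            "population %s: %d pairs skipped (LD undefined)", label, n_failed
        )
    return LDTable(
        population=label,
        table=table,
        n_failed=n_failed,
        provenance={
            "max_distance_bp": max_distance_bp,
            "estimator": estimator,
            "n_samples": panel.n_samples,
            "n_loci": panel.n_loci,
        },
    )


def chromosome_ld_summary(ld: LDTable) -> pd.DataFrame:
    """Mean and sample SD (n-1) of r² per chromosome plus a Total row."""
    t = ld.table
    if len(t) == 0:
        raise UserInputError("empty LD table")
    rows = []
    for chrom, grp in t.groupby("chromosome"):
        r2 = grp["r2"].to_numpy()
        sd = float(np.std(r2, ddof=1)) if len(r2) > 1 else 0.0
        rows.append((str(chrom), float(r2.mean()), sd, len(r2)))
    r2 = t["r2"].to_numpy()
    rows.append(
        (
            "Total",
            float(r2.mean()),
            float(np.std(r2, ddof=1)) if len(r2) > 1 else 0.0,
            len(r2),
        )
    )
    return pd.DataFrame(rows, columns=["chromosome", "mean_r2", "sd_r2", "n_pairs"])


def ld_decay_profile(ld: LDTable, bin_width_bp: int = 100_000) -> pd.DataFrame:
    """Mean r² in half-open distance bins [k·w, (k+1)·w); empty bins omitted."""
    if bin_width_bp <= 0:
        raise UserInputError("bin_width_bp must be positive")
    t = ld.table
    if len(t) == 0:
        return pd.DataFrame(
            columns=["bin_start_bp", "bin_end_bp", "bin_mid_bp", "mean_r2", "n_pairs"]
        )
    k = (t["distance_bp"].to_numpy() // bin_width_bp).astype(int)
    df = pd.DataFrame({"k": k, "r2": t["r2"].to_numpy()})
    agg = df.groupby("k")["r2"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame(
        {
            "bin_start_bp": agg["k"] * bin_width_bp,
            "bin_end_bp": (agg["k"] + 1) * bin_width_bp,
            "bin_mid_bp": agg["k"] * bin_width_bp + bin_width_bp // 2,
            "mean_r2": agg["mean"],
            "n_pairs": agg["size"],
        }
    )
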