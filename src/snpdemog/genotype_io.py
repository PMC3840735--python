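"""Genotype-panel containers, PLINK text/binary I/O and quality control.

Genotypes are stored as an ``(n_samples, n_loci)`` ``int8`` matrix counting
copies of the panel-wide reference allele ``a1`` (0, 1, 2) with ``MISSING``
(= -1) for no-calls.  One allele coding is fixed per locus for the whole
panel, never per population, so that signed LD is comparable across
populations.

Coordinates: positions are 1-based as in ``.map``/``.bim``; all internal
window/bin arithmetic is 0-based half-open and conversion happens only at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from snpdemog.errors import ParseError, UserInputError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_LEGAL_CODES = frozenset({-1, 0, 1, 2})
_SEX_CHROM_CODES = {"X", "Y", "XY", "MT", "M"}

LOCI_COLUMNS = ["locus_id", "chromosome", "position_bp", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "population"]


@dataclass
class GenotypePanel:
    """A sample-by-locus diploid genotype matrix with metadata.

    Parameters
    ----------
    loci
        DataFrame with columns ``locus_id, chromosome, position_bp, a1, a2``,
        sorted by ``(chromosome, position_bp)`` with strictly increasing
        positions within each chromosome.
    samples
        DataFrame with columns ``sample_id, population``.
    genotypes
        ``(n_samples, n_loci)`` int8 array of a1-allele counts; -1 = missing.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in LOCI_COLUMNS:
            if col not in self.loci.columns:
                raise UserInputError(f"loci table lacks column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise UserInputError(f"samples table lacks column {col!r}")
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise UserInputError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        codes = np.unique(self.genotypes)
        if not set(codes.tolist()) <= _LEGAL_CODES:
            bad = sorted(set(codes.tolist()) - _LEGAL_CODES)
            raise UserInputError(f"illegal genotype codes {bad}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise UserInputError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"]
            raise UserInputError(f"duplicate locus ids: {sorted(set(dup))}")
        if (self.loci["position_bp"] < 1).any():
            raise UserInputError("locus positions must be >= 1 (1-based)")
        if (self.loci["chromosome"] < 1).any():
            raise UserInputError("chromosome indices must be positive integers")
        if (self.loci["a1"] == self.loci["a2"]).any():
            raise UserInputError("a1 and a2 must differ at every locus")
        chrom = self.loci["chromosome"].to_numpy()
        pos = self.loci["position_bp"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(pos))):
            raise UserInputError("loci must be sorted by (chromosome, position)")
        same_chrom = chrom[1:] == chrom[:-1]
        if np.any(same_chrom & (pos[1:] <= pos[:-1])):
            raise UserInputError(
                "positions must be strictly increasing within a chromosome"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique().tolist())

    def population_mask(self, population: str) -> np.ndarray:
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise UserInputError(
                f"population {population!r} not in panel; "
                f"available: {self.populations}"
            )
        return mask

    def restrict_samples(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            loci=self.loci.copy(),
            samples=self.samples.loc[mask].copy(),
            genotypes=self.genotypes[mask].copy(),
        )

    def restrict_loci(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            loci=self.loci.loc[mask].copy(),
            samples=self.samples.copy(),
            genotypes=self.genotypes[:, mask].copy(),
        )

    def missing_fraction_per_locus(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.loci.reset_index(drop=True).equals(other.loci.reset_index(drop=True))
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class RecombinationMap:
    """Per-window recombination rates in cM/Mb.

    ``windows`` has columns ``chromosome, start_bp, end_bp, rate_cm_per_mb``
    with half-open 0-based intervals ``[start_bp, end_bp)``, non-overlapping
    and sorted within each chromosome.  Gaps between windows are permitted.
    """

    windows: pd.DataFrame

    COLUMNS = ["chromosome", "start_bp", "end_bp", "rate_cm_per_mb"]

    def __post_init__(self) -> None:
        self.windows = self.windows.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for col in self.COLUMNS:
            if col not in self.windows.columns:
                raise UserInputError(f"recombination map lacks column {col!r}")
        w = self.windows
        if len(w) == 0:
            return
        if (w["rate_cm_per_mb"] < 0).any():
            raise UserInputError("negative recombination rate")
        if (w["end_bp"] <= w["start_bp"]).any():
            raise UserInputError("window end must exceed start")
        for chrom, grp in w.groupby("chromosome"):
            grp = grp.sort_values("start_bp")
            starts = grp["start_bp"].to_numpy()
            ends = grp["end_bp"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise UserInputError(f"overlapping map windows on chromosome {chrom}")
        self.windows = w.sort_values(["chromosome", "start_bp"]).reset_index(drop=True)

    @property
    def is_empty(self) -> bool:
        return len(self.windows) == 0

    def mean_rate(self, chromosome: int | None = None) -> float:
        """Length-weighted mean rate, over one chromosome or the whole map."""
        w = self.windows
        if chromosome is not None:
            w = w[w["chromosome"] == chromosome]
        if len(w) == 0:
            return float("nan")
        length = (w["end_bp"] - w["start_bp"]).to_numpy(dtype=float)
        return float(np.average(w["rate_cm_per_mb"].to_numpy(), weights=length))

    def rate_in_interval(
        self, chromosome: int, start_bp: int, end_bp: int
    ) -> tuple[float, int]:
        """Length-weighted mean rate over ``[start_bp, end_bp)`` (0-based).

        Returns ``(rate, covered_bp)``; ``rate`` is NaN when no window
        overlaps the interval.
        """
        w = self.windows[self.windows["chromosome"] == chromosome]
        if len(w) == 0:
            return float("nan"), 0
        lo = np.maximum(w["start_bp"].to_numpy(), start_bp)
        hi = np.minimum(w["end_bp"].to_numpy(), end_bp)
        overlap = np.maximum(hi - lo, 0)
        covered = int(overlap.sum())
        if covered == 0:
            return float("nan"), 0
        rate = float(np.average(w["rate_cm_per_mb"].to_numpy(), weights=overlap))
        return rate, covered


# ---------------------------------------------------------------------------
# chromosome-code handling
# ---------------------------------------------------------------------------

def _parse_chromosome(code: str, where: str) -> int | None:
    """Return an autosome index, None for sex/mito codes (dropped), or raise."""
    code = code.strip()
    if code.upper() in _SEX_CHROM_CODES:
        return None
    try:
        value = int(code)
    except ValueError:
        raise ParseError(
            f"{where}: chromosome code {code!r} is neither numeric nor X/Y/MT"
        ) from None
    if value < 1:
        raise ParseError(
            f"{where}: chromosome code {code!r} is not a positive autosome index "
            "(unplaced scaffolds are rejected)"
        )
    return value


def _finalize_panel(
    loci: pd.DataFrame, samples: pd.DataFrame, genotypes: np.ndarray
) -> GenotypePanel:
    """Drop sex/mito loci (logged), sort loci by (chromosome, position)."""
    keep = loci["chromosome"].notna().to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("removed %d loci: sex/mitochondrial chromosome", n_dropped)
    loci = loci.loc[keep].copy()
    genotypes = genotypes[:, keep]
    loci["chromosome"] = loci["chromosome"].astype(int)
    order = np.lexsort(
        (loci["position_bp"].to_numpy(), loci["chromosome"].to_numpy())
    )
    loci = loci.iloc[order]
    genotypes = genotypes[:, order]
    return GenotypePanel(loci=loci, samples=samples, genotypes=genotypes)


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a PLINK text fileset into a :class:`GenotypePanel`.

    The population label of each sample is taken from the family-ID column.
    The reference allele ``a1`` of each locus is the first non-missing allele
    encountered in file order (top to bottom, left allele before right), a
    deterministic panel-wide choice.  ``0 0`` (or any genotype containing a
    ``0`` allele) becomes MISSING.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom_s, locus_id, _cm, pos_s = fields
            elif len(fields) == 3:
                chrom_s, locus_id, pos_s = fields
            else:
                raise ParseError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            chrom = _parse_chromosome(chrom_s, f"{map_path}:{lineno}")
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(
                    f"{map_path}:{lineno}: non-integer position {pos_s!r}"
                ) from None
            map_rows.append((locus_id, chrom, pos))
    n_loci = len(map_rows)

    sample_rows = []
    allele_first: list[str | None] = [None] * n_loci
    allele_second: list[str | None] = [None] * n_loci
    raw_alleles: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields "
                    f"(6 + 2x{n_loci} loci), got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            sample_rows.append((iid, fid))
            pairs = []
            for j in range(n_loci):
                x, y = fields[6 + 2 * j], fields[7 + 2 * j]
                pairs.append((x, y))
                for al in (x, y):
                    if al == "0":
                        continue
                    if allele_first[j] is None:
                        allele_first[j] = al
                    elif al != allele_first[j] and allele_second[j] is None:
                        allele_second[j] = al
                    elif al not in (allele_first[j], allele_second[j]):
                        raise ParseError(
                            f"{ped_path}:{lineno}: locus {map_rows[j][0]} has more "
                            f"than two alleles"
                        )
            raw_alleles.append(pairs)

    n_samples = len(sample_rows)
    genotypes = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw_alleles):
        for j, (x, y) in enumerate(pairs):
            if x == "0" or y == "0":
                continue
            a1 = allele_first[j]
            genotypes[i, j] = (x == a1) + (y == a1)

    loci = pd.DataFrame(
        {
            "locus_id": [r[0] for r in map_rows],
            "chromosome": pd.array(
                [r[1] for r in map_rows], dtype=pd.Int64Dtype()
            ),
            "position_bp": [r[2] for r in map_rows],
            "a1": [a if a is not None else "0" for a in allele_first],
            "a2": [a if a is not None else "0" for a in allele_second],
        }
    )
    # a monomorphic or all-missing locus may lack a second (or any) observed
    # allele; keep a placeholder that still satisfies a1 != a2
    fix = loci["a1"] == loci["a2"]
    loci.loc[fix, "a2"] = "?"
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    return _finalize_panel(loci, samples, genotypes)


def write_plink_text(
    panel: GenotypePanel, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a panel as a PLINK text fileset (population label -> family ID)."""
    with open(map_path, "w") as fh:
        for row in panel.loci.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}\n")
    a1 = panel.loci["a1"].to_numpy()
    a2 = panel.loci["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(panel.samples.itertuples(index=False)):
            fields = [srow.population, srow.sample_id, "0", "0", "0", "-9"]
            g = panel.genotypes[i]
            for j in range(panel.n_loci):
                if g[j] == 2:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    # allele order within a heterozygote is meaningless in
                    # the format; write it sorted so round-trips are stable
                    fields += sorted((a1[j], a2[j]))
                elif g[j] == 0:
                    fields += [a2[j], a2[j]]
                else:
                    fields += ["0", "0"]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (.bed / .bim / .fam), SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# two-bit code -> genotype (count of .bim allele-1)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypePanel:
    """Read a SNP-major PLINK binary fileset.

    The ``.bim`` allele-1 column is honoured as the panel ``a1``; two-bit
    codes are 00 = hom a1 (2), 10 = het (1), 11 = hom a2 (0), 01 = missing.
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "locus_id", "cm", "position_bp", "a1", "a2"],
        dtype=str,
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n_samples, n_loci = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise ParseError(f"{bed_path}: missing PLINK .bed magic bytes 6c 1b")
    if raw[2] == 0x00:
        raise UserInputError(
            f"{bed_path}: individual-major .bed files are an unsupported dialect"
        )
    if raw[2] != 0x01:
        raise ParseError(f"{bed_path}: unknown .bed mode byte {raw[2]:#04x}")
    bytes_per_locus = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_locus * n_loci:
        raise ParseError(
            f"{bed_path}: body has {len(body)} bytes, expected "
            f"{bytes_per_locus * n_loci} for {n_samples} samples x {n_loci} loci"
        )
    body = body.reshape(n_loci, bytes_per_locus)
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_loci, 4 * bytes_per_locus)[:, :n_samples]
    genotypes = _BED_DECODE[codes].T.copy()

    chroms = [
        _parse_chromosome(c, f"{bim_path}:{k + 1}")
        for k, c in enumerate(bim["chromosome"])
    ]
    loci = pd.DataFrame(
        {
            "locus_id": bim["locus_id"],
            "chromosome": pd.array(chroms, dtype=pd.Int64Dtype()),
            "position_bp": bim["position_bp"].astype(int),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    samples = pd.DataFrame(
        {"sample_id": fam["iid"], "population": fam["fid"]}
    )
    return _finalize_panel(loci, samples, genotypes)


def write_plink_binary(
    panel: GenotypePanel,
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
) -> None:
    """Write a panel as a SNP-major PLINK binary fileset."""
    with open(bim_path, "w") as fh:
        for row in panel.loci.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}"
                f"\t{row.a1}\t{row.a2}\n"
            )
    with open(fam_path, "w") as fh:
        for row in panel.samples.itertuples(index=False):
            fh.write(f"{row.population} {row.sample_id} 0 0 0 -9\n")
    n_samples = panel.n_samples
    bytes_per_locus = (n_samples + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        for j in range(panel.n_loci):
            g = panel.genotypes[:, j]
            codes = np.empty(n_samples, dtype=np.uint8)
            codes[g == 2] = 0
            codes[g == MISSING] = 1
            codes[g == 1] = 2
            codes[g == 0] = 3
            padded = np.zeros(bytes_per_locus * 4, dtype=np.uint8)
            padded[:n_samples] = codes
            padded = padded.reshape(bytes_per_locus, 4)
            byte = (
                padded[:, 0]
                | (padded[:, 1] << 2)
                | (padded[:, 2] << 4)
                | (padded[:, 3] << 6)
            )
            fh.write(byte.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# recombination map I/O
# ---------------------------------------------------------------------------

def read_recombination_map(path: str | Path) -> RecombinationMap:
    """Read a whitespace/tab-delimited map: chromosome, start, end, cM/Mb.

    A header line is detected by a non-numeric second field and skipped.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start = int(float(fields[1]))
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-numeric start field") from None
            try:
                chrom = int(fields[0])
                end = int(float(fields[2]))
                rate = float(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed row") from None
            if rate < 0:
                raise UserInputError(f"{path}:{lineno}: negative recombination rate")
            rows.append((chrom, start, end, rate))
    windows = pd.DataFrame(rows, columns=RecombinationMap.COLUMNS)
    return RecombinationMap(windows=windows)


def write_recombination_map(rmap: RecombinationMap, path: str | Path) -> None:
    rmap.windows.to_csv(
        path,
        sep="\t",
        index=False,
        header=["chromosome", "start_bp", "end_bp", "rate_cM_per_Mb"],
        float_format="%.10g",
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def filter_panel(
    panel: GenotypePanel, max_missing_fraction: float = 0.05
) -> GenotypePanel:
    """Drop loci whose missing fraction over *all* samples exceeds the cap.

    Sex-chromosome loci are already removed at read time; the missingness
    denominator is the full panel, mirroring a one-shot QC pass on the whole
    cohort before any per-population analysis.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise UserInputError("max_missing_fraction must be within [0, 1]")
    miss = panel.missing_fraction_per_locus()
    keep = miss <= max_missing_fraction
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "removed %d loci: missing fraction > %g", n_removed, max_missing_fraction
        )
    if not keep.any():
        raise UserInputError(
            "all loci removed by the missingness filter; review the threshold"
        )
    return panel.restrict_loci(keep)


def hwe_exact_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count (same parity, same totals) whose probability does not
    exceed that of the observed table.  Returns a p-value in (0, 1].
    """
    if min(n_hom_a1, n_het, n_hom_a2) < 0:
        raise UserInputError("genotype counts must be non-negative")
    n = n_hom_a1 + n_het + n_hom_a2
    if n == 0:
        raise UserInputError("at least one genotype count must be positive")
    n_a1 = 2 * n_hom_a1 + n_het
    n_rare = min(n_a1, 2 * n - n_a1)
    if n_rare == 0:
        return 1.0  # monomorphic: only one table possible
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    # P(het = h | allele counts) ∝ n! / (hom_r! h! hom_c!) * 2^h
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def _hwe_chisq(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    n = n_hom_a1 + n_het + n_hom_a2
    p = (2 * n_hom_a1 + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom_a1, n_het, n_hom_a2], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def apply_ld_qc(
    panel: GenotypePanel,
    population: str,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.001,
    hwe_test: str = "exact",
) -> GenotypePanel:
    """Restrict to one population and drop low-MAF / HWE-deviating loci.

    Minor-allele frequency is computed on the non-missing calls of that
    population; loci with MAF < ``maf_min`` are dropped, then loci whose HWE
    test p-value is below ``hwe_p_min``.  ``hwe_test`` selects the exact
    conditional test (default) or a 1-d.f. chi-square.
    """
    mask = panel.population_mask(population)
    sub = panel.restrict_samples(mask)
    g = sub.genotypes
    n2 = (g == 2).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n0 = (g == 0).sum(axis=0)
    n_called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (2 * n2 + n1) / (2 * n_called), 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min if maf_min > 0 else n_called >= 0
    keep = np.asarray(keep, dtype=bool)
    if maf_min > 0:
        keep &= n_called > 0
    n_maf = int((~keep).sum())

    test = hwe_exact_test if hwe_test == "exact" else _hwe_chisq
    if hwe_test not in ("exact", "chisq"):
        raise UserInputError("hwe_test must be 'exact' or 'chisq'")
    n_hwe = 0
    if hwe_p_min > 0:
        for j in np.flatnonzero(keep):
            if n_called[j] == 0:
                continue
            if test(int(n2[j]), int(n1[j]), int(n0[j])) < hwe_p_min:
                keep[j] = False
                n_hwe += 1
    if n_maf:
        logger.info(
            "removed %d loci: MAF < %g in population %s", n_maf, maf_min, population
        )
    if n_hwe:
        logger.info(
            "removed %d loci: HWE p < %g in population %s",
            n_hwe,
            hwe_p_min,
            population,
        )
    logger.info(
        "population %s: %d loci retained for LD analysis", population, int(keep.sum())
    )
    return sub.restrict_loci(keep)
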