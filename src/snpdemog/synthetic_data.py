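"""Forward Wright-Fisher simulation of SNP panels with known demography.

The generator produces genotype panels whose demographic truth is known, so
every analysis stage (LD decay, Ne recovery, ROH detection, differentiation)
can be tested without external data.  It is a discrete-generation forward
simulator of N monoecious diploids per population: each offspring draws two
parents uniformly at random (selfing permitted), and each transmitted gamete
recombines with a Poisson number of crossovers given the chromosome's
genetic length, breakpoints uniform along the chromosome.  Founder
haplotypes carry biallelic sites at frequencies drawn uniformly from
(0.05, 0.95); there is no mutation during the simulated epochs, which is
adequate for LD/ROH/Ne behaviour over up to a few thousand generations but
not for deep-time equilibria (deep-time checks are therefore trend-level).

Population-size histories are given as forward-time epochs; population
splits and admixture pulses are specified in generations before sampling.
A single mandatory seed drives every random draw deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import (
    GenotypePanel,
    RecombinationMap,
    write_plink_text,
    write_recombination_map,
)

logger = logging.getLogger(__name__)


@dataclass
class DemographyConfig:
    """Demography and genome architecture for one simulation.

    ``epochs`` is a forward-time list of ``(duration_generations,
    diploid_size)`` for the base population.  ``split_events`` entries are
    ``(time_ago, derived_name, diploid_size)`` and ``admixture_events``
    entries ``(time_ago, source, target, fraction)``: in the generation born
    ``time_ago`` generations before sampling, each ``target`` offspring draws
    both parents from ``source`` with probability ``fraction``.
    ``recombination_cm_per_mb`` may be a scalar or one value per chromosome.
    ``sample_size`` may be an int (every population) or a per-population
    mapping.
    """

    epochs: Sequence[tuple[int, int]]
    seed: int
    n_chromosomes: int = 18
    chromosome_length_bp: int = 5_000_000
    recombination_cm_per_mb: float | Sequence[float] = 1.0
    n_snps: int = 2_000
    sample_size: int | dict[str, int] = 25
    split_events: Sequence[tuple[int, str, int]] = ()
    admixture_events: Sequence[tuple[int, str, str, float]] = ()
    base_population: str = "P1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UserInputError("a seed is mandatory")
        if not self.epochs:
            raise UserInputError("at least one epoch required")
        for dur, n in self.epochs:
            if dur < 1 or n < 2:
                raise UserInputError("epoch durations >= 1 and sizes >= 2 required")
        for t, name, n in self.split_events:
            if n < 2 or t < 1:
                raise UserInputError("split sizes >= 2 and times >= 1 required")
            if t >= self.total_generations:
                raise UserInputError("split time predates the simulation start")
        for t, _src, _tgt, f in self.admixture_events:
            if not 0 < f < 1:
                raise UserInputError("admixture fractions must lie in (0, 1)")
            if not 0 < t < self.total_generations:
                raise UserInputError("admixture time outside the simulated span")
        if self.n_chromosomes < 1 or self.chromosome_length_bp < 2:
            raise UserInputError("invalid genome architecture")
        if self.n_snps < self.n_chromosomes:
            raise UserInputError("need at least one SNP per chromosome")

    @property
    def total_generations(self) -> int:
        return sum(d for d, _ in self.epochs)

    def rates(self) -> np.ndarray:
        r = self.recombination_cm_per_mb
        if np.isscalar(r):
            arr = np.full(self.n_chromosomes, float(r))
        else:
            arr = np.asarray(r, dtype=float)
            if len(arr) != self.n_chromosomes:
                raise UserInputError(
                    "recombination_cm_per_mb must be scalar or one per chromosome"
                )
        if (arr < 0).any():
            raise UserInputError("negative recombination rate")
        return arr

    def sample_size_for(self, population: str) -> int:
        if isinstance(self.sample_size, dict):
            return int(self.sample_size[population])
        return int(self.sample_size)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated panel.

    ``founder_frequencies`` and ``founder_haplotypes`` describe the base
    population at generation 0; ``haplotypes`` holds the phased haplotypes of
    the sampled individuals per population (rows 2i, 2i+1 belong to sample
    i).  All arrays are restricted to the loci retained in the panel.
    """

    config: DemographyConfig | None
    population_sizes: dict[str, int] = field(default_factory=dict)
    planted_segments: list[dict] = field(default_factory=list)
    founder_frequencies: np.ndarray | None = None
    founder_haplotypes: np.ndarray | None = None
    haplotypes: dict[str, np.ndarray] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


def _transmit(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    length_bp: int,
    length_morgans: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per parent index from a (2N, S) haplotype pool."""
    n = len(parent_idx)
    start = rng.integers(0, 2, size=n)
    n_xo = rng.poisson(length_morgans, size=n)
    out = np.empty((n, haps.shape[1]), dtype=np.uint8)
    plain = n_xo == 0
    out[plain] = haps[2 * parent_idx[plain] + start[plain]]
    for g in np.flatnonzero(~plain):
        breaks = np.sort(rng.uniform(0, length_bp, size=n_xo[g]))
        n_before = np.searchsorted(breaks, positions)
        use_start = (n_before % 2) == 0
        p = parent_idx[g]
        out[g] = np.where(
            use_start, haps[2 * p + start[g]], haps[2 * p + 1 - start[g]]
        )
    return out


def _reproduce(
    pool_a: list[np.ndarray],
    pool_b: list[np.ndarray],
    pick_b: np.ndarray,
    n_offspring: int,
    lengths_m: np.ndarray,
    length_bp: int,
    positions: list[np.ndarray],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """New diploid generation; offspring flagged in ``pick_b`` draw both
    parents from ``pool_b`` instead of ``pool_a``."""
    n_a = pool_a[0].shape[0] // 2
    n_b = pool_b[0].shape[0] // 2
    dad = np.where(pick_b, rng.integers(0, n_b, n_offspring), rng.integers(0, n_a, n_offspring))
    mom = np.where(pick_b, rng.integers(0, n_b, n_offspring), rng.integers(0, n_a, n_offspring))
    new = []
    for c, (ha, hb) in enumerate(zip(pool_a, pool_b)):
        gam_d = np.empty((n_offspring, ha.shape[1]), dtype=np.uint8)
        gam_m = np.empty_like(gam_d)
        for pool, idx in ((ha, ~pick_b), (hb, pick_b)):
            if idx.any():
                gam_d[idx] = _transmit(
                    pool, dad[idx], length_bp, lengths_m[c], positions[c], rng
                )
                gam_m[idx] = _transmit(
                    pool, mom[idx], length_bp, lengths_m[c], positions[c], rng
                )
        h = np.empty((2 * n_offspring, ha.shape[1]), dtype=np.uint8)
        h[0::2] = gam_d
        h[1::2] = gam_m
        new.append(h)
    return new


def simulate_wright_fisher(
    config: DemographyConfig,
) -> tuple[GenotypePanel, RecombinationMap, SyntheticTruth]:
    """Simulate a genotype panel under the configured demography.

    Returns the sampled panel (monomorphic loci dropped), the true
    recombination map (one uniform window per chromosome) and a
    :class:`SyntheticTruth` record.  The same seed always reproduces the
    identical panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_chrom = config.n_chromosomes
    L = config.chromosome_length_bp
    rates = config.rates()
    lengths_m = rates * (L / 1e6) / 100.0  # genetic length in Morgans

    # SNP positions and founder frequencies
    base = config.n_snps // n_chrom
    extra = config.n_snps - base * n_chrom
    snps_per_chrom = [base + (1 if c < extra else 0) for c in range(n_chrom)]
    positions = []
    for c in range(n_chrom):
        pos = np.sort(rng.choice(L, size=snps_per_chrom[c], replace=False)) + 1
        positions.append(pos.astype(np.int64))

    total = config.total_generations
    epoch_sizes = np.concatenate(
        [np.full(d, n, dtype=int) for d, n in config.epochs]
    )
    n0 = int(epoch_sizes[0])
    pops: dict[str, list[np.ndarray]] = {}
    founders = []
    for c in range(n_chrom):
        p = rng.uniform(0.05, 0.95, size=snps_per_chrom[c])
        founders.append(
            (rng.random((2 * n0, snps_per_chrom[c])) < p).astype(np.uint8)
        )
    pops[config.base_population] = founders
    pop_sizes = {config.base_population: n0}

    splits = {int(t): (name, int(n)) for t, name, n in config.split_events}
    admixtures: dict[int, list[tuple[str, str, float]]] = {}
    for t, src, tgt, f in config.admixture_events:
        admixtures.setdefault(int(t), []).append((src, tgt, float(f)))

    for step in range(1, total + 1):
        time_ago = total - step  # age of the generation being born
        new_pops: dict[str, list[np.ndarray]] = {}
        if time_ago in splits:
            name, size = splits[time_ago]
            if name in pops:
                raise UserInputError(f"split creates existing population {name!r}")
            src = pops[config.base_population]
            new_pops[name] = _reproduce(
                src,
                src,
                np.zeros(size, dtype=bool),
                size,
                lengths_m,
                L,
                positions,
                rng,
            )
            pop_sizes[name] = size
        events = admixtures.get(time_ago, [])
        for name in sorted(pops):
            if name == config.base_population:
                n_next = int(epoch_sizes[step - 1])
            else:
                n_next = pop_sizes[name]
            pool_b = pops[name]
            pick_b = np.zeros(n_next, dtype=bool)
            pool_a = pops[name]
            for src, tgt, f in events:
                if tgt == name:
                    if src not in pops:
                        raise UserInputError(f"admixture source {src!r} unknown")
                    pick_b = rng.random(n_next) < f
                    pool_a = pops[name]
                    pool_b = pops[src]
            new_pops[name] = _reproduce(
                pool_a,
                pool_b,
                pick_b,
                n_next,
                lengths_m,
                L,
                positions,
                rng,
            )
            pop_sizes[name] = n_next
        pops = new_pops

    # sample diploids and build the panel
    sample_rows = []
    geno_blocks = []
    hap_blocks: dict[str, np.ndarray] = {}
    for name in sorted(pops):
        n_avail = pops[name][0].shape[0] // 2
        k = config.sample_size_for(name)
        if k > n_avail:
            raise UserInputError(
                f"cannot sample {k} diploids from population {name!r} of size {n_avail}"
            )
        chosen = np.sort(rng.choice(n_avail, size=k, replace=False))
        per_chrom = []
        hap_per_chrom = []
        for c in range(n_chrom):
            h = pops[name][c]
            hap = np.empty((2 * k, h.shape[1]), dtype=np.uint8)
            hap[0::2] = h[2 * chosen]
            hap[1::2] = h[2 * chosen + 1]
            hap_per_chrom.append(hap)
            per_chrom.append((hap[0::2] + hap[1::2]).astype(np.int8))
        geno_blocks.append(np.concatenate(per_chrom, axis=1))
        hap_blocks[name] = np.concatenate(hap_per_chrom, axis=1)
        width = max(3, len(str(k)))
        sample_rows += [
            (f"{name}_{i + 1:0{width}d}", name) for i in range(k)
        ]
    genotypes = np.concatenate(geno_blocks, axis=0)

    loci_rows = []
    for c in range(n_chrom):
        for j, pos in enumerate(positions[c]):
            loci_rows.append((f"snp{c + 1}_{j + 1}", c + 1, int(pos), "A", "B"))
    loci = pd.DataFrame(
        loci_rows, columns=["locus_id", "chromosome", "position_bp", "a1", "a2"]
    )
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])

    freq = genotypes.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    n_mono = int((~poly).sum())
    if not poly.any():
        raise UserInputError(
            "no polymorphic sites survived; use more sites or fewer generations"
        )
    if n_mono:
        logger.info("removed %d loci: monomorphic at sampling", n_mono)
    panel = GenotypePanel(
        loci=loci.loc[poly], samples=samples, genotypes=genotypes[:, poly]
    )

    windows = pd.DataFrame(
        {
            "chromosome": np.arange(1, n_chrom + 1),
            "start_bp": 0,
            "end_bp": L,
            "rate_cm_per_mb": rates,
        }
    )
    rmap = RecombinationMap(windows=windows)
    founder_all = np.concatenate(founders, axis=1)
    truth = SyntheticTruth(
        config=config,
        population_sizes=dict(pop_sizes),
        founder_frequencies=founder_all.mean(axis=0)[poly],
        founder_haplotypes=founder_all[:, poly],
        haplotypes={name: h[:, poly] for name, h in hap_blocks.items()},
        notes={
            "n_monomorphic_dropped": n_mono,
            "total_generations": total,
            # founder expected heterozygosity over ALL initial loci,
            # including those later dropped as monomorphic
            "founder_mean_heterozygosity": float(
                np.mean(2 * founder_all.mean(axis=0) * (1 - founder_all.mean(axis=0)))
            ),
        },
    )
    return panel, rmap, truth


def plant_autozygous_segments(
    panel: GenotypePanel,
    requests: Sequence[tuple[str, int, int, int]],
    het_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypePanel, SyntheticTruth]:
    """Force autozygosity inside requested intervals of single samples.

    Each request is ``(sample_id, chromosome, start_bp, end_bp)`` (1-based,
    inclusive).  Inside the interval the sample's genotype at each locus is
    set homozygous for an allele drawn by its panel-wide frequency, then
    flipped to heterozygous independently with ``het_error_rate`` (emulating
    genotyping error).  Requests for one sample must not overlap.
    """
    if not 0 <= het_error_rate <= 1:
        raise UserInputError("het_error_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_sample: dict[str, list[tuple[int, int, int]]] = {}
    for sid, chrom, start, end in requests:
        if end < start:
            raise UserInputError("interval end before start")
        for c0, s0, e0 in by_sample.get(sid, []):
            if c0 == chrom and s0 <= end and start <= e0:
                raise UserInputError(
                    f"overlapping planting requests for sample {sid!r}"
                )
        by_sample.setdefault(sid, []).append((chrom, start, end))

    genotypes = panel.genotypes.copy()
    chroms = panel.loci["chromosome"].to_numpy()
    positions = panel.loci["position_bp"].to_numpy()
    called = panel.genotypes != -1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(
            called.sum(axis=0) > 0,
            np.where(called, panel.genotypes, 0).sum(axis=0)
            / (2 * called.sum(axis=0)),
            0.5,
        )
    planted = []
    sample_ids = panel.samples["sample_id"].tolist()
    for sid, chrom, start, end in requests:
        if sid not in sample_ids:
            raise UserInputError(f"sample {sid!r} not in panel")
        i = sample_ids.index(sid)
        sel = np.flatnonzero(
            (chroms == chrom) & (positions >= start) & (positions <= end)
        )
        if len(sel) == 0:
            raise UserInputError(
                f"no loci inside requested interval {chrom}:{start}-{end}"
            )
        hom = np.where(rng.random(len(sel)) < freq[sel], 2, 0).astype(np.int8)
        flip = rng.random(len(sel)) < het_error_rate
        hom[flip] = 1
        genotypes[i, sel] = hom
        planted.append(
            {
                "sample_id": sid,
                "chromosome": int(chrom),
                "start_bp": int(start),
                "end_bp": int(end),
                "n_snps": int(len(sel)),
                "n_het_errors": int(flip.sum()),
                "first_snp_bp": int(positions[sel[0]]),
                "last_snp_bp": int(positions[sel[-1]]),
            }
        )
    new_panel = GenotypePanel(
        loci=panel.loci.copy(), samples=panel.samples.copy(), genotypes=genotypes
    )
    truth = SyntheticTruth(config=None, planted_segments=planted)
    return new_panel, truth


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def _fixture_configs(seed: int) -> dict[str, DemographyConfig]:
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    return {
        "panmixia": DemographyConfig(
            epochs=[(80, 80)],
            n_chromosomes=3,
            chromosome_length_bp=2_000_000,
            recombination_cm_per_mb=1.0,
            n_snps=360,
            sample_size=30,
            base_population="PANM",
            seed=seeds[0],
        ),
        "bottleneck": DemographyConfig(
            epochs=[(60, 200), (15, 12)],
            n_chromosomes=3,
            chromosome_length_bp=2_000_000,
            recombination_cm_per_mb=1.0,
            n_snps=360,
            sample_size=12,
            base_population="BTLN",
            seed=seeds[1],
        ),
        "diverged": DemographyConfig(
            epochs=[(140, 80)],
            n_chromosomes=3,
            chromosome_length_bp=2_000_000,
            recombination_cm_per_mb=1.0,
            n_snps=360,
            sample_size=20,
            split_events=[(100, "DIV2", 80)],
            base_population="DIV1",
            seed=seeds[2],
        ),
        "split_half": DemographyConfig(
            epochs=[(80, 120)],
            n_chromosomes=3,
            chromosome_length_bp=2_000_000,
            recombination_cm_per_mb=1.0,
            n_snps=360,
            sample_size=100,
            base_population="HALF",
            seed=seeds[3],
        ),
        "planted": DemographyConfig(
            epochs=[(40, 100)],
            n_chromosomes=3,
            chromosome_length_bp=2_000_000,
            recombination_cm_per_mb=1.0,
            n_snps=360,
            sample_size=10,
            base_population="PLNT",
            seed=seeds[4],
        ),
    }


def make_fixture_suite(out_dir: str | Path, seed: int) -> dict:
    """Write a suite of small PLINK-text fixtures with truth sidecars.

    Fixtures: (a) constant-N panmixia, (b) recent bottleneck, (c) two
    diverged populations, (d) one population relabelled as two halves,
    (e) panel with planted autozygous segments.  Returns (and writes) a
    manifest recording seeds and parameters; regenerating from the manifest
    seeds reproduces identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    configs = _fixture_configs(seed)
    manifest: dict = {"seed": int(seed), "fixtures": {}}
    for name, cfg in configs.items():
        panel, rmap, truth = simulate_wright_fisher(cfg)
        if name == "split_half":
            half = panel.n_samples // 2
            pops = ["HALF1"] * half + ["HALF2"] * (panel.n_samples - half)
            panel = GenotypePanel(
                loci=panel.loci,
                samples=panel.samples.assign(population=pops),
                genotypes=panel.genotypes,
            )
        planted_truth = None
        if name == "planted":
            sid = panel.samples["sample_id"].iloc[0]
            requests = [
                (sid, 1, 300_000, 1_500_000),
                (sid, 3, 500_000, 1_400_000),
            ]
            panel, planted_truth = plant_autozygous_segments(
                panel, requests, het_error_rate=0.01, seed=cfg.seed + 1
            )
        ped = out_dir / f"{name}.ped"
        map_ = out_dir / f"{name}.map"
        rmap_path = out_dir / f"{name}.rmap.tsv"
        write_plink_text(panel, ped, map_)
        write_recombination_map(rmap, rmap_path)
        sidecar = {
            "config": {
                "epochs": [list(e) for e in cfg.epochs],
                "n_chromosomes": cfg.n_chromosomes,
                "chromosome_length_bp": cfg.chromosome_length_bp,
                "recombination_cm_per_mb": cfg.recombination_cm_per_mb
                if np.isscalar(cfg.recombination_cm_per_mb)
                else list(cfg.recombination_cm_per_mb),
                "n_snps": cfg.n_snps,
                "sample_size": cfg.sample_size,
                "split_events": [list(e) for e in cfg.split_events],
                "seed": cfg.seed,
                "base_population": cfg.base_population,
            },
            "population_sizes": truth.population_sizes,
            "planted_segments": planted_truth.planted_segments
            if planted_truth
            else [],
        }
        sidecar_path = out_dir / f"{name}.truth.json"
        sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        manifest["fixtures"][name] = {
            "ped": ped.name,
            "map": map_.name,
            "recombination_map": rmap_path.name,
            "truth": sidecar_path.name,
            "seed": cfg.seed,
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
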