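from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpdemog import (
    DemographyConfig,
    GenotypePanel,
    simulate_wright_fisher,
)


def build_panel(
    genotypes,
    positions=None,
    chromosomes=None,
    populations=None,
    locus_prefix="L",
) -> GenotypePanel:
    """Construct a small panel from a genotype matrix (rows = samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = g.shape
    if positions is None:
        positions = (np.arange(n_loci) + 1) * 100_000
    if chromosomes is None:
        chromosomes = np.ones(n_loci, dtype=int)
    if populations is None:
        populations = ["POP"] * n_samples
    loci = pd.DataFrame(
        {
            "locus_id": [f"{locus_prefix}{j + 1}" for j in range(n_loci)],
            "chromosome": np.asarray(chromosomes, dtype=int),
            "position_bp": np.asarray(positions, dtype=int),
            "a1": ["A"] * n_loci,
            "a2": ["B"] * n_loci,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n_samples)],
            "population": populations,
        }
    )
    return GenotypePanel(loci=loci, samples=samples, genotypes=g)


@pytest.fixture(scope="session")
def wf_small():
    """Small constant-size panmictic simulation shared across tests."""
    cfg = DemographyConfig(
        epochs=[(120, 60)],
        n_chromosomes=3,
        chromosome_length_bp=2_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=300,
        sample_size=25,
        seed=20_001,
    )
    return simulate_wright_fisher(cfg)


@pytest.fixture(scope="session")
def split_half_panel():
    """One panmictic population sampled at 100 and relabelled as two
    50-sample halves (null model for differentiation and phase)."""
    cfg = DemographyConfig(
        epochs=[(400, 120)],
        n_chromosomes=10,
        chromosome_length_bp=3_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=1_200,
        sample_size=100,
        base_population="HALF",
        seed=20_002,
    )
    panel, rmap, truth = simulate_wright_fisher(cfg)
    pops = ["HALF1"] * 50 + ["HALF2"] * (panel.n_samples - 50)
    panel = GenotypePanel(
        loci=panel.loci,
        samples=panel.samples.assign(population=pops),
        genotypes=panel.genotypes,
    )
    return panel, rmap, truth


@pytest.fixture(scope="session")
def diverged_panels():
    """Two populations split 180 generations ago at size 150 each."""
    cfg = DemographyConfig(
        epochs=[(300, 150)],
        n_chromosomes=10,
        chromosome_length_bp=3_000_000,
        recombination_cm_per_mb=1.0,
        n_snps=1_600,
        sample_size=30,
        split_events=[(180, "DIV2", 150)],
        base_population="DIV1",
        seed=20_003,
    )
    return simulate_wright_fisher(cfg)
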