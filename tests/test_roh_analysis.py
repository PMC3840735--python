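from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import build_panel
from snpdemog import (
    MISSING,
    RecombinationMap,
    ROHParams,
    chromosome_correlation_matrix,
    detect_roh,
    detect_roh_all,
    plant_autozygous_segments,
    summarize_roh,
)
from snpdemog.errors import UserInputError


def _single_sample_panel(genotypes, positions, chromosomes=None):
    g = np.asarray(genotypes, dtype=np.int8).reshape(1, -1)
    return build_panel(g, positions=positions, chromosomes=chromosomes)


def _assert_run_valid_and_maximal(panel, sample_row, rec, params):
    """Independent checker: the emitted run satisfies every constraint and
    cannot be extended by one SNP in either direction."""
    chroms = panel.loci["chromosome"].to_numpy()
    pos = panel.loci["position_bp"].to_numpy()
    sel = np.flatnonzero(chroms == rec.chromosome)
    p = pos[sel]
    g = panel.genotypes[sample_row, sel]
    l = int(np.flatnonzero(p == rec.start_bp)[0])
    r = int(np.flatnonzero(p == rec.end_bp)[0])
    window = g[l : r + 1]
    n_het = int((window == 1).sum())
    n_miss = int((window == MISSING).sum())
    n_hom = len(window) - n_het - n_miss
    length = p[r] - p[l] + 1
    assert g[l] not in (1, MISSING) and g[r] not in (1, MISSING)
    assert n_het <= params.max_het and n_miss <= params.max_missing
    assert n_hom >= params.min_snps
    assert length >= params.min_length_bp
    assert len(window) / (length / 1e6) >= params.min_density_snp_per_mb
    assert (np.diff(p[l : r + 1]) <= params.max_gap_bp).all()

    def extension_violates(lo, hi, edge):
        if edge < 0 or edge >= len(p):
            return True  # chromosome end
        w = g[lo : hi + 1]
        if g[edge] in (1, MISSING) and (
            (edge == lo and g[edge] == 1 and (w == 1).sum() > params.max_het)
            or (edge == lo and g[edge] == MISSING and (w == MISSING).sum() > params.max_missing)
            or g[edge] in (1, MISSING)  # non-homozygous boundary
        ):
            return True
        if (w == 1).sum() > params.max_het or (w == MISSING).sum() > params.max_missing:
            return True
        gap = p[lo + 1 : hi + 1] - p[lo:hi]
        return bool((gap > params.max_gap_bp).any())

    assert extension_violates(l - 1, r, l - 1)
    assert extension_violates(l, r + 1, r + 1)


class TestDetectROH:
    def test_fully_homozygous_single_run(self):
        pos = np.linspace(1, 5_000_000, 100).astype(int)
        panel = _single_sample_panel(np.full(100, 2), pos)
        runs = detect_roh(panel, "S1")
        assert len(runs) == 1
        assert runs[0].start_bp == pos[0] and runs[0].end_bp == pos[-1]
        assert runs[0].n_snps == 100

    def test_alternating_genotypes_no_run(self):
        pos = np.arange(1, 101) * 50_000
        g = np.tile([2, 1], 50)
        assert detect_roh(_single_sample_panel(g, pos), "S1") == []

    def test_short_stretch_fails_length_rule(self):
        pos = np.arange(30) * 275 + 1  # 30 SNPs in ~8 kb
        runs = detect_roh(_single_sample_panel(np.full(30, 2), pos), "S1")
        assert runs == []

    def test_large_gap_splits_runs(self):
        pos = np.concatenate([np.arange(30) * 20_000 + 1, np.arange(30) * 20_000 + 1_800_001])
        runs = detect_roh(_single_sample_panel(np.full(60, 0), pos), "S1")
        assert len(runs) == 2
        assert runs[0].end_bp < 1_800_001 <= runs[1].start_bp

    def test_one_heterozygote_tolerated_two_not(self):
        pos = np.arange(60) * 20_000 + 1
        g = np.full(60, 2)
        g[30] = 1
        runs = detect_roh(_single_sample_panel(g, pos), "S1")
        assert len(runs) == 1 and runs[0].n_het == 1
        g2 = g.copy()
        g2[15] = 1
        runs2 = detect_roh(_single_sample_panel(g2, pos), "S1")
        # two hets cannot share one run; the scan returns pieces instead
        assert all(r.n_het <= 1 for r in runs2)
        assert len(runs2) >= 1

    def test_emitted_runs_satisfy_constraints_and_are_maximal(self):
        rng = np.random.default_rng(12)
        params = ROHParams()
        for trial in range(10):
            n = 400
            pos = np.sort(rng.choice(8_000_000, n, replace=False)) + 1
            g = rng.choice([0, 1, 2, MISSING], size=n, p=[0.35, 0.2, 0.35, 0.1])
            # embed a homozygous block to guarantee some runs
            g[100:180] = 2
            panel = _single_sample_panel(g, pos)
            for rec in detect_roh(panel, "S1", params):
                _assert_run_valid_and_maximal(panel, 0, rec, params)

    def test_runs_never_overlap(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(6_000_000, 300, replace=False)) + 1
        g = rng.choice([0, 1, 2], size=300, p=[0.45, 0.1, 0.45])
        runs = detect_roh(_single_sample_panel(g, pos), "S1")
        runs.sort(key=lambda r: (r.chromosome, r.start_bp))
        for a, b in zip(runs, runs[1:]):
            if a.chromosome == b.chromosome:
                assert b.start_bp > a.end_bp

    def test_order_independence(self, wf_small):
        panel, _, _ = wf_small
        perm = np.random.default_rng(1).permutation(panel.n_samples)
        shuffled = panel.restrict_samples(np.ones(panel.n_samples, dtype=bool))
        shuffled.samples = shuffled.samples.iloc[perm].reset_index(drop=True)
        shuffled.genotypes = shuffled.genotypes[perm]
        a = detect_roh_all(panel).sort_values(["sample_id", "chromosome", "start_bp"])
        b = detect_roh_all(shuffled).sort_values(["sample_id", "chromosome", "start_bp"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


class TestPlantedRecovery:
    def _het_background_panel(self, rng, n_samples=4, n_chrom=3):
        per_chrom = 160
        positions = []
        chroms = []
        for c in range(n_chrom):
            positions.append(np.sort(rng.choice(5_000_000, per_chrom, replace=False)) + 1)
            chroms.append(np.full(per_chrom, c + 1))
        g = np.ones((n_samples, per_chrom * n_chrom), dtype=np.int8)
        # keep allele frequencies informative for the planting draw
        return build_panel(
            g, positions=np.concatenate(positions), chromosomes=np.concatenate(chroms)
        )

    def test_recovery_with_one_het_error(self):
        rng = np.random.default_rng(77)
        panel = self._het_background_panel(rng)
        requests, k = [], 0
        for sid in panel.samples["sample_id"]:
            for chrom in (1, 2, 3):
                start = 500_000 + (k % 3) * 100_000
                requests.append((sid, chrom, start, start + 2_000_000))
                k += 1
        planted, truth = plant_autozygous_segments(panel, requests, het_error_rate=0.01, seed=5)
        rohs = detect_roh_all(planted)
        for seg in truth.planted_segments:
            if seg["n_het_errors"] > 1:
                continue
            sub = rohs[
                (rohs["sample_id"] == seg["sample_id"])
                & (rohs["chromosome"] == seg["chromosome"])
            ]
            assert len(sub) == 1, f"segment {seg} not recovered"
            run = sub.iloc[0]
            sel = (planted.loci["chromosome"] == seg["chromosome"]) & (
                planted.loci["position_bp"].between(seg["start_bp"], seg["end_bp"])
            )
            seg_pos = planted.loci.loc[sel, "position_bp"].to_numpy()
            assert run["start_bp"] <= seg_pos[1]  # at worst one interval in
            assert run["end_bp"] >= seg_pos[-2]
            assert run["start_bp"] >= seg["first_snp_bp"]
            assert run["end_bp"] <= seg["last_snp_bp"]

    def test_fully_heterozygous_yields_no_roh(self):
        pos = np.arange(1, 201) * 20_000
        panel = _single_sample_panel(np.ones(200), pos)
        assert detect_roh(panel, "S1") == []

    def test_planting_rate_extremes(self, wf_small):
        panel, _, _ = wf_small
        sid = panel.samples["sample_id"].iloc[0]
        req = [(sid, 1, 100_000, 1_900_000)]
        p0, t0 = plant_autozygous_segments(panel, req, het_error_rate=0.0, seed=1)
        sel = (p0.loci["chromosome"] == 1) & p0.loci["position_bp"].between(100_000, 1_900_000)
        assert (p0.genotypes[0, sel.to_numpy()] != 1).all()
        p1, _ = plant_autozygous_segments(panel, req, het_error_rate=1.0, seed=1)
        assert (p1.genotypes[0, sel.to_numpy()] == 1).all()

    def test_overlapping_requests_rejected(self, wf_small):
        panel, _, _ = wf_small
        sid = panel.samples["sample_id"].iloc[0]
        with pytest.raises(UserInputError, match="overlap"):
            plant_autozygous_segments(
                panel, [(sid, 1, 1, 500_000), (sid, 1, 400_000, 900_000)], seed=1
            )


class TestSummaries:
    def test_arithmetic_example(self):
        pos = np.arange(1, 2001) * 100_000  # one chromosome spanning ~200 Mb
        panel = build_panel(
            np.ones((8, 2000), dtype=np.int8), positions=pos
        )
        span = pos[-1] - pos[0] + 1
        rohs = pd.DataFrame(
            {
                "sample_id": ["S1", "S1", "S2", "S3", "S4"],
                "chromosome": 1,
                "start_bp": [1, 1, 1, 1, 1],
                "end_bp": [10_000_000, 30_000_000, 120_000_000, 60_000_000, 110_000_000],
                "length_bp": [10_000_000, 30_000_000, 120_000_000, 60_000_000, 110_000_000],
                "n_snps": 100,
                "n_het": 0,
                "n_missing": 0,
            }
        )
        summary = summarize_roh(rohs, panel)
        s1 = summary.per_sample.set_index("sample_id").loc["S1"]
        assert s1["n_roh"] == 2
        assert s1["total_length_bp"] == 40_000_000
        assert s1["mean_length_bp"] == 20_000_000
        assert s1["fraction_genome"] == pytest.approx(40_000_000 / span)
        # zero-ROH samples stay in the population means
        pop = summary.per_population.iloc[0]
        assert pop["n_samples"] == 8
        assert pop["prop_long_roh"] == pytest.approx(2 / 8)  # 120 Mb and 110 Mb runs
        assert pop["prop_mid_roh"] == pytest.approx(1 / 8)  # the 60 Mb run

    def test_fully_autozygous_fraction_near_one(self):
        pos = np.linspace(1, 80_000_000, 400).astype(int)
        panel = _single_sample_panel(np.full(400, 2), pos)
        rohs = detect_roh_all(panel)
        summary = summarize_roh(rohs, panel)
        assert summary.per_sample["fraction_genome"].iloc[0] > 0.95


class TestCorrelationMatrix:
    def _inputs(self, roh_lengths):
        ld = pd.DataFrame(
            {
                "chromosome": ["1", "2", "3", "4", "Total"],
                "mean_r2": [0.1, 0.2, 0.3, 0.4, 0.25],
                "sd_r2": 0.1,
                "n_pairs": 10,
            }
        )
        rohs = pd.DataFrame(
            {
                "sample_id": "S1",
                "chromosome": [1, 2, 3, 4],
                "start_bp": 1,
                "end_bp": roh_lengths,
                "length_bp": roh_lengths,
                "n_snps": 30,
                "n_het": 0,
                "n_missing": 0,
            }
        )
        rmap = RecombinationMap(
            windows=pd.DataFrame(
                {
                    "chromosome": [1, 2, 3, 4],
                    "start_bp": 0,
                    "end_bp": 10_000_000,
                    "rate_cm_per_mb": [4.0, 3.0, 2.0, 1.0],
                }
            )
        )
        return ld, rohs, rmap

    def test_perfect_correlations(self):
        ld, rohs, rmap = self._inputs([1_000_000, 2_000_000, 3_000_000, 4_000_000])
        rho, pval = chromosome_correlation_matrix(ld, rohs, rmap)
        assert rho.loc["mean_r2", "mean_roh_length_bp"] == pytest.approx(1.0)
        assert rho.loc["mean_roh_length_bp", "rate_cm_per_mb"] == pytest.approx(-1.0)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)

    def test_too_few_chromosomes_error(self):
        ld, rohs, rmap = self._inputs([1_000_000, 2_000_000, 3_000_000, 4_000_000])
        with pytest.raises(UserInputError, match="3 chromosomes"):
            chromosome_correlation_matrix(ld.iloc[:2], rohs, rmap)
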