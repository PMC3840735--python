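from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hwe_exact_enumeration
from snpdemog import (
    MISSING,
    apply_ld_qc,
    filter_panel,
    hwe_exact_test,
    read_plink_binary,
    read_plink_text,
    read_recombination_map,
    write_plink_binary,
    write_plink_text,
)
from snpdemog.errors import ParseError, UserInputError
from conftest import build_panel


def _write(path, text):
    path.write_text(text)
    return path


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

class TestPlinkText:
    def test_recoding_convention(self, tmp_path):
        """a1 is the first allele seen in file order; genotypes count a1."""
        ped = _write(tmp_path / "x.ped", "F1 S1 0 0 1 -9 A A C G\n")
        map_ = _write(tmp_path / "x.map", "1 rs1 0 100\n1 rs2 0 200\n")
        panel = read_plink_text(ped, map_)
        assert panel.n_samples == 1 and panel.n_loci == 2
        assert panel.genotypes.tolist() == [[2, 1]]
        assert panel.loci["a1"].tolist() == ["A", "C"]
        assert panel.samples["population"].tolist() == ["F1"]

    def test_zero_zero_is_missing(self, tmp_path):
        ped = _write(tmp_path / "x.ped", "F1 S1 0 0 1 -9 0 0\nF1 S2 0 0 1 -9 A A\n")
        map_ = _write(tmp_path / "x.map", "1 rs1 0 100\n")
        panel = read_plink_text(ped, map_)
        assert panel.genotypes[0, 0] == MISSING
        assert panel.genotypes[1, 0] == 2  # A first seen -> a1

    def test_file_round_trip_identity(self, tmp_path, wf_small):
        """write(read(file)) reproduces the .ped/.map files byte for byte,
        and genotype codes are stable after one read-write cycle."""
        panel, _, _ = wf_small
        write_plink_text(panel, tmp_path / "a.ped", tmp_path / "a.map")
        once = read_plink_text(tmp_path / "a.ped", tmp_path / "a.map")
        write_plink_text(once, tmp_path / "b.ped", tmp_path / "b.map")
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()
        assert (tmp_path / "a.map").read_bytes() == (tmp_path / "b.map").read_bytes()
        twice = read_plink_text(tmp_path / "b.ped", tmp_path / "b.map")
        assert twice.equals(once)
        assert once.loci["locus_id"].tolist() == panel.loci["locus_id"].tolist()
        assert once.samples["sample_id"].tolist() == panel.samples["sample_id"].tolist()

    def test_ragged_row_names_line(self, tmp_path):
        ped = _write(tmp_path / "x.ped", "F1 S1 0 0 1 -9 A A\nF1 S2 0 0 1 -9 A\n")
        map_ = _write(tmp_path / "x.map", "1 rs1 0 100\n")
        with pytest.raises(ParseError, match="x.ped:2"):
            read_plink_text(ped, map_)

    def test_duplicate_locus_ids_rejected(self, tmp_path):
        ped = _write(tmp_path / "x.ped", "F1 S1 0 0 1 -9 A A G G\n")
        map_ = _write(tmp_path / "x.map", "1 rs1 0 100\n1 rs1 0 200\n")
        with pytest.raises(UserInputError, match="duplicate locus ids"):
            read_plink_text(ped, map_)

    def test_sex_chromosomes_dropped_bad_code_rejected(self, tmp_path):
        ped = _write(tmp_path / "x.ped", "F1 S1 0 0 1 -9 A A C C\n")
        map_ = _write(tmp_path / "x.map", "1 rs1 0 100\nX rsx 0 200\n")
        panel = read_plink_text(ped, map_)
        assert panel.n_loci == 1 and panel.loci["locus_id"].tolist() == ["rs1"]
        map_bad = _write(tmp_path / "y.map", "1 rs1 0 100\nZZ rs2 0 200\n")
        with pytest.raises(ParseError, match="chromosome code"):
            read_plink_text(ped, map_bad)


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

class TestPlinkBinary:
    def _fileset(self, tmp_path, bed_bytes, n_samples=4, n_loci=1):
        bed = tmp_path / "x.bed"
        bed.write_bytes(bed_bytes)
        bim = _write(
            tmp_path / "x.bim",
            "".join(f"1\trs{j}\t0\t{100 * (j + 1)}\tA\tG\n" for j in range(n_loci)),
        )
        fam = _write(
            tmp_path / "x.fam",
            "".join(f"F1 S{i} 0 0 0 -9\n" for i in range(n_samples)),
        )
        return bed, bim, fam

    def test_two_bit_code_table(self, tmp_path):
        """Byte 0b11_10_01_00 decodes to [2, MISSING, 1, 0] in sample order."""
        bed, bim, fam = self._fileset(tmp_path, b"\x6c\x1b\x01" + bytes([0b11100100]))
        panel = read_plink_binary(bed, bim, fam)
        assert panel.genotypes[:, 0].tolist() == [2, MISSING, 1, 0]
        assert panel.loci["a1"].tolist() == ["A"]

    def test_round_trip_and_cross_format(self, tmp_path, wf_small):
        """Binary round-trips are lossless (the .bim fixes allele order);
        text and binary readers agree on a text-canonical panel."""
        panel, _, _ = wf_small
        write_plink_binary(panel, tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
        back = read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
        assert back.equals(panel)
        # canonicalize allele order through one text cycle, then compare
        write_plink_text(panel, tmp_path / "c.ped", tmp_path / "c.map")
        canon = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        write_plink_binary(canon, tmp_path / "d.bed", tmp_path / "d.bim", tmp_path / "d.fam")
        from_bin = read_plink_binary(tmp_path / "d.bed", tmp_path / "d.bim", tmp_path / "d.fam")
        from_text = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        assert np.array_equal(from_text.genotypes, from_bin.genotypes)
        assert from_text.loci["a1"].tolist() == from_bin.loci["a1"].tolist()

    def test_individual_major_unsupported(self, tmp_path):
        bed, bim, fam = self._fileset(tmp_path, b"\x6c\x1b\x00" + b"\x00")
        with pytest.raises(UserInputError, match="individual-major"):
            read_plink_binary(bed, bim, fam)

    def test_bad_magic_and_length(self, tmp_path):
        bed, bim, fam = self._fileset(tmp_path, b"\x00\x00\x01" + b"\x00")
        with pytest.raises(ParseError, match="magic"):
            read_plink_binary(bed, bim, fam)
        bed2, bim2, fam2 = self._fileset(tmp_path, b"\x6c\x1b\x01" + b"\x00\x00")
        with pytest.raises(ParseError, match="bytes"):
            read_plink_binary(bed2, bim2, fam2)

    def test_allele_coding_stable_under_sample_permutation(self, tmp_path, wf_small):
        panel, _, _ = wf_small
        write_plink_binary(panel, tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        perm = np.random.default_rng(0).permutation(panel.n_samples)
        shuffled = panel.restrict_samples(np.zeros(panel.n_samples, dtype=bool) | True)
        shuffled = build_panel(
            panel.genotypes[perm],
            positions=panel.loci["position_bp"],
            chromosomes=panel.loci["chromosome"],
            populations=panel.samples["population"].to_numpy()[perm].tolist(),
        )
        write_plink_binary(shuffled, tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
        a = read_plink_binary(tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        s = read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")
        assert a.loci["a1"].tolist() == panel.loci["a1"].tolist()
        assert s.loci["a1"].tolist() == shuffled.loci["a1"].tolist()


# ---------------------------------------------------------------------------
# recombination map
# ---------------------------------------------------------------------------

class TestRecombinationMap:
    def test_row_parse_and_header(self, tmp_path):
        path = _write(
            tmp_path / "m.tsv",
            "chrom start end rate\n1 0 1000000 0.36\n1 1000000 2000000 1.5\n",
        )
        rmap = read_recombination_map(path)
        w = rmap.windows
        assert tuple(w.iloc[0]) == (1, 0, 1_000_000, 0.36)
        assert len(w) == 2

    def test_mean_rate_weighted(self, tmp_path):
        path = _write(tmp_path / "m.tsv", "1 0 1000000 0.5\n1 1000000 2000000 1.5\n")
        rmap = read_recombination_map(path)
        assert rmap.mean_rate() == pytest.approx(1.0)
        assert rmap.rate_in_interval(1, 0, 2_000_000) == (pytest.approx(1.0), 2_000_000)

    def test_negative_rate_and_overlap_rejected(self, tmp_path):
        with pytest.raises(UserInputError, match="negative"):
            read_recombination_map(
                _write(tmp_path / "n.tsv", "1 0 1000000 -0.5\n")
            )
        with pytest.raises(UserInputError, match="overlap"):
            read_recombination_map(
                _write(tmp_path / "o.tsv", "1 0 1000000 0.5\n1 500000 1500000 1.0\n")
            )

    def test_empty_map(self, tmp_path):
        rmap = read_recombination_map(_write(tmp_path / "e.tsv", ""))
        assert rmap.is_empty


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

class TestFilterPanel:
    def _panel_with_missing(self, n_missing_locus1, n_missing_locus2, n=97):
        g = np.ones((n, 2), dtype=np.int8)
        g[:n_missing_locus1, 0] = MISSING
        g[:n_missing_locus2, 1] = MISSING
        return build_panel(g)

    def test_five_percent_threshold(self):
        panel = self._panel_with_missing(6, 4)  # 6.2% vs 4.1%
        out = filter_panel(panel, 0.05)
        assert out.loci["locus_id"].tolist() == ["L2"]

    def test_vacuous_threshold_keeps_all(self):
        panel = self._panel_with_missing(6, 4)
        assert filter_panel(panel, 1.0).n_loci == 2

    def test_all_removed_is_error(self):
        panel = self._panel_with_missing(97, 97)
        with pytest.raises(UserInputError, match="threshold"):
            filter_panel(panel, 0.05)

    def test_idempotent(self):
        panel = self._panel_with_missing(6, 4)
        once = filter_panel(panel, 0.05)
        twice = filter_panel(once, 0.05)
        assert twice.equals(once)


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_reference_table_matches_enumeration(self):
        p = hwe_exact_test(57, 78, 46)
        assert p == pytest.approx(hwe_exact_enumeration(57, 78, 46), abs=1e-12)

    def test_max_heterozygosity_table(self):
        for n in (4, 9, 30):
            p = hwe_exact_test(0, n, 0)
            assert p == pytest.approx(hwe_exact_enumeration(0, n, 0), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(0, 70),
        st.integers(0, 70),
        st.integers(0, 60),
    )
    def test_agrees_with_enumeration(self, a, b, c):
        if a + b + c == 0:
            a = 1
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_exact_enumeration(a, b, c), abs=1e-12
        )


class TestApplyLdQc:
    def _panel(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(25, 6)).astype(np.int8)
        g[:, 0] = 2  # monomorphic -> MAF 0
        g[:, 1] = np.where(rng.random(25) < 0.97, 2, 1)  # MAF ~0.015
        g[:12, 2] = 2
        g[12:, 2] = 0  # no hets at intermediate freq -> extreme HWE deviation
        return build_panel(g)

    def test_maf_filter(self):
        panel = self._panel()
        out = apply_ld_qc(panel, "POP", maf_min=0.05, hwe_p_min=0.0)
        assert "L1" not in out.loci["locus_id"].tolist()
        assert "L2" not in out.loci["locus_id"].tolist()

    def test_hwe_filter(self):
        panel = self._panel()
        out = apply_ld_qc(panel, "POP", maf_min=0.05, hwe_p_min=0.001)
        assert "L3" not in out.loci["locus_id"].tolist()

    def test_vacuous_filters_keep_loci(self):
        panel = self._panel()
        out = apply_ld_qc(panel, "POP", maf_min=0.0, hwe_p_min=0.0)
        assert out.n_loci == panel.n_loci
        assert out.n_samples == panel.n_samples

    def test_idempotent(self):
        panel = self._panel()
        once = apply_ld_qc(panel, "POP", maf_min=0.05, hwe_p_min=0.001)
        twice = apply_ld_qc(once, "POP", maf_min=0.05, hwe_p_min=0.001)
        assert twice.equals(once)

    def test_unknown_population_lists_labels(self):
        with pytest.raises(UserInputError, match="POP"):
            apply_ld_qc(self._panel(), "NOPE")
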