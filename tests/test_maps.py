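import numpy as np
import pandas as pd
import pytest

from snpdesign import maps
from snpdesign.maps import (
    CandidateMap,
    HaplotypePanel,
    MapValidationError,
    SnpRecord,
    chrom_ordinal,
    read_candidate_map,
    read_haplotypes,
    read_selection,
    write_selection,
)
from snpdesign.optimizer import SelectionResult


def write_tsv(path, rows, header="snp_id\tchrom\tpos\tmaf\tobligatory"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestReadCandidateMap:
    def test_four_row_tsv(self, tmp_path):
        p = tmp_path / "map.tsv"
        write_tsv(p, [
            "A\t1\t10\t0.4239\t0",
            "B\t1\t48\t0.3524\t0",
            "C\t1\t50\t0.2000\t1",
            "D\t1\t90\t0.1708\t0",
        ])
        cmap = read_candidate_map(p, "tsv")
        assert len(cmap) == 4
        assert cmap.chromosomes == [1]
        assert list(cmap.positions(1)) == [10, 48, 50, 90]
        assert cmap.obligatory_ids() == ["C"]
        assert cmap.chrom_length(1) == 80  # span default

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("")
        with pytest.raises(MapValidationError):
            read_candidate_map(p, "tsv")

    def test_header_only_errors(self, tmp_path):
        p = tmp_path / "map.tsv"
        write_tsv(p, [])
        with pytest.raises(MapValidationError):
            read_candidate_map(p, "tsv")

    def test_maf_out_of_range_errors(self, tmp_path):
        p = tmp_path / "map.tsv"
        write_tsv(p, ["A\t1\t10\t0.6\t0"])
        with pytest.raises(MapValidationError, match="MAF"):
            read_candidate_map(p, "tsv")

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "map.tsv"
        write_tsv(p, ["A\t1\t10\t0.2\t0", "A\t1\t20\t0.3\t0"])
        with pytest.raises(MapValidationError, match="duplicate"):
            read_candidate_map(p, "tsv")

    def test_missing_position_flagged_no_map(self, tmp_path):
        p = tmp_path / "map.tsv"
        write_tsv(p, ["A\t1\t10\t0.2\t0", "B\t\t\t0.3\t1"])
        cmap = read_candidate_map(p, "tsv")
        assert len(cmap.unmapped) == 1
        assert cmap.unmapped["snp_id"].iloc[0] == "B"
        assert len(cmap.mapped) == 1

    def test_plink_pair(self, tmp_path):
        (tmp_path / "chip.bim").write_text(
            "1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tA\tG\nX\trs3\t0\t50\tA\tG\n"
        )
        (tmp_path / "chip.frq").write_text(
            " CHR  SNP  A1  A2  MAF  NCHROBS\n"
            " 1  rs1  A  G  0.25  100\n"
            " 1  rs2  A  G  0.4  100\n"
            " X  rs3  A  G  0.1  100\n"
        )
        cmap = read_candidate_map(tmp_path / "chip", "plink")
        assert cmap.chromosomes == [1, 30]  # X carried as ordinal 30
        assert cmap.chromosome(1)["maf"].tolist() == [0.25, 0.4]


def test_chrom_ordinal_x_is_30():
    assert chrom_ordinal("X") == 30
    assert chrom_ordinal("chr5") == 5
    assert chrom_ordinal(12) == 12


def test_duplicate_positions_keep_higher_maf():
    cmap = CandidateMap([
        SnpRecord("lo", 1, 100, 0.1),
        SnpRecord("hi", 1, 100, 0.4),
        SnpRecord("z", 1, 200, 0.2),
    ])
    assert cmap.chromosome(1)["snp_id"].tolist() == ["hi", "z"]


class TestHaplotypes:
    def test_symmetric_matrix(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("s1\ts2\n0\t0\n0\t1\n1\t0\n1\t1\n")
        panel = read_haplotypes(p, "matrix_tsv")
        assert panel.n_haplotypes == 4
        assert np.allclose(panel.frequencies(), [0.5, 0.5])

    def test_entry_two_errors(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("s1\n0\n2\n")
        with pytest.raises(MapValidationError, match="0/1"):
            read_haplotypes(p, "matrix_tsv")

    def test_unphased_vcf_errors(self, tmp_path):
        p = tmp_path / "h.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(MapValidationError, match="phased"):
            read_haplotypes(p, "vcf")

    def test_phased_vcf_round_trip(self, tmp_path):
        from snpdesign.simulate import write_haplotypes_vcf
        from tests.conftest import make_map

        cmap = make_map(n_candidates=10, n_chromosomes=1, seed=5)
        from snpdesign import simulate_haplotypes

        panel = simulate_haplotypes(cmap, 8, 1e4, seed=6)
        path = tmp_path / "h.vcf"
        write_haplotypes_vcf(panel, cmap, path)
        back = read_haplotypes(path, "vcf")
        assert back.n_haplotypes == 8
        assert np.array_equal(back.allele_matrix, panel.allele_matrix)
        assert back.snp_ids == panel.snp_ids

    def test_align_unknown_id_errors(self):
        panel = HaplotypePanel(np.zeros((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(MapValidationError, match="not in panel"):
            panel.align(["a", "zzz"])

    def test_panel_frequency_matches_map_maf(self):
        # a map whose MAFs were taken from the panel agrees to within the
        # panel's own frequency resolution 1/(2 * haplotype count)
        mat = np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0], [1, 1, 0]])
        panel = HaplotypePanel(mat, ["s0", "s1", "s2"])
        cmap = CandidateMap([
            SnpRecord(f"s{i}", 1, 100 * (i + 1), float(f))
            for i, f in enumerate(panel.frequencies())
        ])
        tol = 1.0 / (2 * panel.n_haplotypes)
        recomputed = panel.align(list(cmap.mapped["snp_id"])).frequencies()
        assert np.all(np.abs(recomputed - cmap.mapped["maf"].to_numpy()) <= tol)


class TestSelectionIO:
    def _result(self):
        chosen = pd.DataFrame({
            "snp_id": ["A", "B", "U"],
            "chrom": [1, 1, None],
            "pos": [10.0, 90.0, None],
            "maf": [0.4, 0.3, 0.2],
            "provenance": ["boundary", "optimized", "obligatory_unmapped"],
            "bin_index": [0, 1, -1],
        })
        return SelectionResult(chosen, 0.9, {"gamma": 0.5})

    def test_round_trip(self, tmp_path):
        res = self._result()
        path = tmp_path / "sel.tsv"
        write_selection(res, path)
        back = read_selection(path)
        assert back["snp_id"].tolist() == ["A", "B", "U"]
        assert back["provenance"].tolist() == [
            "boundary", "optimized", "obligatory_unmapped"]
        assert back["pos"].tolist()[:2] == [10.0, 90.0]
        assert pd.isna(back["pos"].iloc[2])  # unplaced obligatory: empty pos
        assert (tmp_path / "sel.tsv.json").exists()

    def test_empty_selection_header_only(self, tmp_path):
        res = SelectionResult(pd.DataFrame(columns=maps.SELECTION_COLUMNS), 0.0)
        path = tmp_path / "sel.tsv"
        write_selection(res, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == maps.SELECTION_COLUMNS
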