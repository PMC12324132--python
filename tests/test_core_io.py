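import numpy as np
import pytest

import popstruct as ps
from popstruct.core_io import InputError, write_snp_panel


def write(path, text):
    path.write_text(text)
    return str(path)


class TestSnpPanel:
    def test_biallelic_row_parses(self, tmp_path):
        p = write(
            tmp_path / "p.tsv",
            "rsid\tregion\trisk_allele\tother_alleles\todds_ratio\tgenes\n"
            "rs17042852\t2p16.3\tC\tT\t2.82\tLINC01867\n",
        )
        panel = ps.read_snp_panel(p)
        rec = panel["rs17042852"]
        assert rec.risk_allele == "C"
        assert rec.other_alleles == ("T",)
        assert rec.odds_ratio == 2.82
        assert rec.alleles == ("C", "T")

    def test_triallelic_row_parses(self, tmp_path):
        p = write(
            tmp_path / "p.tsv",
            "rsid\tregion\trisk_allele\tother_alleles\todds_ratio\tgenes\n"
            "rs3922636\t8q21.13\tA\tC,G\t2.98\tRPL3P9,MITA1\n",
        )
        rec = ps.read_snp_panel(p)["rs3922636"]
        assert rec.other_alleles == ("C", "G")
        assert len(rec.alleles) == 3

    @pytest.mark.parametrize(
        "row",
        [
            "rs1\t1p1\tA\tG\t0\tX",       # OR zero
            "rs1\t1p1\tA\tG\t-1.2\tX",    # OR negative
            "rs1\t1p1\tA\tA,G\t1.5\tX",   # risk allele among others
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, row):
        p = write(
            tmp_path / "p.tsv",
            "rsid\tregion\trisk_allele\tother_alleles\todds_ratio\tgenes\n" + row + "\n",
        )
        with pytest.raises(InputError):
            ps.read_snp_panel(p)

    def test_duplicate_rsid_rejected(self):
        rec = ps.SnpRecord("rs1", "1p1", "A", ("G",), 1.5)
        with pytest.raises(InputError):
            ps.SnpPanel([rec, rec])


class TestPanelFile:
    def test_counts_and_header_skip(self, tmp_path):
        p = write(
            tmp_path / "s.panel",
            "sample\tpop\tsuper_pop\tgender\n"
            "S1\tCEU\tEUR\tmale\nS2\tCEU\tEUR\tfemale\n"
            "S3\tYRI\tAFR\tmale\nS4\tYRI\tAFR\tmale\nS5\tYRI\tAFR\tfemale\n",
        )
        h = ps.read_panel_file(p)
        assert h.counts("subpopulation") == {"CEU": 2, "YRI": 3}
        assert h.sub_to_super == {"CEU": "EUR", "YRI": "AFR"}

    def test_duplicate_sample_rejected(self, tmp_path):
        p = write(tmp_path / "s.panel", "S1\tCEU\tEUR\nS1\tCEU\tEUR\n")
        with pytest.raises(InputError):
            ps.read_panel_file(p)

    def test_subpop_in_two_superpops_rejected(self, tmp_path):
        p = write(tmp_path / "s.panel", "S1\tACB\tAFR\nS2\tACB\tAMR\n")
        with pytest.raises(InputError):
            ps.read_panel_file(p)


class TestVcf:
    def _write_vcf(self, path, body, samples=("S1", "S2")):
        head = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
        )
        path.write_text(head + body)
        return str(path)

    @pytest.fixture
    def panel(self):
        return ps.SnpPanel([ps.SnpRecord("rs1", "1p1", "A", ("G",), 1.5)])

    def test_gt_decode_and_phasing_ignored(self, tmp_path, panel):
        p = self._write_vcf(tmp_path / "v.vcf", "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1|1\n")
        gm = ps.read_vcf(p, panel)
        assert gm.calls("S1", "rs1") == ("G", "A")
        assert gm.calls("S2", "rs1") == ("A", "A")

    def test_missing_gt(self, tmp_path, panel):
        p = self._write_vcf(tmp_path / "v.vcf", "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\n")
        gm = ps.read_vcf(p, panel)
        assert gm.calls("S1", "rs1") is None
        assert gm.calls("S2", "rs1") == ("G", "G")

    def test_unmatched_panel_locus_reported(self, tmp_path):
        panel = ps.SnpPanel(
            [ps.SnpRecord("rs1", "1p1", "A", ("G",), 1.5), ps.SnpRecord("rs2", "1p2", "C", ("T",), 2.0)]
        )
        p = self._write_vcf(tmp_path / "v.vcf", "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        gm = ps.read_vcf(p, panel)
        assert gm.loci == ["rs1"]
        assert gm.dropped_loci == ["rs2"]

    def test_duplicate_rsid_rejected(self, tmp_path, panel):
        p = self._write_vcf(
            tmp_path / "v.vcf",
            "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n1\t200\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n",
        )
        with pytest.raises(InputError):
            ps.read_vcf(p, panel)

    def test_zero_matches_rejected(self, tmp_path):
        panel = ps.SnpPanel([ps.SnpRecord("rs99", "1p1", "A", ("G",), 1.5)])
        p = self._write_vcf(tmp_path / "v.vcf", "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        with pytest.raises(InputError):
            ps.read_vcf(p, panel)


class TestRoundTrip:
    def test_write_read_reproduces_calls(self, tmp_path, small_dataset_missing):
        gm, _, panel = small_dataset_missing
        path = tmp_path / "rt.vcf"
        ps.write_vcf(gm, path)
        gm2 = ps.read_vcf(str(path), panel)
        assert gm2.loci == gm.loci
        assert gm2.samples == gm.samples
        assert np.array_equal(gm.codes, gm2.codes)

    def test_subset_commutes_with_reading(self, tmp_path, small_dataset):
        gm, _, panel = small_dataset
        path = tmp_path / "rt.vcf"
        ps.write_vcf(gm, path)
        subset = gm.samples[5:20]
        read_then_subset = ps.read_vcf(str(path), panel).subset_samples(subset)
        subset_then_read = ps.read_vcf(str(path), panel, sample_subset=subset)
        assert read_then_subset.samples == subset_then_read.samples
        assert np.array_equal(read_then_subset.codes, subset_then_read.codes)


def test_labelled_symmetric_matrix_invariants():
    with pytest.raises(InputError):
        ps.LabelledSymmetricMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(InputError):
        ps.LabelledSymmetricMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))
    m = ps.LabelledSymmetricMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert m.to_frame().loc["a", "b"] == 1.0
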