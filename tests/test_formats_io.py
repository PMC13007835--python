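"""File-format readers/writers: PLINK codec, summary stats, gene.loc, annotations."""

import numpy as np
import pytest

from multimagma import formats_io as fio
from multimagma.formats_io import (
    ConsistencyError,
    FormatError,
    GeneAnnotation,
    GeneLocus,
    P_VALUE_EPS,
    VariantRecord,
    apply_panel_qc,
    read_annotation,
    read_gene_loc,
    read_plink_panel,
    read_summary_stats,
    write_annotation,
    write_plink_panel,
)


def _write_tiny_triplet(tmp_path):
    """Hand-encoded 2-individual, 3-SNP PLINK triplet.

    SNP-major, one byte per SNP (2 individuals -> 2 low bit-pairs).
    Codes: 00=hom a1 (dosage 2), 01=missing, 10=het (1), 11=hom a2 (0).
    SNP1: ind1 hom a1 (00), ind2 het (10)      -> byte 0b00001000 = 0x08
    SNP2: ind1 missing (01), ind2 hom a2 (11)  -> byte 0b00001101 = 0x0d
    SNP3: ind1 het (10), ind2 het (10)         -> byte 0b00001010 = 0x0a
    """
    bed = tmp_path / "t.bed"
    bed.write_bytes(bytes([0x6C, 0x1B, 0x01, 0x08, 0x0D, 0x0A]))
    (tmp_path / "t.bim").write_text(
        "1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tC\tT\n2\trs3\t0\t300\tA\tC\n"
    )
    (tmp_path / "t.fam").write_text("f1 i1 0 0 0 -9\nf2 i2 0 0 0 -9\n")
    return bed, tmp_path / "t.bim", tmp_path / "t.fam"


class TestPlinkCodec:
    def test_hand_decoded_fixture(self, tmp_path):
        """The 2-bit layout decodes to the dosage matrix derived by hand."""
        variants, geno = read_plink_panel(*_write_tiny_triplet(tmp_path))
        expected = np.array([[2.0, np.nan, 1.0], [1.0, 0.0, 1.0]])
        np.testing.assert_array_equal(geno, expected)
        assert [v.snp_id for v in variants] == ["rs1", "rs2", "rs3"]
        assert variants[0].chromosome == "1"
        # MAF from non-missing calls: SNP1 freq 3/4 -> maf 0.25; SNP2 freq 0 -> 0
        assert variants[0].maf == pytest.approx(0.25)
        assert variants[1].maf == pytest.approx(0.0)

    def test_bad_magic_rejected(self, tmp_path):
        bed, bim, fam = _write_tiny_triplet(tmp_path)
        bed.write_bytes(b"\x00\x00\x00" + bed.read_bytes()[3:])
        with pytest.raises(FormatError, match="magic"):
            read_plink_panel(bed, bim, fam)

    def test_zero_individuals_is_consistency_error(self, tmp_path):
        bed, bim, fam = _write_tiny_triplet(tmp_path)
        fam.write_text("")
        with pytest.raises((ConsistencyError, Exception)):
            read_plink_panel(bed, bim, fam)

    def test_dimension_mismatch(self, tmp_path):
        bed, bim, fam = _write_tiny_triplet(tmp_path)
        bed.write_bytes(bed.read_bytes() + b"\x00")
        with pytest.raises(ConsistencyError):
            read_plink_panel(bed, bim, fam)

    def test_all_missing_snp_has_undefined_maf(self, tmp_path):
        bed, bim, fam = _write_tiny_triplet(tmp_path)
        # SNP2 -> both individuals missing (01 01 = 0b0101 = 0x05)
        raw = bytearray(bed.read_bytes())
        raw[4] = 0x05
        bed.write_bytes(bytes(raw))
        variants, geno = read_plink_panel(bed, bim, fam)
        assert variants[1].maf is None
        assert np.isnan(geno[:, 1]).all()

    def test_duplicate_snp_id_keeps_first(self, tmp_path):
        bed, bim, fam = _write_tiny_triplet(tmp_path)
        bim.write_text(
            "1\trs1\t0\t100\tA\tG\n1\trs1\t0\t200\tC\tT\n2\trs3\t0\t300\tA\tC\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            variants, geno = read_plink_panel(bed, bim, fam)
        assert [v.snp_id for v in variants] == ["rs1", "rs3"]
        assert geno.shape == (2, 2)

    def test_write_read_round_trip_bit_exact(self, tmp_path, rng):
        n, m = 17, 9  # n not divisible by 4 exercises padding
        geno = rng.integers(0, 3, size=(n, m)).astype(float)
        geno[rng.random((n, m)) < 0.1] = np.nan
        variants = [
            VariantRecord(f"rs{j}", "1", 100 + j, "A", "G") for j in range(m)
        ]
        prefix = tmp_path / "rt"
        write_plink_panel(variants, geno, prefix)
        variants2, geno2 = read_plink_panel(
            prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
        np.testing.assert_array_equal(geno2, geno)
        assert [v.snp_id for v in variants2] == [v.snp_id for v in variants]


class TestPanelQc:
    def _variants(self):
        return [
            VariantRecord("a", "1", 1, "A", "G", maf=0.005),   # fails MAF < 0.01
            VariantRecord("b", "1", 2, "A", "T", maf=0.3),     # ambiguous
            VariantRecord("c", "X", 3, "A", "G", maf=0.3),     # nonautosomal
            VariantRecord("d", "2", 4, "C", "G", maf=0.2),     # ambiguous
            VariantRecord("e", "2", 5, "A", "C", maf=0.4),     # passes
            VariantRecord("f", "3", 6, "A", "G", maf=None),    # undefined MAF
        ]

    def test_filters(self):
        geno = np.zeros((4, 6))
        kept, g2, counts = apply_panel_qc(self._variants(), geno, maf_min=0.01)
        assert [v.snp_id for v in kept] == ["e"]
        assert g2.shape == (4, 1)
        assert counts["maf"] == 1 and counts["ambiguous"] == 2
        assert counts["nonautosomal"] == 1 and counts["no_maf"] == 1

    def test_order_independence(self):
        """Applying the three filters in any order gives the same survivors."""
        geno = np.zeros((4, 6))
        variants = self._variants()
        full, _, _ = apply_panel_qc(variants, geno)

        for order in (["maf", "amb", "auto"], ["auto", "maf", "amb"], ["amb", "auto", "maf"]):
            v, g = variants, geno
            for step in order:
                v, g, _ = apply_panel_qc(
                    v, g,
                    maf_min=0.01 if step == "maf" else 0.0,
                    drop_ambiguous=step == "amb",
                    autosomes_only=step == "auto",
                )
            assert [x.snp_id for x in v] == [x.snp_id for x in full]


class TestSummaryStats:
    def test_basic_and_clamping(self, tmp_path):
        path = tmp_path / "ss.txt"
        path.write_text("SNP P\nrs1 0.02\nrs2 0\nrs3 notanumber\nrs1 0.5\n")
        with pytest.warns(UserWarning):
            recs = read_summary_stats(path)
        assert [(r.snp_id, r.p_value) for r in recs] == [
            ("rs1", 0.02), ("rs2", P_VALUE_EPS),
        ]

    def test_column_map_and_n(self, tmp_path):
        path = tmp_path / "ss.txt"
        path.write_text("marker\tpval\tsize\nrs1\t0.3\t1000\n")
        recs = read_summary_stats(path, column_map={"SNP": "marker", "P": "pval", "N": "size"})
        assert recs[0].n == 1000

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "ss.txt"
        path.write_text("SNP Z\nrs1 1.0\n")
        with pytest.raises(FormatError, match="P"):
            read_summary_stats(path)

    def test_header_only_gives_empty(self, tmp_path):
        path = tmp_path / "ss.txt"
        path.write_text("SNP P\n")
        with pytest.warns(UserWarning, match="no usable"):
            assert read_summary_stats(path) == []


class TestGeneLoc:
    def test_parse_with_strand_and_symbol(self, tmp_path):
        path = tmp_path / "g.loc"
        path.write_text("G1 3 100 200 + GENE1\nG2 chr4 50 60\n")
        genes = read_gene_loc(path)
        assert genes[0] == GeneLocus("G1", "3", 100, 200, "+", "GENE1")
        assert genes[1].chromosome == "4" and genes[1].strand == "unknown"

    def test_start_after_stop_rejected_with_line(self, tmp_path):
        path = tmp_path / "g.loc"
        path.write_text("G1 1 100 200\nG2 1 300 200\n")
        with pytest.raises(FormatError, match=":2"):
            read_gene_loc(path)

    def test_minus_strand_tss(self):
        g = GeneLocus("G", "1", 100, 200, "-")
        assert g.tss == 200


class TestAnnotationFile:
    def test_round_trip_identity(self, tmp_path):
        ann = GeneAnnotation(
            entries={"G1": ["rs1", "rs2"], "G2": ["rs2"], "G3": ["rs9"]},
            mode="meqtl",
            loci={"G1": "1:100:200", "G2": "2:5:6", "G3": "3:1:2"},
        )
        path = tmp_path / "a.annot"
        write_annotation(ann, path)
        back = read_annotation(path)
        assert back.entries == ann.entries
        assert back.mode == "meqtl"
        assert back.loci == ann.loci

    def test_empty_gene_omitted_on_write(self, tmp_path):
        ann = GeneAnnotation(entries={"G1": ["rs1"], "G2": []})
        path = tmp_path / "a.annot"
        write_annotation(ann, path)
        assert "G2" not in read_annotation(path).entries

    def test_duplicate_snps_rejected_in_type(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneAnnotation(entries={"G1": ["rs1", "rs1"]})


def test_gene_results_round_trip(tmp_path):
    results = [
        fio.GeneTestResult("G1", "1", 100, 200, 5, 3, 2.5, 0.01, 0.03, 0.05),
        fio.GeneTestResult("G2", "2", 10, 20, 1, 1, 0.1, 0.9, 0.9, 1.0),
    ]
    path = tmp_path / "r.genes.out"
    fio.write_gene_results(results, path)
    df = fio.read_gene_results(path)
    assert list(df.columns) == ["GENE", "CHR", "START", "STOP", "NSNPS", "NUSED",
                                "STAT", "P", "P_FDR", "P_BONF"]
    assert df["P"].tolist() == [0.01, 0.9]
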