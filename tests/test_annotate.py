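"""Positional, eQTL and chromatin-contact annotation builders."""

import numpy as np
import pytest

from multimagma.annotate import (
    ChromatinContact,
    QtlPair,
    hic_annotate,
    positional_annotate,
    qtl_annotate,
    read_bedpe,
    read_qtl_pairs,
    write_qtl_pairs,
)
from multimagma.formats_io import GeneLocus, VariantRecord


def V(snp, chrom, pos):
    return VariantRecord(snp, chrom, pos, "A", "G")


class TestPositional:
    def test_boundary_inclusive(self):
        genes = [GeneLocus("G", "1", 100, 200)]
        variants = [V("in_lo", "1", 100), V("out_lo", "1", 99),
                    V("in_hi", "1", 200), V("out_hi", "1", 201)]
        ann = positional_annotate(variants, genes)
        assert ann.snp_set("G") == {"in_lo", "in_hi"}

    def test_minus_strand_upstream_window(self):
        """Upstream of a minus-strand gene extends beyond its end coordinate."""
        genes = [GeneLocus("G", "1", 1000, 2000, strand="-")]
        variants = [V("up", "1", 2500), V("down", "1", 500)]
        ann = positional_annotate(variants, genes, window_up_kb=1.0)
        assert ann.snp_set("G") == {"up"}
        ann2 = positional_annotate(variants, genes, window_down_kb=1.0)
        assert ann2.snp_set("G") == {"down"}

    def test_chromosome_mismatch_excluded(self):
        ann = positional_annotate([V("s", "2", 150)], [GeneLocus("G", "3", 100, 200)])
        assert ann.entries == {}

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            positional_annotate([], [], window_up_kb=-1)

    def test_matches_brute_force_overlap(self, rng):
        """Interval-membership oracle over all SNP x gene pairs."""
        variants = [V(f"rs{i}", str(rng.integers(1, 4)), int(rng.integers(1, 5000)))
                    for i in range(300)]
        genes = [
            GeneLocus(f"G{j}", str(rng.integers(1, 4)),
                      int(s := rng.integers(1, 4500)), int(s + rng.integers(10, 500)),
                      strand=["+", "-", "unknown"][int(rng.integers(0, 3))])
            for j in range(40)
        ]
        up, down = 0.2, 0.1  # kb
        ann = positional_annotate(variants, genes, up, down)
        for g in genes:
            lo, hi = g.start_bp - 200, g.end_bp + 100
            if g.strand == "-":
                lo, hi = g.start_bp - 100, g.end_bp + 200
            expected = {v.snp_id for v in variants
                        if v.chromosome == g.chromosome and lo <= v.position_bp <= hi}
            assert ann.snp_set(g.gene_id) == expected

    def test_window_monotonicity(self, rng):
        """Enlarging windows never removes an assignment."""
        variants = [V(f"rs{i}", "1", int(rng.integers(1, 3000))) for i in range(100)]
        genes = [GeneLocus("G1", "1", 1000, 1500), GeneLocus("G2", "1", 2000, 2100, "-")]
        prev = positional_annotate(variants, genes, 0, 0)
        for w in (0.1, 0.5, 1.0):
            cur = positional_annotate(variants, genes, w, w)
            for g in genes:
                assert prev.snp_set(g.gene_id) <= cur.snp_set(g.gene_id)
            prev = cur


class TestQtlAnnotate:
    GENES = [GeneLocus("G1", "1", 1, 10), GeneLocus("G2", "1", 20, 30)]

    def test_direct_mapping(self):
        pairs = [QtlPair("rs1", "G1"), QtlPair("rs2", "G1"), QtlPair("rs1", "G2")]
        ann = qtl_annotate(pairs, self.GENES)
        assert ann.snp_set("G1") == {"rs1", "rs2"}
        assert ann.snp_set("G2") == {"rs1"}
        assert ann.mode == "eqtl"

    def test_fdr_filter(self):
        pairs = [QtlPair("rs1", "G1", fdr=0.2), QtlPair("rs2", "G1", fdr=0.01)]
        ann = qtl_annotate(pairs, self.GENES, fdr_max=0.05)
        assert ann.snp_set("G1") == {"rs2"}

    def test_empty_pairs(self):
        assert qtl_annotate([], self.GENES).entries == {}

    def test_unresolvable_target_dropped(self):
        ann = qtl_annotate([QtlPair("rs1", "NOPE")], self.GENES)
        assert ann.entries == {}


class TestHicAnnotate:
    def test_stage1_gene_body_only(self):
        genes = [GeneLocus("G", "1", 1000, 2000, "+")]
        ann = hic_annotate([V("s", "1", 1500)], genes, contacts=[])
        assert ann.snp_set("G") == {"s"}

    def test_stage1_promoter(self):
        genes = [GeneLocus("G", "1", 10000, 20000, "+")]
        ann = hic_annotate([V("p", "1", 9500), V("far", "1", 7000)], genes, [],
                           promoter_up_kb=2.0)
        assert ann.snp_set("G") == {"p"}

    def test_stage2_contact_assignment(self):
        """Intergenic SNP in anchor A reaches the gene whose promoter overlaps
        anchor B (0-based half-open anchors)."""
        genes = [GeneLocus("G1", "1", 50000, 60000, "+")]
        contact = ChromatinContact(("1", 0, 1000), ("1", 48500, 49500))
        snp = V("distal", "1", 500)
        ann = hic_annotate([snp], genes, [contact], promoter_up_kb=2.0)
        assert ann.snp_set("G1") == {"distal"}

    def test_unassigned_snp(self):
        genes = [GeneLocus("G", "1", 1000, 2000)]
        ann = hic_annotate([V("lone", "1", 900000)], genes, [])
        assert "lone" not in ann.snp_set("G")

    def test_contacts_only_add(self):
        """Stage-1 output is a subset of the full output."""
        genes = [GeneLocus("G1", "1", 50000, 60000), GeneLocus("G2", "1", 80000, 90000)]
        variants = [V(f"s{i}", "1", p) for i, p in enumerate([55000, 500, 85000, 70000])]
        contacts = [ChromatinContact(("1", 0, 1000), ("1", 49000, 51000))]
        base = hic_annotate(variants, genes, [])
        full = hic_annotate(variants, genes, contacts)
        for g in genes:
            assert base.snp_set(g.gene_id) <= full.snp_set(g.gene_id)

    def test_exon_restriction(self):
        genes = [GeneLocus("G", "1", 1000, 5000, "+")]
        exons = {"G": [(1000, 1200), (4800, 5000)]}
        ann = hic_annotate([V("ex", "1", 1100), V("intron", "1", 3000)],
                           genes, [], exon_intervals=exons)
        assert ann.snp_set("G") == {"ex"}


class TestIo:
    def test_qtl_pairs_round_trip(self, tmp_path):
        pairs = [QtlPair("rs1", "cg1", fdr=0.01, effect=0.5), QtlPair("rs2", "cg2")]
        path = tmp_path / "p.tsv"
        write_qtl_pairs(pairs, path)
        back = read_qtl_pairs(path)
        assert [(p.snp_id, p.target_id, p.fdr) for p in back] == [
            ("rs1", "cg1", 0.01), ("rs2", "cg2", None)]

    def test_bedpe_drops_interchromosomal(self, tmp_path):
        path = tmp_path / "c.bedpe"
        path.write_text("chr1\t0\t100\tchr1\t500\t600\nchr1\t0\t100\tchr2\t0\t100\n")
        with pytest.warns(UserWarning, match="inter-chromosomal"):
            contacts = read_bedpe(path)
        assert len(contacts) == 1
        assert contacts[0].anchor_a == ("1", 0, 100)

    def test_invalid_anchor_rejected(self):
        with pytest.raises(ValueError):
            ChromatinContact(("1", 100, 100), ("1", 0, 50))
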