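"""SNP-to-gene annotation strategies: positional, QTL-based, chromatin-contact.

Each builder returns a :class:`~multimagma.formats_io.GeneAnnotation` mapping
genes to the SNPs that should contribute to their gene-level statistic.

* ``positional_annotate`` — SNP inside the gene span, optionally extended by
  strand-aware upstream/downstream windows.
* ``qtl_annotate`` — SNP linked to the gene by an eQTL pair table (optionally
  FDR-filtered).
* ``hic_annotate`` — two-stage: exonic/gene-body/promoter SNPs go to their
  host gene; remaining SNPs inside a chromatin-contact anchor go to genes
  whose promoter or exons overlap the paired anchor.

Gene/bim coordinates are 1-based inclusive; contact anchors (BEDPE) are
0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import (
    FormatError,
    GeneAnnotation,
    GeneLocus,
    VariantRecord,
    normalize_chromosome,
)

logger = logging.getLogger(__name__)


@dataclass
class QtlPair:
    """A SNP-to-target QTL association row.

    ``target_id`` is a CpG id for meQTL pairs and a gene id for eQTL pairs.
    """

    snp_id: str
    target_id: str
    fdr: float | None = None
    effect: float | None = None


@dataclass
class ChromatinContact:
    """An intra- or inter-chromosomal contact between two anchors.

    Anchors are ``(chromosome, start, end)`` in 0-based half-open coordinates.
    """

    anchor_a: tuple[str, int, int]
    anchor_b: tuple[str, int, int]

    def __post_init__(self) -> None:
        for name, (_, s, e) in (("A", self.anchor_a), ("B", self.anchor_b)):
            if s >= e:
                raise ValueError(f"anchor {name}: start {s} >= end {e}")

    @property
    def intra(self) -> bool:
        return self.anchor_a[0] == self.anchor_b[0]


# ---------------------------------------------------------------------------
# Readers for QTL pair tables and BEDPE contacts
# ---------------------------------------------------------------------------


def read_qtl_pairs(path: str | Path, sep: str = "\t") -> list[QtlPair]:
    """Read a QTL pair TSV with header columns ``snp``, ``target`` and
    optional ``fdr``, ``effect``.  Duplicate (snp, target) rows keep first."""
    df = pd.read_csv(path, sep=sep, dtype={"snp": str, "target": str})
    for col in ("snp", "target"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    pairs: list[QtlPair] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for row in df.itertuples(index=False):
        key = (row.snp, row.target)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        fdr = float(row.fdr) if "fdr" in df.columns and pd.notna(row.fdr) else None
        eff = float(row.effect) if "effect" in df.columns and pd.notna(row.effect) else None
        pairs.append(QtlPair(snp_id=row.snp, target_id=row.target, fdr=fdr, effect=eff))
    if n_dup:
        warnings.warn(f"{n_dup} duplicate QTL pair row(s) dropped (keep-first)")
    return pairs


def write_qtl_pairs(pairs: Iterable[QtlPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp\ttarget\tfdr\teffect\n")
        for p in pairs:
            fdr = "" if p.fdr is None else f"{p.fdr:.6g}"
            eff = "" if p.effect is None else f"{p.effect:.6g}"
            fh.write(f"{p.snp_id}\t{p.target_id}\t{fdr}\t{eff}\n")


def read_bedpe(path: str | Path) -> list[ChromatinContact]:
    """Read chromatin contacts from BEDPE (>= 6 columns, 0-based half-open).

    Inter-chromosomal contacts are dropped with a warning; the assignment
    logic only uses intra-chromosomal loops.
    """
    contacts: list[ChromatinContact] = []
    n_inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            c = ChromatinContact(
                anchor_a=(normalize_chromosome(parts[0]), int(parts[1]), int(parts[2])),
                anchor_b=(normalize_chromosome(parts[3]), int(parts[4]), int(parts[5])),
            )
            if not c.intra:
                n_inter += 1
                continue
            contacts.append(c)
    if n_inter:
        warnings.warn(f"{n_inter} inter-chromosomal contact(s) dropped")
    return contacts


# ---------------------------------------------------------------------------
# Positional annotation
# ---------------------------------------------------------------------------


def _gene_window(gene: GeneLocus, up_bp: int, down_bp: int) -> tuple[int, int]:
    """Strand-aware extension of a gene span: the upstream window is applied
    on the 5' side (before start on '+', after end on '-'); unknown strand
    is treated as '+' so the extension is applied symmetrically with respect
    to coordinates (up before start, down after end)."""
    if gene.strand == "-":
        return gene.start_bp - down_bp, gene.end_bp + up_bp
    return gene.start_bp - up_bp, gene.end_bp + down_bp


def positional_annotate(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneLocus],
    window_up_kb: float = 0.0,
    window_down_kb: float = 0.0,
) -> GeneAnnotation:
    """Assign each SNP to every gene whose (window-extended) span contains it.

    A SNP at position ``p`` on the gene's chromosome is assigned iff
    ``start - up <= p <= end + down`` after the strand-aware window swap for
    minus-strand genes.  Windows are in kb and must be non-negative.
    """
    if window_up_kb < 0 or window_down_kb < 0:
        raise ValueError("annotation windows must be non-negative")
    up_bp = int(round(window_up_kb * 1000))
    down_bp = int(round(window_down_kb * 1000))

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for v in variants:
        by_chrom.setdefault(v.chromosome, []).append((v.position_bp, v.snp_id))
    for lst in by_chrom.values():
        lst.sort()

    import bisect

    entries: dict[str, list[str]] = {}
    loci: dict[str, str] = {}
    for gene in genes:
        snps_here = by_chrom.get(gene.chromosome)
        if not snps_here:
            continue
        lo, hi = _gene_window(gene, up_bp, down_bp)
        i = bisect.bisect_left(snps_here, (lo, ""))
        j = bisect.bisect_right(snps_here, (hi, "￿"))
        assigned = [snp for _, snp in snps_here[i:j]]
        if assigned:
            entries[gene.gene_id] = assigned
            loci[gene.gene_id] = f"{gene.chromosome}:{gene.start_bp}:{gene.end_bp}"
    return GeneAnnotation(entries=entries, mode="positional", loci=loci)


# ---------------------------------------------------------------------------
# QTL (eQTL) annotation
# ---------------------------------------------------------------------------


def qtl_annotate(
    pairs: Sequence[QtlPair],
    genes: Sequence[GeneLocus],
    fdr_max: float | None = None,
) -> GeneAnnotation:
    """Build an eQTL annotation: gene g receives every SNP with a pair
    ``(snp, g)`` passing ``fdr <= fdr_max`` (no filter when ``fdr_max`` is
    None; pairs without an FDR value pass).  Target gene ids that do not
    resolve in ``genes`` are dropped with a count."""
    gene_by_id = {g.gene_id: g for g in genes}
    entries: dict[str, list[str]] = {}
    seen: dict[str, set[str]] = {}
    n_unresolved = 0
    for p in pairs:
        if fdr_max is not None and p.fdr is not None and p.fdr > fdr_max:
            continue
        gene = gene_by_id.get(p.target_id)
        if gene is None:
            n_unresolved += 1
            continue
        bucket = seen.setdefault(gene.gene_id, set())
        if p.snp_id not in bucket:
            bucket.add(p.snp_id)
            entries.setdefault(gene.gene_id, []).append(p.snp_id)
    if n_unresolved:
        logger.info("qtl_annotate: %d pair(s) with unresolvable target gene id", n_unresolved)
    loci = {
        gid: f"{gene_by_id[gid].chromosome}:{gene_by_id[gid].start_bp}:{gene_by_id[gid].end_bp}"
        for gid in entries
    }
    return GeneAnnotation(entries=entries, mode="eqtl", loci=loci)


# ---------------------------------------------------------------------------
# Chromatin-contact (Hi-C) annotation
# ---------------------------------------------------------------------------


def _promoter_interval(gene: GeneLocus, promoter_up_bp: int) -> tuple[int, int]:
    """Promoter span (1-based inclusive): ``promoter_up_bp`` upstream of the
    TSS, strand-aware; unknown strand treated as '+'."""
    if gene.strand == "-":
        return gene.end_bp + 1, gene.end_bp + promoter_up_bp
    return gene.start_bp - promoter_up_bp, gene.start_bp - 1


def _overlaps_halfopen(feat_lo1: int, feat_hi1: int, a_start0: int, a_end0: int) -> bool:
    """>= 1 bp intersection between a 1-based inclusive feature interval and
    a 0-based half-open anchor."""
    # Convert the feature to 0-based half-open: [lo-1, hi)
    return max(feat_lo1 - 1, a_start0) < min(feat_hi1, a_end0)


def hic_annotate(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneLocus],
    contacts: Sequence[ChromatinContact],
    promoter_up_kb: float = 2.0,
    exon_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> GeneAnnotation:
    """Two-stage chromatin-interaction annotation.

    Stage 1 assigns SNPs located in a gene's body (or its exons when
    ``exon_intervals`` restricts the body) or promoter to that gene directly.
    Stage 2 takes every other SNP lying inside a contact anchor and assigns
    it to any gene whose promoter or exon/body overlaps the paired anchor
    (both anchor orientations are used).  The result is the deduplicated
    union; genes with no SNPs are omitted.
    """
    promoter_up_bp = int(round(promoter_up_kb * 1000))

    def gene_feature_intervals(gene: GeneLocus) -> list[tuple[int, int]]:
        """1-based inclusive intervals defining the gene's assignable
        footprint: exons (or whole body) plus the promoter."""
        if exon_intervals and gene.gene_id in exon_intervals:
            feats = list(exon_intervals[gene.gene_id])
        else:
            feats = [(gene.start_bp, gene.end_bp)]
        plo, phi = _promoter_interval(gene, promoter_up_bp)
        if plo <= phi:
            feats.append((plo, phi))
        return feats

    features: dict[str, list[tuple[int, int]]] = {
        g.gene_id: gene_feature_intervals(g) for g in genes
    }
    genes_by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    entries: dict[str, list[str]] = {}
    membership: dict[str, set[str]] = {}

    def assign(gene_id: str, snp_id: str) -> None:
        bucket = membership.setdefault(gene_id, set())
        if snp_id not in bucket:
            bucket.add(snp_id)
            entries.setdefault(gene_id, []).append(snp_id)

    # Stage 1: direct assignment of SNPs in gene features.
    stage1_assigned: set[str] = set()
    for v in variants:
        for g in genes_by_chrom.get(v.chromosome, []):
            if any(lo <= v.position_bp <= hi for lo, hi in features[g.gene_id]):
                assign(g.gene_id, v.snp_id)
                stage1_assigned.add(v.snp_id)

    # Stage 2: contact-mediated assignment for the remaining SNPs.
    intra = [c for c in contacts if c.intra]
    for v in variants:
        if v.snp_id in stage1_assigned:
            continue
        pos0 = v.position_bp - 1  # anchor coordinates are 0-based half-open
        for c in intra:
            if c.anchor_a[0] != v.chromosome:
                continue
            for snp_anchor, gene_anchor in ((c.anchor_a, c.anchor_b), (c.anchor_b, c.anchor_a)):
                if not (snp_anchor[1] <= pos0 < snp_anchor[2]):
                    continue
                for g in genes_by_chrom.get(gene_anchor[0], []):
                    if any(
                        _overlaps_halfopen(lo, hi, gene_anchor[1], gene_anchor[2])
                        for lo, hi in features[g.gene_id]
                    ):
                        assign(g.gene_id, v.snp_id)

    gene_by_id = {g.gene_id: g for g in genes}
    loci = {
        gid: f"{gene_by_id[gid].chromosome}:{gene_by_id[gid].start_bp}:{gene_by_id[gid].end_bp}"
        for gid in entries
    }
    return GeneAnnotation(entries=entries, mode="hic", loci=loci)
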