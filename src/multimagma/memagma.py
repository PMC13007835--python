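"""meQTL-based SNP-to-gene annotation.

Methylation QTLs link SNPs to CpG sites; an array annotation (Illumina
450K-style) links CpG sites to their nearest genes.  Joining the two tables
on the CpG id yields SNP-CpG-gene triplets, which collapse (deduplicated per
gene) into a MAGMA-compliant gene annotation.  The join is the core of the
meQTL annotation layer:

    (snp, cpg) pairs  x  (cpg, gene) links  ->  (snp, cpg, gene) triplets

An optional FDR threshold is applied to the pair table before joining;
``check_cis_window`` offers an advisory validation that every pair respects
a cis-distance limit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import QtlPair
from .formats_io import FormatError, GeneAnnotation, GeneLocus, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class CpgGeneLink:
    """A CpG-to-gene row from an array annotation table."""

    cpg_id: str
    gene_symbol: str
    ensembl_id: str | None = None
    chromosome: str | None = None
    gene_start: int | None = None
    gene_end: int | None = None


@dataclass
class TripletReport:
    """Cardinalities of the SNP-CpG-gene join, counted after FDR filtering."""

    n_unique_cpgs: int
    n_unique_snps: int
    n_triplets: int
    n_unmapped_cpgs: int
    n_genes: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_unique_cpgs": self.n_unique_cpgs,
            "n_unique_snps": self.n_unique_snps,
            "n_triplets": self.n_triplets,
            "n_unmapped_cpgs": self.n_unmapped_cpgs,
            "n_genes": self.n_genes,
        }


def read_cpg_gene_map(path: str | Path) -> list[CpgGeneLink]:
    """Read a CpG-to-gene map TSV with header ``cpg_id, symbol, ensembl_id,
    chr, start, end`` (coordinates optional).  Duplicate (cpg, gene) rows
    keep first."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cpg_id", "symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    links: list[CpgGeneLink] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        ens = getattr(row, "ensembl_id", None)
        ens = str(ens) if pd.notna(ens) else None
        key = (row.cpg_id, ens or row.symbol)
        if key in seen:
            continue
        seen.add(key)
        links.append(
            CpgGeneLink(
                cpg_id=str(row.cpg_id),
                gene_symbol=str(row.symbol),
                ensembl_id=ens,
                chromosome=str(row.chr) if "chr" in df.columns and pd.notna(row.chr) else None,
                gene_start=int(row.start) if "start" in df.columns and pd.notna(row.start) else None,
                gene_end=int(row.end) if "end" in df.columns and pd.notna(row.end) else None,
            )
        )
    return links


def write_cpg_gene_map(links: Sequence[CpgGeneLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cpg_id\tsymbol\tensembl_id\tchr\tstart\tend\n")
        for l in links:
            fh.write(
                "\t".join(
                    [
                        l.cpg_id,
                        l.gene_symbol,
                        l.ensembl_id or "",
                        l.chromosome or "",
                        "" if l.gene_start is None else str(l.gene_start),
                        "" if l.gene_end is None else str(l.gene_end),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# The join
# ---------------------------------------------------------------------------


def join_meqtl_to_genes(
    meqtl_pairs: Sequence[QtlPair],
    links: Sequence[CpgGeneLink],
    fdr_max: float | None = 0.05,
) -> tuple[list[tuple[str, str, CpgGeneLink]], TripletReport]:
    """Join meQTL (snp, cpg) pairs to (cpg, gene) links on the CpG key.

    Every pair passing ``fdr <= fdr_max`` (pairs without an FDR value pass;
    no filter when ``fdr_max`` is None) is crossed with every link sharing
    its CpG id.  Returns the triplets ``(snp_id, cpg_id, link)`` and a
    :class:`TripletReport` whose cardinalities are computed on the
    post-filter pair set: ``n_unique_cpgs``/``n_unique_snps`` count CpGs and
    SNPs that appear in at least one triplet, and ``n_unmapped_cpgs`` counts
    distinct filtered-pair CpGs with no link.  Duplicate input rows do not
    change the output.
    """
    links_by_cpg: dict[str, list[CpgGeneLink]] = {}
    seen_links: set[tuple[str, str]] = set()
    for link in links:
        key = (link.cpg_id, link.ensembl_id or link.gene_symbol)
        if key in seen_links:
            continue
        seen_links.add(key)
        links_by_cpg.setdefault(link.cpg_id, []).append(link)

    triplets: list[tuple[str, str, CpgGeneLink]] = []
    seen_pairs: set[tuple[str, str]] = set()
    mapped_cpgs: set[str] = set()
    mapped_snps: set[str] = set()
    unmapped_cpgs: set[str] = set()
    genes: set[str] = set()
    for pair in meqtl_pairs:
        if fdr_max is not None and pair.fdr is not None and pair.fdr > fdr_max:
            continue
        key = (pair.snp_id, pair.target_id)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        cpg_links = links_by_cpg.get(pair.target_id)
        if not cpg_links:
            unmapped_cpgs.add(pair.target_id)
            continue
        mapped_cpgs.add(pair.target_id)
        mapped_snps.add(pair.snp_id)
        for link in cpg_links:
            triplets.append((pair.snp_id, pair.target_id, link))
            genes.add(link.ensembl_id or link.gene_symbol)

    report = TripletReport(
        n_unique_cpgs=len(mapped_cpgs),
        n_unique_snps=len(mapped_snps),
        n_triplets=len(triplets),
        n_unmapped_cpgs=len(unmapped_cpgs),
        n_genes=len(genes),
    )
    logger.info(
        "meQTL join: %d triplets from %d CpGs x %d SNPs (%d unmapped CpGs)",
        report.n_triplets, report.n_unique_cpgs, report.n_unique_snps,
        report.n_unmapped_cpgs,
    )
    return triplets, report


def triplets_to_annotation(
    triplets: Sequence[tuple[str, str, CpgGeneLink]],
    genes: Sequence[GeneLocus],
) -> GeneAnnotation:
    """Collapse SNP-CpG-gene triplets into a gene annotation.

    Gene identity is resolved by Ensembl id first, then by symbol; a symbol
    matching several loci is expanded to all of them with a warning.  A SNP
    reaching one gene through several CpGs appears once.  Genes absent from
    the gene model are dropped with a count.
    """
    by_id = {g.gene_id: g for g in genes}
    by_symbol: dict[str, list[GeneLocus]] = {}
    for g in genes:
        if g.symbol:
            by_symbol.setdefault(g.symbol, []).append(g)

    entries: dict[str, list[str]] = {}
    membership: dict[str, set[str]] = {}
    n_unresolved = 0
    ambiguous_symbols: set[str] = set()
    for snp_id, _cpg_id, link in triplets:
        targets: list[GeneLocus] = []
        if link.ensembl_id and link.ensembl_id in by_id:
            targets = [by_id[link.ensembl_id]]
        elif link.gene_symbol in by_id:
            targets = [by_id[link.gene_symbol]]
        elif link.gene_symbol in by_symbol:
            targets = by_symbol[link.gene_symbol]
            if len(targets) > 1:
                ambiguous_symbols.add(link.gene_symbol)
        if not targets:
            n_unresolved += 1
            continue
        for gene in targets:
            bucket = membership.setdefault(gene.gene_id, set())
            if snp_id not in bucket:
                bucket.add(snp_id)
                entries.setdefault(gene.gene_id, []).append(snp_id)

    if ambiguous_symbols:
        warnings.warn(
            f"{len(ambiguous_symbols)} gene symbol(s) map to multiple loci; "
            "expanded to all matches"
        )
    if n_unresolved:
        logger.info(
            "triplets_to_annotation: %d triplet(s) with genes absent from the "
            "gene model dropped", n_unresolved,
        )
    loci = {
        gid: f"{by_id[gid].chromosome}:{by_id[gid].start_bp}:{by_id[gid].end_bp}"
        for gid in entries
    }
    return GeneAnnotation(entries=entries, mode="meqtl", loci=loci)


def build_meqtl_annotation(
    meqtl_pairs: Sequence[QtlPair],
    links: Sequence[CpgGeneLink],
    genes: Sequence[GeneLocus],
    fdr_max: float | None = 0.05,
) -> tuple[GeneAnnotation, TripletReport]:
    """Convenience wrapper: join then collapse into an annotation."""
    triplets, report = join_meqtl_to_genes(meqtl_pairs, links, fdr_max=fdr_max)
    return triplets_to_annotation(triplets, genes), report


# ---------------------------------------------------------------------------
# Advisory cis-window validation
# ---------------------------------------------------------------------------


def check_cis_window(
    meqtl_pairs: Sequence[QtlPair],
    variants: Sequence[VariantRecord] | Mapping[str, tuple[str, int]],
    cpg_positions: Mapping[str, tuple[str, int]],
    max_distance_bp: int = 500_000,
) -> list[dict]:
    """Report pairs violating a cis-distance limit (default +/- 500 kb).

    ``variants`` maps SNP positions (a list of VariantRecords or a dict
    ``snp_id -> (chrom, pos)``); ``cpg_positions`` maps
    ``cpg_id -> (chrom, pos)``.  Pure validation: returns a list of
    violation dicts (reason ``distance``, ``chromosome`` or
    ``missing_position``) and mutates nothing.
    """
    if not isinstance(variants, Mapping):
        snp_pos = {v.snp_id: (v.chromosome, v.position_bp) for v in variants}
    else:
        snp_pos = dict(variants)

    violations: list[dict] = []
    for pair in meqtl_pairs:
        sp = snp_pos.get(pair.snp_id)
        cp = cpg_positions.get(pair.target_id)
        if sp is None or cp is None:
            violations.append(
                {"snp": pair.snp_id, "cpg": pair.target_id, "reason": "missing_position"}
            )
            continue
        if sp[0] != cp[0]:
            violations.append(
                {"snp": pair.snp_id, "cpg": pair.target_id, "reason": "chromosome"}
            )
        elif abs(sp[1] - cp[1]) > max_distance_bp:
            violations.append(
                {
                    "snp": pair.snp_id,
                    "cpg": pair.target_id,
                    "reason": "distance",
                    "distance_bp": abs(sp[1] - cp[1]),
                }
            )
    return violations
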