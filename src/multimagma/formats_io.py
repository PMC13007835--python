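"""Readers and writers for the standard files the pipeline touches.

Formats handled here:

* PLINK binary genotype triplets (``.bed``/``.bim``/``.fam``, v1.0 SNP-major)
  used as the LD reference panel.  Genotypes are returned as an
  ``individuals x SNPs`` float matrix of allele1 dosages in ``{0, 1, 2}``
  with ``NaN`` marking missing calls.
* GWAS summary statistics: delimited text with configurable column names.
* MAGMA-style ``gene.loc`` gene location files.
* Gene annotation files (``gene_id <TAB> chr:start:stop <TAB> snp ...``).
* Gene-level result tables (TSV).

Coordinate conventions: ``.bim`` and ``gene.loc`` positions are 1-based
inclusive (PLINK/MAGMA convention); chromatin-contact BEDPE input elsewhere
in the package is 0-based half-open.  Chromosome labels are normalized by
stripping a ``chr`` prefix and upper-casing ``X``/``Y``/``MT``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lower clamp for p-values of exactly zero: the chi-square quantile
#: transform diverges at p = 0.
P_VALUE_EPS = 1e-300

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: PLINK 2-bit codes -> allele1 dosage (NaN = missing).
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

_AUTOSOMES = {str(i) for i in range(1, 23)}


class FormatError(ValueError):
    """A file violates its declared on-disk format."""


class ConsistencyError(ValueError):
    """Files of a multi-file format disagree with each other."""


def normalize_chromosome(chrom: str) -> str:
    """Normalize a chromosome label: strip ``chr`` prefix, uppercase X/Y/MT."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y", "mt", "m"):
        c = "MT" if c.lower() in ("mt", "m") else c.upper()
    return c


def is_autosome(chrom: str) -> bool:
    return normalize_chromosome(chrom) in _AUTOSOMES


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """A reference-panel SNP with position, alleles and panel MAF."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele1: str
    allele2: str
    maf: float | None = None

    @property
    def is_snp(self) -> bool:
        """True when both alleles are single A/C/G/T bases."""
        return (
            len(self.allele1) == 1
            and len(self.allele2) == 1
            and self.allele1 in "ACGT"
            and self.allele2 in "ACGT"
        )

    @property
    def is_ambiguous(self) -> bool:
        """Strand-ambiguous allele pair: A/T or C/G."""
        return frozenset((self.allele1, self.allele2)) in _AMBIGUOUS_PAIRS


@dataclass
class SummaryStatRecord:
    """A single GWAS summary-statistic row: SNP id, p-value, optional N."""

    snp_id: str
    p_value: float
    n: int | None = None


@dataclass
class GeneLocus:
    """A gene's genomic span, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "unknown"  # one of "+", "-", "unknown"
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site under the strand convention (start for
        '+'/unknown, end for '-')."""
        return self.end_bp if self.strand == "-" else self.start_bp


@dataclass
class GeneAnnotation:
    """Mapping gene_id -> ordered, deduplicated list of assigned SNP ids.

    ``mode`` records the assignment strategy (positional, eqtl, meqtl, hic);
    ``loci`` optionally carries the ``chr:start:stop`` span string per gene.
    """

    entries: dict[str, list[str]]
    mode: str = "positional"
    loci: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, snps in self.entries.items():
            if len(snps) != len(set(snps)):
                raise ValueError(f"gene {gene}: duplicate SNP ids in annotation")

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    @property
    def n_assignments(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def snp_set(self, gene_id: str) -> set[str]:
        return set(self.entries.get(gene_id, []))


@dataclass
class GeneTestResult:
    """Per-gene association result: mean-chi-square statistic and p-values."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps_annotated: int
    n_snps_used: int
    stat: float
    p_nominal: float
    p_fdr: float | None = None
    p_bonferroni: float | None = None


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def read_plink_panel(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> tuple[list[VariantRecord], np.ndarray]:
    """Read a PLINK v1.0 binary triplet into variants and a dosage matrix.

    Returns ``(variants, genotypes)`` where ``genotypes`` has shape
    ``(n_individuals, n_snps)`` holding allele1 dosages (bim column 5), with
    ``NaN`` for missing calls.  MAF is computed from non-missing calls;
    an all-missing SNP gets ``maf=None`` and should be dropped by QC.
    Duplicate SNP ids keep the first occurrence (later columns are removed
    with a warning).
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None)
    n_ind = len(fam)
    n_snp = len(bim)
    if n_ind == 0:
        raise ConsistencyError("fam file lists 0 individuals")
    if n_snp == 0:
        raise ConsistencyError("bim file lists 0 variants")

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed_path}: bad .bed magic bytes {raw[:3].hex()} "
            f"(expected {_BED_MAGIC.hex()}, v1.0 SNP-major)"
        )
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_snp
    if len(raw) != expected:
        raise ConsistencyError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} for "
            f"{n_ind} individuals x {n_snp} SNPs"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snp, bytes_per_snp)
    # Unpack 2-bit codes, little-endian within each byte.
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snp, bytes_per_snp * 4)[:, :n_ind]
    genotypes = _BED_CODE_TO_DOSAGE[codes].T  # individuals x SNPs

    variants: list[VariantRecord] = []
    for row in bim.itertuples(index=False):
        variants.append(
            VariantRecord(
                snp_id=row.snp_id,
                chromosome=normalize_chromosome(row.chrom),
                position_bp=int(row.pos),
                allele1=str(row.a1),
                allele2=str(row.a2),
            )
        )

    # Deduplicate snp ids: keep first.
    seen: set[str] = set()
    keep = np.ones(n_snp, dtype=bool)
    for j, v in enumerate(variants):
        if v.snp_id in seen:
            keep[j] = False
        seen.add(v.snp_id)
    n_dup = int((~keep).sum())
    if n_dup:
        warnings.warn(f"{n_dup} duplicate SNP id(s) in bim; keeping first occurrence")
        genotypes = genotypes[:, keep]
        variants = [v for v, k in zip(variants, keep) if k]

    _attach_mafs(variants, genotypes)
    return variants, genotypes


def _attach_mafs(variants: Sequence[VariantRecord], genotypes: np.ndarray) -> None:
    """Compute allele1 frequency per SNP and store the folded MAF."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(genotypes, axis=0) / 2.0
    for j, v in enumerate(variants):
        if np.isnan(freq[j]):
            v.maf = None
        else:
            v.maf = float(min(freq[j], 1.0 - freq[j]))


def write_plink_panel(
    variants: Sequence[VariantRecord],
    genotypes: np.ndarray,
    prefix: str | Path,
    individual_ids: Sequence[str] | None = None,
) -> tuple[Path, Path, Path]:
    """Write a PLINK v1.0 SNP-major binary triplet ``prefix.{bed,bim,fam}``.

    ``genotypes`` is individuals x SNPs allele1 dosage with NaN for missing.
    Inverse of :func:`read_plink_panel` (bit-exact round trip).
    """
    prefix = Path(prefix)
    n_ind, n_snp = genotypes.shape
    if n_snp != len(variants):
        raise ConsistencyError("genotype column count != number of variants")

    # dosage -> 2-bit code
    codes = np.full(genotypes.shape, 1, dtype=np.uint8)  # missing
    codes[genotypes == 2] = 0
    codes[genotypes == 1] = 2
    codes[genotypes == 0] = 3

    bytes_per_snp = (n_ind + 3) // 4
    padded = np.ones((n_snp, bytes_per_snp * 4), dtype=np.uint8) * 3  # pad = hom a2
    padded[:, :n_ind] = codes.T
    packed = (
        padded.reshape(n_snp, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)

    bed_path = prefix.with_suffix(".bed")
    bed_path.write_bytes(_BED_MAGIC + packed.tobytes())

    bim_path = prefix.with_suffix(".bim")
    with open(bim_path, "w") as fh:
        for v in variants:
            fh.write(
                f"{v.chromosome}\t{v.snp_id}\t0\t{v.position_bp}\t{v.allele1}\t{v.allele2}\n"
            )

    fam_path = prefix.with_suffix(".fam")
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(n_ind)]
    with open(fam_path, "w") as fh:
        for iid in individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Panel QC
# ---------------------------------------------------------------------------


def apply_panel_qc(
    variants: Sequence[VariantRecord],
    genotypes: np.ndarray,
    maf_min: float = 0.01,
    drop_ambiguous: bool = True,
    autosomes_only: bool = True,
) -> tuple[list[VariantRecord], np.ndarray, dict[str, int]]:
    """Filter panel SNPs: MAF floor, strand-ambiguous pairs, non-autosomes.

    A SNP with undefined MAF (all calls missing) is always removed.  Returns
    the surviving ``(variants, genotypes, counts)`` where ``counts`` gives
    the number removed per filter (a SNP failing several filters is counted
    under each).  Filters are independent per SNP, so application order does
    not change the surviving set.
    """
    n = len(variants)
    keep = np.ones(n, dtype=bool)
    counts = {"maf": 0, "ambiguous": 0, "nonautosomal": 0, "no_maf": 0}
    for j, v in enumerate(variants):
        if v.maf is None:
            counts["no_maf"] += 1
            keep[j] = False
            continue
        if v.maf < maf_min:
            counts["maf"] += 1
            keep[j] = False
        if drop_ambiguous and v.is_ambiguous:
            counts["ambiguous"] += 1
            keep[j] = False
        if autosomes_only and not is_autosome(v.chromosome):
            counts["nonautosomal"] += 1
            keep[j] = False
    if not keep.any():
        warnings.warn("panel QC removed every SNP")
    surviving = [v for v, k in zip(variants, keep) if k]
    return surviving, genotypes[:, keep], counts


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SummaryStatRecord]:
    """Read GWAS summary statistics from delimited text with a header.

    ``column_map`` maps the logical names ``SNP``, ``P`` and (optionally)
    ``N`` to the file's column names; defaults to those same names.  P-values
    of 0 or below are clamped to ``P_VALUE_EPS`` with a warning, p > 1 rows
    are rejected, unparseable p rows are skipped, and duplicate SNP ids keep
    the first record.
    """
    cmap = {"SNP": "SNP", "P": "P", "N": "N"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep or r"\s+", dtype=str)
    for logical in ("SNP", "P"):
        if cmap[logical] not in df.columns:
            raise FormatError(
                f"{path}: required column {cmap[logical]!r} (for {logical}) not found; "
                f"columns are {list(df.columns)}"
            )
    has_n = cmap["N"] in df.columns

    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    n_clamped = n_skipped = n_dup = 0
    for _, row in df.iterrows():
        snp = str(row[cmap["SNP"]])
        try:
            p = float(row[cmap["P"]])
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        if not np.isfinite(p) or p > 1.0:
            n_skipped += 1
            continue
        if p <= 0.0:
            p = P_VALUE_EPS
            n_clamped += 1
        if snp in seen:
            n_dup += 1
            continue
        seen.add(snp)
        n_val: int | None = None
        if has_n and pd.notna(row[cmap["N"]]):
            try:
                n_val = int(float(row[cmap["N"]]))
            except (TypeError, ValueError):
                n_val = None
        records.append(SummaryStatRecord(snp_id=snp, p_value=p, n=n_val))

    if n_clamped:
        warnings.warn(f"{n_clamped} p-value(s) <= 0 clamped to {P_VALUE_EPS}")
    if n_dup:
        warnings.warn(f"{n_dup} duplicate SNP id(s); kept first occurrence")
    if n_skipped:
        warnings.warn(f"{n_skipped} row(s) with unparseable/invalid p skipped")
    if not records:
        warnings.warn(f"{path}: no usable summary-statistic rows")
    logger.info(
        "read %d summary-stat records (%d clamped, %d duplicate, %d skipped)",
        len(records), n_clamped, n_dup, n_skipped,
    )
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP\tP\tN\n")
        for r in records:
            n = "" if r.n is None else str(r.n)
            fh.write(f"{r.snp_id}\t{r.p_value:.10g}\t{n}\n")


# ---------------------------------------------------------------------------
# gene.loc
# ---------------------------------------------------------------------------


def read_gene_loc(path: str | Path) -> list[GeneLocus]:
    """Read a MAGMA-style gene location file.

    Whitespace-delimited columns: gene_id, chromosome, start, stop, then
    optional strand and symbol.  A record with start > stop is rejected with
    an error naming the line.
    """
    genes: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            gene_id, chrom, start_s, stop_s = parts[:4]
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > stop:
                raise FormatError(f"{path}:{lineno}: start {start} > stop {stop}")
            strand = "unknown"
            symbol = None
            if len(parts) >= 5 and parts[4] in ("+", "-"):
                strand = parts[4]
                if len(parts) >= 6:
                    symbol = parts[5]
            elif len(parts) >= 5:
                symbol = parts[4]
            if gene_id in seen:
                warnings.warn(f"duplicate gene id {gene_id}; keeping first")
                continue
            seen.add(gene_id)
            genes.append(
                GeneLocus(
                    gene_id=gene_id,
                    chromosome=normalize_chromosome(chrom),
                    start_bp=start,
                    end_bp=stop,
                    strand=strand,
                    symbol=symbol,
                )
            )
    return genes


def write_gene_loc(genes: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cols = [g.gene_id, g.chromosome, str(g.start_bp), str(g.end_bp)]
            if g.strand != "unknown":
                cols.append(g.strand)
                if g.symbol:
                    cols.append(g.symbol)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation files
# ---------------------------------------------------------------------------


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write an annotation file: ``gene_id TAB chr:start:stop TAB snp ...``.

    Genes mapped to zero SNPs are omitted (and logged), preserving the
    invariant that every written gene has at least one SNP.
    """
    n_empty = 0
    with open(path, "w") as fh:
        fh.write(f"# mode={annotation.mode}\n")
        for gene_id, snps in annotation.entries.items():
            if not snps:
                n_empty += 1
                continue
            span = annotation.loci.get(gene_id, "NA")
            fh.write(f"{gene_id}\t{span}\t" + "\t".join(snps) + "\n")
    if n_empty:
        logger.info("write_annotation: omitted %d gene(s) with 0 SNPs", n_empty)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read an annotation file written by :func:`write_annotation`."""
    entries: dict[str, list[str]] = {}
    loci: dict[str, str] = {}
    mode = "positional"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "mode=" in line:
                    mode = line.split("mode=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected gene, span, >= 1 SNP")
            gene_id, span = parts[0], parts[1]
            snps = list(dict.fromkeys(parts[2:]))  # dedupe, keep order
            if gene_id in entries:
                warnings.warn(f"{path}:{lineno}: duplicate gene {gene_id}; keeping first")
                continue
            entries[gene_id] = snps
            if span != "NA":
                loci[gene_id] = span
    return GeneAnnotation(entries=entries, mode=mode, loci=loci)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "GENE", "CHR", "START", "STOP", "NSNPS", "NUSED", "STAT", "P", "P_FDR", "P_BONF",
]


def write_gene_results(results: Iterable[GeneTestResult], path: str | Path) -> None:
    """Write gene-level results as a TSV with the canonical header."""
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.chromosome,
                        str(r.start_bp),
                        str(r.end_bp),
                        str(r.n_snps_annotated),
                        str(r.n_snps_used),
                        f"{r.stat:.6g}",
                        f"{r.p_nominal:.6g}",
                        "NA" if r.p_fdr is None else f"{r.p_fdr:.6g}",
                        "NA" if r.p_bonferroni is None else f"{r.p_bonferroni:.6g}",
                    ]
                )
                + "\n"
            )


def read_gene_results(path: str | Path) -> pd.DataFrame:
    """Read a gene-level results TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"GENE": str, "CHR": str})
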