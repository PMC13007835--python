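"""Per-gene linkage-disequilibrium (LD) blocks from a genotype panel.

The gene test's null distribution depends only on the eigenvalue spectrum of
the SNP-by-SNP Pearson correlation matrix over the gene's usable SNPs.  This
module builds that matrix from hard-call genotypes (per-SNP mean imputation
of missing calls) and intersects the three SNP sources — annotation, summary
statistics, QC-passing panel — into the per-gene usable list.

No allele alignment between the summary statistics and the panel is
performed: the mean-chi-square statistic is sign-free, so the orientation of
the correlation (which flips with allele coding) never enters the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GeneAnnotation, SummaryStatRecord, VariantRecord

logger = logging.getLogger(__name__)

#: Eigenvalues below this are treated as numerically zero.
EIG_CLIP_TOL = 1e-8


@dataclass
class LDBlock:
    """SNP correlation matrix for one gene, with its eigenvalue spectrum.

    ``R`` is symmetric with unit diagonal; ``eigenvalues`` are non-increasing
    and clipped at zero, so their sum equals the SNP count (trace of R) up to
    the clipping tolerance.
    """

    snp_ids: list[str]
    R: np.ndarray
    eigenvalues: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.R.shape != (m, m):
            raise ValueError(f"R shape {self.R.shape} != ({m}, {m})")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R is not symmetric")
        eig = np.linalg.eigvalsh(self.R)[::-1]
        eig = np.where(eig < EIG_CLIP_TOL, 0.0, eig)
        self.eigenvalues = eig

    @property
    def m(self) -> int:
        return len(self.snp_ids)


def build_ld_block(
    genotypes: np.ndarray,
    snp_ids: Sequence[str],
    snp_subset: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> LDBlock:
    """Estimate an LD block from hard-call genotypes.

    ``genotypes`` is individuals x SNPs (dosage 0/1/2, NaN missing) with
    columns named by ``snp_ids``; ``snp_subset`` selects and orders the
    columns to use (default: all).  Missing calls are mean-imputed per SNP,
    columns are standardized, and R is the sample Pearson correlation.
    Zero-variance columns after imputation are dropped with a warning.
    ``ridge`` applies optional shrinkage ``R <- (1-g) R + g I`` for
    ill-conditioned blocks (default off).
    """
    if snp_subset is None:
        snp_subset = list(snp_ids)
    if len(snp_subset) == 0:
        raise ValueError("empty SNP subset")
    index = {s: j for j, s in enumerate(snp_ids)}
    try:
        cols = [index[s] for s in snp_subset]
    except KeyError as exc:
        raise KeyError(f"SNP {exc.args[0]} not in panel") from None
    X = np.array(genotypes[:, cols], dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 individuals to estimate correlations")

    # Per-SNP mean imputation of missing calls.
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.all():
        dropped = [s for s, k in zip(snp_subset, ok) if not k]
        warnings.warn(f"{len(dropped)} zero-variance SNP(s) dropped from LD block")
        X = X[:, ok]
        snp_subset = [s for s, k in zip(snp_subset, ok) if k]
        if X.shape[1] == 0:
            raise ValueError("all SNPs in subset have zero variance")

    R = np.corrcoef(X, rowvar=False)
    if R.ndim == 0:  # single SNP
        R = np.array([[1.0]])
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    if ridge > 0.0:
        R = (1.0 - ridge) * R + ridge * np.eye(R.shape[0])
    return LDBlock(snp_ids=list(snp_subset), R=R)


def intersect_sources(
    annotation: GeneAnnotation,
    summary_stats: Iterable[SummaryStatRecord] | Mapping[str, float],
    panel_variants: Iterable[VariantRecord] | Iterable[str],
) -> tuple[dict[str, list[str]], dict[str, dict[str, int]], list[str]]:
    """Per-gene usable SNP lists: annotated ∩ summary stats ∩ panel.

    Order follows the annotation order.  Returns ``(usable, accounting,
    excluded)`` where ``accounting[gene] = {"n_annotated", "n_used"}`` and
    ``excluded`` lists genes with zero usable SNPs (removed from
    ``usable``).
    """
    if isinstance(summary_stats, Mapping):
        stat_ids = set(summary_stats)
    else:
        stat_ids = {r.snp_id for r in summary_stats}
    panel_ids = {
        v.snp_id if isinstance(v, VariantRecord) else str(v) for v in panel_variants
    }

    usable: dict[str, list[str]] = {}
    accounting: dict[str, dict[str, int]] = {}
    excluded: list[str] = []
    for gene_id, snps in annotation.entries.items():
        used = [s for s in snps if s in stat_ids and s in panel_ids]
        accounting[gene_id] = {"n_annotated": len(snps), "n_used": len(used)}
        if used:
            usable[gene_id] = used
        else:
            excluded.append(gene_id)
    if excluded:
        logger.info("%d gene(s) with no usable SNPs excluded from testing", len(excluded))
    return usable, accounting, excluded
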