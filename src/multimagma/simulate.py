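"""Synthetic fixtures with planted ground truth for every pipeline input.

Three generators cover the pipeline's inputs:

* :func:`simulate_reference_panel` — a PLINK genotype panel whose per-gene
  SNP blocks carry a *target* AR(rho) correlation structure
  (``R_target[i, j] = rho ** |i - j|``) on the genotype scale.  Each
  haplotype's allele indicators follow a stationary two-state Markov chain
  along the block (stationary allele frequency f, second eigenvalue rho),
  whose autocorrelation at lag d is exactly ``rho ** d``; a genotype is the
  sum of two independent haplotypes, so genotype correlations equal the
  target exactly in expectation and marginals are Binomial(2, f)
  (Hardy-Weinberg).
* :func:`simulate_summary_stats` — per-gene SNP z-scores drawn from
  ``N(mu, R_target)`` with ``mu = 0`` for null genes and ``mu = delta * 1``
  for causal genes; two-sided normal p-values.
* :func:`simulate_meqtl_fixture` — meQTL pair and CpG-to-gene link tables
  constructed so the SNP-CpG-gene join has exactly the planted
  cardinalities, plus configurable unmapped CpGs and supra-threshold FDR
  rows to exercise the filters.

All randomness flows from the spec's single seed through named
``SeedSequence`` streams, so each artifact is independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .annotate import QtlPair
from .formats_io import (
    GeneAnnotation,
    GeneLocus,
    SummaryStatRecord,
    VariantRecord,
    write_gene_loc,
    write_plink_panel,
    write_summary_stats,
)
from .memagma import CpgGeneLink, TripletReport

__all__ = [
    "FixtureSpec",
    "MeqtlSpec",
    "PanelTruth",
    "simulate_reference_panel",
    "simulate_summary_stats",
    "simulate_meqtl_fixture",
    "ar_correlation",
]


@dataclass
class MeqtlSpec:
    """Planted cardinalities for the meQTL join fixture.

    ``n_cpgs``/``n_snps``/``n_triplets`` are the cardinalities the join must
    reproduce exactly; ``unmapped_fraction`` adds ``ceil(frac * n_cpgs)``
    extra CpGs that have pairs but no gene link; ``supra_fdr_fraction`` adds
    pairs whose FDR exceeds the 5% threshold (they must be filtered out
    before the join).
    """

    n_cpgs: int = 100
    n_snps: int = 300
    n_triplets: int = 450
    unmapped_fraction: float = 0.1
    supra_fdr_fraction: float = 0.1
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if self.n_cpgs < 2 or self.n_snps < 2:
            raise ValueError("need at least 2 CpGs and 2 SNPs")
        if self.n_triplets < max(self.n_cpgs, self.n_snps):
            raise ValueError(
                f"n_triplets={self.n_triplets} infeasible: every CpG and every "
                f"SNP must appear in at least one triplet, so n_triplets >= "
                f"max(n_cpgs, n_snps) = {max(self.n_cpgs, self.n_snps)}"
            )


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic panel and summary statistics.

    Defaults mirror the calibration experiments: 2 000 panel individuals,
    10 SNPs per gene in an AR(0.8) LD block, allele frequencies in
    [0.1, 0.5], causal genes shifting every SNP z-score by ``delta``.
    """

    n_individuals: int = 2000
    n_genes: int = 50
    snps_per_gene: int = 10
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_genes: tuple[str, ...] = ()
    delta: float = 2.0
    seed: int = 1
    meqtl: MeqtlSpec = field(default_factory=MeqtlSpec)

    def validate(self) -> None:
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_individuals < 2 or self.n_genes < 1 or self.snps_per_gene < 1:
            raise ValueError("n_individuals >= 2, n_genes >= 1, snps_per_gene >= 1")


@dataclass
class PanelTruth:
    """In-memory result of panel simulation with the planted LD targets."""

    spec: FixtureSpec
    variants: list[VariantRecord]
    genotypes: np.ndarray
    genes: list[GeneLocus]
    snps_by_gene: dict[str, list[str]]
    target_R: dict[str, np.ndarray]

    def positional_annotation(self) -> GeneAnnotation:
        """The true gene-to-SNP assignment used by the generator."""
        loci = {
            g.gene_id: f"{g.chromosome}:{g.start_bp}:{g.end_bp}" for g in self.genes
        }
        return GeneAnnotation(
            entries={g: list(s) for g, s in self.snps_by_gene.items()},
            mode="positional",
            loci=loci,
        )


def ar_correlation(m: int, rho: float) -> np.ndarray:
    """AR(rho) correlation matrix: R[i, j] = rho ** |i - j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------


def _haplotype_block(rng: np.random.Generator, n: int, m: int, f: float, rho: float) -> np.ndarray:
    """n haplotypes of m allele indicators from a stationary two-state
    Markov chain with stationary frequency f and second eigenvalue rho.

    Each step copies the previous indicator with probability rho and
    redraws Bernoulli(f) otherwise, so corr(I_i, I_j) = rho ** |i - j|
    exactly and every marginal is Bernoulli(f).
    """
    fresh = (rng.random((n, m)) < f)
    copy = rng.random((n, m)) < rho
    hap = np.empty((n, m), dtype=bool)
    hap[:, 0] = fresh[:, 0]
    for j in range(1, m):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    return hap


def _stream(seed: int, *tags: int) -> np.random.Generator:
    """Independent, reproducible random stream for one artifact."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def _gene_layout(spec: FixtureSpec) -> list[GeneLocus]:
    """Lay genes out round-robin over the autosomes, 1 Mb apart."""
    genes = []
    span = spec.snps_per_gene * 100
    for g in range(spec.n_genes):
        chrom = str((g % 22) + 1)
        block = g // 22
        start = 1_000_000 + block * 1_000_000
        genes.append(
            GeneLocus(
                gene_id=f"G{g + 1:04d}",
                chromosome=chrom,
                start_bp=start,
                end_bp=start + span,
                strand="+",
                symbol=f"SYM{g + 1:04d}",
            )
        )
    return genes


def simulate_reference_panel(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> PanelTruth:
    """Simulate a reference panel with per-gene AR(rho) LD blocks.

    One allele frequency is drawn per gene from ``maf_range`` and shared by
    the block's SNPs (tightly linked SNPs on a common haplotype background
    have similar frequencies; sharing the frequency keeps the AR correlation
    target exactly attainable).  Genotypes are sums of two independent
    Markov-chain haplotypes (:func:`_haplotype_block`), so the genotype
    correlation at lag d is ``rho ** d`` exactly in expectation and
    marginals are Binomial(2, f).

    When ``out_dir`` is given, writes ``panel.{bed,bim,fam}``,
    ``genes.loc`` and a ``panel.truth.json`` sidecar recording the target
    correlation parameters.
    """
    spec.validate()
    genes = _gene_layout(spec)
    m = spec.snps_per_gene
    lo, hi = spec.maf_range
    n = spec.n_individuals

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    snps_by_gene: dict[str, list[str]] = {}
    target_R: dict[str, np.ndarray] = {}
    R_t = ar_correlation(m, spec.block_rho)

    for g_idx, gene in enumerate(genes):
        rng = _stream(spec.seed, 1, g_idx)
        f = rng.uniform(lo, hi)
        hap1 = _haplotype_block(rng, n, m, f, spec.block_rho)
        hap2 = _haplotype_block(rng, n, m, f, spec.block_rho)
        geno = hap1.astype(float) + hap2.astype(float)

        snp_ids = []
        for j in range(m):
            snp_id = f"rs{g_idx + 1:04d}_{j + 1:03d}"
            snp_ids.append(snp_id)
            variants.append(
                VariantRecord(
                    snp_id=snp_id,
                    chromosome=gene.chromosome,
                    position_bp=gene.start_bp + j * 100,
                    allele1="A",
                    allele2="G",
                    maf=None,
                )
            )
        columns.append(geno)
        snps_by_gene[gene.gene_id] = snp_ids
        target_R[gene.gene_id] = R_t

    genotypes = np.hstack(columns)
    # Attach realized MAFs.
    freq = genotypes.mean(axis=0) / 2.0
    for j, v in enumerate(variants):
        v.maf = float(min(freq[j], 1.0 - freq[j]))

    truth = PanelTruth(
        spec=spec,
        variants=variants,
        genotypes=genotypes,
        genes=genes,
        snps_by_gene=snps_by_gene,
        target_R=target_R,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_plink_panel(variants, genotypes, out_dir / "panel")
        write_gene_loc(genes, out_dir / "genes.loc")
        sidecar = {
            "seed": spec.seed,
            "block_rho": spec.block_rho,
            "snps_per_gene": m,
            "genes": {g.gene_id: snps_by_gene[g.gene_id] for g in genes},
        }
        (out_dir / "panel.truth.json").write_text(json.dumps(sidecar, indent=1))
    return truth


def simulate_summary_stats(
    truth: PanelTruth,
    causal_genes: Sequence[str] | None = None,
    delta: float | None = None,
    seed: int | None = None,
    out_path: str | Path | None = None,
) -> list[SummaryStatRecord]:
    """Simulate GWAS summary statistics over the panel's SNPs.

    Per gene, z-scores are drawn from ``N(mu, R_target)`` with the gene's
    planted LD target as covariance; ``mu = delta * 1`` for causal genes and
    0 otherwise.  P-values are two-sided normal tails.  Defaults for
    ``causal_genes``/``delta``/``seed`` come from the spec.
    """
    spec = truth.spec
    causal = set(causal_genes if causal_genes is not None else spec.causal_genes)
    d = spec.delta if delta is None else delta
    base_seed = spec.seed if seed is None else seed

    records: list[SummaryStatRecord] = []
    for g_idx, gene in enumerate(truth.genes):
        rng = _stream(base_seed, 2, g_idx)
        R = truth.target_R[gene.gene_id]
        m = R.shape[0]
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(m))
        mu = d if gene.gene_id in causal else 0.0
        z = mu + chol @ rng.standard_normal(m)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, 1e-300, 1.0)
        for snp_id, pj in zip(truth.snps_by_gene[gene.gene_id], p):
            records.append(SummaryStatRecord(snp_id=snp_id, p_value=float(pj)))
    if out_path is not None:
        write_summary_stats(records, out_path)
    return records


# ---------------------------------------------------------------------------
# meQTL fixture with planted join cardinalities
# ---------------------------------------------------------------------------


def simulate_meqtl_fixture(
    meqtl_spec: MeqtlSpec, seed: int = 1
) -> tuple[list[QtlPair], list[CpgGeneLink], TripletReport]:
    """Construct meQTL pairs and CpG-gene links whose join has exactly the
    planted cardinalities.

    Construction: the first CpG receives exactly one pair (with the first
    SNP, used nowhere else); the remaining SNPs and CpGs are paired
    round-robin so every SNP and every CpG appears, giving
    ``P = max(n_snps, n_cpgs)`` distinct pairs.  With one gene link per CpG
    that yields P triplets; the deficit ``n_triplets - P`` is closed by
    granting extra gene links to CpGs greedily (adding a link to a CpG with
    k pairs adds exactly k triplets; the single-pair first CpG guarantees
    termination).  Unmapped CpGs and supra-threshold FDR pairs are appended
    on top and must be removed by the join's filters.
    """
    meqtl_spec.validate()
    rng = _stream(seed, 3)
    C, S, T = meqtl_spec.n_cpgs, meqtl_spec.n_snps, meqtl_spec.n_triplets

    cpg_ids = [f"cg{i + 1:07d}" for i in range(C)]
    snp_ids = [f"rsme{i + 1:06d}" for i in range(S)]

    # Pair construction: CpG 1 <- SNP 1 only; round-robin over the rest.
    pairs_idx: list[tuple[int, int]] = [(0, 0)]  # (snp, cpg)
    P = max(S, C)
    for t in range(P - 1):
        s = 1 + (t % (S - 1))
        c = 1 + (t % (C - 1))
        pairs_idx.append((s, c))

    # Pair counts per CpG, then extra links to reach the planted triplets.
    k = np.zeros(C, dtype=int)
    for _, c in pairs_idx:
        k[c] += 1
    links_per_cpg = np.ones(C, dtype=int)
    deficit = T - P
    order = np.argsort(-k)  # prefer closing the deficit in large steps
    while deficit > 0:
        for c in order:
            if k[c] <= deficit:
                links_per_cpg[c] += 1
                deficit -= k[c]
                break

    n_gene_pool = max(int(links_per_cpg.max()), 3)
    gene_symbols = [f"MEG{i + 1:04d}" for i in range(n_gene_pool)]

    links: list[CpgGeneLink] = []
    for c in range(C):
        for j in range(links_per_cpg[c]):
            gi = (c + j) % n_gene_pool
            links.append(
                CpgGeneLink(
                    cpg_id=cpg_ids[c],
                    gene_symbol=gene_symbols[gi],
                    ensembl_id=f"ENSME{gi + 1:06d}",
                )
            )

    pairs: list[QtlPair] = [
        QtlPair(
            snp_id=snp_ids[s],
            target_id=cpg_ids[c],
            fdr=float(rng.uniform(0.0, meqtl_spec.fdr_threshold)),
        )
        for s, c in pairs_idx
    ]

    # Unmapped CpGs: pairs present, no gene link.
    n_unmapped = math.ceil(meqtl_spec.unmapped_fraction * C)
    for i in range(n_unmapped):
        pairs.append(
            QtlPair(
                snp_id=f"rsun{i + 1:06d}",
                target_id=f"cgun{i + 1:07d}",
                fdr=float(rng.uniform(0.0, meqtl_spec.fdr_threshold)),
            )
        )

    # Supra-threshold pairs: must be filtered out before the join.
    n_supra = math.ceil(meqtl_spec.supra_fdr_fraction * P)
    for i in range(n_supra):
        pairs.append(
            QtlPair(
                snp_id=f"rssup{i + 1:06d}",
                target_id=cpg_ids[int(rng.integers(0, C))],
                fdr=float(rng.uniform(meqtl_spec.fdr_threshold + 0.01, 1.0)),
            )
        )

    planted = TripletReport(
        n_unique_cpgs=C,
        n_unique_snps=S,
        n_triplets=T,
        n_unmapped_cpgs=n_unmapped,
        n_genes=len({(c + j) % n_gene_pool for c in range(C) for j in range(links_per_cpg[c])}),
    )
    return pairs, links, planted
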