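"""Multiple-testing adjustment of gene p-values and cross-method overlaps.

Adjustment is applied per analysis run (per phenotype x annotation mode),
never pooled across modes, and m is the number of genes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Each adjusted value is >= the raw one and capped at 1; ties follow the
    step-up cumulative-minimum rule.  Empty input gives empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def adjust_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: min(1, m*p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    return [float(v) for v in np.minimum(1.0, p * p.size)]


@dataclass
class OverlapReport:
    """Exact region counts for the intersection of per-method significant
    gene sets (the numbers a Venn diagram would display)."""

    methods: list[str]
    significant: dict[str, set[str]]
    region_counts: dict[frozenset[str], int]
    common_to_all: list[str]

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "significant_counts": {m: len(s) for m, s in self.significant.items()},
            "regions": {
                "+".join(sorted(k)): v for k, v in self.region_counts.items() if v
            },
            "common_to_all": self.common_to_all,
        }


def overlap_report(
    results_by_method: Mapping[str, Sequence],
    alpha: float = 0.05,
    adjusted_by: str = "fdr",
) -> OverlapReport:
    """Cross-method overlap of significant genes.

    ``results_by_method`` maps a method name to its GeneTestResult list (or
    to a pre-computed set of significant gene ids).  Significance is
    adjusted p <= alpha using the chosen adjustment (``fdr`` or
    ``bonferroni``).  Supports up to 5 methods; every gene in the union is
    counted in exactly one intersection region.
    """
    if len(results_by_method) < 2:
        raise ValueError("need >= 2 methods to report overlaps")
    if len(results_by_method) > 5:
        raise ValueError("more than 5 methods unsupported; compare pairwise instead")
    if adjusted_by not in ("fdr", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjusted_by!r}")

    significant: dict[str, set[str]] = {}
    for name, results in results_by_method.items():
        if isinstance(results, (set, frozenset)):
            significant[name] = set(results)
            continue
        sig: set[str] = set()
        for r in results:
            p_adj = r.p_fdr if adjusted_by == "fdr" else r.p_bonferroni
            if p_adj is not None and p_adj <= alpha:
                sig.add(r.gene_id)
        significant[name] = sig

    methods = list(significant)
    universe = set().union(*significant.values())
    region_counts: dict[frozenset[str], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            region_counts[frozenset(combo)] = 0
    for gene in universe:
        members = frozenset(m for m in methods if gene in significant[m])
        region_counts[members] += 1

    common = sorted(set.intersection(*significant.values())) if methods else []
    return OverlapReport(
        methods=methods,
        significant=significant,
        region_counts=region_counts,
        common_to_all=common,
    )
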