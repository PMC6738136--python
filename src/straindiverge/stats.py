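"""Functional-category-stratified statistics and KEGG-module completeness.

Per-gene variant rates are grouped by functional category. Within each
category, a one-way ANOVA compares each variant type's per-gene rates across
the strains; between-strain mutation rates (pairwise gene divergence) are
compared across strain pairs with a Kruskal-Wallis test because those rates
are far from normal. Results are flagged significant at P < 0.01, with no
multiple-testing correction by default (Holm available behind a flag).
Wilcoxon signed-rank post-hoc tests compare groups pairwise on matched
items; unmatched items are dropped.

A KEGG module is complete in a strain if all genes of a two-gene module are
present, or at most one gene of a larger module is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

ALPHA = 0.01
ANOVA, KRUSKAL, WILCOXON = "one-way ANOVA", "Kruskal-Wallis", "Wilcoxon signed-rank"


@dataclass
class StatResult:
    test: str
    grouping: str
    statistic: float
    pvalue: float
    n: int
    alpha: float = ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


@dataclass
class ModuleDefinition:
    module_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(
                f"module {self.module_id} needs at least two genes"
            )


class InsufficientGroups(RuntimeError):
    pass


def module_complete(module: ModuleDefinition, present_genes: set[str] | frozenset[str]) -> bool:
    """Two-gene modules must be complete; larger ones may miss one gene."""
    missing = len(module.genes - set(present_genes))
    if len(module.genes) == 2:
        return missing == 0
    return missing <= 1


def _group_test(
    groups: list[np.ndarray], test: str, grouping: str, alpha: float
) -> StatResult:
    n = sum(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return StatResult(test, grouping, float("nan"), 1.0, n, alpha, degenerate=True)
    if test == ANOVA:
        stat, p = sps.f_oneway(*groups)
    else:
        stat, p = sps.kruskal(*groups)
    if not np.isfinite(p):
        return StatResult(test, grouping, float(stat), 1.0, n, alpha, degenerate=True)
    return StatResult(test, grouping, float(stat), float(p), n, alpha)


def allelic_variation_tests(
    rates_by_strain: dict[str, np.ndarray],
    grouping: str = "",
    alpha: float = ALPHA,
    min_genes: int = 3,
) -> StatResult:
    """One-way ANOVA of per-gene rates across strains within one category
    (one variant type at a time)."""
    groups = [np.asarray(v, dtype=float) for _, v in sorted(rates_by_strain.items())]
    if len(groups) < 2 or any(g.size < min_genes for g in groups):
        raise InsufficientGroups(
            f"need >=2 strains with >={min_genes} genes each in {grouping!r}"
        )
    return _group_test(groups, ANOVA, grouping, alpha)


def between_strain_tests(
    rates_by_pair: dict[tuple[str, str], np.ndarray],
    grouping: str = "",
    alpha: float = ALPHA,
    min_genes: int = 3,
) -> StatResult:
    """Kruskal-Wallis on per-family mutation rates grouped by strain pair."""
    groups = [np.asarray(v, dtype=float) for _, v in sorted(rates_by_pair.items())]
    if len(groups) < 2 or any(g.size < min_genes for g in groups):
        raise InsufficientGroups(
            f"need >=2 strain pairs with >={min_genes} families each in {grouping!r}"
        )
    return _group_test(groups, KRUSKAL, grouping, alpha)


def wilcoxon_posthoc(
    values_by_group: dict[str, dict[str, float]],
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[StatResult]:
    """Pairwise Wilcoxon signed-rank between groups on matched items.

    ``values_by_group`` maps group label -> {item id -> value}; each pair of
    groups is compared on the items present in both, the rest dropped.
    """
    labels = sorted(values_by_group)
    results: list[StatResult] = []
    for a, b in combinations(labels, 2):
        shared = sorted(set(values_by_group[a]) & set(values_by_group[b]))
        grouping = f"{a} vs {b}"
        if len(shared) < 3:
            results.append(
                StatResult(WILCOXON, grouping, float("nan"), 1.0, len(shared), alpha, True)
            )
            continue
        x = np.array([values_by_group[a][i] for i in shared])
        y = np.array([values_by_group[b][i] for i in shared])
        if np.allclose(x, y):
            results.append(
                StatResult(WILCOXON, grouping, float("nan"), 1.0, len(shared), alpha, True)
            )
            continue
        stat, p = sps.wilcoxon(x, y, zero_method="wilcox")
        results.append(StatResult(WILCOXON, grouping, float(stat), float(p), len(shared), alpha))
    if holm:
        results = holm_correct(results)
    return results


def holm_correct(results: list[StatResult]) -> list[StatResult]:
    order = np.argsort([r.pvalue for r in results])
    m = len(results)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        p_adj = min(1.0, (m - rank) * results[idx].pvalue)
        running = max(running, p_adj)
        adjusted[idx] = running
    return [
        StatResult(r.test, r.grouping, r.statistic, adjusted[i], r.n, r.alpha, r.degenerate)
        for i, r in enumerate(results)
    ]


def read_category_table(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, cat = line.rstrip("\n").split("\t")[:2]
            out[gene] = cat or "unannotated"
    return out


def read_module_table(path) -> list[ModuleDefinition]:
    """TSV with columns module_id<TAB>gene (one row per module gene)."""
    genes: dict[str, set[str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mod, gene = line.rstrip("\n").split("\t")[:2]
            genes.setdefault(mod, set()).add(gene)
    return [ModuleDefinition(m, frozenset(g)) for m, g in sorted(genes.items())]
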