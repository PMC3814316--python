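"""Tissue-expression ranking and top-tissue assignment.

Average expression differs strongly between tissue cDNA libraries, so raw
abundances are not comparable across tissues. Genes are therefore ranked
within each tissue (1 = lowest; ties get the average rank) and each gene is
assigned the tissue where it attains its highest rank — its tissue of
highest normalized expression. Class compositions per tissue are compared
with a fold of proportions and Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ExpressionMatrix
from .stats import ContingencyTable2x2, chi2_2x2, fisher_exact_2x2, fold_of_proportions

__all__ = [
    "RankMatrix",
    "rank_within_tissue",
    "top_tissue_per_gene",
    "TissueAssignment",
    "tissue_class_enrichment",
]


class RankMatrix:
    """Genes x tissues matrix of within-tissue ranks (tie-averaged)."""

    def __init__(self, ranks: pd.DataFrame) -> None:
        self.ranks = ranks

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass(frozen=True)
class TissueAssignment:
    """Per-gene top tissue with a flag for cross-tissue rank ties."""

    tissue: str
    tied: bool


def rank_within_tissue(expr: ExpressionMatrix) -> RankMatrix:
    """Rank genes within each tissue, ascending with expression."""
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    ranked = expr.values.apply(lambda col: rankdata(col, method="average"), axis=0)
    return RankMatrix(pd.DataFrame(ranked, index=expr.genes, columns=expr.tissues))


def top_tissue_per_gene(
    ranks: RankMatrix,
    exclude_all_zero_of: ExpressionMatrix | None = None,
) -> dict[str, TissueAssignment]:
    """Assign each gene the tissue of its highest rank.

    Ties across tissues resolve to the first tissue in declared column order
    and are flagged. Genes with all-zero expression (when the source matrix
    is supplied) are excluded: an argmax over a flat zero profile carries no
    signal.
    """
    excluded: set[str] = set()
    if exclude_all_zero_of is not None:
        zero = (exclude_all_zero_of.values == 0).all(axis=1)
        excluded = set(exclude_all_zero_of.values.index[zero])
    arr = ranks.ranks.to_numpy()
    out: dict[str, TissueAssignment] = {}
    for i, gene in enumerate(ranks.genes):
        if gene in excluded:
            continue
        row = arr[i]
        j = int(np.argmax(row))
        tied = bool(np.sum(row == row[j]) > 1)
        out[gene] = TissueAssignment(tissue=ranks.tissues[j], tied=tied)
    return out


def tissue_class_enrichment(
    group_a: set[str],
    group_b: set[str],
    assignments: Mapping[str, TissueAssignment],
    tissue: str,
    test: str = "fisher",
) -> tuple[float, float]:
    """Fold and p for tissue-assignment enrichment of group A over group B.

    fold = (k_A/n_A)/(k_B/n_B) with k = members assigned to ``tissue``; the
    p-value comes from the two-sided Fisher exact test on the 2x2 table
    (``test="chi2"`` switches to Pearson chi-square).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    k_a = sum(1 for g in group_a if g in assignments and assignments[g].tissue == tissue)
    k_b = sum(1 for g in group_b if g in assignments and assignments[g].tissue == tissue)
    n_a, n_b = len(group_a), len(group_b)
    fold = fold_of_proportions(k_a, n_a, k_b, n_b)
    table = ContingencyTable2x2(k_a, n_a - k_a, k_b, n_b - k_b)
    if test == "fisher":
        p = fisher_exact_2x2(table)
    elif test == "chi2":
        p = chi2_2x2(table)[1]
    else:
        raise ValueError(f"unknown test {test!r}")
    return fold, p
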