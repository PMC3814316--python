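"""Shared exact/asymptotic statistics and seeded random-set sampling.

Thin, validated wrappers over :mod:`scipy.stats` plus the one sampling
primitive every permutation test in the pipeline funnels through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "hypergeometric_pvalue",
    "chi2_2x2",
    "fisher_exact_2x2",
    "fold_of_proportions",
    "draw_random_gene_sets",
    "bh_qvalues",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group A in/out of a class and (c, d) for group B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing n from N with K successes.

    Exact tail computed by scipy's hypergeometric survival function, which
    stays finite on genome-scale backgrounds (N ~ 2e4).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}"
        )
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def chi2_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (1 df), optional continuity correction."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero marginal in 2x2 table")
    res = sps.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


def fold_of_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """(k1/n1) / (k2/n2); infinite when k2 = 0 and k1 > 0, NaN when both 0."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    if p2 == 0:
        return float("nan") if p1 == 0 else float("inf")
    return p1 / p2


def draw_random_gene_sets(
    universe: Sequence[str],
    size: int,
    n_sets: int,
    seed: int,
    disjoint_from_previous: bool = False,
) -> list[frozenset[str]]:
    """Draw ``n_sets`` uniform random gene sets of ``size`` from ``universe``.

    Sampling is without replacement within each set; with
    ``disjoint_from_previous``, an element is used at most once across all
    sets. Deterministic under a fixed seed (the universe is sorted before
    sampling so results do not depend on input ordering).
    """
    pool = sorted(set(universe))
    if size > len(pool):
        raise ValueError(f"set size {size} exceeds universe size {len(pool)}")
    if disjoint_from_previous and n_sets * size > len(pool):
        raise ValueError(
            f"cannot draw {n_sets} disjoint sets of {size} from {len(pool)} genes"
        )
    rng = np.random.default_rng(seed)
    out: list[frozenset[str]] = []
    for _ in range(n_sets):
        idx = rng.choice(len(pool), size=size, replace=False)
        chosen = frozenset(pool[i] for i in idx)
        out.append(chosen)
        if disjoint_from_previous:
            pool = [g for g in pool if g not in chosen]
    return out


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
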