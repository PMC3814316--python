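"""Phototaxis quantification and per-gene phenotype aggregation.

The countercurrent phototaxis assay fractionates a population of flies over
six tubes by their movement toward light. The Phototaxis Index

    PI = (sum_i i * N_i) / N,   i = 1..6

(N_i flies end in tube i, N total) ranges from 1 (fully photo-unresponsive)
to 6 (all flies reach the last tube). Wild-type-like controls score around
5.2; a line is called a phototaxis hit below a stringent cut-off of 4.

Per-gene phenotype profiles take the union of category calls over that
gene's RNAi lines (a single positive line suffices: RNAi knockdown is
variable, so one inefficient line must not veto an efficient one), and are
then folded into major classes: EMD (any of the 13 eye-morphology
categories), ERG_defective, lethal, and NED (no phenotype at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import (
    MORPHOLOGY_CATEGORIES,
    GenePhenotypeProfile,
    PhenotypeCategory,
    ScreenLineResult,
)

__all__ = [
    "PhototaxisCounts",
    "phototaxis_index",
    "summarize_pi",
    "classify_phototaxis_hit",
    "aggregate_gene_phenotypes",
    "assign_major_classes",
    "DEFAULT_PI_THRESHOLD",
    "DEFAULT_MAX_PI_SD",
]

DEFAULT_PI_THRESHOLD = 4.0
DEFAULT_MAX_PI_SD = 1.2


@dataclass(frozen=True)
class PhototaxisCounts:
    """Fly counts per tube (tube 1 .. tube 6) of the countercurrent device."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != 6:
            raise ValueError("expected 6 tube counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("tube counts must be non-negative")
        if sum(self.counts) == 0:
            raise ValueError("no flies assayed (N = 0)")

    @property
    def total(self) -> int:
        return sum(self.counts)


def phototaxis_index(counts: PhototaxisCounts) -> float:
    """PI = (sum_i i*N_i)/N, bounded in [1, 6]."""
    weighted = sum(i * n for i, n in enumerate(counts.counts, start=1))
    return weighted / counts.total


def summarize_pi(
    replicates: Sequence[float], max_sd: float = DEFAULT_MAX_PI_SD
) -> tuple[float, Optional[float], bool]:
    """Mean and sample SD over replicate PIs, plus a QC flag.

    SD uses the n-1 denominator and is None for a single replicate. The QC
    flag is raised when SD exceeds ``max_sd`` (default 1.2, the screen's
    maximal accepted per-line spread).
    """
    if not replicates:
        raise ValueError("no PI replicates")
    n = len(replicates)
    mean = sum(replicates) / n
    if n == 1:
        return mean, None, False
    var = sum((x - mean) ** 2 for x in replicates) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, sd > max_sd


def classify_phototaxis_hit(
    mean_pi: float, threshold: float = DEFAULT_PI_THRESHOLD
) -> bool:
    """True iff mean PI is strictly below the cut-off (default PI < 4)."""
    if not (1.0 <= mean_pi <= 6.0):
        raise ValueError(f"mean PI {mean_pi} outside [1,6]")
    return mean_pi < threshold


def aggregate_gene_phenotypes(
    lines: Iterable[ScreenLineResult],
    s19_min: Optional[float] = None,
    pi_threshold: float = DEFAULT_PI_THRESHOLD,
) -> GenePhenotypeProfile:
    """Aggregate one gene's RNAi lines into a phenotype profile.

    Lines failing ``s19_min`` (if set; lines with missing s19 pass) are
    excluded first. Categories are the union over remaining lines;
    ``phototaxis_defective`` is added when any line's mean PI is a hit.
    The reported mean/SD are those of the line with the lowest mean PI
    (the gene's strongest phototaxis evidence, matching the
    any-line-is-a-hit rule).
    """
    lines = list(lines)
    if not lines:
        raise ValueError("no screen lines to aggregate")
    fly_ids = {ln.fly_id for ln in lines}
    if len(fly_ids) != 1:
        raise ValueError(f"lines span multiple genes: {sorted(fly_ids)}")
    gene_id = fly_ids.pop()

    if s19_min is not None:
        lines = [ln for ln in lines if ln.s19 is None or ln.s19 >= s19_min]
        if not lines:
            return assign_major_classes(GenePhenotypeProfile(gene_id=gene_id))

    categories: set[PhenotypeCategory] = set()
    for ln in lines:
        categories |= ln.category_calls

    best: Optional[tuple[float, Optional[float]]] = None
    any_hit = False
    for ln in lines:
        if not ln.pi_replicates:
            continue
        mean, sd, _ = summarize_pi(ln.pi_replicates)
        if best is None or mean < best[0]:
            best = (mean, sd)
        if classify_phototaxis_hit(mean, pi_threshold):
            any_hit = True
    if any_hit:
        categories.add(PhenotypeCategory.PHOTOTAXIS_DEFECTIVE)

    profile = GenePhenotypeProfile(
        gene_id=gene_id,
        categories=frozenset(categories),
        mean_pi=best[0] if best else None,
        pi_sd=best[1] if best else None,
    )
    return assign_major_classes(profile)


def assign_major_classes(profile: GenePhenotypeProfile) -> GenePhenotypeProfile:
    """Fill in major classes: EMD / ERG_defective / lethal / NED.

    NED holds exactly when no category at all was called; the other classes
    are not mutually exclusive.
    """
    classes: set[str] = set()
    if profile.categories & MORPHOLOGY_CATEGORIES:
        classes.add("EMD")
    if PhenotypeCategory.ERG_DEFECTIVE in profile.categories:
        classes.add("ERG_defective")
    if PhenotypeCategory.LETHAL in profile.categories:
        classes.add("lethal")
    if not profile.categories:
        classes.add("NED")
    profile.major_classes = frozenset(classes)
    return profile
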