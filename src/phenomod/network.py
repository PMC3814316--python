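"""Interaction-network connectivity statistics.

Three related questions about a gene set on the combined interaction
network:

* how many unique connections fall **within** the set (``within_set_edge_count``);
* is that count larger than for random same-size gene sets —
  either uniform draws from a declared universe (``homotypic_enrichment``,
  the fold-enrichment statistic used per phenotype category) or
  degree-matched draws from the whole network (``pie_score``, the Physical
  Interaction Enrichment score, which corrects for the tendency of
  well-studied disease genes to carry more reported interactions);
* which connected gene groups share a phenotype category
  (``extract_homotypic_modules``): genes with non-overlapping phenotypes
  can never join the same module.

Empirical p-values use the add-one estimator (1 + #{null >= obs})/(n + 1),
so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import InteractionNetwork, PhenotypeCategory

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "HomotypicModule",
    "ModuleSummary",
    "within_set_edge_count",
    "homotypic_enrichment",
    "pie_score",
    "extract_homotypic_modules",
    "module_summary",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed within-set connectivity against a permutation null."""

    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_empirical: float
    n_perm: int
    seed: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class HomotypicModule:
    """Connected genes sharing one screen phenotype category."""

    category: PhenotypeCategory
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a module needs at least 2 genes")
        for a, b in self.edges:
            if a not in self.genes or b not in self.genes:
                raise ValueError(f"edge ({a},{b}) leaves the module gene set")


def within_set_edge_count(net: InteractionNetwork, genes: Iterable[str]) -> int:
    """Unique unordered pairs of ``genes`` connected in ``net``.

    Genes absent from the network contribute no edges.
    """
    gs = set(genes) & net.nodes
    adj = net.graph.adj
    total = 0
    for g in gs:
        total += sum(1 for nb in adj[g] if nb in gs)
    return total // 2


def _null_counts(
    adj: Sequence[frozenset[int]],
    draws: np.ndarray,
) -> np.ndarray:
    """Within-set edge counts for each row of integer gene draws."""
    out = np.empty(len(draws), dtype=np.int64)
    for r, row in enumerate(draws):
        members = set(int(x) for x in row)
        c = 0
        for g in members:
            c += sum(1 for nb in adj[g] if nb in members)
        out[r] = c // 2
    return out


def _summarize_null(
    observed: int, null: np.ndarray, seed: int
) -> EnrichmentResult:
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    degenerate = False
    if null_mean == 0.0:
        if observed > 0:
            fold = float("inf")
        else:
            fold = 1.0
            degenerate = True
    else:
        fold = observed / null_mean
    p = (1 + int(np.sum(null >= observed))) / (len(null) + 1)
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=fold,
        p_empirical=p,
        n_perm=len(null),
        seed=seed,
        degenerate=degenerate,
    )


def homotypic_enrichment(
    net: InteractionNetwork,
    category_genes: set[str],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    restrict_to_network: bool = True,
) -> EnrichmentResult:
    """Fold enrichment of within-category connections over uniform null sets.

    The null draws ``n_perm`` same-size gene sets uniformly (without
    replacement within a draw) from ``universe``. By default both the
    category and the universe are restricted to network-present genes, so
    set sizes match the genes that can actually contribute edges.
    """
    if not category_genes <= universe:
        raise ValueError("category_genes must be a subset of universe")
    if len(category_genes) < 2:
        raise ValueError("need at least 2 category genes")
    if restrict_to_network:
        universe = universe & net.nodes
        category_genes = category_genes & universe
        if len(category_genes) < 2:
            raise ValueError("fewer than 2 category genes present in the network")

    pool = sorted(universe)
    index = {g: i for i, g in enumerate(pool)}
    adj = [
        frozenset(index[nb] for nb in net.graph.adj[g] if nb in index)
        if g in net.nodes
        else frozenset()
        for g in pool
    ]
    observed = within_set_edge_count(net, category_genes)
    rng = np.random.default_rng(seed)
    k = len(category_genes)
    draws = np.empty((n_perm, k), dtype=np.int64)
    for r in range(n_perm):
        draws[r] = rng.choice(len(pool), size=k, replace=False)
    null = _null_counts(adj, draws)
    return _summarize_null(observed, null, seed)


def pie_score(
    net: InteractionNetwork,
    gene_set: set[str],
    n_samples: int = 1_000,
    seed: int = 0,
    degree_bins: int = 10,
) -> EnrichmentResult:
    """Physical Interaction Enrichment with a degree-aware null.

    Each null set substitutes every member with a gene drawn from the same
    equal-frequency degree-quantile bin of the whole network (never the gene
    itself, no duplicates within a draw). This normalization keeps the null
    comparable for gene sets whose members carry unusually many (or few)
    reported interactions. PIE = observed / null mean.
    """
    if len(gene_set) < 2:
        raise ValueError("need at least 2 genes")
    missing = gene_set - net.nodes
    if missing:
        raise ValueError(f"genes absent from network: {sorted(missing)[:5]}")
    if degree_bins < 1:
        raise ValueError("degree_bins must be >= 1")

    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    degrees = np.array([net.degree(g) for g in nodes], dtype=float)
    # equal-frequency bins on the degree distribution
    n_bins = min(degree_bins, len(nodes))
    qs = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    bin_of = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, len(edges) - 2) if len(edges) > 1 else np.zeros(len(nodes), dtype=int)
    bins: dict[int, list[int]] = {}
    for i, b in enumerate(bin_of):
        bins.setdefault(int(b), []).append(i)
    order = sorted(bins)

    def candidates_for(b: int) -> list[int]:
        # widen to neighboring bins until a substitute exists
        cand = list(bins[b])
        width = 1
        while len(cand) < 2 and width <= len(order):
            pos = order.index(b)
            lo, hi = max(0, pos - width), min(len(order), pos + width + 1)
            cand = [i for bb in order[lo:hi] for i in bins[bb]]
            width += 1
        if width > 1:
            logger.warning(
                "degree bin %d widened to %d neighbors: no substitute available",
                b,
                width - 1,
            )
        return cand

    member_bins = {index[g]: int(bin_of[index[g]]) for g in gene_set}
    by_bin: dict[int, list[int]] = {}
    for g, b in sorted(member_bins.items()):
        by_bin.setdefault(b, []).append(g)
    cand_cache = {b: candidates_for(b) for b in by_bin}

    adj = [frozenset(index[nb] for nb in net.graph.adj[g]) for g in nodes]
    observed = within_set_edge_count(net, gene_set)
    all_nodes = list(range(len(nodes)))

    rng = np.random.default_rng(seed)
    null = np.empty(n_samples, dtype=np.int64)
    for r in range(n_samples):
        chosen: set[int] = set()
        for b in sorted(by_bin):
            members = by_bin[b]
            pool = [c for c in cand_cache[b] if c not in chosen]
            if len(pool) < len(members):
                # widened bins of a large gene set can exhaust; fall back to
                # the whole network for the remainder
                extra = [c for c in all_nodes if c not in chosen and c not in pool]
                pool += extra
            picks = list(rng.choice(len(pool), size=len(members), replace=False))
            picks = [pool[i] for i in picks]
            # resolve self-substitutions by swapping within the draw
            for i, g in enumerate(members):
                if picks[i] != g:
                    continue
                for j in range(len(members)):
                    if j != i and picks[j] != g and members[j] != picks[i]:
                        picks[i], picks[j] = picks[j], picks[i]
                        break
                else:
                    spare = next(
                        (c for c in pool if c != g and c not in picks), None
                    )
                    if spare is not None:
                        picks[i] = spare
            chosen.update(picks)
        c = 0
        for g in chosen:
            c += sum(1 for nb in adj[g] if nb in chosen)
        null[r] = c // 2
    return _summarize_null(observed, null, seed)


def extract_homotypic_modules(
    net: InteractionNetwork,
    profiles: Mapping[str, Iterable[PhenotypeCategory]],
    category: PhenotypeCategory,
) -> list[HomotypicModule]:
    """Connected components (size >= 2) of the network restricted to genes
    carrying ``category``.

    Modules are ordered by size descending, then by lexicographically
    smallest gene.
    """
    carriers = {g for g, cats in profiles.items() if category in set(cats)}
    sub = net.graph.subgraph(carriers & net.nodes)
    modules: list[HomotypicModule] = []
    for comp in nx.connected_components(sub):
        if len(comp) < 2:
            continue
        comp_edges = frozenset(
            tuple(sorted((a, b))) for a, b in sub.subgraph(comp).edges
        )
        modules.append(
            HomotypicModule(
                category=category, genes=frozenset(comp), edges=comp_edges
            )
        )
    modules.sort(key=lambda m: (-len(m.genes), min(m.genes)))
    return modules


@dataclass(frozen=True)
class ModuleSummary:
    n_modules: int
    n_genes: int
    n_connections: int          # unique pairs, deduplicated across categories
    n_connections_by_category: int  # pair counted once per category

    def as_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "n_genes": self.n_genes,
            "n_connections": self.n_connections,
            "n_connections_by_category": self.n_connections_by_category,
        }


def module_summary(modules: Sequence[HomotypicModule]) -> ModuleSummary:
    """Counts over modules from all categories.

    A gene in modules of two categories counts once in ``n_genes``; a pair
    homotypic in two categories counts once in ``n_connections`` (the
    per-category tally is also reported).
    """
    genes: set[str] = set()
    unique_pairs: set[tuple[str, str]] = set()
    by_category = 0
    for m in modules:
        genes |= m.genes
        unique_pairs |= m.edges
        by_category += len(m.edges)
    return ModuleSummary(
        n_modules=len(modules),
        n_genes=len(genes),
        n_connections=len(unique_pairs),
        n_connections_by_category=by_category,
    )
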