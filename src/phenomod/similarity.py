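"""Ontology-based human phenotype similarity.

Each gene's direct phenotype-term annotations are turned into a weighted
feature vector over the ontology: rare terms weigh more
(weight = -ln(frequency), with frequency the fraction of annotated genes
carrying the term directly or via a descendant), long annotation lists are
down-weighted (division by the number of direct terms), and ancestors are
added recursively with geometrically decaying weight (factor ``decay`` per
level up) until the root. The root itself is dropped — it appears in every
augmented vector and would only inflate correlations. Because the genes
under study were ascertained through one designated phenotype, that
phenotype's entire subtree can be excluded so similarity reflects features
*beyond* the ascertainment criterion.

Similarity between two genes is the Pearson correlation of their vectors
over the union of their feature terms; a gene group's coherence is the mean
over all pairs, compared against equal-size random gene sets for an
empirical p-value.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from math import log, sqrt
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .core import AnnotationMap, Ontology
from .stats import ContingencyTable2x2, chi2_2x2, hypergeometric_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityConfig",
    "GroupSimilarityResult",
    "FeatureEnrichment",
    "CategoryComparison",
    "ancestor_closure",
    "prune_excluded_subtree",
    "term_rarity_weights",
    "build_feature_vector",
    "build_all_vectors",
    "pairwise_similarity",
    "SimilarityMatrix",
    "group_mean_similarity",
    "similarity_null_test",
    "top_overrepresented_features",
    "compare_category_composition",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Knobs of the feature-vector construction.

    decay: per-level ancestor weight multiplier in (0,1).
    length_norm: divide contributions by the number of direct terms.
    excluded_root: subtree to drop entirely (ascertainment phenotype).
    """

    decay: float = 0.5
    rarity_scheme: str = "neg_log_freq"
    length_norm: bool = True
    excluded_root: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ValueError("decay must lie strictly between 0 and 1")
        if self.rarity_scheme != "neg_log_freq":
            raise ValueError(f"unknown rarity scheme {self.rarity_scheme!r}")


@dataclass(frozen=True)
class GroupSimilarityResult:
    mean_score: float
    null_mean: float
    null_q25: float
    null_q75: float
    p_empirical: float
    n_samples: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "mean_score": self.mean_score,
            "null_mean": self.null_mean,
            "null_q25": self.null_q25,
            "null_q75": self.null_q75,
            "p_empirical": self.p_empirical,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Ontology traversal
# ---------------------------------------------------------------------------

def ancestor_closure(ont: Ontology, term: str) -> dict[str, int]:
    """Minimal BFS level of every ancestor of ``term`` (0 = the term itself).

    With multiple paths to an ancestor the shortest one wins. The root is
    always included.
    """
    if term not in ont:
        raise KeyError(f"unknown term {term!r}")
    cache = getattr(ont, "_closure_cache", None)
    if cache is None:
        cache = {}
        setattr(ont, "_closure_cache", cache)
    if term in cache:
        return cache[term]
    levels: dict[str, int] = {term: 0}
    queue = deque([(term, 0)])
    while queue:
        t, lvl = queue.popleft()
        for p in ont.parents(t):
            if p not in levels:
                levels[p] = lvl + 1
                queue.append((p, lvl + 1))
    cache[term] = levels
    return levels


def prune_excluded_subtree(
    annos: AnnotationMap, ont: Ontology, excluded_root: str
) -> AnnotationMap:
    """Remove the descendant closure of ``excluded_root`` (inclusive) from
    every gene's direct annotations. Genes left with nothing are kept but
    flagged in the log (they get no feature vector downstream)."""
    if excluded_root not in ont:
        raise KeyError(f"excluded root {excluded_root!r} not in ontology")
    banned = ont.descendants(excluded_root, inclusive=True)
    pruned: dict[str, frozenset[str]] = {}
    emptied = []
    for gene in annos.genes:
        kept = annos.terms_of(gene) - banned
        if not kept and annos.terms_of(gene):
            emptied.append(gene)
        pruned[gene] = kept
    if emptied:
        logger.info(
            "%d gene(s) annotated only inside the excluded subtree: %s",
            len(emptied),
            sorted(emptied)[:5],
        )
    return AnnotationMap(pruned, ont)


# ---------------------------------------------------------------------------
# Weighted feature vectors
# ---------------------------------------------------------------------------

def term_rarity_weights(annos: AnnotationMap, ont: Ontology) -> dict[str, float]:
    """-ln(g_t / G) per term, g_t = genes annotated to the term directly or
    via a descendant, G = total annotated genes (frequency clipped >= 1/G)."""
    G = max(len(annos), 1)
    counts: dict[str, int] = {}
    for gene in annos.genes:
        hit: set[str] = set()
        for d in annos.terms_of(gene):
            hit |= ancestor_closure(ont, d).keys()
        for t in hit:
            counts[t] = counts.get(t, 0) + 1
    return {
        t: -log(max(counts.get(t, 0), 1) / G) if counts.get(t, 0) < G else 0.0
        for t in ont.terms
    }


def build_feature_vector(
    gene: str,
    annos: AnnotationMap,
    ont: Ontology,
    cfg: SimilarityConfig = SimilarityConfig(),
    rarity: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Weighted feature vector of one gene.

    weight(t) = rarity(t) * decay^level * (1/#direct if length_norm),
    summed over the direct terms that reach t; root and excluded-subtree
    terms never enter.
    """
    banned: set[str] = {ont.root}
    if cfg.excluded_root is not None:
        banned |= ont.descendants(cfg.excluded_root, inclusive=True)
    direct = annos.terms_of(gene) - banned
    if not direct:
        raise ValueError(f"gene {gene!r} has no usable annotations after pruning")
    if rarity is None:
        rarity = term_rarity_weights(annos, ont)
    norm = 1.0 / len(direct) if cfg.length_norm else 1.0
    vec: dict[str, float] = {}
    for d in direct:
        for t, lvl in ancestor_closure(ont, d).items():
            if t in banned:
                continue
            vec[t] = vec.get(t, 0.0) + rarity[t] * cfg.decay**lvl * norm
    return vec


def build_all_vectors(
    annos: AnnotationMap,
    ont: Ontology,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> dict[str, dict[str, float]]:
    """Vectors for every gene with usable annotations (others skipped)."""
    if cfg.excluded_root is not None:
        annos = prune_excluded_subtree(annos, ont, cfg.excluded_root)
    rarity = term_rarity_weights(annos, ont)
    out: dict[str, dict[str, float]] = {}
    for gene in sorted(annos.genes):
        try:
            out[gene] = build_feature_vector(gene, annos, ont, cfg, rarity)
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# Similarity scores
# ---------------------------------------------------------------------------

def pairwise_similarity(
    va: Mapping[str, float], vb: Mapping[str, float]
) -> Optional[float]:
    """Pearson correlation over the union of both vectors' terms (absent
    terms count as 0). None when either vector has zero variance over the
    union (e.g. two single-term vectors on the same term)."""
    if not va or not vb:
        raise ValueError("vectors must be nonempty")
    small, large = (va, vb) if len(va) <= len(vb) else (vb, va)
    overlap = sum(1 for t in small if t in large)
    n = len(va) + len(vb) - overlap
    sa = sum(va.values())
    sb = sum(vb.values())
    sa2 = sum(v * v for v in va.values())
    sb2 = sum(v * v for v in vb.values())
    cross = sum(v * large[t] for t, v in small.items() if t in large)
    var_a = sa2 - sa * sa / n
    var_b = sb2 - sb * sb / n
    if var_a <= 1e-15 or var_b <= 1e-15:
        return None
    return (cross - sa * sb / n) / sqrt(var_a * var_b)


class SimilarityMatrix:
    """All pairwise similarities of a vector collection, vectorized.

    Computes the same per-pair Pearson-over-support-union statistic as
    :func:`pairwise_similarity`, but for every pair at once via sparse
    matrix products; undefined pairs are NaN. Used by the permutation null
    test, where group means reduce to submatrix averages.
    """

    def __init__(self, vectors: Mapping[str, Mapping[str, float]]) -> None:
        self.genes: list[str] = sorted(vectors)
        self.index = {g: i for i, g in enumerate(self.genes)}
        terms = sorted({t for v in vectors.values() for t in v})
        t_index = {t: j for j, t in enumerate(terms)}
        rows, cols, vals = [], [], []
        for i, g in enumerate(self.genes):
            for t, w in vectors[g].items():
                rows.append(i)
                cols.append(t_index[t])
                vals.append(w)
        X = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.genes), len(terms))
        )
        B = X.copy()
        B.data = np.ones_like(B.data)
        cross = np.asarray((X @ X.T).todense(), dtype=float)
        overlap = np.asarray((B @ B.T).todense(), dtype=float)
        s = np.asarray(X.sum(axis=1)).ravel()
        s2 = np.asarray(X.multiply(X).sum(axis=1)).ravel()
        size = np.asarray(B.sum(axis=1)).ravel()
        n_union = size[:, None] + size[None, :] - overlap
        with np.errstate(invalid="ignore", divide="ignore"):
            var_a = s2[:, None] - (s[:, None] ** 2) / n_union
            var_b = s2[None, :] - (s[None, :] ** 2) / n_union
            num = cross - s[:, None] * s[None, :] / n_union
            denom = np.sqrt(var_a * var_b)
            S = num / denom
        S[(var_a <= 1e-15) | (var_b <= 1e-15)] = np.nan
        self.matrix = S

    def mean_of(self, genes: Sequence[str]) -> float:
        idx = np.array([self.index[g] for g in genes])
        if len(idx) < 2:
            raise ValueError("need at least 2 genes")
        sub = self.matrix[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError("no defined pairwise scores in group")
        return float(vals.mean())


def group_mean_similarity(
    genes: Sequence[str], vectors: Mapping[str, Mapping[str, float]]
) -> float:
    """Mean pairwise similarity over all C(n,2) defined pairs."""
    usable = [g for g in genes if g in vectors]
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with feature vectors")
    scores = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            s = pairwise_similarity(vectors[usable[i]], vectors[usable[j]])
            if s is not None:
                scores.append(s)
    if not scores:
        raise ValueError("no defined pairwise scores in group")
    return float(np.mean(scores))


def similarity_null_test(
    genes: Sequence[str],
    vectors: Optional[Mapping[str, Mapping[str, float]]] = None,
    n_samples: int = 1_000,
    seed: int = 0,
    matrix: Optional[SimilarityMatrix] = None,
) -> GroupSimilarityResult:
    """Empirical test of a group's mean similarity against equal-size random
    gene sets drawn (without replacement within a set) from all genes with
    vectors. A precomputed :class:`SimilarityMatrix` can be passed when many
    groups are tested against the same universe."""
    if matrix is None:
        if vectors is None:
            raise ValueError("pass either vectors or a SimilarityMatrix")
        matrix = SimilarityMatrix(vectors)
    usable = sorted(g for g in genes if g in matrix.index)
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with feature vectors")
    universe = matrix.genes
    if len(universe) < len(usable):
        raise ValueError("universe smaller than the group")
    observed = matrix.mean_of(usable)
    rng = np.random.default_rng(seed)
    null = np.empty(n_samples)
    for r in range(n_samples):
        idx = rng.choice(len(universe), size=len(usable), replace=False)
        null[r] = matrix.mean_of([universe[i] for i in idx])
    p = (1 + int(np.sum(null >= observed))) / (n_samples + 1)
    return GroupSimilarityResult(
        mean_score=observed,
        null_mean=float(null.mean()),
        null_q25=float(np.quantile(null, 0.25)),
        null_q75=float(np.quantile(null, 0.75)),
        p_empirical=p,
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Over-represented features and category composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureEnrichment:
    term: str
    name: str
    count_set: int
    count_universe: int
    fold: float
    p: float


def _closure_membership(
    annos: AnnotationMap, ont: Ontology, genes: Sequence[str]
) -> dict[str, set[str]]:
    """term -> genes annotated to it directly or via descendants."""
    members: dict[str, set[str]] = {}
    for g in genes:
        hit: set[str] = set()
        for d in annos.terms_of(g):
            hit |= ancestor_closure(ont, d).keys()
        for t in hit:
            members.setdefault(t, set()).add(g)
    return members


def top_overrepresented_features(
    gene_set: set[str],
    universe_annos: AnnotationMap,
    ont: Ontology,
    K: int = 200,
) -> list[FeatureEnrichment]:
    """Top-K features by hypergeometric over-representation in ``gene_set``.

    Term membership is descendant-inclusive. Ranking: ascending p, ties by
    higher fold, then term id. The root is uninformative and skipped.
    """
    missing = gene_set - universe_annos.genes
    if missing:
        raise ValueError(f"genes outside annotated universe: {sorted(missing)[:5]}")
    universe = sorted(universe_annos.genes)
    N, n = len(universe), len(gene_set)
    membership = _closure_membership(universe_annos, ont, universe)
    rows: list[FeatureEnrichment] = []
    for term, genes_with in membership.items():
        if term == ont.root:
            continue
        K_t = len(genes_with)
        k = len(genes_with & gene_set)
        p = hypergeometric_pvalue(k, K_t, n, N)
        fold = (k / n) / (K_t / N)
        rows.append(
            FeatureEnrichment(term, ont.name(term), k, K_t, fold, p)
        )
    rows.sort(key=lambda r: (r.p, -r.fold, r.term))
    if K > len(rows):
        logger.warning("requested top %d of only %d testable terms", K, len(rows))
    return rows[:K]


@dataclass(frozen=True)
class CategoryComparison:
    count_a: int
    count_b: int
    fold: float
    chi2_p: float


def compare_category_composition(
    top_a: Sequence[FeatureEnrichment],
    top_b: Sequence[FeatureEnrichment],
    ont: Ontology,
    top_level_terms: Optional[set[str]] = None,
) -> dict[str, CategoryComparison]:
    """Distribute two top-feature lists over top-level ontology categories.

    Each feature counts toward every top-level term it descends from
    (features reaching none go to an ``unclassified`` bucket). Fold is the
    ratio of per-category fractions; the chi-square (no continuity
    correction) compares in/out counts of the two lists.
    """
    if top_level_terms is None:
        top_level_terms = ont.children(ont.root)
    bad = {t for t in top_level_terms if t not in ont}
    if bad:
        raise KeyError(f"unknown top-level terms: {sorted(bad)}")

    def bucket_counts(top: Sequence[FeatureEnrichment]) -> dict[str, int]:
        counts = {t: 0 for t in top_level_terms}
        counts["unclassified"] = 0
        for feat in top:
            ancs = set(ancestor_closure(ont, feat.term))
            hits = ancs & top_level_terms
            if hits:
                for t in hits:
                    counts[t] += 1
            else:
                counts["unclassified"] += 1
        return counts

    ka, kb = len(top_a), len(top_b)
    ca, cb = bucket_counts(top_a), bucket_counts(top_b)
    out: dict[str, CategoryComparison] = {}
    for cat in sorted(ca):
        a, b = ca[cat], cb[cat]
        if b == 0:
            fold = float("nan") if a == 0 else float("inf")
        else:
            fold = (a / ka) / (b / kb)
        try:
            _, p = chi2_2x2(ContingencyTable2x2(a, ka - a, b, kb - b))
        except ValueError:
            p = float("nan")
        out[cat] = CategoryComparison(a, b, fold, p)
    return out
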