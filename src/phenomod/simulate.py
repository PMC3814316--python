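"""Synthetic-data generators with retained ground truth.

Every stage of the pipeline can be exercised without external downloads:
the generators emit inputs with the statistical structure the analysis
assumes — a rooted-DAG ontology with a designated excludable subtree,
sparse interaction networks with planted within-category edge excess,
group-coherent term annotations with noise, screen tables with planted
phenotype groups, and heavy-tailed expression matrices with planted
tissue-specific genes. The planted structure is retained in a
:class:`GeneratorTruth` so recovery can be scored exactly.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationMap,
    ExpressionMatrix,
    InteractionNetwork,
    Ontology,
    PhenotypeCategory,
    ScreenLineResult,
)

__all__ = [
    "GeneratorTruth",
    "SyntheticOntology",
    "generate_ontology",
    "generate_screen_annotations",
    "generate_interaction_network",
    "generate_group_annotations",
    "generate_expression_matrix",
]

_SOURCES = ("ppi_hprd", "interolog", "coap_complex", "genetic")


@dataclass
class GeneratorTruth:
    """Planted structure of a synthetic dataset, sufficient to score
    recovery exactly. Serializes to/from JSON."""

    seeds: dict[str, int] = field(default_factory=dict)
    planted_modules: list[dict] = field(default_factory=list)
    coherent_groups: list[dict] = field(default_factory=list)
    spiked: list[dict] = field(default_factory=list)
    line_efficacy: dict[str, float] = field(default_factory=dict)
    true_pi: dict[str, float] = field(default_factory=dict)
    planted_screen_groups: list[dict] = field(default_factory=list)
    excluded_root: Optional[str] = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneratorTruth):
            return NotImplemented
        return json.dumps(self.__dict__, sort_keys=True) == json.dumps(
            other.__dict__, sort_keys=True
        )


@dataclass(frozen=True)
class SyntheticOntology:
    ontology: Ontology
    excluded_root: str


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def generate_ontology(
    n_terms: int,
    max_parents: int = 2,
    excluded_subtree_size: int = 7,
    seed: int = 0,
) -> tuple[SyntheticOntology, GeneratorTruth]:
    """Single-root random DAG of ``n_terms`` terms with one marked subtree
    of exactly ``excluded_subtree_size`` terms (its root included).

    Terms outside the marked subtree never descend from it, so the subtree's
    descendant closure is exactly the marked set.
    """
    if excluded_subtree_size < 1:
        raise ValueError("excluded_subtree_size must be >= 1")
    if n_terms < excluded_subtree_size + 2:
        raise ValueError(
            f"need n_terms >= {excluded_subtree_size + 2} "
            f"(root + subtree + >=1 ordinary term)"
        )
    rng = np.random.default_rng(seed)
    ids = [f"T:{i:07d}" for i in range(n_terms)]
    root = ids[0]
    terms: dict[str, tuple[str, frozenset[str]]] = {root: ("root", frozenset())}

    # marked subtree: ids[1] is its root (child of the global root)
    sub_ids = ids[1 : 1 + excluded_subtree_size]
    terms[sub_ids[0]] = ("excluded subtree root", frozenset({root}))
    for i, t in enumerate(sub_ids[1:], start=1):
        k = 1 + int(rng.integers(min(max_parents, i)))
        parents = rng.choice(i, size=min(k, i), replace=False)
        terms[t] = (f"excluded term {i}", frozenset(sub_ids[j] for j in parents))

    # ordinary terms attach only to root/ordinary terms
    ordinary = [root] + ids[1 + excluded_subtree_size :]
    for i, t in enumerate(ids[1 + excluded_subtree_size :], start=1):
        k = 1 + int(rng.integers(min(max_parents, i)))
        parents = rng.choice(i, size=min(k, i), replace=False)
        terms[t] = (f"term {i}", frozenset(ordinary[j] for j in parents))

    ont = Ontology(terms, root=root)
    truth = GeneratorTruth(seeds={"ontology": seed}, excluded_root=sub_ids[0])
    return SyntheticOntology(ont, sub_ids[0]), truth


# ---------------------------------------------------------------------------
# Screen tables
# ---------------------------------------------------------------------------

def generate_screen_annotations(
    n_genes: int,
    category_probs: Mapping[PhenotypeCategory, float],
    planted_groups: Sequence[tuple[PhenotypeCategory, Sequence[str]]] = (),
    lines_per_gene: int = 2,
    line_efficacy: float = 0.8,
    seed: int = 0,
    control_pi: float = 5.2,
    pi_noise_sd: float = 0.4,
) -> tuple[list[ScreenLineResult], GeneratorTruth]:
    """Per-line screen results with planted phenotype groups.

    ``category_probs`` are per-line background call probabilities (the
    derived ``phototaxis_defective`` label is not drawable). Planted groups
    receive their category with probability ``line_efficacy`` per line;
    planted phototaxis-defective genes get a true PI below 4, all others a
    control-like true PI (default 5.2). Replicates are
    Normal(true_pi, 0.4) truncated to [1, 6] — with that spread
    control-like lines essentially never cross the hit threshold.
    """
    for c, p in category_probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for {c} outside [0,1]: {p}")
        if c == PhenotypeCategory.PHOTOTAXIS_DEFECTIVE:
            raise ValueError("phototaxis_defective is derived from PI, not drawable")
    gene_ids = [f"Fg{i:04d}" for i in range(n_genes)]
    planted_cat: dict[str, PhenotypeCategory] = {}
    for cat, members in planted_groups:
        for g in members:
            if g not in gene_ids:
                raise ValueError(f"planted gene {g!r} outside gene range")
            if g in planted_cat and planted_cat[g] != cat:
                raise ValueError(
                    f"gene {g} planted with conflicting categories "
                    f"{planted_cat[g].value} and {cat.value}"
                )
            planted_cat[g] = cat

    rng = np.random.default_rng(seed)
    lines: list[ScreenLineResult] = []
    truth = GeneratorTruth(seeds={"screen": seed})
    truth.planted_screen_groups = [
        {"category": cat.value, "genes": list(members)}
        for cat, members in planted_groups
    ]
    for g in gene_ids:
        planted = planted_cat.get(g)
        if planted is PhenotypeCategory.PHOTOTAXIS_DEFECTIVE:
            true_pi = float(rng.uniform(1.5, 3.4))
        else:
            true_pi = control_pi
        truth.true_pi[g] = true_pi
        for j in range(lines_per_gene):
            line_id = f"{g}_L{j + 1}"
            cats: set[PhenotypeCategory] = set()
            if planted is not None and planted is not PhenotypeCategory.PHOTOTAXIS_DEFECTIVE:
                if rng.random() < line_efficacy:
                    cats.add(planted)
            for c, p in category_probs.items():
                if rng.random() < p:
                    cats.add(c)
            reps = tuple(
                float(np.clip(rng.normal(true_pi, pi_noise_sd), 1.0, 6.0))
                for _ in range(3)
            )
            s19 = float(rng.uniform(0.98, 1.0) if rng.random() < 0.97 else rng.uniform(0.85, 0.98))
            truth.line_efficacy[line_id] = line_efficacy if planted else 0.0
            lines.append(
                ScreenLineResult(
                    line_id=line_id,
                    fly_id=g,
                    s19=s19,
                    pi_replicates=reps,
                    category_calls=frozenset(cats),
                )
            )
    return lines, truth


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

def generate_interaction_network(
    n_genes: int,
    background_density: float,
    planted_modules: Sequence[tuple[Sequence[str], float]] = (),
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
) -> tuple[InteractionNetwork, GeneratorTruth]:
    """Erdos-Renyi background plus planted dense modules.

    Each planted module adds edges among its genes at ``within_density``
    (union with any background edges). Edge source tags are assigned at
    random for provenance realism; connectivity statistics ignore them.
    """
    if not (0.0 <= background_density <= 1.0):
        raise ValueError("background_density outside [0,1]")
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    id_set = set(gene_ids)
    rng = np.random.default_rng(seed)

    net = InteractionNetwork()
    for g in gene_ids:
        net.add_node(g)

    n = len(gene_ids)
    if background_density > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < background_density
        for i, j in zip(iu[mask], ju[mask]):
            tag = _SOURCES[int(rng.integers(len(_SOURCES)))]
            net.add_edge(gene_ids[int(i)], gene_ids[int(j)], {tag})

    truth = GeneratorTruth(seeds={"network": seed})
    for members, dens in planted_modules:
        members = list(members)
        if not (0.0 <= dens <= 1.0):
            raise ValueError("within_density outside [0,1]")
        outside = set(members) - id_set
        if outside:
            raise ValueError(f"module genes outside range: {sorted(outside)}")
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if rng.random() < dens:
                    tag = _SOURCES[int(rng.integers(len(_SOURCES)))]
                    net.add_edge(members[a_i], members[b_i], {tag})
        truth.planted_modules.append(
            {"genes": members, "within_density": dens}
        )
    return net, truth


# ---------------------------------------------------------------------------
# Group-coherent annotations
# ---------------------------------------------------------------------------

def generate_group_annotations(
    ont: SyntheticOntology | Ontology,
    n_genes: int,
    groups: Sequence[tuple[int, float]] = (),
    terms_per_gene: int = 5,
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
) -> tuple[AnnotationMap, GeneratorTruth]:
    """Gene annotations with planted coherent groups.

    Each group ``(size, coherence)`` owns a hidden pool of
    ``terms_per_gene`` terms; members draw round(coherence * terms_per_gene)
    terms from the pool and the remainder uniformly from the other
    non-excluded, non-root terms. Background genes draw fully uniformly.
    Group members are assigned from the front of the gene list, in order.
    """
    if isinstance(ont, SyntheticOntology):
        ontology, excluded_root = ont.ontology, ont.excluded_root
    else:
        ontology, excluded_root = ont, None
    banned = {ontology.root}
    if excluded_root is not None:
        banned |= ontology.descendants(excluded_root, inclusive=True)
    vocab = sorted(set(ontology.terms) - banned)
    if terms_per_gene > len(vocab):
        raise ValueError("terms_per_gene exceeds usable vocabulary")
    if gene_ids is None:
        gene_ids = [f"HG{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    if sum(size for size, _ in groups) > n_genes:
        raise ValueError("groups need more genes than available")

    rng = np.random.default_rng(seed)
    truth = GeneratorTruth(seeds={"annotations": seed}, excluded_root=excluded_root)
    annos: dict[str, set[str]] = {}
    cursor = 0
    for size, coherence in groups:
        if not (0.0 <= coherence <= 1.0):
            raise ValueError("coherence outside [0,1]")
        pool_idx = rng.choice(len(vocab), size=terms_per_gene, replace=False)
        pool = [vocab[i] for i in pool_idx]
        members = list(gene_ids[cursor : cursor + size])
        cursor += size
        n_pool = round(coherence * terms_per_gene)
        for g in members:
            take_idx = rng.choice(terms_per_gene, size=n_pool, replace=False)
            terms = {pool[i] for i in take_idx}
            rest = [t for t in vocab if t not in terms]
            extra_idx = rng.choice(len(rest), size=terms_per_gene - n_pool, replace=False)
            terms |= {rest[i] for i in extra_idx}
            annos[g] = terms
        truth.coherent_groups.append(
            {"genes": members, "coherence": coherence, "pool": sorted(pool)}
        )
    for g in gene_ids[cursor:]:
        idx = rng.choice(len(vocab), size=terms_per_gene, replace=False)
        annos[g] = {vocab[i] for i in idx}
    return AnnotationMap(annos, ontology), truth


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def generate_expression_matrix(
    n_genes: int,
    tissues: int | Sequence[str] = 45,
    spiked: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
    baseline_sigma: float = 1.0,
    noise_sigma: float = 0.4,
) -> tuple[ExpressionMatrix, GeneratorTruth]:
    """Log-normal EST-like counts with per-tissue scale factors and spikes.

    Each entry is exp(mu + a_g + b_t + eps): a per-gene abundance effect
    ``a_g`` (sigma = ``baseline_sigma``, giving the heavy right tail typical
    of EST profiles and realistic cross-tissue rank correlation), a
    per-tissue library scale ``b_t`` emulating the strong between-library
    abundance differences that motivate within-tissue ranking, and cell
    noise ``eps`` (sigma = ``noise_sigma``). Spiked (gene, tissue) entries
    are multiplied by ``foldboost``; the signal-to-noise of a spike is
    ln(foldboost)/noise_sigma.
    """
    if isinstance(tissues, int):
        tissue_names = [f"tissue{i:02d}" for i in range(tissues)]
    else:
        tissue_names = list(tissues)
    if gene_ids is None:
        gene_ids = [f"HG{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    seen_genes = set()
    for g, t, boost in spiked:
        if boost <= 1.0:
            raise ValueError(f"foldboost must exceed 1 (gene {g})")
        if g in seen_genes:
            raise ValueError(f"duplicate spike for gene {g}")
        seen_genes.add(g)
        if g not in set(gene_ids) or t not in tissue_names:
            raise ValueError(f"spike ({g},{t}) outside matrix")

    rng = np.random.default_rng(seed)
    gene_effect = rng.normal(0.0, baseline_sigma, size=n_genes)
    tissue_scale = rng.normal(0.0, 1.0, size=len(tissue_names))
    noise = rng.normal(0.0, noise_sigma, size=(n_genes, len(tissue_names)))
    values = np.exp(2.0 + gene_effect[:, None] + tissue_scale[None, :] + noise)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    tissue_index = {t: j for j, t in enumerate(tissue_names)}
    truth = GeneratorTruth(seeds={"expression": seed})
    for g, t, boost in spiked:
        values[gene_index[g], tissue_index[t]] *= boost
        truth.spiked.append({"gene": g, "tissue": t, "foldboost": boost})
    df = pd.DataFrame(values, index=list(gene_ids), columns=tissue_names)
    return ExpressionMatrix(df), truth
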