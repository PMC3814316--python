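"""Domain types shared across the pipeline.

The analysis revolves around a screened set of fly genes (orthologs of human
intellectual-disability genes), per-RNAi-line screen results, a combined
undirected interaction network, a rooted-DAG phenotype ontology with
gene-to-term annotations, and a genes x tissues expression matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeCategory",
    "MORPHOLOGY_CATEGORIES",
    "MAJOR_CLASSES",
    "GeneRecord",
    "ScreenLineResult",
    "GenePhenotypeProfile",
    "InteractionNetwork",
    "Ontology",
    "AnnotationMap",
    "ExpressionMatrix",
    "EDGE_SOURCES",
]

EDGE_SOURCES = frozenset({"ppi_hprd", "interolog", "coap_complex", "genetic"})


class PhenotypeCategory(str, enum.Enum):
    """Closed vocabulary of screen phenotype categories.

    The thirteen morphology labels cover external-eye defects; the remaining
    three record lethality, phototaxis behaviour and electroretinogram defects.
    """

    MILDLY_ROUGH = "mildly_rough"
    ROUGH = "rough"
    PARTIALLY_FUSED = "partially_fused"
    FUSED = "fused"
    FEWER_BRISTLES = "fewer_bristles"
    NO_BRISTLES = "no_bristles"
    STUBBLE_BRISTLES = "stubble_bristles"
    LONG_BRISTLES = "long_bristles"
    NECROSIS = "necrosis"
    LOSS_OF_PIGMENTATION = "loss_of_pigmentation"
    SMALL_EYE = "small_eye"
    WRINKLED_SURFACE = "wrinkled_surface"
    DENTED_SURFACE = "dented_surface"
    LETHAL = "lethal"
    PHOTOTAXIS_DEFECTIVE = "phototaxis_defective"
    ERG_DEFECTIVE = "erg_defective"

    @classmethod
    def parse(cls, label: str) -> "PhenotypeCategory":
        try:
            return cls(label.strip())
        except ValueError:
            raise ValueError(
                f"unknown phenotype category {label!r}; "
                f"allowed: {sorted(c.value for c in cls)}"
            ) from None


MORPHOLOGY_CATEGORIES = frozenset(
    c
    for c in PhenotypeCategory
    if c
    not in {
        PhenotypeCategory.LETHAL,
        PhenotypeCategory.PHOTOTAXIS_DEFECTIVE,
        PhenotypeCategory.ERG_DEFECTIVE,
    }
)

#: Major phenotype classes a gene can belong to. EMD = eye morphology
#: defective (any of the 13 morphology categories); NED = no eye defect
#: (no category at all).
MAJOR_CLASSES = ("EMD", "ERG_defective", "lethal", "NED")


@dataclass(frozen=True)
class GeneRecord:
    """A screened fly gene and its human ortholog symbol(s)."""

    fly_id: str
    human_symbols: tuple[str, ...]
    is_screened: bool = True

    def __post_init__(self) -> None:
        if not self.fly_id:
            raise ValueError("fly_id must be nonempty")
        if not self.human_symbols or any(not s for s in self.human_symbols):
            raise ValueError(
                f"gene {self.fly_id}: human_symbols must be nonempty strings"
            )


@dataclass
class ScreenLineResult:
    """Result of one RNAi line: specificity score, phototaxis replicates and
    the phenotype categories called for that line."""

    line_id: str
    fly_id: str
    s19: Optional[float]
    pi_replicates: tuple[float, ...] = ()
    category_calls: frozenset[PhenotypeCategory] = frozenset()

    def __post_init__(self) -> None:
        if self.s19 is not None and not (0.0 <= self.s19 <= 1.0):
            raise ValueError(f"line {self.line_id}: s19 {self.s19} outside [0,1]")
        for v in self.pi_replicates:
            if not (1.0 <= v <= 6.0):
                raise ValueError(
                    f"line {self.line_id}: PI replicate {v} outside [1,6]"
                )
        self.category_calls = frozenset(
            PhenotypeCategory.parse(c) if isinstance(c, str) else c
            for c in self.category_calls
        )


@dataclass
class GenePhenotypeProfile:
    """Per-gene aggregate over its RNAi lines."""

    gene_id: str
    categories: frozenset[PhenotypeCategory] = frozenset()
    mean_pi: Optional[float] = None
    pi_sd: Optional[float] = None
    major_classes: frozenset[str] = frozenset()


class InteractionNetwork:
    """Undirected multi-source gene interaction graph.

    A gene pair is one "unique connection" regardless of how many sources
    report it; source tags are kept per edge for provenance. Self-loops are
    rejected and pairs are stored in canonical (sorted) order via the
    underlying :class:`networkx.Graph`.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def add_edge(self, a: str, b: str, sources: Iterable[str] = ()) -> bool:
        """Add the unordered pair {a, b}. Returns False for a self-loop
        (dropped), True otherwise. Tags accumulate across calls."""
        if a == b:
            return False
        tags = set(sources)
        unknown = tags - EDGE_SOURCES
        if unknown:
            raise ValueError(f"unknown edge source tags: {sorted(unknown)}")
        if self.graph.has_edge(a, b):
            self.graph.edges[a, b]["sources"] |= tags
        else:
            self.graph.add_edge(a, b, sources=tags)
        return True

    def merge(self, other: "InteractionNetwork") -> "InteractionNetwork":
        for g in other.nodes:
            self.add_node(g)
        for a, b, data in other.graph.edges(data=True):
            self.add_edge(a, b, data.get("sources", ()))
        return self

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    def edge_sources(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[a, b]["sources"])

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


class Ontology:
    """Rooted DAG of phenotype terms (child -> parent ``is_a`` links)."""

    def __init__(
        self,
        terms: Mapping[str, tuple[str, frozenset[str]]],
        root: str,
    ) -> None:
        self.terms: dict[str, tuple[str, frozenset[str]]] = {
            t: (name, frozenset(parents)) for t, (name, parents) in terms.items()
        }
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.terms:
            raise ValueError(f"root {self.root!r} not among terms")
        if self.parents(self.root):
            raise ValueError(f"root {self.root!r} has parents")
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for t in self.terms:
            for p in self.parents(t):
                if p not in self.terms:
                    raise ValueError(f"term {t}: unknown parent {p}")
                dg.add_edge(t, p)
        try:
            cyc = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            cyc = None
        if cyc:
            a, b = cyc[0][0], cyc[0][1]
            raise ValueError(f"ontology contains a cycle (e.g. edge {a} -> {b})")
        # every term must reach the root
        reaches = nx.ancestors(dg, self.root) | {self.root}
        orphans = set(self.terms) - reaches
        if orphans:
            raise ValueError(
                f"{len(orphans)} term(s) do not reach root {self.root!r}: "
                f"{sorted(orphans)[:5]}"
            )

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def parents(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    def children(self, term: str) -> set[str]:
        return {t for t in self.terms if term in self.parents(t)}

    def descendants(self, term: str, inclusive: bool = True) -> set[str]:
        """All terms below ``term`` (terms whose ancestor closure contains it)."""
        out: set[str] = {term} if inclusive else set()
        frontier = [term]
        child_index: dict[str, list[str]] = {}
        for t in self.terms:
            for p in self.parents(t):
                child_index.setdefault(p, []).append(t)
        seen = {term}
        while frontier:
            nxt = []
            for t in frontier:
                for c in child_index.get(t, ()):
                    if c not in seen:
                        seen.add(c)
                        out.add(c)
                        nxt.append(c)
            frontier = nxt
        return out

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


class AnnotationMap:
    """Direct gene -> ontology-term annotations."""

    def __init__(
        self,
        annotations: Mapping[str, Iterable[str]],
        ontology: Optional[Ontology] = None,
    ) -> None:
        self.annotations: dict[str, frozenset[str]] = {}
        for gene, terms in annotations.items():
            if not gene:
                raise ValueError("empty gene symbol in annotation map")
            ts = frozenset(terms)
            if ontology is not None:
                missing = {t for t in ts if t not in ontology}
                if missing:
                    raise ValueError(
                        f"gene {gene}: terms absent from ontology: {sorted(missing)}"
                    )
            self.annotations[gene] = ts

    @property
    def genes(self) -> set[str]:
        return set(self.annotations)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.annotations[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self.annotations == other.annotations


class ExpressionMatrix:
    """Genes x tissues matrix of non-negative transcript abundances."""

    def __init__(self, values: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate tissue names in expression matrix")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative expression values")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
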