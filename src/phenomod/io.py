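"""Readers and writers for the pipeline's plain-text input formats.

All tabular inputs are UTF-8, tab-delimited, with ``#``-prefixed comment
lines allowed. Headers are required except for two-column edge lists.
The ontology travels as OBO 1.2 (parsed with :mod:`obonet`).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, NamedTuple, TypeVar

import obonet
import pandas as pd

from .core import (
    AnnotationMap,
    ExpressionMatrix,
    GeneRecord,
    InteractionNetwork,
    Ontology,
    PhenotypeCategory,
    ScreenLineResult,
)

logger = logging.getLogger(__name__)

T = TypeVar("T")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Ontology (OBO)
# ---------------------------------------------------------------------------

def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2 file into an :class:`Ontology`.

    Obsolete terms are skipped. Only ``is_a`` links are used. Exactly one
    root (a term with no ``is_a`` parent) must remain; multiple roots or a
    cycle in the parent relation are structural errors.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise ParseError(f"{path}: {exc}") from exc
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for node, data in graph.nodes(data=True):
        parents = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        terms[node] = (data.get("name", node), parents)
    roots = sorted(t for t, (_, ps) in terms.items() if not ps)
    if not terms:
        raise ParseError(f"{path}: no terms found")
    if len(roots) != 1:
        raise ParseError(f"{path}: expected exactly one root, found {roots}")
    return Ontology(terms, root=roots[0])


def write_obo(ont: Ontology, path: str | Path) -> None:
    """Serialize an :class:`Ontology` as minimal OBO 1.2."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: phenomod-synthetic\n")
        for term in sorted(ont.terms):
            name, parents = ont.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\n")
            for p in sorted(parents):
                fh.write(f"is_a: {p} ! {ont.name(p)}\n")


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

def load_interaction_edges(
    path: str | Path,
    source_tag: str,
    header: bool = False,
) -> InteractionNetwork:
    """Load a two-column gene-pair TSV into an :class:`InteractionNetwork`.

    Duplicate pairs (either orientation) are merged; self-loops are dropped
    with a logged count. Every edge carries ``source_tag``.
    """
    net = InteractionNetwork()
    n_rows = n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header:
                header = False
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ParseError(
                    f"{path}: row {lineno}: expected 2 gene columns, got {fields!r}"
                )
            a, b = (f.strip() for f in fields)
            n_rows += 1
            net.add_node(a)
            net.add_node(b)
            if not net.add_edge(a, b, {source_tag}):
                n_self += 1
    if n_self:
        logger.info("%s: dropped %d self-loop row(s)", path, n_self)
    if n_rows == 0:
        logger.warning("%s: empty edge list", path)
    return net


def write_interaction_edges(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene-to-phenotype annotations
# ---------------------------------------------------------------------------

class AnnotationLoadResult(NamedTuple):
    annotations: AnnotationMap
    n_dropped: int


def load_gene_phenotype_map(
    path: str | Path, ontology: Ontology
) -> AnnotationLoadResult:
    """Load a gene-symbol / term-id TSV (HPO ``genes_to_phenotype`` dialect).

    Rows whose term id is absent from ``ontology`` are dropped and counted;
    per-gene term sets are deduplicated.
    """
    df = _read_tsv(path)
    for col in ("gene_symbol", "term_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    annos: dict[str, set[str]] = {}
    n_dropped = 0
    for gene, term in zip(df["gene_symbol"], df["term_id"]):
        gene, term = str(gene).strip(), str(term).strip()
        if term not in ontology:
            n_dropped += 1
            continue
        annos.setdefault(gene, set()).add(term)
    if not annos:
        raise ParseError(f"{path}: no rows with terms present in the ontology")
    if n_dropped:
        logger.info("%s: dropped %d row(s) with unknown terms", path, n_dropped)
    return AnnotationLoadResult(AnnotationMap(annos, ontology), n_dropped)


def write_gene_phenotype_map(annos: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tterm_id\n")
        for gene in sorted(annos.genes):
            for term in sorted(annos.terms_of(gene)):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Gene (orthology) table
# ---------------------------------------------------------------------------

def load_gene_table(path: str | Path) -> dict[str, GeneRecord]:
    """Load the fly-gene / human-ortholog table.

    Columns: ``fly_id``, ``human_symbols`` (semicolon-separated, >=1) and
    optionally ``is_screened`` (0/1, default 1).
    """
    df = _read_tsv(path)
    for col in ("fly_id", "human_symbols"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    records: dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        fly_id = str(row["fly_id"]).strip()
        if fly_id in records:
            raise ParseError(f"{path}: duplicate fly_id {fly_id!r}")
        symbols = tuple(
            s.strip() for s in str(row["human_symbols"]).split(";") if s.strip()
        )
        screened = bool(int(row["is_screened"])) if "is_screened" in df.columns else True
        records[fly_id] = GeneRecord(fly_id, symbols, screened)
    return records


def write_gene_table(genes: Mapping[str, GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fly_id\thuman_symbols\tis_screened\n")
        for fly_id in sorted(genes):
            rec = genes[fly_id]
            fh.write(
                f"{rec.fly_id}\t{';'.join(rec.human_symbols)}\t{int(rec.is_screened)}\n"
            )


# ---------------------------------------------------------------------------
# Screen results table
# ---------------------------------------------------------------------------

def load_screen_table(path: str | Path) -> list[ScreenLineResult]:
    """Load per-RNAi-line screen results.

    Columns: ``line_id``, ``fly_id``, ``s19`` (blank allowed),
    ``pi_rep1..pi_rep3`` (blanks allowed) and ``categories``
    (semicolon-separated phenotype labels; blank for none).
    """
    df = _read_tsv(path)
    required = ("line_id", "fly_id", "s19", "categories")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    rep_cols = [c for c in df.columns if c.startswith("pi_rep")]
    lines: list[ScreenLineResult] = []
    for _, row in df.iterrows():
        reps = tuple(
            float(row[c]) for c in rep_cols if not _is_blank(row[c])
        )
        cats = frozenset(
            PhenotypeCategory.parse(c)
            for c in str(row["categories"]).split(";")
            if c.strip() and not _is_blank(row["categories"])
        )
        s19 = None if _is_blank(row["s19"]) else float(row["s19"])
        lines.append(
            ScreenLineResult(
                line_id=str(row["line_id"]).strip(),
                fly_id=str(row["fly_id"]).strip(),
                s19=s19,
                pi_replicates=reps,
                category_calls=cats,
            )
        )
    return lines


def write_screen_table(lines: list[ScreenLineResult], path: str | Path) -> None:
    n_reps = max((len(l.pi_replicates) for l in lines), default=3) or 3
    rep_cols = [f"pi_rep{i}" for i in range(1, n_reps + 1)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("line_id\tfly_id\ts19\t" + "\t".join(rep_cols) + "\tcategories\n")
        for ln in lines:
            reps = [f"{v:.4f}" for v in ln.pi_replicates]
            reps += [""] * (n_reps - len(reps))
            cats = ";".join(sorted(c.value for c in ln.category_calls))
            s19 = "" if ln.s19 is None else f"{ln.s19:.4f}"
            fh.write(
                f"{ln.line_id}\t{ln.fly_id}\t{s19}\t" + "\t".join(reps) + f"\t{cats}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Load a genes x tissues TSV (first column gene id, header = tissues)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene column plus >=1 tissue column")
    df = df.set_index(df.columns[0])
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Orthology expansion
# ---------------------------------------------------------------------------

def expand_orthology(
    profiles: Mapping[str, T], genes: Mapping[str, GeneRecord]
) -> dict[str, T]:
    """Duplicate each fly gene's data to every listed human ortholog symbol.

    One fly gene with two human paralogs yields two human records carrying
    the same data. Two distinct fly genes mapping to the same human symbol
    would silently collide and is rejected.
    """
    out: dict[str, T] = {}
    owner: dict[str, str] = {}
    for fly_id, data in profiles.items():
        if fly_id not in genes:
            raise KeyError(f"fly gene {fly_id!r} absent from gene table")
        for symbol in genes[fly_id].human_symbols:
            if symbol in out:
                raise ValueError(
                    f"human symbol {symbol!r} mapped from both "
                    f"{owner[symbol]!r} and {fly_id!r}"
                )
            out[symbol] = data
            owner[symbol] = fly_id
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def _is_blank(v: object) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""
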