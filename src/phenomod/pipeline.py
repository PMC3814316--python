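"""End-to-end orchestration: screen -> classes -> expression -> network ->
similarity, with one global seed, per-stage derived seeds, and
machine-readable outputs.

One global seed derives a per-stage seed by hashing the stage name
(CRC32 XOR seed, reduced below 2^31), so any stage can be rerun in
isolation and reproduce the full run's results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .core import GenePhenotypeProfile, InteractionNetwork, PhenotypeCategory
from .expression import rank_within_tissue, tissue_class_enrichment, top_tissue_per_gene
from .io import (
    expand_orthology,
    load_expression_matrix,
    load_gene_phenotype_map,
    load_gene_table,
    load_interaction_edges,
    load_screen_table,
    parse_obo,
)
from .network import (
    extract_homotypic_modules,
    homotypic_enrichment,
    module_summary,
    pie_score,
)
from .screen import aggregate_gene_phenotypes
from .similarity import (
    SimilarityConfig,
    SimilarityMatrix,
    build_all_vectors,
    compare_category_composition,
    similarity_null_test,
    top_overrepresented_features,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "classify_report", "stage_seed"]

ALL_STAGES = ("screen", "expression", "network", "similarity")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (zlib.crc32(stage.encode("utf-8")) ^ seed) % (2**31)


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    gene_table: str
    screen_table: str
    edge_files: list[list[str]]  # [path, source_tag] pairs
    obo_file: str
    annotations_file: str
    expression_file: str
    out_dir: str
    seed: int
    pi_threshold: float = 4.0
    s19_min: Optional[float] = None
    n_perm: int = 10_000
    pie_samples: int = 1_000
    degree_bins: int = 10
    n_similarity_samples: int = 1_000
    top_k_features: int = 200
    similarity_decay: float = 0.5
    similarity_length_norm: bool = True
    excluded_root: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("n_perm", "pie_samples", "n_similarity_samples", "top_k_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.edge_files:
            raise ValueError("at least one edge file is required")

    @property
    def similarity_config(self) -> SimilarityConfig:
        return SimilarityConfig(
            decay=self.similarity_decay,
            length_norm=self.similarity_length_norm,
            excluded_root=self.excluded_root,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def classify_report(profiles: Mapping[str, GenePhenotypeProfile]) -> pd.DataFrame:
    """Counts and percentages per major class and per phenotype category."""
    n = len(profiles)
    rows = []
    for cls in ("EMD", "ERG_defective", "lethal", "NED"):
        k = sum(1 for p in profiles.values() if cls in p.major_classes)
        rows.append(("class", cls, k, 100.0 * k / n if n else 0.0))
    k_any = sum(1 for p in profiles.values() if p.categories)
    rows.append(("class", "any_phenotype", k_any, 100.0 * k_any / n if n else 0.0))
    for cat in PhenotypeCategory:
        k = sum(1 for p in profiles.values() if cat in p.categories)
        rows.append(("category", cat.value, k, 100.0 * k / n if n else 0.0))
    return pd.DataFrame(rows, columns=["kind", "label", "count", "percent"])


def run_pipeline(
    config: PipelineConfig, stages: Optional[Iterable[str]] = None
) -> dict:
    """Execute the requested stages (default: all) and write per-stage TSVs
    plus a JSON summary to ``config.out_dir``.

    The screen stage always runs: every later stage consumes its per-gene
    phenotype profiles. Returns the summary dict (also written to
    ``summary.json``).
    """
    wanted = set(ALL_STAGES if stages is None else stages)
    unknown = wanted - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("phenomod")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    t0 = time.time()
    try:
        summary = _run_stages(config, out_dir, wanted)
    finally:
        root.removeHandler(handler)
        handler.close()
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return summary


def _run_stages(config: PipelineConfig, out_dir: Path, wanted: set[str]) -> dict:
    logger.info("phenomod %s, python %s", __version__, sys.version.split()[0])
    logger.info("config: %s", dataclasses.asdict(config))
    config.to_yaml(out_dir / "effective_config.yaml")

    human_profiles, class_sets, report = _screen_stage(config, out_dir)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": sorted(wanted),
        "n_human_genes": len(human_profiles),
        "class_counts": {
            row["label"]: int(row["count"])
            for _, row in report[report["kind"] == "class"].iterrows()
        },
        "class_percent": {
            row["label"]: round(float(row["percent"]), 4)
            for _, row in report[report["kind"] == "class"].iterrows()
        },
    }
    if "expression" in wanted:
        summary["expression"] = _expression_stage(config, out_dir, class_sets)
    if "network" in wanted:
        summary["network"] = _network_stage(
            config, out_dir, human_profiles, class_sets
        )
    if "similarity" in wanted:
        summary["similarity"] = _similarity_stage(
            config, out_dir, human_profiles, class_sets
        )
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _screen_stage(config: PipelineConfig, out_dir: Path):
    genes = load_gene_table(config.gene_table)
    screen_lines = load_screen_table(config.screen_table)
    by_gene: dict[str, list] = {}
    for ln in screen_lines:
        by_gene.setdefault(ln.fly_id, []).append(ln)
    fly_profiles = {
        g: aggregate_gene_phenotypes(
            lns, s19_min=config.s19_min, pi_threshold=config.pi_threshold
        )
        for g, lns in sorted(by_gene.items())
    }
    report = classify_report(fly_profiles)
    report.to_csv(out_dir / "class_report.tsv", sep="\t", index=False)
    _write_profiles(fly_profiles, out_dir / "gene_profiles.tsv")
    human_profiles = {
        symbol: dataclasses.replace(prof, gene_id=symbol)
        for symbol, prof in expand_orthology(fly_profiles, genes).items()
    }
    class_sets = {
        cls: {g for g, p in human_profiles.items() if cls in p.major_classes}
        for cls in ("EMD", "ERG_defective", "lethal", "NED")
    }
    return human_profiles, class_sets, report


def _expression_stage(
    config: PipelineConfig, out_dir: Path, class_sets: Mapping[str, set[str]]
) -> dict:
    expr = load_expression_matrix(config.expression_file)
    ranks = rank_within_tissue(expr)
    assignments = top_tissue_per_gene(ranks, exclude_all_zero_of=expr)
    pd.DataFrame(
        [(g, a.tissue, int(a.tied)) for g, a in sorted(assignments.items())],
        columns=["gene", "top_tissue", "tied"],
    ).to_csv(out_dir / "tissue_assignments.tsv", sep="\t", index=False)

    emd, ned = class_sets["EMD"], class_sets["NED"]
    top_tissue_stats: dict = {}
    if emd and ned:
        rows = []
        for tissue in ranks.tissues:
            fold, p = tissue_class_enrichment(emd, ned, assignments, tissue)
            k_emd = sum(
                1 for g in emd if g in assignments and assignments[g].tissue == tissue
            )
            k_ned = sum(
                1 for g in ned if g in assignments and assignments[g].tissue == tissue
            )
            rows.append((tissue, k_emd, k_ned, fold, p))
        df = pd.DataFrame(rows, columns=["tissue", "k_emd", "k_ned", "fold", "p"])
        df.to_csv(out_dir / "tissue_enrichment.tsv", sep="\t", index=False)
        top = df.sort_values(["k_emd", "tissue"], ascending=[False, True]).iloc[0]
        top_tissue_stats = {
            "tissue": str(top["tissue"]),
            "k_emd": int(top["k_emd"]),
            "k_ned": int(top["k_ned"]),
            "fold": float(top["fold"]),
            "p": float(top["p"]),
        }
    return {"top_tissue": top_tissue_stats}


def _network_stage(
    config: PipelineConfig,
    out_dir: Path,
    human_profiles: Mapping[str, GenePhenotypeProfile],
    class_sets: Mapping[str, set[str]],
) -> dict:
    net = InteractionNetwork()
    for path, tag in config.edge_files:
        net.merge(load_interaction_edges(path, tag))
    universe = set(human_profiles)
    category_enrichment = {}
    for cat in PhenotypeCategory:
        members = {g for g, p in human_profiles.items() if cat in p.categories}
        if len(members & net.nodes & universe) < 2:
            continue
        res = homotypic_enrichment(
            net,
            members & universe,
            universe,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"homotypic:{cat.value}"),
        )
        category_enrichment[cat.value] = res.as_dict()

    modules = []
    cats_by_gene = {g: p.categories for g, p in human_profiles.items()}
    for cat in PhenotypeCategory:
        modules.extend(extract_homotypic_modules(net, cats_by_gene, cat))
    msum = module_summary(modules)
    _write_modules(modules, out_dir / "modules.tsv")

    pie_results = {}
    for cls in ("EMD", "NED"):
        members = class_sets[cls] & net.nodes
        if len(members) >= 2:
            res = pie_score(
                net,
                members,
                n_samples=config.pie_samples,
                seed=stage_seed(config.seed, f"pie:{cls}"),
                degree_bins=config.degree_bins,
            )
            pie_results[cls] = res.as_dict()
    return {
        "n_nodes": len(net),
        "n_edges": net.n_edges,
        "category_enrichment": category_enrichment,
        "pie": pie_results,
        "module_summary": msum.as_dict(),
    }


def _similarity_stage(
    config: PipelineConfig,
    out_dir: Path,
    human_profiles: Mapping[str, GenePhenotypeProfile],
    class_sets: Mapping[str, set[str]],
) -> dict:
    ont = parse_obo(config.obo_file)
    annos, n_dropped = load_gene_phenotype_map(config.annotations_file, ont)
    vectors = build_all_vectors(annos, ont, config.similarity_config)
    sim_matrix = SimilarityMatrix(vectors) if vectors else None
    group_results = {}
    groups: dict[str, set[str]] = {
        cat.value: {g for g, p in human_profiles.items() if cat in p.categories}
        for cat in PhenotypeCategory
    }
    groups["EMD"] = class_sets["EMD"]
    groups["NED"] = class_sets["NED"]
    for label, members in sorted(groups.items()):
        usable = sorted(members & set(vectors))
        if len(usable) < 2:
            continue
        res = similarity_null_test(
            usable,
            n_samples=config.n_similarity_samples,
            seed=stage_seed(config.seed, f"similarity:{label}"),
            matrix=sim_matrix,
        )
        group_results[label] = res.as_dict()
    _write_similarity(group_results, out_dir / "similarity_groups.tsv")

    composition: dict = {}
    top_counts: dict = {}
    emd_annotated = class_sets["EMD"] & annos.genes
    ned_annotated = class_sets["NED"] & annos.genes
    if len(emd_annotated) >= 2 and len(ned_annotated) >= 2:
        top_emd = top_overrepresented_features(
            emd_annotated, annos, ont, K=config.top_k_features
        )
        top_ned = top_overrepresented_features(
            ned_annotated, annos, ont, K=config.top_k_features
        )
        _write_features(top_emd, out_dir / "top_features_EMD.tsv")
        _write_features(top_ned, out_dir / "top_features_NED.tsv")
        comp = compare_category_composition(top_emd, top_ned, ont)
        composition = {cat: dataclasses.asdict(c) for cat, c in sorted(comp.items())}
        pd.DataFrame(
            [
                (cat, c["count_a"], c["count_b"], c["fold"], c["chi2_p"])
                for cat, c in composition.items()
            ],
            columns=["category", "count_emd", "count_ned", "fold", "chi2_p"],
        ).to_csv(out_dir / "category_composition.tsv", sep="\t", index=False)
        top_counts = {"n_top_emd": len(top_emd), "n_top_ned": len(top_ned)}
    return {
        "n_vectors": len(vectors),
        "n_annotation_rows_dropped": n_dropped,
        "groups": group_results,
        "category_composition": composition,
        **top_counts,
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_profiles(profiles: Mapping[str, GenePhenotypeProfile], path: Path) -> None:
    rows = []
    for g, p in sorted(profiles.items()):
        rows.append(
            (
                g,
                ";".join(sorted(c.value for c in p.categories)),
                "" if p.mean_pi is None else f"{p.mean_pi:.3f}",
                "" if p.pi_sd is None else f"{p.pi_sd:.3f}",
                ";".join(sorted(p.major_classes)),
            )
        )
    pd.DataFrame(
        rows, columns=["gene", "categories", "mean_pi", "pi_sd", "major_classes"]
    ).to_csv(path, sep="\t", index=False)


def _write_modules(modules, path: Path) -> None:
    rows = []
    for idx, m in enumerate(modules):
        rows.append(
            (
                m.category.value,
                idx,
                len(m.genes),
                ";".join(sorted(m.genes)),
                ";".join(f"{a}--{b}" for a, b in sorted(m.edges)),
            )
        )
    pd.DataFrame(
        rows, columns=["category", "module_index", "size", "genes", "edges"]
    ).to_csv(path, sep="\t", index=False)


def _write_similarity(group_results: dict, path: Path) -> None:
    rows = [
        (
            label,
            r["mean_score"],
            r["null_mean"],
            r["null_q25"],
            r["null_q75"],
            r["p_empirical"],
            r["n_samples"],
        )
        for label, r in sorted(group_results.items())
    ]
    pd.DataFrame(
        rows,
        columns=["group", "mean_score", "null_mean", "q25", "q75", "p", "n_samples"],
    ).to_csv(path, sep="\t", index=False)


def _write_features(features, path: Path) -> None:
    rows = [
        (rank + 1, f.term, f.name, f.count_set, f.count_universe, f.fold, f.p)
        for rank, f in enumerate(features)
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "term", "name", "count_set", "count_universe", "fold", "p"],
    ).to_csv(path, sep="\t", index=False)
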