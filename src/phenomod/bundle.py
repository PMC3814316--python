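"""Write a complete synthetic input bundle (ontology + five TSVs + truth).

The bundle emulates the study conditions of the screen analysis: 270
screened fly genes (eight with two human paralogs, hence 278 human
records), two RNAi lines per gene, background per-line phenotype rates that
put roughly two thirds of genes into some phenotype class, five planted
six-gene phenotype groups that are also dense modules in a sparse
278-node interaction network and coherent annotation groups in a 150-term
ontology (with a designated 7-term excludable subtree), 45 tissues with the
planted morphology-group genes spiked in ``nerve``, and a planted
phototaxis-defective group with true PI below the hit threshold.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import AnnotationMap, PhenotypeCategory
from .io import (
    write_expression_matrix,
    write_gene_phenotype_map,
    write_gene_table,
    write_interaction_edges,
    write_obo,
    write_screen_table,
)
from .core import GeneRecord
from .pipeline import PipelineConfig, stage_seed
from .simulate import (
    GeneratorTruth,
    generate_expression_matrix,
    generate_group_annotations,
    generate_interaction_network,
    generate_ontology,
    generate_screen_annotations,
)

__all__ = ["write_synthetic_bundle", "DEFAULT_PLANTED_CATEGORIES"]

DEFAULT_PLANTED_CATEGORIES = (
    PhenotypeCategory.LONG_BRISTLES,
    PhenotypeCategory.STUBBLE_BRISTLES,
    PhenotypeCategory.NECROSIS,
    PhenotypeCategory.SMALL_EYE,
    PhenotypeCategory.LETHAL,
)

# per-line background call probabilities, calibrated so that together with
# the planted groups about two thirds of genes end up with some phenotype
# (the screen's overall hit rate); mildly rough and rough dominate
_BACKGROUND_RATES = {
    PhenotypeCategory.MILDLY_ROUGH: 0.115,
    PhenotypeCategory.ROUGH: 0.115,
    PhenotypeCategory.PARTIALLY_FUSED: 0.023,
    PhenotypeCategory.FUSED: 0.031,
    PhenotypeCategory.FEWER_BRISTLES: 0.019,
    PhenotypeCategory.NO_BRISTLES: 0.011,
    PhenotypeCategory.STUBBLE_BRISTLES: 0.008,
    PhenotypeCategory.LONG_BRISTLES: 0.004,
    PhenotypeCategory.NECROSIS: 0.011,
    PhenotypeCategory.LOSS_OF_PIGMENTATION: 0.023,
    PhenotypeCategory.SMALL_EYE: 0.015,
    PhenotypeCategory.WRINKLED_SURFACE: 0.015,
    PhenotypeCategory.DENTED_SURFACE: 0.011,
    PhenotypeCategory.LETHAL: 0.019,
    PhenotypeCategory.ERG_DEFECTIVE: 0.031,
}


def write_synthetic_bundle(
    out_dir: str | Path,
    seed: int,
    n_fly_genes: int = 270,
    n_paralog_pairs: int = 8,
    n_background_annotated: int = 122,
    n_tissues: int = 45,
    module_size: int = 6,
    within_density: float = 0.8,
    background_density: float = 0.02,
    coherence: float = 0.8,
    n_perm: int = 2_000,
    n_similarity_samples: int = 500,
    pie_samples: int = 500,
    top_k_features: int = 100,
) -> tuple[PipelineConfig, GeneratorTruth]:
    """Generate and write the full input bundle plus a pipeline config.

    Returns the config (also written as ``config.yaml``) and the merged
    generator truth (written as ``truth.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fly_ids = [f"Fg{i:04d}" for i in range(n_fly_genes)]
    genes = {}
    for i, fid in enumerate(fly_ids):
        symbols = [f"Hs{i:04d}"]
        if i < n_paralog_pairs:
            symbols.append(f"Hs{i:04d}B")
        genes[fid] = GeneRecord(fid, tuple(symbols))
    human_of = {fid: genes[fid].human_symbols for fid in fly_ids}
    all_human = [s for fid in fly_ids for s in human_of[fid]]

    # planted phenotype groups (fly gene ids; indices clear of the paralogs)
    planted_groups = []
    for gi, cat in enumerate(DEFAULT_PLANTED_CATEGORIES):
        start = 10 + 10 * gi
        planted_groups.append((cat, fly_ids[start : start + module_size]))
    phototaxis_members = fly_ids[200:220]
    planted_groups.append(
        (PhenotypeCategory.PHOTOTAXIS_DEFECTIVE, phototaxis_members)
    )

    screen_lines, screen_truth = generate_screen_annotations(
        n_fly_genes,
        _BACKGROUND_RATES,
        planted_groups,
        lines_per_gene=2,
        line_efficacy=0.95,
        seed=stage_seed(seed, "sim:screen"),
    )

    module_human = [
        ([s for fid in members for s in human_of[fid]], within_density)
        for cat, members in planted_groups[: len(DEFAULT_PLANTED_CATEGORIES)]
    ]
    net, net_truth = generate_interaction_network(
        len(all_human),
        background_density,
        module_human,
        seed=stage_seed(seed, "sim:network"),
        gene_ids=all_human,
    )

    synth_ont, ont_truth = generate_ontology(
        150, excluded_subtree_size=7, seed=stage_seed(seed, "sim:ontology")
    )

    # annotation universe: planted-group genes first, then the remaining
    # screened genes, then extra background genes (the "full HPO list")
    group_genes = [g for genes_h, _ in module_human for g in genes_h]
    rest = [s for s in all_human if s not in set(group_genes)]
    extra = [f"Hx{i:04d}" for i in range(n_background_annotated)]
    anno_gene_ids = group_genes + rest + extra
    annos, anno_truth = generate_group_annotations(
        synth_ont,
        len(anno_gene_ids),
        groups=[(len(genes_h), coherence) for genes_h, _ in module_human],
        terms_per_gene=5,
        seed=stage_seed(seed, "sim:annotations"),
        gene_ids=anno_gene_ids,
    )
    # sprinkle ascertainment-subtree annotations so pruning has work to do
    rng = np.random.default_rng(stage_seed(seed, "sim:subtree"))
    subtree_terms = sorted(
        synth_ont.ontology.descendants(synth_ont.excluded_root, inclusive=True)
    )
    patched = {g: set(annos.terms_of(g)) for g in annos.genes}
    for g in sorted(patched):
        if rng.random() < 0.3:
            patched[g].add(subtree_terms[int(rng.integers(len(subtree_terms)))])
    annos = AnnotationMap(patched, synth_ont.ontology)

    tissue_names = ["nerve"] + [f"tissue{i:02d}" for i in range(1, n_tissues)]
    # nerve-specific genes: drawn from the morphology (EMD) planted groups,
    # mirroring the enrichment of eye-defective genes in nervous tissue
    morphology_human = [
        s
        for cat, members in planted_groups[: len(DEFAULT_PLANTED_CATEGORIES)]
        if cat is not PhenotypeCategory.LETHAL
        for fid in members
        for s in human_of[fid]
    ]
    spiked = [(g, "nerve", 30.0) for g in morphology_human[:16]]
    expr, expr_truth = generate_expression_matrix(
        len(all_human),
        tissue_names,
        spiked,
        seed=stage_seed(seed, "sim:expression"),
        gene_ids=all_human,
    )

    # ---- write everything -------------------------------------------
    write_gene_table(genes, out / "gene_table.tsv")
    write_screen_table(screen_lines, out / "screen.tsv")
    write_interaction_edges(net, out / "edges_combined.tsv")
    write_obo(synth_ont.ontology, out / "ontology.obo")
    write_gene_phenotype_map(annos, out / "annotations.tsv")
    write_expression_matrix(expr, out / "expression.tsv")

    truth = GeneratorTruth(
        seeds={
            **screen_truth.seeds,
            **net_truth.seeds,
            **ont_truth.seeds,
            **anno_truth.seeds,
            **expr_truth.seeds,
        },
        planted_modules=net_truth.planted_modules,
        coherent_groups=anno_truth.coherent_groups,
        spiked=expr_truth.spiked,
        line_efficacy=screen_truth.line_efficacy,
        true_pi=screen_truth.true_pi,
        planted_screen_groups=screen_truth.planted_screen_groups,
        excluded_root=synth_ont.excluded_root,
    )
    truth.to_json(out / "truth.json")

    config = PipelineConfig(
        gene_table=str(out / "gene_table.tsv"),
        screen_table=str(out / "screen.tsv"),
        edge_files=[[str(out / "edges_combined.tsv"), "ppi_hprd"]],
        obo_file=str(out / "ontology.obo"),
        annotations_file=str(out / "annotations.tsv"),
        expression_file=str(out / "expression.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
        n_perm=n_perm,
        n_similarity_samples=n_similarity_samples,
        pie_samples=pie_samples,
        top_k_features=top_k_features,
        excluded_root=synth_ont.excluded_root,
    )
    config.to_yaml(out / "config.yaml")
    return config, truth
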