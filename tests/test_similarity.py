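import itertools
import math

import numpy as np
import pytest

from phenomod.core import AnnotationMap
from phenomod.similarity import (
    SimilarityConfig,
    SimilarityMatrix,
    ancestor_closure,
    build_all_vectors,
    build_feature_vector,
    compare_category_composition,
    group_mean_similarity,
    pairwise_similarity,
    prune_excluded_subtree,
    similarity_null_test,
    term_rarity_weights,
    top_overrepresented_features,
)
from phenomod.simulate import generate_group_annotations, generate_ontology
from phenomod.stats import hypergeometric_pvalue

from conftest import make_ontology


def corrcoef_oracle(va, vb):
    """Independent Pearson oracle over the padded union."""
    terms = sorted(set(va) | set(vb))
    a = np.array([va.get(t, 0.0) for t in terms])
    b = np.array([vb.get(t, 0.0) for t in terms])
    return float(np.corrcoef(a, b)[0, 1])


class TestAncestorClosure:
    def test_chain(self, chain_ontology):
        assert ancestor_closure(chain_ontology, "B") == {"B": 0, "A": 1, "root": 2}

    def test_diamond_min_level(self, diamond_ontology):
        # B -> A -> D (2 steps) beats B -> C1 -> C2 -> D (3 steps)
        assert ancestor_closure(diamond_ontology, "B")["D"] == 2

    def test_matches_matrix_power_oracle(self):
        synth, _ = generate_ontology(40, excluded_subtree_size=5, seed=6)
        ont = synth.ontology
        terms = sorted(ont.terms)
        idx = {t: i for i, t in enumerate(terms)}
        adj = np.zeros((len(terms), len(terms)), dtype=bool)
        for t in terms:
            for p in ont.parents(t):
                adj[idx[t], idx[p]] = True
        reach = np.eye(len(terms), dtype=bool)
        power = np.eye(len(terms), dtype=bool)
        for _ in range(len(terms)):
            power = power @ adj
            reach |= power
        for t in terms[:10]:
            assert set(ancestor_closure(ont, t)) == {
                u for u in terms if reach[idx[t], idx[u]]
            }

    def test_unknown_term_is_error(self, chain_ontology):
        with pytest.raises(KeyError):
            ancestor_closure(chain_ontology, "nope")


class TestPruning:
    def test_whole_subtree_removed(self):
        synth, _ = generate_ontology(30, excluded_subtree_size=7, seed=2)
        ont = synth.ontology
        subtree = ont.descendants(synth.excluded_root, inclusive=True)
        assert len(subtree) == 7
        annos, _ = generate_group_annotations(synth.ontology, 10, seed=2, terms_per_gene=3)
        # inject subtree terms into every gene
        patched = {
            g: set(annos.terms_of(g)) | {synth.excluded_root} for g in annos.genes
        }
        annos = AnnotationMap(patched, ont)
        pruned = prune_excluded_subtree(annos, ont, synth.excluded_root)
        for g in pruned.genes:
            assert not (pruned.terms_of(g) & subtree)

    def test_gene_annotated_only_in_subtree_becomes_empty(self, chain_ontology):
        annos = AnnotationMap({"G1": {"B"}, "G2": {"A"}}, chain_ontology)
        pruned = prune_excluded_subtree(annos, chain_ontology, "B")
        assert pruned.terms_of("G1") == frozenset()
        assert pruned.terms_of("G2") == {"A"}

    def test_untouched_gene_unchanged(self, diamond_ontology):
        annos = AnnotationMap({"G1": {"A"}}, diamond_ontology)
        pruned = prune_excluded_subtree(annos, diamond_ontology, "C1")
        assert pruned.terms_of("G1") == {"A"}


class TestFeatureVectors:
    def test_single_term_parent_weight(self, chain_ontology):
        annos = AnnotationMap({"G1": {"B"}, "G2": {"A"}}, chain_ontology)
        rarity = term_rarity_weights(annos, chain_ontology)
        vec = build_feature_vector(
            "G1", annos, chain_ontology, SimilarityConfig(decay=0.5)
        )
        # direct term B at level 0, parent A at level 1; root dropped
        assert vec["B"] == pytest.approx(rarity["B"])
        assert vec["A"] == pytest.approx(0.5 * rarity["A"])
        assert "root" not in vec

    def test_shared_parent_sums_contributions(self):
        ont = make_ontology({"P": ["root"], "X": ["P"], "Y": ["P"]})
        annos = AnnotationMap({"G1": {"X", "Y"}, "G2": {"X"}, "G3": {"Y"}}, ont)
        rarity = term_rarity_weights(annos, ont)
        vec = build_feature_vector("G1", annos, ont, SimilarityConfig(decay=0.5))
        # two direct terms, length norm 1/2; P reached at level 1 from both
        assert vec["P"] == pytest.approx(2 * (rarity["P"] * 0.5 * 0.5))
        assert vec["X"] == pytest.approx(rarity["X"] * 0.5)

    def test_decay_to_zero_limit_keeps_direct_terms_only(self, chain_ontology):
        annos = AnnotationMap({"G1": {"B"}, "G2": {"A"}}, chain_ontology)
        vec = build_feature_vector(
            "G1", annos, chain_ontology, SimilarityConfig(decay=1e-9)
        )
        direct_w = vec["B"]
        assert all(w <= direct_w * 1e-8 for t, w in vec.items() if t != "B")

    def test_rarity_is_descendant_inclusive(self, chain_ontology):
        annos = AnnotationMap({"G1": {"B"}, "G2": {"A"}}, chain_ontology)
        rarity = term_rarity_weights(annos, chain_ontology)
        # A is hit by both genes (G2 directly, G1 via descendant B)
        assert rarity["A"] == pytest.approx(-math.log(2 / 2))
        assert rarity["B"] == pytest.approx(-math.log(1 / 2))

    def test_empty_after_pruning_is_error(self, chain_ontology):
        annos = AnnotationMap({"G1": {"B"}, "G2": {"A"}}, chain_ontology)
        with pytest.raises(ValueError, match="G1"):
            build_feature_vector(
                "G1", annos, chain_ontology, SimilarityConfig(excluded_root="B")
            )


class TestPairwiseSimilarity:
    def test_identical_vectors_score_one(self):
        v = {"a": 1.0, "b": 2.0, "c": 0.5}
        assert pairwise_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_vectors_score_low(self):
        va = {"a": 1.0, "b": 2.0}
        vb = {"c": 1.5, "d": 0.5}
        s = pairwise_similarity(va, vb)
        assert s is not None and s < 0.5

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(4)
        terms = [f"t{i}" for i in range(8)]
        for _ in range(20):
            va = {t: float(rng.uniform(0.1, 2)) for t in rng.choice(terms, 5, replace=False)}
            vb = {t: float(rng.uniform(0.1, 2)) for t in rng.choice(terms, 5, replace=False)}
            assert pairwise_similarity(va, vb) == pytest.approx(
                corrcoef_oracle(va, vb), abs=1e-10
            )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        terms = [f"t{i}" for i in range(10)]
        for _ in range(30):
            va = {t: float(rng.uniform(0.1, 2)) for t in rng.choice(terms, 4, replace=False)}
            vb = {t: float(rng.uniform(0.1, 2)) for t in rng.choice(terms, 6, replace=False)}
            s1, s2 = pairwise_similarity(va, vb), pairwise_similarity(vb, va)
            assert s1 == pytest.approx(s2)
            assert -1.0 - 1e-12 <= s1 <= 1.0 + 1e-12

    def test_zero_variance_is_undefined(self):
        # both vectors carry the same single term: union has one element
        assert pairwise_similarity({"a": 1.0}, {"a": 2.0}) is None

    def test_matrix_path_agrees_with_dict_path(self):
        rng = np.random.default_rng(11)
        terms = [f"t{i}" for i in range(12)]
        vectors = {
            f"g{i}": {
                t: float(rng.uniform(0.1, 2))
                for t in rng.choice(terms, 5, replace=False)
            }
            for i in range(8)
        }
        sm = SimilarityMatrix(vectors)
        for a, b in itertools.combinations(sorted(vectors), 2):
            expected = pairwise_similarity(vectors[a], vectors[b])
            got = sm.matrix[sm.index[a], sm.index[b]]
            assert got == pytest.approx(expected, abs=1e-10)


class TestGroupSimilarity:
    def _vectors(self, seed=0, n=30, coherent=None):
        synth, _ = generate_ontology(60, excluded_subtree_size=5, seed=seed)
        groups = [coherent] if coherent else []
        annos, truth = generate_group_annotations(
            synth, n, groups=groups, terms_per_gene=5, seed=seed
        )
        cfg = SimilarityConfig(excluded_root=synth.excluded_root)
        return build_all_vectors(annos, synth.ontology, cfg), truth

    def test_two_identical_genes_score_one(self, chain_ontology):
        ont = make_ontology({"A": ["root"], "B": ["root"], "C": ["A"]})
        annos = AnnotationMap({"G1": {"C", "B"}, "G2": {"C", "B"}, "G3": {"A"}}, ont)
        vectors = build_all_vectors(annos, ont)
        assert group_mean_similarity(["G1", "G2"], vectors) == pytest.approx(1.0)

    def test_three_gene_mean_is_pair_average(self):
        vectors, _ = self._vectors(seed=3)
        genes = sorted(vectors)[:3]
        pairs = [
            pairwise_similarity(vectors[a], vectors[b])
            for a, b in itertools.combinations(genes, 2)
        ]
        assert group_mean_similarity(genes, vectors) == pytest.approx(
            np.mean([p for p in pairs if p is not None])
        )

    def test_coherent_group_hits_p_floor(self):
        vectors, truth = self._vectors(seed=7, n=60, coherent=(8, 0.9))
        group = truth.coherent_groups[0]["genes"]
        res = similarity_null_test(group, vectors, n_samples=499, seed=5)
        assert res.p_empirical == 1 / (499 + 1)
        assert res.mean_score > res.null_mean

    def test_incoherent_group_not_at_floor(self):
        vectors, truth = self._vectors(seed=8, n=60, coherent=(8, 0.0))
        group = truth.coherent_groups[0]["genes"]
        res = similarity_null_test(group, vectors, n_samples=499, seed=5)
        assert res.p_empirical > 1 / (499 + 1)

    def test_direction_below_null_mean_gives_large_p(self):
        vectors, _ = self._vectors(seed=9, n=40)
        genes = sorted(vectors)
        rng = np.random.default_rng(0)
        ps = []
        for i in range(20):
            group = list(rng.choice(genes, size=5, replace=False))
            res = similarity_null_test(group, vectors, n_samples=199, seed=i)
            if res.mean_score < res.null_mean:
                ps.append(res.p_empirical)
        assert ps and all(p > 0.3 for p in ps)

    def test_subtree_exclusion_metamorphic(self):
        # pair scores are unchanged by exclusion for genes with no subtree terms
        synth, _ = generate_ontology(50, excluded_subtree_size=7, seed=12)
        annos, _ = generate_group_annotations(synth, 20, terms_per_gene=4, seed=12)
        with_excl = build_all_vectors(
            annos, synth.ontology, SimilarityConfig(excluded_root=synth.excluded_root)
        )
        without = build_all_vectors(annos, synth.ontology, SimilarityConfig())
        genes = sorted(with_excl)[:6]
        for a, b in itertools.combinations(genes, 2):
            s1 = pairwise_similarity(with_excl[a], with_excl[b])
            s2 = pairwise_similarity(without[a], without[b])
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_similarity_increases_with_annotation_overlap(self):
        # median similarity rises as two genes share more direct terms
        synth, _ = generate_ontology(80, excluded_subtree_size=5, seed=20)
        ont = synth.ontology
        vocab = sorted(
            set(ont.terms)
            - ont.descendants(synth.excluded_root)
            - {ont.root}
        )
        medians = []
        for n_shared in [0, 2, 4, 6]:
            scores = []
            for seed in range(20):
                rng = np.random.default_rng(1000 * n_shared + seed)
                shared = list(rng.choice(vocab, size=6, replace=False))
                rest = [t for t in vocab if t not in shared]
                a_terms = shared[:n_shared] + list(
                    rng.choice(rest, size=6 - n_shared, replace=False)
                )
                rest2 = [t for t in rest if t not in a_terms]
                b_terms = shared[:n_shared] + list(
                    rng.choice(rest2, size=6 - n_shared, replace=False)
                )
                # background genes so rarity weights are informative
                gene_annos = {"A": set(a_terms), "B": set(b_terms)}
                for k in range(30):
                    gene_annos[f"bg{k}"] = set(
                        rng.choice(vocab, size=6, replace=False)
                    )
                annos = AnnotationMap(gene_annos, ont)
                vecs = build_all_vectors(annos, ont, SimilarityConfig())
                s = pairwise_similarity(vecs["A"], vecs["B"])
                if s is not None:
                    scores.append(s)
            medians.append(np.median(scores))
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(medians, medians[1:]))


class TestTopFeatures:
    def _setup(self, seed=4):
        synth, _ = generate_ontology(60, excluded_subtree_size=5, seed=seed)
        annos, truth = generate_group_annotations(
            synth, 50, groups=[(10, 0.9)], terms_per_gene=5, seed=seed
        )
        return synth, annos, truth

    def test_universal_rare_term_ranks_first(self):
        ont = make_ontology({"A": ["root"], "B": ["root"]})
        annos = AnnotationMap(
            {"G1": {"A"}, "G2": {"A"}, "G3": {"B"}, "G4": {"B"}, "G5": {"B"}}, ont
        )
        top = top_overrepresented_features({"G1", "G2"}, annos, ont, K=5)
        assert top[0].term == "A"

    def test_k_larger_than_term_count_returns_all(self):
        ont = make_ontology({"A": ["root"]})
        annos = AnnotationMap({"G1": {"A"}, "G2": {"A"}}, ont)
        top = top_overrepresented_features({"G1"}, annos, ont, K=50)
        assert len(top) == 1

    def test_ranking_matches_exact_hypergeometric_recompute(self):
        synth, annos, truth = self._setup()
        ont = synth.ontology
        gene_set = set(truth.coherent_groups[0]["genes"])
        top = top_overrepresented_features(gene_set, annos, ont, K=30)
        # independent recompute: descendant-inclusive membership by brute force
        universe = sorted(annos.genes)
        rows = []
        for term in ont.terms:
            if term == ont.root:
                continue
            carriers = set()
            down = ont.descendants(term, inclusive=True)
            for g in universe:
                if annos.terms_of(g) & down:
                    carriers.add(g)
            if not carriers:
                continue
            k = len(carriers & gene_set)
            p = hypergeometric_pvalue(k, len(carriers), len(gene_set), len(universe))
            fold = (k / len(gene_set)) / (len(carriers) / len(universe))
            rows.append((p, -fold, term))
        rows.sort()
        assert [r.term for r in top] == [t for _, _, t in rows[:30]]


class TestCategoryComposition:
    def _ont_with_two_branches(self, n_head=70, n_meta=70):
        edges = {"head": ["root"], "meta": ["root"]}
        for i in range(n_head):
            edges[f"h{i}"] = ["head"]
        for i in range(n_meta):
            edges[f"m{i}"] = ["meta"]
        return make_ontology(edges)

    @staticmethod
    def _features(terms):
        from phenomod.similarity import FeatureEnrichment

        return [FeatureEnrichment(t, t, 1, 1, 1.0, 0.01) for t in terms]

    def test_printed_64_vs_22_rounds_to_three(self):
        ont = self._ont_with_two_branches()
        top_a = self._features([f"h{i}" for i in range(64)] + [f"m{i}" for i in range(66)])
        top_b = self._features([f"h{i}" for i in range(22)] + [f"m{i}" for i in range(44)])
        # pad both lists to 200 features with the other branch
        top_a += self._features([f"m{66 + i % 4}" for i in range(70)])
        top_b += self._features([f"m{44 + i % 4}" for i in range(134)])
        assert len(top_a) == len(top_b) == 200
        comp = compare_category_composition(top_a, top_b, ont, {"head", "meta"})
        assert comp["head"].count_a == 64 and comp["head"].count_b == 22
        assert round(comp["head"].fold) == 3
        assert comp["head"].chi2_p < 1e-6

    def test_printed_17_vs_1_fold(self):
        ont = self._ont_with_two_branches(30, 30)
        top_a = self._features([f"h{i}" for i in range(17)] + [f"m{i}" for i in range(13)])
        top_b = self._features([f"h{0}"] + [f"m{i}" for i in range(29)])
        comp = compare_category_composition(top_a, top_b, ont, {"head", "meta"})
        assert comp["head"].fold == pytest.approx(17.0)

    def test_equal_counts_fold_one_p_one(self):
        ont = self._ont_with_two_branches(10, 10)
        top_a = self._features([f"h{i}" for i in range(5)] + [f"m{i}" for i in range(5)])
        top_b = self._features([f"h{i}" for i in range(5)] + [f"m{i+5}" for i in range(5)])
        comp = compare_category_composition(top_a, top_b, ont, {"head", "meta"})
        assert comp["head"].fold == pytest.approx(1.0)
        assert comp["head"].chi2_p == pytest.approx(1.0)

    def test_feature_under_no_top_level_goes_unclassified(self):
        ont = make_ontology({"head": ["root"], "x": ["root"], "h0": ["head"]})
        comp = compare_category_composition(
            self._features(["x"]), self._features(["h0"]), ont, {"head"}
        )
        assert comp["unclassified"].count_a == 1
        assert comp["head"].count_b == 1
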