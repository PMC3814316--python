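# Methods

This note documents the models and procedures implemented in `phenomod`,
the parameters that matter, the synthetic-data generators, and the design
choices made where the analysis left the design open.

## Screen quantification

The Phototaxis Index of a tube distribution (N₁..N₆ flies, N = ΣNᵢ) is
PI = (Σᵢ i·Nᵢ)/N, bounded in [1, 6]. Replicate PIs are summarised by the
arithmetic mean and the **sample** standard deviation (n−1 denominator;
population vs sample SD is not dictated by the assay, so the unbiased
estimator is used; SD is undefined for a single replicate). A quality flag
is raised when the SD exceeds 1.2, the screen's maximal accepted per-line
spread. A line is a phototaxis hit when its mean PI is **strictly** below
the cut-off (default 4.0; wild-type-like controls score about 5.2).

Per-gene profiles take the union of category calls over the gene's RNAi
lines: RNAi knockdown strength varies, so a single positive line suffices
and an inefficient line cannot veto an efficient one. If any line is a
phototaxis hit, the `phototaxis_defective` category is added; the reported
per-gene mean PI is that of the lowest-scoring line, consistent with the
any-line rule. An optional s19 specificity threshold excludes lines before
the union; it is off by default because screen inputs are normally
pre-filtered. Category calls themselves (including the >90%-penetrance
convention for mildly-rough) are upstream annotation decisions taken as
given in the input table.

Major classes: EMD iff any of the 13 morphology categories is present;
`lethal` and `ERG_defective` mirror their labels; NED iff the category set
is empty. Only NED is exclusive.

## Orthology expansion

Fly-gene results are duplicated to every listed human ortholog symbol
(one fly gene with two human paralogs yields two human records). Gene
identifiers are case-sensitive strings with no aliasing — inputs must be
pre-resolved; silent symbol matching is a classic source of wrong joins.
Two fly genes mapping to the same human symbol is rejected as an input
error rather than merged.

## Tissue expression

Because average expression differs strongly between tissue libraries, raw
abundances are not comparable across tissues. Genes are ranked within each
tissue (ascending with expression, ties averaged), which makes the
procedure invariant under any strictly monotone per-tissue transform; each
gene is assigned the tissue of its highest rank. Cross-tissue rank ties
resolve to the first tissue in declared column order and are flagged.
Genes with all-zero expression are excluded from assignment (their argmax
is meaningless) and counted separately. Class compositions per tissue are
compared by the fold of proportions (k_A/n_A)/(k_B/n_B); significance uses
the two-sided Fisher exact test by default (χ² is available) since the
counts involved are small.

## Network enrichment

The combined interaction network is undirected; a gene pair is **one**
unique connection no matter how many sources report it, with source tags
(`ppi_hprd`, `interolog`, `coap_complex`, `genetic`) kept as provenance.
Self-loops are dropped at load time. Genes absent from any edge list are
retained as degree-0 nodes.

*Homotypic enrichment.* Observed = within-set edge count of a category's
genes; the null draws 10,000 (configurable) same-size gene sets uniformly
without replacement from a declared universe. By default both category and
universe are restricted to network-present genes so set sizes match the
genes that can contribute edges. Fold = observed / null mean (the null
median is available); empirical p uses the add-one estimator
(1 + #{null ≥ obs})/(n + 1), so p can never be 0 and its floor is
1/(n + 1).

*PIE.* The degree-aware variant replaces every member of the gene set with
a gene drawn from the same equal-frequency degree-quantile bin (default 10
bins) of the whole network — never the gene itself, no duplicates within a
draw; bins without a substitute are widened to neighbouring bins with a
logged warning. This normalisation counters the tendency of intensely
studied disease genes to carry more reported interactions. The published
PIE description leaves its modified normalisation factor unspecified;
degree-quantile resampling is this package's interpretation of "accounting
for biases in the number of reported interactions" and the bin count is
exposed as a parameter. With one bin the PIE null reduces to uniform
sampling over the network (verified by an equivalence test).

*Modules.* A homotypic module is a connected component (size ≥ 2) of the
network restricted to genes carrying one phenotype category — genes with
non-overlapping phenotypes can never share a module. Pairs count as
modules. Module summaries report the union of genes across categories and
two connection counts: unique pairs deduplicated across categories (the
headline number) and the per-category tally, since a pair can be homotypic
in two categories and the published counting convention is ambiguous.

## Human phenotype similarity

Each gene's direct ontology annotations become a weighted feature vector:

  w(t) = rarity(t) · decay^level(t) · (1/|direct terms|)

summed over the direct terms that reach t. Rarity(t) = −ln(g_t/G) where
g_t counts genes annotated to t directly **or via a descendant** and G is
the number of annotated genes (frequency clipped to ≥ 1/G). Ancestor
levels are minimal BFS distances; the decay default is 0.5 per level
(geometric — the published algorithm states only "progressively lower
weights", so the rate is a declared assumption exposed in
`SimilarityConfig`). Length normalisation divides by the number of direct
terms so richly annotated genes do not dominate. The root term is dropped
(it occurs in every augmented vector and would inflate all correlations).
The ascertainment subtree (e.g. the intellectual-disability terms when the
gene list was selected on that phenotype) is pruned from direct
annotations **and** filtered after augmentation, so excluded terms cannot
re-enter as ancestors.

Pair similarity is the Pearson correlation over the union of the two
vectors' terms (absent terms contribute 0); pairs whose union has zero
variance are undefined and excluded. Pearson is the default reading of an
unqualified "correlation coefficient". Group coherence is the mean over
all C(n,2) defined pairs, tested against equal-size sets sampled uniformly
(without replacement within a set) from all genes with vectors; quartiles
of the null are reported alongside the empirical p. A vectorized
all-pairs similarity matrix (sparse products over term supports) backs the
permutation test; it computes the identical statistic as the per-pair
path, and the test suite checks the two against each other.

Feature over-representation uses the exact hypergeometric upper tail with
descendant-inclusive term membership (standard for ontology enrichment);
ranking is by ascending p, ties broken by higher fold then term id, top K
(default 200) kept, with Benjamini–Hochberg q-values additionally emitted.
Feature lists are compared by mapping each feature to every top-level
category (child of the root) it descends from — features reaching none go
to an `unclassified` bucket — with per-category folds and a χ² (no
continuity correction, matching the plain-χ² convention of the original
comparisons).

## Statistics

Hypergeometric tails, Fisher's exact test, χ² and rank transforms are
delegated to `scipy.stats` behind validated wrappers; the permutation
machinery and the samplers are owned by this package. All random-set
sampling funnels through one seeded NumPy generator; the universe is
sorted before sampling so results do not depend on input order, and a
fixed seed gives bit-identical draws.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes; every planted structure is retained in a serializable
`GeneratorTruth`.

* **Ontology:** single-root random DAG (≤2 parents per term) with one
  marked subtree of exactly 7 terms (by default) whose descendant closure
  never leaks into ordinary terms, so subtree exclusion is exactly
  scoreable.
* **Screen:** per-line background category probabilities; planted groups
  receive their category with per-line efficacy (default 0.95); PI
  replicates are Normal(true PI, 0.4) truncated to [1, 6] — with that
  noise, control-like genes (true PI 5.2) essentially never cross the
  hit threshold, mirroring the screen's stringency; planted
  phototaxis-defective genes get true PI drawn below 4.
* **Network:** Erdős–Rényi background plus planted modules at a chosen
  within-density; random source tags.
* **Annotations:** each coherent group owns a hidden term pool; members
  draw a `coherence` fraction of their terms from it, the rest uniformly.
* **Expression:** log(value) = 2 + a_g + b_t + ε with per-gene abundance
  a_g ~ N(0,1) (heavy-tailed counts and realistic cross-tissue rank
  correlation), per-tissue library scale b_t ~ N(0,1) (motivating
  within-tissue ranking; it cancels exactly under ranking) and cell noise
  ε ~ N(0,0.4). A spike multiplies one (gene, tissue) entry by
  `foldboost`; its signal-to-noise is ln(foldboost)/0.4.

The demonstration bundle (`phenomod simulate`, `bundle.py`) mirrors the
screen's shape: 270 fly genes, 8 paralog pairs (278 human records), two
lines per gene, background rates calibrated so about two thirds of genes
carry some phenotype, five planted six-gene groups that are simultaneously
dense network modules (within-density 0.8 on a 0.02 background) and
coherent annotation groups (coherence 0.8) over a 150-term ontology with a
7-term excludable subtree, 45 tissues with 16 morphology-group genes
spiked in `nerve`, and a 20-gene planted phototaxis group. What passing
tests on these data show is that the pipeline recovers planted structure
and is calibrated under its own null; they do not certify the biological
conclusions of any particular real dataset, whose database snapshots
(interaction sources, ontology builds, EST profiles) are not bundled and
whose version-dependent fold values are therefore out of scope.

## Problem sizes and numerics

Default analysis parameters are n_perm = 10,000 permutations, 1000
similarity null samples, top-200 features. The demonstration config
written by `simulate` and the test suite use scaled-down nulls
(n_perm 300–2000, 99–500 similarity samples) — permutation p-value floors
scale accordingly and are always reported as 1/(n+1). One global seed
derives per-stage seeds by CRC32-hashing the stage name (kept below 2³¹),
so any stage reruns reproducibly in isolation. Frequencies in rarity
weights are clipped to ≥ 1/G; pair variance below 1e−15 over the union is
treated as zero (undefined pair). Cross-tissue rank ties break to declared
tissue order; feature-rank ties break by fold then term id; modules order
by size then lexicographically smallest gene. Degenerate enrichment
(observed = null mean = 0) reports fold 1 with a degenerate flag rather
than 0/0.

## Known limitations

* The PIE normalisation is an interpretation (degree-quantile resampling);
  other degree-preserving nulls (edge rewiring) are not implemented.
* Information-content similarity schemes (Resnik, Lin) are out of scope;
  only the rarity-weighted correlation family is provided.
* No identifier mapping: inputs must use consistent gene symbols.
* Permutations run single-threaded; determinism is guaranteed by the
  per-stage seed derivation rather than by chunked parallel draws.
* The synthetic generators do not fit real marginals (degree
  distributions, annotation depth, EST library sizes); they emulate
  structure, not scale.
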