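# Methods

## The analysis model

The pipeline treats a disease gene's pleiotropy as a property to be related
to its position in the protein interaction network. Genes are partitioned by
their number of associated diseases (specific = 1, shared ≥ 2), shared genes
are sub-partitioned by the minimum phenotype-similarity score over their
unordered disease pairs (phenosim ≥ cutoff, phenodiv < cutoff), and
essentiality (knockout-lethal ortholog) is carried as an independent axis.
Each class is then profiled on the interactome (degree, closeness,
betweenness, eccentricity, clustering coefficient), on tissue co-expression
with interaction partners, on the fraction of disease-gene interactors, and
on annotation-category membership, with nonparametric two-sided tests
throughout.

### Per-gene similarity: minimum over disease pairs

A gene's phenotypic coherence is summarized as the **minimum** pairwise
similarity among its diseases, so a single divergent disease pair is enough
to mark a gene phenodiv. The phrasing "score for all diseases" admits a
per-disease reading; `assign_min_similarity(mode="per_disease")` implements
it (mean of each disease's pairwise scores, then the minimum), but pairwise
phenotype similarity is the semantically natural unit and is the default.
Genes with any unscored pair are excluded from the split and counted, never
silently dropped.

The cutoff resolves either to a fixed number (reproducible across datasets)
or to the median of the per-gene minima of the dataset at hand. The split is
monotone: raising the cutoff can only move genes phenosim → phenodiv.

### Graph conventions

The interactome is simplified (self-loops removed, duplicate pairs
collapsed) before any measure is computed. Because real interactomes have
satellite components, all distance-based measures are **per component**:
closeness is (n_c − 1)/Σd within the component (0 for isolates), eccentricity
is the component-wise maximum distance (0 for isolates), and betweenness uses
Brandes accumulation per component with endpoint-excluding normalization by
(n_c − 1)(n_c − 2)/2, which keeps values in [0, 1] and reproduces the
~10⁻⁴ scale of mean betweenness on a ~10⁴-node network. These conventions
are recorded in `run_metadata.json` so alternatives can be compared.
Standard graph algorithms are delegated to networkx; the test suite checks
all five measures to 1e-9 against an independent Floyd-Warshall oracle that
enumerates every shortest path explicitly.

The clustering coefficient is **undefined** for degree < 2 and reported as
NaN rather than 0; class means over hubs would otherwise be deflated by
leaves. `clustering_coefficient(undefined_as_zero=True)` restores the other
convention.

An exact betweenness computation is the default at all problem sizes used
here; `compute_centralities(betweenness_pivots=k)` switches to pivot
sampling for graphs where exactness is impractical.

### Tissue co-expression

TCI(g, i) = |tissues(g) ∩ tissues(i)| / T over the T surveyed tissues
(T = 79 by default, matching whole-body expression atlases), computed on the
binarized expression matrix (value ≥ threshold; matrices containing only
0/1 are treated as already binarized). TCI is symmetric, bounded in [0, 1],
and monotone non-increasing in the detection threshold. Reports carry both
the fraction and the ×100 percentage scale. Class comparisons run on
per-gene mean TCI, with the pair-level pooled records also emitted — which
unit a study means is often ambiguous, so both are available. Local
interactome profiles (which interactors of one gene are expressed in a
disease-tissue condition matrix) default to an "expressed in ≥ half of the
columns" rule, configurable to any/all.

### Permutation enrichment

For query size N (after restriction to the annotated universe), each of
`n_reps` (default 10,000) replicates draws N genes uniformly without
replacement and counts members per category; categories with fewer than 5
annotated genes are excluded after counting. The empirical p-value uses the
add-one estimator (1 + #{random ≥ observed})/(n_reps + 1): the plain ratio
with a strict > tail returns exactly 0 at extremes, which misstates the
evidence; add-one is never zero and biased at most 1/(n_reps+1) upward. The
raw estimator remains available (`estimator="raw"`) and the choice is
recorded in the output. Because ties count toward the tail, the estimator is
conservative under the null — visible in calibration tests as a mean p
slightly above 0.5. The exact hypergeometric tail (integer-exact binomial
coefficients) serves as the analytic cross-check; at 10,000 reps the two
agree within 3 Monte-Carlo standard errors across random configurations.

The sampling universe is all annotated genes by default (configurable to a
different universe such as the interactome). Annotations are consumed as a
flat gene → category table assumed pre-propagated to ancestor categories;
ontology-graph handling is out of scope.

### Statistics

All tests are two-sided; directions are reported separately via class means.
Mann-Whitney U uses the exact null distribution for small tie-free samples
(n_a·n_b ≤ 400) and the tie- and continuity-corrected normal approximation
otherwise — a deterministic rule, so p-values are bit-reproducible. Spearman
uses midranks with the t-approximation; Fisher's exact test sums
probabilities of tables at most as probable as the observed one. scipy
provides the implementations; enumeration, midrank-formula and
rational-arithmetic oracles in the test suite verify them independently.

## The synthetic-data generator

The generator emulates the joint structure the analysis assumes, with every
effect planted explicitly so downstream recovery is checkable.

- **Classes.** Default fractions: specific 0.25, phenosim 0.08, phenodiv
  0.08, essential non-disease 0.15, remainder unclassified background —
  roughly the proportions of curated disease-gene datasets, where specific
  genes outnumber scored shared genes ~5:1 and the phenosim/phenodiv split
  is balanced.
- **Interactome.** Per-gene degrees are lognormal with σ_log = 1.2 (degree
  SDs in curated interactomes run near twice the mean; CV ≈ 1.8 implies
  σ_log = √ln(1+CV²) ≈ 1.2), scaled per class by `degree_multiplier`
  (defaults 1.0 / 1.0 / 1.5 / 1.6 / 0.8 for specific / phenosim / phenodiv /
  essential / background, the observed centrality ordering of those
  classes), wired by a configuration model and simplified. Simplification
  collapses multi-edges at hubs, so stub counts are redrawn inflated until
  the realized edge count is within 7% of target; the residual loss is
  logged. Isolated nodes are reattached by one random edge so every gene
  appears in every input file.
- **Diseases and similarity.** Each shared gene gets `diseases_per_shared`
  (default 3) private diseases. Phenosim genes draw all pair scores from
  m + (1−m)·Beta(2,2); phenodiv genes draw one designated minimum pair from
  m·Beta(2,2) and the rest above it (m = `similarity_median`, default 0.33).
  The two families straddle the cutoff by construction, so classification at
  the known cutoff reproduces the truth labels exactly (the closure property
  tested over 20 seeds). When the dataset's *median* is used as the cutoff
  instead, exact closure additionally requires the phenosim and phenodiv
  counts to be equal — otherwise the empirical median falls inside one score
  family — which the default balanced fractions satisfy.
- **Essentiality.** All essential-non-disease-class genes, plus disease
  genes at class rates (defaults: specific 0.17, phenosim/phenodiv 0.44,
  the observed essential-disease-gene proportions).
- **Expression.** Each gene's expressed-tissue set is drawn exactly once, in
  random order: with probability ρ (`coexpression_coupling`, default 0.3)
  and at least one already-assigned neighbor, the set is resampled from that
  partner's expressed tissues (count kept at Binomial(T, breadth));
  otherwise tissues are chosen uniformly, which is exactly independent
  Bernoulli(breadth) per tissue. Single-assignment avoids later edges
  overwriting earlier couplings, making mean TCI strictly increasing in ρ
  (verified over ρ ∈ {0, 0.4, 0.8}); at ρ = 0 mean TCI converges to
  breadth², the independence limit. Default breadth 0.65 puts baseline TCI
  near 0.42-0.46 on the percentage scale, the range reported for human
  gene-interactor pairs.
- **Annotations.** 30 categories with base membership probability uniform in
  [0.02, 0.10]; `planted_enrichment=(class, categories, fold)` multiplies
  the probability for chosen categories in one class (default: 3× in
  phenodiv for C01-C03).
- **Null variant.** `simulate_null` sets all multipliers to 1, equalizes
  essentiality rates and breadths across classes, and removes the planted
  enrichment, leaving the coupling uniform — the global null used for
  calibration.

What the generator does **not** emulate: literature-curation ascertainment
bias, disease sharing between genes (each gene's diseases are private),
correlated tissue structure (tissues are exchangeable), ontology DAG
topology, and degree-similarity confounding beyond what the class structure
induces. Passing recovery tests therefore shows the pipeline is correct and
well calibrated under the assumed structure, not that real data satisfy that
structure.

## Problem sizes and numerical choices

- Planted-effect recovery runs at 2,000 genes / ~10,000 edges with 400
  genes per class; the smaller calibration studies use 200-400 genes per
  dataset with 200 seeds for the Mann-Whitney null (3·SE band around 5%)
  and 20 seeds × 1,000 replicates for enrichment-p uniformity. These sizes
  give the checks adequate power while keeping the default suite quick.
- Degrees enter tests as integers; ties are handled by the corrected normal
  approximation, whose null calibration is itself tested.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed yields byte-identical dataset files and reports (TSV floats printed
  with `%.10g`, JSON metadata without timestamps).
- Degenerate inputs are explicit errors (empty edge list, zero tissues,
  zero-margin 2×2 tables, no scored shared genes) or counted exclusions
  (unscored shared genes, genes missing from the graph or expression
  matrix), never silent.

## Known limitations

- The phenosim/phenodiv cutoff is a hard threshold; genes near the cutoff
  are classified with certainty the score quality may not support. The
  Spearman correlations against the continuous score are the cutoff-free
  complement.
- Betweenness and closeness are computed on the unweighted graph;
  interaction confidence weights are ignored by design.
- The permutation test treats genes as exchangeable within the universe;
  degree- or annotation-length-matched null models are not implemented.
- Expression binarization uses a single global threshold; platform-specific
  detection calls should be made upstream and supplied as a 0/1 matrix.
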