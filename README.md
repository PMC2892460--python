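# pleionet

Network analysis of pleiotropy in human disease genes.

Pleiotropy, in human genetic disease, is the ability of different mutations in
one gene to cause different disorders. `pleionet` asks how a disease gene's
pleiotropy relates to the position of its protein product in the
protein-protein interaction network. It is a toolkit for systems-biology
analyses of gene-disease tables, interactome edge lists, phenotype-similarity
scores, tissue-expression atlases and flat functional annotations — plus a
synthetic-data generator that emulates the statistical structure of those
inputs so the whole pipeline is testable without any external database.

## What it computes

**Gene classes.** From a gene-disease association table, genes are *specific*
(one disease) or *shared* (two or more; pleiotropic). Each shared gene whose
disease pairs all carry a phenotype-similarity score s ∈ [0, 1] receives the
minimum score over its unordered disease pairs, and shared genes are split at
a cutoff c (the dataset median by default) into *phenosim* (min s ≥ c:
similar phenotypes) and *phenodiv* (min s < c: divergent phenotypes).
Essentiality — ortholog of a knockout-lethal mouse gene — is an independent
axis: *essential disease genes* vs *essential (non-disease) genes*.

**Network centrality.** On the simple undirected interactome, per node:
degree k; closeness (reciprocal mean hop distance within the connected
component); betweenness (fraction of shortest paths through the node,
endpoints excluded, normalized per component by (n−1)(n−2)/2); eccentricity
(distance to the farthest node of the component); and the clustering
coefficient 2·e(N(v))/(k(k−1)), undefined for k < 2.

**Comparisons.** Mann-Whitney U between classes for every measure,
Spearman's ρ of each measure against the phenotype-similarity score,
Fisher's exact test for essential-disease-gene enrichment, and per-gene
fractions of disease-gene interactors.

**Tissue co-expression.** The Tissue Co-expression Index (TCI) of a
gene-interactor pair is the fraction of surveyed tissues in which both are
detected as expressed; low TCI at high degree marks an inter-modular hub,
high TCI an intra-modular one.

**Enrichment.** Permutation-based category overrepresentation: the observed
count of query genes per annotation category is compared against 10,000
random same-size gene lists; empirical p = (1 + #{random ≥ observed}) /
(reps + 1), cross-checkable against the exact hypergeometric tail.

## Worked example

Generate a synthetic dataset with the default planted structure (phenodiv
and essential genes more connected, essentiality enriched in shared genes)
and run the full pipeline:

```python
from pleionet import (SimulationConfig, simulate, write_dataset,
                      AnalysisConfig, run_all)

cfg = SimulationConfig(
    seed=1, n_genes=2000, n_edges_target=10_000,
    class_fractions={"specific": 0.2, "phenosim": 0.2, "phenodiv": 0.2,
                     "essential_nondisease": 0.2})
paths = write_dataset(simulate(cfg), "sim/")
bundle = run_all(AnalysisConfig(
    assoc_path=str(paths["assoc"]), edges_path=str(paths["edges"]),
    sims_path=str(paths["sims"]), essential_path=str(paths["essential"]),
    expr_path=str(paths["expr"]), annot_path=str(paths["annot"]),
    outdir="out/", cutoff=0.33, seed=1))
t1 = bundle.tables["table1_centrality"].set_index(["metric", "class_a", "class_b"])
print(t1.loc[("degree", "phenosim", "phenodiv"),
             ["mean_a", "mean_b", "p_value"]])
print(bundle.tables["essential_fisher"][["class_a", "class_b",
                                         "frac_a", "frac_b", "p_value"]])
```

prints

```
mean_a        8.145
mean_b      11.3175
p_value    0.000052
class_a   class_b  frac_a  frac_b       p_value
 shared  specific  0.4250  0.1675  5.362383e-20
phenodiv phenosim  0.4275  0.4225  9.429905e-01
```

i.e. phenodiv genes are significantly more connected than phenosim genes
(mean degree 11.3 vs 8.1, Mann-Whitney p ≈ 5×10⁻⁵), and shared genes carry
essential disease genes at 42.5% against 16.8% for specific genes (Fisher
p ≈ 5×10⁻²⁰) — the planted structure recovered end to end. The report
bundle also contains per-gene centrality and TCI tables, the
similarity-correlation table, disease-interactor fractions and the
permutation-enrichment results, all as TSV plus a `run_metadata.json`
recording seed, conventions and input checksums.

The same analyses are available from the shell:

```sh
pleionet simulate --seed 1 -o sim/
pleionet classify --assoc sim/assoc.tsv --sims sim/sims.tsv \
    --essential sim/essential.txt --cutoff median -o classes.tsv
pleionet centrality --edges sim/edges.tsv -o centrality.tsv
pleionet run --config analysis.yaml
```

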