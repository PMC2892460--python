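"""Synthetic dataset generator for the pleiotropy-network analysis.

Generates, from one seed, the full set of inputs the pipeline consumes —
gene-disease associations, an interactome edge list, phenotype-similarity
scores, an essential-gene list, a binary tissue-expression matrix and a flat
annotation table — together with the ground-truth gene classes, so every
stage of the analysis can be exercised and planted effects recovered.

Structure emulated:

- a heavy-tailed interactome (~10^3-10^4 nodes) built by a configuration
  model from lognormal degree draws whose class means are controlled by
  ``degree_multiplier`` (defaults follow the observed ordering of disease
  gene classes: phenodiv and essential genes most connected, specific and
  phenosim least, non-disease genes peripheral);
- each shared gene carries ``diseases_per_shared`` diseases whose pairwise
  similarity scores are drawn from two scaled Beta distributions straddling
  ``similarity_median``, so the median cutoff recovers the planted
  phenosim/phenodiv truth exactly;
- binary expression over ``n_tissues`` tissues, Bernoulli(breadth) per
  tissue, with an edge-wise coupling: with probability ``coexpression_coupling``
  one endpoint's expressed tissue set is resampled from its partner's,
  raising gene-interactor co-expression;
- annotation categories of random base frequency with a fold-enrichment
  planted in a chosen class.

The generator is fully seed-deterministic: the same config yields
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as pio

log = logging.getLogger("pleionet")

#: Lognormal dispersion of within-class degrees. Disease-gene degree
#: distributions are strongly overdispersed (SD roughly twice the mean),
#: which corresponds to sigma ~ 1.2 on the log scale.
DEGREE_SIGMA_LOG = 1.2


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_edges_target: int = 5000
    #: fraction of genes per planted class; the remainder is "unclassified"
    #: (interactome-only genes with no disease or essentiality annotation).
    class_fractions: dict = field(default_factory=lambda: {
        "specific": 0.25, "phenosim": 0.08, "phenodiv": 0.08,
        "essential_nondisease": 0.15,
    })
    #: planted per-class mean-degree ratios (observed ordering: essential >
    #: phenodiv > specific ~ phenosim > non-disease background).
    degree_multiplier: dict = field(default_factory=lambda: {
        "specific": 1.0, "phenosim": 1.0, "phenodiv": 1.5,
        "essential_nondisease": 1.6, "unclassified": 0.8,
    })
    degree_sigma_log: float = DEGREE_SIGMA_LOG
    n_tissues: int = 79
    #: probability a gene is expressed in any one tissue, per class
    #: ("default" is the fallback).
    expression_breadth: dict = field(default_factory=lambda: {"default": 0.65})
    coexpression_coupling: float = 0.3
    similarity_median: float = 0.33
    n_categories: int = 30
    #: (class label, category ids, fold) membership enrichment, or None.
    planted_enrichment: tuple | None = ("phenodiv", ("C01", "C02", "C03"), 3.0)
    diseases_per_shared: int = 3
    #: probability a disease gene of each class is essential (pleiotropic
    #: classes are enriched, as observed for essential disease genes).
    essential_fraction: dict = field(default_factory=lambda: {
        "specific": 0.17, "phenosim": 0.44, "phenodiv": 0.44,
    })
    annotation_prob_range: tuple = (0.02, 0.10)

    def validate(self) -> None:
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")
        for p in list(self.expression_breadth.values()) + [self.coexpression_coupling]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.diseases_per_shared < 2:
            raise ValueError("diseases_per_shared must be >= 2")
        if self.n_genes < 10 or self.n_edges_target < self.n_genes // 2:
            raise ValueError("degenerate problem size")


@dataclass
class SyntheticDataset:
    assoc: pio.DiseaseAssociationTable
    edges: pio.InteractionEdgeList
    sims: pio.SimilarityTable
    essential: pio.GeneSet
    expr: pio.ExpressionMatrix
    annot: pio.AnnotationTable
    truth: pd.DataFrame  # gene_id-indexed: true_class, is_essential, ...
    config: SimulationConfig


def _assign_classes(cfg: SimulationConfig) -> pd.Series:
    width = len(str(cfg.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    labels = []
    for label in sorted(cfg.class_fractions):
        labels += [label] * int(round(cfg.class_fractions[label] * cfg.n_genes))
    labels = labels[:cfg.n_genes]
    labels += ["unclassified"] * (cfg.n_genes - len(labels))
    return pd.Series(labels, index=genes, name="true_class")


def _degree_sequence(cfg: SimulationConfig, classes: pd.Series,
                     rng: np.random.Generator,
                     inflation: float = 1.0) -> np.ndarray:
    mult = np.array([cfg.degree_multiplier.get(c, 1.0) for c in classes])
    mean_overall = 2.0 * cfg.n_edges_target * inflation / cfg.n_genes
    class_mean = mean_overall * mult / float(np.mean(mult))
    sigma = cfg.degree_sigma_log
    mu = np.log(class_mean) - sigma**2 / 2.0
    deg = np.maximum(1, np.round(rng.lognormal(mu, sigma)).astype(int))
    deg = np.minimum(deg, cfg.n_genes - 1)
    if deg.sum() % 2:
        deg[int(rng.integers(len(deg)))] += 1
    return deg


def _build_interactome(cfg: SimulationConfig, classes: pd.Series,
                       rng: np.random.Generator, max_retries: int = 5) -> nx.Graph:
    genes = list(classes.index)
    inflation = 1.0
    for attempt in range(max_retries):
        deg = _degree_sequence(cfg, classes, rng, inflation=inflation)
        try:
            multi = nx.configuration_model(deg, seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            log.warning("infeasible degree sequence (attempt %d); resampling", attempt + 1)
            continue
        G = nx.Graph(multi)
        G.remove_edges_from(nx.selfloop_edges(G))
        G = nx.relabel_nodes(G, dict(enumerate(genes)))
        # keep every gene attached so all inputs share one gene universe
        isolated = [n for n in genes if G.degree(n) == 0]
        for n in isolated:
            partner = genes[int(rng.integers(len(genes)))]
            while partner == n:
                partner = genes[int(rng.integers(len(genes)))]
            G.add_edge(n, partner)
        loss = 1.0 - 2.0 * G.number_of_edges() / max(int(deg.sum()), 1)
        G.graph["degree_inflation_loss"] = loss
        # simplification collapses multi-edges from heavy-tailed hubs; redraw
        # with inflated stub counts until the realized edge count is close
        if G.number_of_edges() < 0.93 * cfg.n_edges_target and attempt < max_retries - 1:
            inflation *= cfg.n_edges_target / max(G.number_of_edges(), 1)
            continue
        log.info("simulate: %d nodes, %d edges (%.1f%% of stubs lost to "
                 "simplification), %d isolated nodes reattached",
                 G.number_of_nodes(), G.number_of_edges(), 100 * loss, len(isolated))
        return G
    raise RuntimeError("could not realize a degree sequence after retries")


def _make_diseases(cfg: SimulationConfig, classes: pd.Series,
                   rng: np.random.Generator):
    assoc_rows = []
    sim_records = []
    truth_min = {}
    m = cfg.similarity_median
    for gene, label in classes.items():
        if label == "specific":
            assoc_rows.append((gene, f"D.{gene}.1", ""))
        elif label in ("phenosim", "phenodiv"):
            diseases = [f"D.{gene}.{j}" for j in range(1, cfg.diseases_per_shared + 1)]
            assoc_rows += [(gene, d, "") for d in diseases]
            pairs = [(diseases[i], diseases[j])
                     for i in range(len(diseases)) for j in range(i + 1, len(diseases))]
            if label == "phenosim":
                scores = m + (1.0 - m) * rng.beta(2.0, 2.0, size=len(pairs))
            else:
                # one pair carries the minimum, planted strictly below the cutoff
                low = m * rng.beta(2.0, 2.0)
                rest = low + (1.0 - low) * rng.random(len(pairs) - 1)
                scores = np.concatenate([[low], rest])
                rng.shuffle(scores)
            for (a, b), s in zip(pairs, scores):
                sim_records.append((a, b, float(s)))
            truth_min[gene] = float(np.min(scores))
    assoc = pio.DiseaseAssociationTable(
        pd.DataFrame(assoc_rows, columns=["gene_id", "disease_id", "disease_name"]))
    return assoc, pio.SimilarityTable.from_records(sim_records), truth_min


def _make_essential(cfg: SimulationConfig, classes: pd.Series,
                    rng: np.random.Generator) -> set[str]:
    essential = set()
    for gene, label in classes.items():
        if label == "essential_nondisease":
            essential.add(gene)
        elif label in cfg.essential_fraction:
            if rng.random() < cfg.essential_fraction[label]:
                essential.add(gene)
    return essential


def _make_expression(cfg: SimulationConfig, classes: pd.Series, G: nx.Graph,
                     rng: np.random.Generator) -> pio.ExpressionMatrix:
    genes = list(classes.index)
    breadth = np.array([
        cfg.expression_breadth.get(c, cfg.expression_breadth.get("default", 0.65))
        for c in classes])
    idx = {g: i for i, g in enumerate(genes)}
    nbrs = [[] for _ in genes]
    for a, b in sorted((min(a, b), max(a, b)) for a, b in G.edges()):
        nbrs[idx[a]].append(idx[b])
        nbrs[idx[b]].append(idx[a])
    rho = cfg.coexpression_coupling
    T = cfg.n_tissues
    all_t = np.arange(T)
    B = np.zeros((cfg.n_genes, T), dtype=bool)
    assigned = np.zeros(cfg.n_genes, dtype=bool)
    # each gene's expressed set is drawn exactly once, in random order: with
    # probability rho it is resampled from an already-assigned interaction
    # partner's expressed tissues, otherwise independently (Bernoulli breadth)
    for gi in rng.permutation(cfg.n_genes):
        n_t = int(rng.binomial(T, breadth[gi]))
        prev = [j for j in nbrs[gi] if assigned[j]]
        row = np.zeros(T, dtype=bool)
        if prev and rng.random() < rho:
            src = all_t[B[prev[int(rng.integers(len(prev)))]]]
            take = min(n_t, len(src))
            if take:
                row[rng.choice(src, size=take, replace=False)] = True
            if n_t > take:
                comp = all_t[~row]
                row[rng.choice(comp, size=n_t - take, replace=False)] = True
        elif n_t:
            row[rng.choice(all_t, size=n_t, replace=False)] = True
        B[gi] = row
        assigned[gi] = True
    values = pd.DataFrame(B.astype(float), index=genes,
                          columns=[f"T{t+1:02d}" for t in range(cfg.n_tissues)])
    return pio.ExpressionMatrix(values, threshold=0.5, prebinarized=True)


def _make_annotations(cfg: SimulationConfig, classes: pd.Series,
                      rng: np.random.Generator) -> pio.AnnotationTable:
    cats = [f"C{j+1:02d}" for j in range(cfg.n_categories)]
    lo, hi = cfg.annotation_prob_range
    base = rng.uniform(lo, hi, size=cfg.n_categories)
    planted_label, planted_cats, fold = (None, (), 1.0)
    if cfg.planted_enrichment is not None:
        planted_label, planted_cats, fold = cfg.planted_enrichment
    rows = []
    for gene, label in classes.items():
        for j, cat in enumerate(cats):
            p = base[j]
            if label == planted_label and cat in planted_cats:
                p = min(1.0, p * fold)
            if rng.random() < p:
                rows.append((gene, cat))
    return pio.AnnotationTable(pd.DataFrame(rows, columns=["gene_id", "category_id"]))


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(config)
    G = _build_interactome(config, classes, rng)
    assoc, sims, truth_min = _make_diseases(config, classes, rng)
    essential = _make_essential(config, classes, rng)
    expr = _make_expression(config, classes, G, rng)
    annot = _make_annotations(config, classes, rng)
    truth = pd.DataFrame({
        "true_class": classes,
        "is_essential": classes.index.isin(sorted(essential)),
        "disease_count": [
            0 if c in ("essential_nondisease", "unclassified")
            else (1 if c == "specific" else config.diseases_per_shared)
            for c in classes],
        "min_similarity": [truth_min.get(g, np.nan) for g in classes.index],
    })
    truth.index.name = "gene_id"
    edge_rows = sorted((min(a, b), max(a, b)) for a, b in G.edges())
    return SyntheticDataset(
        assoc=assoc,
        edges=pio.InteractionEdgeList(edge_rows),
        sims=sims,
        essential=pio.GeneSet(essential, label="essential"),
        expr=expr,
        annot=annot,
        truth=truth,
        config=config,
    )


def simulate_null(config: SimulationConfig) -> SyntheticDataset:
    """Global-null variant: no planted degree, essentiality, expression or
    annotation differences between classes (coupling applied uniformly)."""
    flat_essential = float(np.mean(list(config.essential_fraction.values()))) \
        if config.essential_fraction else 0.25
    null_cfg = replace(
        config,
        degree_multiplier={k: 1.0 for k in
                           list(config.degree_multiplier) + ["unclassified"]},
        expression_breadth={"default":
                            config.expression_breadth.get("default", 0.65)},
        planted_enrichment=None,
        essential_fraction={k: flat_essential for k in config.essential_fraction},
    )
    return simulate(null_cfg)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the six standard inputs plus truth.tsv; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assoc": outdir / "assoc.tsv",
        "edges": outdir / "edges.tsv",
        "sims": outdir / "sims.tsv",
        "essential": outdir / "essential.txt",
        "expr": outdir / "expr.tsv",
        "annot": outdir / "annot.tsv",
        "truth": outdir / "truth.tsv",
    }
    pio.write_disease_associations(ds.assoc, paths["assoc"])
    pio.write_interactions(ds.edges, paths["edges"])
    pio.write_similarity_scores(ds.sims, paths["sims"])
    pio.write_gene_list(ds.essential, paths["essential"])
    pio.write_expression(ds.expr, paths["expr"])
    pio.write_annotations(ds.annot, paths["annot"])
    truth = ds.truth.copy()
    truth.insert(0, "gene_id", truth.index)
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
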