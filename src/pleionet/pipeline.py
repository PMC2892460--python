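"""End-to-end analysis: classify -> centralities -> group comparisons ->
tissue co-expression -> interactor fractions -> enrichment.

``run_all`` executes every stage in dependency order on the six standard
inputs and writes a tabular report bundle plus a ``run_metadata.json``
recording the seed, every convention decision, filter attrition counts and
input checksums. Re-running with the same inputs and config produces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .classify import classify_all
from .coexpression import gene_mean_tci, pair_tci
from .enrichment import empirical_enrichment
from .network import build_graph, compute_centralities, disease_interactor_fraction
from .stats import mann_whitney, spearman, summarize_by_class, fisher_exact
from .classify import essential_enrichment_table

log = logging.getLogger("pleionet")

CENTRALITY_METRICS = ["degree", "closeness", "betweenness", "eccentricity", "clustering"]
TABLE1_PAIRS = [("specific", "shared"), ("phenosim", "phenodiv")]
TABLE2_PAIRS = [("essential_nondisease", "specific"),
                ("essential_nondisease", "shared"),
                ("essential_nondisease", "phenosim"),
                ("essential_nondisease", "phenodiv")]
TABLE3_PAIRS = [("essential_nondisease", "specific"),
                ("essential_nondisease", "shared"),
                ("essential_nondisease", "phenosim"),
                ("essential_nondisease", "phenodiv"),
                ("specific", "shared"),
                ("phenosim", "phenodiv")]


@dataclass
class AnalysisConfig:
    assoc_path: str
    edges_path: str
    sims_path: str
    essential_path: str
    expr_path: str
    annot_path: str
    outdir: str
    cutoff: float | str = "median"
    expression_threshold: float = pio.DEFAULT_EXPRESSION_THRESHOLD
    n_reps: int = 10_000
    min_category_size: int = 5
    seed: int = 0
    tci_scale: float = 100.0  # report TCI on the 0-100 percentage scale
    p_estimator: str = "add_one"
    similarity_mode: str = "pairs"
    make_plots: bool = False

    def input_paths(self) -> dict[str, str]:
        return {"assoc": self.assoc_path, "edges": self.edges_path,
                "sims": self.sims_path, "essential": self.essential_path,
                "expr": self.expr_path, "annot": self.annot_path}


@dataclass
class ReportBundle:
    outdir: Path
    tables: dict[str, pd.DataFrame]
    metadata: dict
    files: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: AnalysisConfig) -> ReportBundle:
    """Run the full analysis; returns the report bundle (also written to disk)."""
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            raise pio.InputError(f"missing {name} input: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assoc = pio.read_disease_associations(config.assoc_path)
    edges = pio.read_interactions(config.edges_path)
    sims = pio.read_similarity_scores(config.sims_path)
    essential = pio.read_gene_list(config.essential_path, label="essential")
    expr = pio.read_expression(config.expr_path, threshold=config.expression_threshold)
    annot = pio.read_annotations(config.annot_path)

    G = build_graph(edges)
    classified = classify_all(assoc, sims, essential, cutoff=config.cutoff,
                              network_genes=set(G.nodes),
                              similarity_mode=config.similarity_mode)
    profile = compute_centralities(G)

    tables: dict[str, pd.DataFrame] = {}
    tables["classes"] = classified.to_frame()
    prof_out = profile.copy()
    prof_out.insert(0, "gene_id", prof_out.index)
    tables["centrality"] = prof_out.reset_index(drop=True)

    tables["table1_centrality"] = summarize_by_class(
        profile, classified, TABLE1_PAIRS, metrics=CENTRALITY_METRICS)
    tables["table2_essential"] = summarize_by_class(
        profile, classified, TABLE2_PAIRS, metrics=CENTRALITY_METRICS)

    # correlation of centrality with phenotype similarity over scored shared genes
    scored = classified.df["min_similarity"].notna()
    corr_genes = sorted(set(classified.df.index[scored]) & set(profile.index))
    corr_rows = []
    for metric in CENTRALITY_METRICS:
        sub = profile.loc[corr_genes, metric].dropna()
        if len(sub) >= 3:
            r = spearman(classified.df.loc[sub.index, "min_similarity"],
                         sub, metric=metric)
            corr_rows.append((metric, r.rho, r.n, r.p_value))
    tables["similarity_correlations"] = pd.DataFrame(
        corr_rows, columns=["metric", "rho", "n", "p_value"])

    # disease-gene interactors (per-gene fraction + class comparisons)
    disease_genes = pio.GeneSet(classified.genes_in_class("disease"), "disease")
    frac = disease_interactor_fraction(G, disease_genes, disease_genes)
    frac_df = pd.DataFrame({"gene_id": frac.index, "fraction_disease_interactors": frac.values})
    frac_df["gene_class"] = classified.df.loc[frac.index, "gene_class"].values
    tables["interactor_fractions"] = frac_df
    frac_profile = pd.DataFrame({"fraction_disease_interactors": frac})
    tables["interactor_fraction_comparisons"] = summarize_by_class(
        frac_profile, classified, TABLE1_PAIRS)

    # essentiality enrichment (Fisher)
    fisher_rows = []
    for a, b in (("shared", "specific"), ("phenodiv", "phenosim")):
        try:
            t = essential_enrichment_table(classified, a, b)
        except ValueError:
            log.warning("essentiality comparison %s vs %s skipped (empty class)", a, b)
            continue
        r = fisher_exact(t, metric="essential_fraction", class_a=a, class_b=b)
        fisher_rows.append((a, b, t[0][0], t[0][1], t[1][0], t[1][1],
                            r.mean_a, r.mean_b, r.statistic, r.p_value))
    tables["essential_fisher"] = pd.DataFrame(
        fisher_rows, columns=["class_a", "class_b", "ess_a", "noness_a", "ess_b",
                              "noness_b", "frac_a", "frac_b", "odds_ratio", "p_value"])

    # tissue co-expression
    all_genes = pio.GeneSet(set(classified.df.index), "all")
    tci = pair_tci(G, expr, all_genes, disease_genes=disease_genes)
    tci_out = tci.copy()
    tci_out["tci_pct"] = tci_out["tci"] * config.tci_scale
    tables["tci_pairs"] = tci_out
    mean_tci = gene_mean_tci(tci) * config.tci_scale
    tci_profile = pd.DataFrame({"mean_tci_pct": mean_tci})
    tables["table3_tci"] = summarize_by_class(tci_profile, classified, TABLE3_PAIRS)
    # pooled pair-level comparison, restricted to disease-gene interactors
    tci_dis = tci[tci["interactor_is_disease_gene"]]
    mean_tci_dis = gene_mean_tci(tci_dis) * config.tci_scale
    tables["table3_tci_disease_interactors"] = summarize_by_class(
        pd.DataFrame({"mean_tci_dis_pct": mean_tci_dis}), classified, TABLE3_PAIRS)

    # permutation enrichment for the essential and phenodiv gene sets
    for label, sub_seed in (("essential_disease", 0), ("phenodiv", 1)):
        genes = classified.genes_in_class(label) if label != "essential_disease" \
            else set(classified.df.index[classified.df["is_essential"]])
        name = "enrichment_essential" if label == "essential_disease" \
            else f"enrichment_{label}"
        if not genes:
            log.warning("enrichment for %s skipped (empty set)", label)
            tables[name] = pd.DataFrame()
            continue
        tables[name] = empirical_enrichment(
            pio.GeneSet(genes, label), annot, n_reps=config.n_reps,
            min_size=config.min_category_size, seed=config.seed + sub_seed,
            estimator=config.p_estimator)

    metadata = {
        "pleionet_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "resolved_cutoff": classified.resolved_cutoff,
        "n_unscored_shared": classified.n_unscored_shared,
        "class_counts": {k: int(v) for k, v in
                         sorted(classified.class_counts().items())},
        "graph": {"n_nodes": G.number_of_nodes(), "n_edges": G.number_of_edges(),
                  "n_components": G.graph["n_components"],
                  "n_self_loops_removed": G.graph["n_self_loops_removed"],
                  "n_duplicate_edges_removed": G.graph["n_duplicate_edges_removed"]},
        "conventions": {
            "betweenness": "Brandes, endpoints excluded, per-component "
                           "normalization (n-1)(n-2)/2",
            "closeness": "reciprocal mean hop distance within component",
            "clustering_low_degree": "undefined (NaN) for degree < 2, excluded",
            "phenosim_rule": "min similarity >= cutoff",
            "tci_scale": config.tci_scale,
            "p_estimator": config.p_estimator,
            "similarity_mode": config.similarity_mode,
        },
        "input_checksums": {k: _sha256(v) for k, v in
                            sorted(config.input_paths().items())},
    }

    files = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        _write(df, path)
        files[name] = path
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    files["run_metadata"] = meta_path

    if config.make_plots:
        plot_distributions(profile, classified, outdir)
    return ReportBundle(outdir=outdir, tables=tables, metadata=metadata, files=files)


def plot_distributions(profile: pd.DataFrame, classified, outdir: str | Path,
                       groupings: list[tuple[str, ...]] | None = None) -> list[Path]:
    """Histogram overlays of each centrality per gene-class grouping.

    Purely descriptive; one PNG per metric per grouping. Empty classes are
    omitted from the plot and noted in a captions file.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - plotting backend missing
        log.warning("plotting skipped: %s", exc)
        return []
    if groupings is None:
        groupings = [("specific", "shared", "essential_nondisease"),
                     ("phenosim", "phenodiv", "essential_nondisease")]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    captions = []
    metrics = ["degree", "closeness", "betweenness", "eccentricity"]
    for gi, grouping in enumerate(groupings, start=1):
        for metric in metrics:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            plotted = []
            for label in grouping:
                vals = profile.loc[
                    sorted(classified.genes_in_class(label) & set(profile.index)),
                    metric].dropna()
                if vals.empty:
                    captions.append(f"group{gi}_{metric}: class {label} empty, omitted")
                    continue
                ax.hist(vals, bins=30, density=True, histtype="step", label=label)
                plotted.append(label)
            ax.set_xlabel(metric)
            ax.set_ylabel("density")
            if plotted:
                ax.legend(fontsize=8)
            path = outdir / f"dist_group{gi}_{metric}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    (outdir / "plot_captions.txt").write_text("\n".join(captions) + "\n")
    return written
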