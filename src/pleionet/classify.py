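"""Disease-gene classification.

A gene associated with exactly one disease is *specific*; with two or more,
*shared* (pleiotropic). Shared genes whose associated diseases carry a
phenotype-similarity score for every unordered disease pair receive a
per-gene score equal to the minimum over those pairs, and are split at a
cutoff into *phenosim* (score >= cutoff: phenotypically similar diseases)
and *phenodiv* (score < cutoff: divergent diseases). Essentiality — being
the human ortholog of a knockout-lethal mouse gene — is an independent axis:
an essential gene that is also a disease gene is an *essential disease
gene*; otherwise it is an essential (non-disease) gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DiseaseAssociationTable, GeneSet, SimilarityTable

log = logging.getLogger("pleionet")

CLASS_LABELS = (
    "specific", "shared", "phenosim", "phenodiv",
    "essential_disease", "essential_nondisease", "unclassified",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class ClassifiedGenes:
    """Per-gene classification state, carried as a DataFrame.

    Columns: disease_count (int), gene_class (str), min_similarity (float,
    NaN when absent), is_essential (bool), is_disease_gene (bool).
    """

    df: pd.DataFrame
    resolved_cutoff: float | None = None
    n_unscored_shared: int = 0
    extra: dict = field(default_factory=dict)

    def genes_in_class(self, label: str) -> set[str]:
        """Genes of one class. ``shared`` covers every pleiotropic gene
        (>= 2 diseases) whether or not it was split into phenosim/phenodiv;
        ``disease`` covers all disease genes; the essential_* labels are the
        essentiality axis."""
        if label == "essential_disease":
            mask = self.df["is_essential"] & self.df["is_disease_gene"]
        elif label == "essential_nondisease":
            mask = self.df["is_essential"] & ~self.df["is_disease_gene"]
        elif label == "shared":
            mask = self.df["is_disease_gene"] & (self.df["disease_count"] >= 2)
        elif label == "disease":
            mask = self.df["is_disease_gene"]
        else:
            mask = self.df["gene_class"] == label
        return set(self.df.index[mask])

    def class_counts(self) -> pd.Series:
        return self.df["gene_class"].value_counts()

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def classify_by_disease_count(assoc: DiseaseAssociationTable) -> ClassifiedGenes:
    """Label every gene specific (1 disease) or shared (>=2 diseases)."""
    if assoc.df.empty:
        raise ConfigurationError("association table is empty")
    counts = assoc.df.groupby("gene_id")["disease_id"].nunique().sort_index()
    df = pd.DataFrame({
        "disease_count": counts,
        "gene_class": np.where(counts >= 2, "shared", "specific"),
        "min_similarity": np.nan,
        "is_essential": False,
        "is_disease_gene": True,
    })
    n_specific = int((df["gene_class"] == "specific").sum())
    log.info("classify_by_disease_count: %d specific, %d shared",
             n_specific, len(df) - n_specific)
    return ClassifiedGenes(df)


def assign_min_similarity(classified: ClassifiedGenes, assoc: DiseaseAssociationTable,
                          sims: SimilarityTable, mode: str = "pairs") -> ClassifiedGenes:
    """Record the lowest phenotype-similarity score for each shared gene.

    ``mode="pairs"`` (default): minimum over all unordered pairs of the
    gene's diseases — the natural reading for pairwise phenotype similarity.
    ``mode="per_disease"``: each disease is first summarized as the mean of
    its pairwise scores within the gene's disease set, then the minimum over
    diseases is taken (the alternative per-disease reading).

    A shared gene with any unscorable pair gets no score and is excluded
    from the phenosim/phenodiv split; the count of such genes is recorded.
    """
    if mode not in ("pairs", "per_disease"):
        raise ConfigurationError(f"unknown similarity mode {mode!r}")
    disease_sets = assoc.disease_sets()
    df = classified.df.copy()
    unscored = 0
    for gene in df.index[df["gene_class"].isin(("shared", "phenosim", "phenodiv"))]:
        diseases = sorted(disease_sets.get(gene, ()))
        pair_scores = {}
        ok = True
        for a, b in itertools.combinations(diseases, 2):
            s = sims.lookup(a, b)
            if s is None:
                ok = False
                break
            pair_scores[(a, b)] = s
        if not ok or not pair_scores:
            unscored += 1
            continue
        if mode == "pairs":
            df.loc[gene, "min_similarity"] = min(pair_scores.values())
        else:
            per_disease = {
                d: float(np.mean([s for (a, b), s in pair_scores.items() if d in (a, b)]))
                for d in diseases
            }
            df.loc[gene, "min_similarity"] = min(per_disease.values())
    if unscored:
        log.info("assign_min_similarity: %d shared genes lack a complete score set", unscored)
    return ClassifiedGenes(df, resolved_cutoff=classified.resolved_cutoff,
                           n_unscored_shared=unscored, extra=dict(classified.extra))


def split_phenosim_phenodiv(classified: ClassifiedGenes,
                            cutoff: float | str = "median") -> ClassifiedGenes:
    """Split scored shared genes at the cutoff: >= cutoff phenosim, < phenodiv.

    ``cutoff="median"`` resolves to the median of the per-gene minimum scores
    over the scored shared genes; a float fixes the cutoff for
    reproducibility across datasets.
    """
    df = classified.df.copy()
    shared_mask = df["gene_class"].isin(("shared", "phenosim", "phenodiv"))
    scored = shared_mask & df["min_similarity"].notna()
    if not scored.any():
        raise ConfigurationError("no scored shared genes: cannot split phenosim/phenodiv")
    if cutoff == "median":
        resolved = float(df.loc[scored, "min_similarity"].median())
    else:
        resolved = float(cutoff)
    df.loc[scored, "gene_class"] = np.where(
        df.loc[scored, "min_similarity"] >= resolved, "phenosim", "phenodiv")
    df.loc[shared_mask & ~scored, "gene_class"] = "shared"
    log.info("split_phenosim_phenodiv: cutoff %.4g -> %d phenosim, %d phenodiv",
             resolved, int((df["gene_class"] == "phenosim").sum()),
             int((df["gene_class"] == "phenodiv").sum()))
    return ClassifiedGenes(df, resolved_cutoff=resolved,
                           n_unscored_shared=classified.n_unscored_shared,
                           extra=dict(classified.extra))


def mark_essential(classified: ClassifiedGenes, essential: GeneSet,
                   network_genes: set[str] | None = None) -> ClassifiedGenes:
    """Flag essential genes; add essential non-disease genes as rows.

    Essential genes absent from the association table become
    ``essential_nondisease`` context rows (disease_count 0). When
    ``network_genes`` is given, interactome nodes absent from every other
    input are added as ``unclassified`` context rows.
    """
    df = classified.df.copy()
    df["is_essential"] = df.index.isin(essential.ids)
    new_rows = []
    for g in sorted(essential.ids - set(df.index)):
        new_rows.append((g, 0, "essential_nondisease", np.nan, True, False))
    if network_genes:
        known = set(df.index) | essential.ids
        for g in sorted(network_genes - known):
            new_rows.append((g, 0, "unclassified", np.nan, False, False))
    if new_rows:
        add = pd.DataFrame(new_rows, columns=["gene_id", "disease_count", "gene_class",
                                              "min_similarity", "is_essential",
                                              "is_disease_gene"]).set_index("gene_id")
        df = pd.concat([df, add])
    if len(essential) and not df["is_essential"].any():
        log.warning("mark_essential: essential set has zero overlap with all inputs")
    return ClassifiedGenes(df, resolved_cutoff=classified.resolved_cutoff,
                           n_unscored_shared=classified.n_unscored_shared,
                           extra=dict(classified.extra))


def essential_enrichment_table(classified: ClassifiedGenes, class_a: str,
                               class_b: str) -> list[list[int]]:
    """2x2 essentiality counts [[ess_a, noness_a], [ess_b, noness_b]]."""
    out = []
    for label in (class_a, class_b):
        genes = classified.genes_in_class(label)
        if not genes:
            raise ConfigurationError(f"class {label!r} is empty")
        ess = int(classified.df.loc[sorted(genes), "is_essential"].sum())
        out.append([ess, len(genes) - ess])
    return out


def classify_all(assoc: DiseaseAssociationTable, sims: SimilarityTable,
                 essential: GeneSet, cutoff: float | str = "median",
                 network_genes: set[str] | None = None,
                 similarity_mode: str = "pairs") -> ClassifiedGenes:
    """Full classification: count split, similarity, pheno split, essentiality."""
    c = classify_by_disease_count(assoc)
    c = assign_min_similarity(c, assoc, sims, mode=similarity_mode)
    if c.df["min_similarity"].notna().any():
        c = split_phenosim_phenodiv(c, cutoff=cutoff)
    c = mark_essential(c, essential, network_genes=network_genes)
    return c
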