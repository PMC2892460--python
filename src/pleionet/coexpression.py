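"""Tissue co-expression of genes with their interaction partners.

The Tissue Co-expression Index (TCI) of a gene-interactor pair is the
fraction of surveyed tissues in which both genes are detected as expressed.
A high TCI marks a pair active together across most tissues (intra-modular
behaviour); a hub with low TCI to its partners behaves as an inter-modular
connector. The index is symmetric in the pair and lies in [0, 1]; reports
also carry the conventional 0-100 percentage scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

log = logging.getLogger("pleionet")


def pair_tci(G: nx.Graph, expr: ExpressionMatrix, genes: GeneSet,
             restrict_to: GeneSet | None = None,
             disease_genes: GeneSet | None = None) -> pd.DataFrame:
    """One TCI record per (gene, interactor) edge with expression for both.

    ``restrict_to`` keeps only interactors in the given set (e.g. disease
    genes only); ``disease_genes`` fills the ``interactor_is_disease_gene``
    flag. Genes without an expression row are skipped and counted.
    """
    T = expr.n_tissues
    if T == 0:
        raise ValueError("expression matrix has zero tissues")
    expressed = expr.expressed
    have_expr = set(expressed.index)
    arr = expressed.to_numpy()
    row_of = {g: i for i, g in enumerate(expressed.index)}
    rows = []
    n_missing_gene = 0
    n_missing_interactor = 0
    for g in sorted(genes.ids):
        if g not in G or g not in have_expr:
            n_missing_gene += 1
            continue
        for nbr in sorted(G.neighbors(g)):
            if restrict_to is not None and nbr not in restrict_to:
                continue
            if nbr not in have_expr:
                n_missing_interactor += 1
                continue
            both = int(np.count_nonzero(arr[row_of[g]] & arr[row_of[nbr]]))
            rows.append((g, nbr, both / T, T,
                         disease_genes is not None and nbr in disease_genes))
    if n_missing_gene or n_missing_interactor:
        log.info("pair_tci: skipped %d genes and %d interactors without "
                 "expression/graph rows", n_missing_gene, n_missing_interactor)
    return pd.DataFrame(rows, columns=["gene_id", "interactor_id", "tci",
                                       "n_tissues", "interactor_is_disease_gene"])


def gene_mean_tci(records: pd.DataFrame) -> pd.Series:
    """Mean TCI over each gene's interactors (order-insensitive)."""
    if records.empty:
        return pd.Series(dtype=float)
    return records.groupby("gene_id")["tci"].mean().sort_index()


@dataclass
class LocalExpressionProfile:
    """Expression of a gene's interactors in one condition (e.g. a disease tissue)."""

    gene_id: str
    interactor_expressed: dict[str, bool]
    condition: str

    @property
    def n_interactors(self) -> int:
        return len(self.interactor_expressed)

    @property
    def n_expressed(self) -> int:
        return sum(self.interactor_expressed.values())

    @property
    def fraction_expressed(self) -> float:
        if not self.interactor_expressed:
            return 0.0
        return self.n_expressed / self.n_interactors


def interactor_expression_profile(G: nx.Graph, gene: str,
                                  condition_expr: ExpressionMatrix,
                                  rule: str = "half",
                                  condition: str = "") -> LocalExpressionProfile:
    """Which interactors of ``gene`` are expressed in a condition matrix.

    The condition matrix columns are samples (or replicate tissues) of one
    condition. ``rule``: "half" — expressed in >= half of the columns
    (default); "any" — in at least one; "all" — in every column.
    Interactors without an expression row count as not expressed.
    """
    if gene not in G:
        raise ValueError(f"gene {gene!r} absent from graph")
    if rule not in ("half", "any", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    expressed = condition_expr.expressed
    ncol = expressed.shape[1]
    flags = {}
    for nbr in sorted(G.neighbors(gene)):
        if nbr not in expressed.index:
            flags[nbr] = False
            continue
        n_on = int(expressed.loc[nbr].sum())
        if rule == "any":
            flags[nbr] = n_on >= 1
        elif rule == "all":
            flags[nbr] = n_on == ncol
        else:
            flags[nbr] = n_on * 2 >= ncol
    return LocalExpressionProfile(gene_id=gene, interactor_expressed=flags,
                                  condition=condition)
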