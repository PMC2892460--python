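"""Readers and writers for the pipeline's tabular inputs and outputs.

All tables are tab-delimited UTF-8 text; lines starting with ``#`` are
comments. Interaction files may also be SIF-like (``node relation node``).
Identifiers are opaque strings (Entrez-style); no identifier mapping is
performed — callers are responsible for using one namespace across inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("pleionet")

#: Default detection threshold for continuous expression values, following the
#: common microarray-atlas convention of a fixed average-difference cutoff.
DEFAULT_EXPRESSION_THRESHOLD = 200.0


class InputError(ValueError):
    """Missing file or structurally invalid input."""


class ParseError(ValueError):
    """A row that cannot be interpreted; message names the line number."""


def _read_lines(path: str | Path) -> list[tuple[int, str]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((i, line))
    return out


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DiseaseAssociationTable:
    """Gene-disease links; one row per (gene, disease) pair, deduplicated."""

    df: pd.DataFrame  # columns: gene_id, disease_id, disease_name (may be "")
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if "disease_name" not in self.df.columns:
            self.df = self.df.assign(disease_name="")
        bad = (self.df["gene_id"] == "") | (self.df["disease_id"] == "")
        if bad.any():
            raise InputError("empty gene_id or disease_id in association table")

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene_id"])

    @property
    def diseases(self) -> set[str]:
        return set(self.df["disease_id"])

    def disease_sets(self) -> dict[str, set[str]]:
        """Map gene -> set of associated disease ids."""
        return {g: set(sub) for g, sub in self.df.groupby("gene_id")["disease_id"]}


@dataclass
class InteractionEdgeList:
    """Raw undirected interaction pairs; graph-level cleaning happens later."""

    edges: list[tuple[str, str]]
    n_dropped: int = 0


@dataclass
class ExpressionMatrix:
    """Gene-by-tissue expression with a recorded binarization threshold.

    ``expressed`` is derived deterministically: value >= threshold. A matrix
    containing only 0/1 is treated as pre-binarized (expressed = value > 0).
    """

    values: pd.DataFrame  # genes x tissues, numeric
    threshold: float
    prebinarized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InputError("duplicate gene identifiers in expression matrix")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate tissue identifiers in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    @property
    def expressed(self) -> pd.DataFrame:
        if self.prebinarized:
            return self.values > 0
        return self.values >= self.threshold


@dataclass
class SimilarityTable:
    """Symmetric phenotype-similarity scores between disease pairs."""

    scores: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[tuple[str, str, float]]) -> "SimilarityTable":
        scores: dict[frozenset, float] = {}
        for a, b, s in records:
            if not np.isfinite(s):
                raise InputError(f"non-finite similarity score for ({a}, {b})")
            scores[frozenset((a, b))] = float(s)
        return cls(scores)

    def lookup(self, a: str, b: str) -> float | None:
        return self.scores.get(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self.scores)

    def records(self) -> list[tuple[str, str, float]]:
        out = []
        for key, s in self.scores.items():
            pair = sorted(key)
            if len(pair) == 1:  # self-pair
                pair = [pair[0], pair[0]]
            out.append((pair[0], pair[1], s))
        return sorted(out)


@dataclass
class AnnotationTable:
    """Flat gene -> category membership (assumed pre-propagated to ancestors)."""

    df: pd.DataFrame  # columns: gene_id, category_id

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene_id"])

    @property
    def categories(self) -> set[str]:
        return set(self.df["category_id"])

    def category_sizes(self) -> pd.Series:
        return self.df.groupby("category_id")["gene_id"].nunique()

    def members(self) -> dict[str, set[str]]:
        return {c: set(sub) for c, sub in self.df.groupby("category_id")["gene_id"]}


@dataclass
class GeneSet:
    ids: set[str]
    label: str = ""

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, g: str) -> bool:
        return g in self.ids


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_disease_associations(path: str | Path, header: bool | None = None) -> DiseaseAssociationTable:
    """Read a MorbidMap-style gene-disease TSV (gene_id, disease_id[, name]).

    ``header=None`` auto-detects a header row named ``gene_id``; ``True`` /
    ``False`` force the decision. Duplicate (gene, disease) rows are dropped
    and counted.
    """
    lines = _read_lines(path)
    records = []
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
        records.append((lineno, parts[0].strip(), parts[1].strip(),
                        parts[2].strip() if len(parts) > 2 else ""))
    if records and (header is True or (header is None and records[0][1].lower() == "gene_id")):
        records = records[1:]
    for lineno, g, d, _ in records:
        if not g or not d:
            raise ParseError(f"{path}: line {lineno}: empty identifier")
    df = pd.DataFrame(
        [(g, d, name) for _, g, d, name in records],
        columns=["gene_id", "disease_id", "disease_name"],
    )
    n0 = len(df)
    df = df.drop_duplicates(subset=["gene_id", "disease_id"], keep="first").reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        log.info("read_disease_associations: dropped %d duplicate rows", dropped)
    return DiseaseAssociationTable(df, n_duplicates_dropped=dropped)


def read_interactions(path: str | Path) -> InteractionEdgeList:
    """Read a 2-column TSV or SIF-like (``A relation B``) interaction file.

    SIF rows may be tab- or space-delimited; the relation token is ignored.
    Rows with an empty endpoint are dropped with a warning.
    """
    lines = _read_lines(path)
    edges: list[tuple[str, str]] = []
    dropped = 0
    for lineno, line in lines:
        parts = line.split("\t") if "\t" in line else line.split()
        parts = [p.strip() for p in parts]
        if len(parts) == 2:
            a, b = parts
        elif len(parts) == 3:
            a, b = parts[0], parts[2]  # SIF: node relation node
        else:
            raise ParseError(f"{path}: line {lineno}: expected 2 or 3 fields, got {len(parts)}")
        if lineno == lines[0][0] and a.lower() in ("gene_a", "source", "node_a"):
            continue
        if not a or not b:
            log.warning("read_interactions: line %d has an empty identifier; dropped", lineno)
            dropped += 1
            continue
        edges.append((a, b))
    return InteractionEdgeList(edges, n_dropped=dropped)


def read_expression(path: str | Path, threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
                    header: bool | None = None) -> ExpressionMatrix:
    """Read a gene-by-tissue matrix TSV; first column is the gene id.

    A leading row whose second field is non-numeric is treated as a header
    (override with ``header``). A matrix containing only 0/1 values is taken
    as pre-binarized presence/absence and the threshold is not applied.
    """
    lines = _read_lines(path)
    if not lines:
        raise InputError(f"empty expression matrix: {path}")
    rows = [(lineno, line.split("\t")) for lineno, line in lines]
    ncol = len(rows[0][1])
    if ncol < 2:
        raise ParseError(f"{path}: line {rows[0][0]}: expression matrix needs >=2 columns")
    has_header = header if header is not None else not _is_number(rows[0][1][1])
    if has_header:
        tissue_ids = [c.strip() for c in rows[0][1][1:]]
        rows = rows[1:]
    else:
        tissue_ids = [f"T{i+1}" for i in range(ncol - 1)]
    genes, data = [], []
    for lineno, parts in rows:
        if len(parts) != ncol:
            raise ParseError(f"{path}: line {lineno}: ragged row ({len(parts)} fields, expected {ncol})")
        genes.append(parts[0].strip())
        try:
            data.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from exc
    values = pd.DataFrame(data, index=genes, columns=tissue_ids)
    arr = values.to_numpy()
    prebinarized = bool(np.isin(arr, (0.0, 1.0)).all())
    return ExpressionMatrix(values, threshold=threshold, prebinarized=prebinarized)


def read_similarity_scores(path: str | Path) -> SimilarityTable:
    """Read a 3-column TSV of (disease_a, disease_b, score); symmetric lookup."""
    lines = _read_lines(path)
    records = []
    for lineno, line in lines:
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        if lineno == lines[0][0] and not _is_number(parts[2]):
            continue  # header
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric score {parts[2]!r}") from exc
        records.append((parts[0], parts[1], score))
    return SimilarityTable.from_records(records)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a flat 2-column gene -> category table; duplicates collapsed."""
    lines = _read_lines(path)
    records = []
    for lineno, line in lines:
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        if lineno == lines[0][0] and parts[0].lower() == "gene_id":
            continue
        records.append((parts[0], parts[1]))
    df = pd.DataFrame(records, columns=["gene_id", "category_id"]).drop_duplicates().reset_index(drop=True)
    return AnnotationTable(df)


def read_gene_list(path: str | Path, label: str = "") -> GeneSet:
    """Read a 1-column gene list into a set; ids are whitespace-trimmed."""
    lines = _read_lines(path)
    ids = {line.split("\t")[0].strip() for _, line in lines}
    ids.discard("")
    if not ids:
        log.warning("read_gene_list: %s is empty", path)
    return GeneSet(ids=ids, label=label)


# ---------------------------------------------------------------------------
# Writers (all TSV with header, deterministic row order)
# ---------------------------------------------------------------------------

def write_disease_associations(table: DiseaseAssociationTable, path: str | Path) -> None:
    df = table.df.sort_values(["gene_id", "disease_id"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def write_interactions(edges: InteractionEdgeList, path: str | Path) -> None:
    df = pd.DataFrame(edges.edges, columns=["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_similarity_scores(table: SimilarityTable, path: str | Path) -> None:
    df = pd.DataFrame(table.records(), columns=["disease_a", "disease_b", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    df = table.df.sort_values(["gene_id", "category_id"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes.ids):
            fh.write(g + "\n")


def universe_overlap_report(*gene_sets: tuple[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap counts between named gene universes across inputs."""
    rows = []
    for i, (name_a, a) in enumerate(gene_sets):
        for name_b, b in gene_sets[i + 1:]:
            rows.append((name_a, name_b, len(a), len(b), len(a & b)))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b", "n_overlap"])
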