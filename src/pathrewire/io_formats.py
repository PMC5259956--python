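"""Readers and writers for the pipeline's external file formats.

All tabular files are plain TSV (UTF-8, "." decimal separator); gene sets use
the standard GMT dialect. Gene identifiers are opaque, case-sensitive
strings — no symbol normalization is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum samples per phenotype for a Pearson correlation to be meaningful.
MIN_SAMPLES_PER_GROUP = 3

_PPI_HEADER_TOKENS = {
    "gene1",
    "gene2",
    "gene_a",
    "gene_b",
    "genea",
    "geneb",
    "protein1",
    "protein2",
    "source",
    "target",
    "node1",
    "node2",
    "from",
    "to",
    "symbol_a",
    "symbol_b",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a two-group phenotype labelling.

    Parameters
    ----------
    genes
        Ordered unique gene identifiers (matrix rows).
    samples
        Ordered unique sample identifiers (matrix columns).
    values
        ``(len(genes), len(samples))`` float array, expression units as given.
        Missing values are NaN.
    labels
        Mapping from sample identifier to phenotype label; exactly two
        distinct labels must be present, each with at least three samples.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.samples = tuple(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing[:5]}")
        self._validate_groups()
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def _validate_groups(self) -> None:
        groups = self.phenotypes
        if len(groups) != 2:
            raise ValueError(
                f"two phenotypes required, found {len(groups)}: {sorted(groups)}"
            )
        for g in groups:
            n = len(self.samples_for(g))
            if n < MIN_SAMPLES_PER_GROUP:
                raise ValueError(
                    f"phenotype {g!r} has {n} samples; at least "
                    f"{MIN_SAMPLES_PER_GROUP} are required"
                )

    @property
    def phenotypes(self) -> tuple[str, ...]:
        """The two phenotype labels, sorted."""
        return tuple(sorted({self.labels[s] for s in self.samples}))

    def samples_for(self, phenotype: str) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.labels[s] == phenotype)

    def matrix_for(self, phenotype: str) -> np.ndarray:
        """Sub-matrix (all genes x samples of one phenotype)."""
        cols = [i for i, s in enumerate(self.samples) if self.labels[s] == phenotype]
        if not cols:
            raise KeyError(f"phenotype {phenotype!r} not present")
        return self.values[:, cols]

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index


@dataclass(frozen=True)
class PpiEdgeList:
    """Undirected protein-protein interaction edge list over gene symbols.

    Edges are canonical ``(a, b)`` tuples with ``a < b``; no self-loops, no
    duplicates.
    """

    edges: frozenset[tuple[str, str]]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PpiEdgeList":
        edges = set()
        n_self = n_dup = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            e = cls.canonical(a, b)
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self or n_dup:
            logger.info(
                "PPI cleanup: dropped %d self-loops, %d duplicate pairs", n_self, n_dup
            )
        return cls(edges=frozenset(edges))


@dataclass
class GeneSetCollection:
    """Ordered collection of (pathway_id, name, genes) entries from a GMT."""

    entries: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, pathway_id: str) -> tuple[str, str, tuple[str, ...]]:
        for e in self.entries:
            if e[0] == pathway_id:
                return e
        raise KeyError(pathway_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)


def read_expression(matrix_path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Load a gene x sample TSV matrix plus a two-column sample-label TSV.

    The matrix has a header row of sample IDs and gene IDs in the first
    column; the labels file has columns ``sample_id`` and ``phenotype``.
    Duplicate gene rows are collapsed by mean; samples absent from the labels
    file are dropped. Both events are logged as warnings.
    """
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression matrix {matrix_path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from exc

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicated gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()

    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d all-missing gene rows", int(all_missing.sum()))
        df = df.loc[~all_missing]

    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sample_id", "phenotype"}
    if not required.issubset(lab.columns):
        raise FormatError(
            f"labels file must have columns {sorted(required)}, got {list(lab.columns)}"
        )
    labels = dict(zip(lab["sample_id"], lab["phenotype"]))

    unlabeled = [s for s in df.columns if s not in labels]
    if unlabeled:
        logger.warning("dropping %d samples absent from labels file", len(unlabeled))
        df = df.drop(columns=unlabeled)
    if df.shape[1] == 0:
        raise FormatError("no labelled samples remain")

    labels = {s: labels[s] for s in df.columns}
    return ExpressionDataset(
        genes=tuple(df.index),
        samples=tuple(df.columns),
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def read_ppi(path: str | Path) -> PpiEdgeList:
    """Read an undirected PPI edge list (first two TSV columns = gene symbols).

    A single header line with recognizable column names (``gene1``,
    ``source`` ...) is skipped automatically. Self-loops and duplicate pairs
    (in either orientation) are dropped with counts logged.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 2 tab-separated columns"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a.lower() in _PPI_HEADER_TOKENS and b.lower() in _PPI_HEADER_TOKENS:
                continue
            if not a or not b:
                raise FormatError(f"{path}: line {lineno}: empty gene symbol")
            pairs.append((a, b))
    if not pairs:
        raise FormatError(f"{path}: no edges found")
    return PpiEdgeList.from_pairs(pairs)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in the standard GMT dialect.

    Each line is ``set_id <TAB> description <TAB> gene1 <TAB> gene2 ...``.
    Gene lists are deduplicated preserving order; a line with fewer than
    three fields is rejected with its line number.
    """
    entries: list[tuple[str, str, tuple[str, ...]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (id, description, genes...), got {len(fields)}"
                )
            set_id, description = fields[0].strip(), fields[1].strip()
            genes = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene list")
            entries.append((set_id, description, tuple(genes)))
    if not entries:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(entries=entries)


RESULT_COLUMNS = (
    "rank",
    "pathway_id",
    "name",
    "score",
    "abs_corr",
    "n_seed_genes",
    "n_expanded_genes_A",
    "n_expanded_genes_B",
    "n_union_edges",
    "theta_A",
    "theta_B",
    "status",
)


def _fmt(value, decimals: int = 6) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def write_results(records: Sequence, path: str | Path) -> None:
    """Write ranked pathway score records as TSV.

    Records must already carry ranks (scored ones) and statuses; skipped
    pathways appear with an empty score field and their skip status. Scores
    are written to six decimals.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in records:
            row = [
                _fmt(r.rank),
                r.pathway_id,
                r.name,
                _fmt(r.score),
                _fmt(r.abs_corr),
                _fmt(r.n_seed_genes),
                _fmt(r.n_expanded_A),
                _fmt(r.n_expanded_B),
                _fmt(r.n_union_edges),
                _fmt(r.theta_A),
                _fmt(r.theta_B),
                r.status,
            ]
            fh.write("\t".join(row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Parse a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"pathway_id": str, "name": str, "status": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results file missing columns: {sorted(missing)}")
    return df
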