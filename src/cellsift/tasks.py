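"""Enrichment tables and the six binary cell-type classification tasks.

A gene-enrichment table lists, for each gene, the cell type(s) it is enriched
in (astrocyte, neuron, oligodendrocyte) with a fold-enrichment value; genes
in none of the lists form the negative set. At a fold threshold t a gene is
"enriched in T" iff it has a record (gene, T, fold) with fold > t (strict).
Six tasks are built from these sets: each cell type against the negative set,
and each pair of cell types against one another. Canonical thresholds are
1.5 (the reported lists), 10 and 20 (increasingly strict specificity).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError

logger = logging.getLogger(__name__)

CELL_TYPES = ("astrocyte", "neuron", "oligodendrocyte")

_LETTER = {"A": "astrocyte", "N": "neuron", "O": "oligodendrocyte", "Neg": None}

TASK_NAMES = ("A-vs-Neg", "N-vs-Neg", "O-vs-Neg", "O-vs-A", "A-vs-N", "N-vs-O")


def parse_task(name: str) -> tuple[str, str | None]:
    """Task name -> (positive cell type, negative cell type or None=negative set)."""
    if name not in TASK_NAMES:
        raise ConfigurationError(f"unknown task {name!r}; expected one of {TASK_NAMES}")
    pos, neg = name.split("-vs-")
    return _LETTER[pos], _LETTER[neg]


# ---------------------------------------------------------------------------
# enrichment table
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """Validated (gene_id, cell_type, fold_enrichment) records.

    Records are kept sorted by fold descending within each cell type,
    mirroring enrichment lists ranked by fold. A gene may appear under more
    than one cell type.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "cell_type", "fold_enrichment"]
        if list(self.df.columns[:3]) != required:
            raise ValidationError(f"enrichment table must have columns {required}")
        bad_types = set(self.df["cell_type"]) - set(CELL_TYPES)
        if bad_types:
            raise ValidationError(f"unknown cell types: {sorted(bad_types)}")
        folds = self.df["fold_enrichment"].to_numpy(dtype=float)
        if not np.all(np.isfinite(folds)) or np.any(folds <= 0):
            raise ValidationError("fold_enrichment values must be positive and finite")
        dup = self.df.duplicated(subset=["gene_id", "cell_type"])
        if dup.any():
            pairs = self.df.loc[dup, ["gene_id", "cell_type"]].values.tolist()
            raise ValidationError(f"duplicate (gene_id, cell_type) records: {pairs}")
        self.df = (
            self.df.assign(cell_type=pd.Categorical(self.df["cell_type"], CELL_TYPES))
            .sort_values(["cell_type", "fold_enrichment"],
                         ascending=[True, False], kind="stable")
            .assign(cell_type=lambda d: d["cell_type"].astype(str))
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records: list[tuple[str, str, float]]) -> "EnrichmentTable":
        return cls(pd.DataFrame(records, columns=["gene_id", "cell_type", "fold_enrichment"]))

    def __len__(self) -> int:
        return len(self.df)

    def genes_enriched_in(self, cell_type: str, threshold: float) -> set[str]:
        """Genes with a record (gene, cell_type, fold) with fold > threshold."""
        if cell_type not in CELL_TYPES:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        sel = (self.df["cell_type"] == cell_type) & (self.df["fold_enrichment"] > threshold)
        return set(self.df.loc[sel, "gene_id"])

    def enriched_genes(self) -> set[str]:
        """Genes with any enrichment record at all."""
        return set(self.df["gene_id"])

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_enrichment_table(path: str | Path) -> EnrichmentTable:
    """Read and validate a gene_id,cell_type,fold_enrichment CSV."""
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["gene_id", "cell_type", "fold_enrichment"]:
            raise ValidationError(
                f"{path}: expected header gene_id,cell_type,fold_enrichment, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValidationError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            gene, cell_type, fold_str = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                fold = float(fold_str)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: fold_enrichment {fold_str!r} is not a number"
                ) from None
            rows.append((gene, cell_type, fold))
    return EnrichmentTable.from_records(rows)


# ---------------------------------------------------------------------------
# task construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    """One of the six binary tasks at a given fold threshold."""

    task: str
    fold_threshold: float = 1.5

    def __post_init__(self) -> None:
        parse_task(self.task)
        if not self.fold_threshold > 0:
            raise ConfigurationError("fold_threshold must be > 0")


@dataclass
class LabeledDataset:
    """Feature rows with +/-1 labels for one task."""

    X: np.ndarray
    y: np.ndarray
    gene_ids: np.ndarray
    image_ids: np.ndarray
    task: TaskSpec

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.gene_ids = np.asarray(self.gene_ids)
        self.image_ids = np.asarray(self.image_ids)
        if len(self.y) != len(self.X):
            raise ValidationError("X and y lengths differ")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValidationError("labels must be in {-1, +1}")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.gene_ids[idx],
                              self.image_ids[idx], self.task)

    def genes_by_label(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lbl in (-1, 1):
            genes = pd.unique(self.gene_ids[self.y == lbl])
            out[lbl] = list(genes)
        return out


def task_gene_sets(table: EnrichmentTable, spec: TaskSpec,
                   universe: set[str]) -> tuple[set[str], set[str]]:
    """Positive and negative gene sets for a task over a gene universe.

    For X-vs-Neg the negatives are genes of the universe with no enrichment
    record of any type. For X-vs-Y, genes qualifying for both sides are
    excluded (and logged).
    """
    pos_type, neg_type = parse_task(spec.task)
    positives = table.genes_enriched_in(pos_type, spec.fold_threshold) & universe
    if neg_type is None:
        negatives = universe - table.enriched_genes()
    else:
        negatives = table.genes_enriched_in(neg_type, spec.fold_threshold) & universe
        both = positives & negatives
        if both:
            logger.info("excluding %d genes enriched in both %s and %s: %s",
                        len(both), pos_type, neg_type, sorted(both))
            positives -= both
            negatives -= both
    if not positives:
        raise DataError(f"task {spec.task} at threshold {spec.fold_threshold}: "
                        "empty positive set")
    if not negatives:
        raise DataError(f"task {spec.task} at threshold {spec.fold_threshold}: "
                        "empty negative set")
    return positives, negatives


def build_task(table: EnrichmentTable, spec: TaskSpec,
               features: pd.DataFrame) -> LabeledDataset:
    """Assemble the labeled dataset for a task from a feature table.

    ``features`` must have a ``gene_id`` column, optionally ``image_id`` and
    ``section``, and feature columns named ``f0..f{p-1}``. Every feature row
    of a gene inherits the gene's label.
    """
    if "gene_id" not in features.columns:
        raise ValidationError("feature table must have a gene_id column")
    universe = set(features["gene_id"])
    positives, negatives = task_gene_sets(table, spec, universe)
    fcols = [c for c in features.columns if c.startswith("f") and c[1:].isdigit()]
    if not fcols:
        raise ValidationError("feature table has no f0..f{p-1} columns")
    fcols = sorted(fcols, key=lambda c: int(c[1:]))
    sel = features["gene_id"].isin(positives | negatives)
    sub = features.loc[sel]
    y = np.where(sub["gene_id"].isin(positives), 1, -1)
    image_ids = (sub["image_id"].to_numpy() if "image_id" in sub.columns
                 else np.array([""] * len(sub)))
    return LabeledDataset(
        sub[fcols].to_numpy(dtype=np.float64), y,
        sub["gene_id"].to_numpy(), image_ids, spec,
    )


def split_dataset(
    dataset: LabeledDataset,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    group_by_gene: bool = True,
    stratify: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random train/test partition, deterministic given the seed.

    With ``group_by_gene`` all rows of one gene land on the same side (no
    leakage between a gene's image series); with ``stratify`` the class
    proportions are approximately preserved.
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    units: list[tuple] = []   # (label, unit_key, row_indices)
    if group_by_gene:
        for lbl, genes in dataset.genes_by_label().items():
            if len(genes) < 2:
                raise DataError(
                    f"class {lbl} has a single gene; cannot split with grouping"
                )
            for g in genes:
                rows = np.flatnonzero(dataset.gene_ids == g)
                units.append((lbl, g, rows))
    else:
        for i in range(len(dataset)):
            units.append((int(dataset.y[i]), i, np.array([i])))

    train_rows, test_rows = [], []
    if stratify:
        groups: dict[int, list[tuple]] = {-1: [], 1: []}
        for u in units:
            groups[u[0]].append(u)
        for lbl, members in groups.items():
            order = rng.permutation(len(members))
            n_train = int(np.floor(train_fraction * len(members) + 0.5))
            n_train = min(max(n_train, 1), len(members) - 1)
            for rank, j in enumerate(order):
                (train_rows if rank < n_train else test_rows).append(members[j][2])
    else:
        order = rng.permutation(len(units))
        n_train = int(np.floor(train_fraction * len(units)))
        n_train = min(max(n_train, 1), len(units) - 1)
        for rank, j in enumerate(order):
            (train_rows if rank < n_train else test_rows).append(units[j][2])

    tr = np.sort(np.concatenate(train_rows))
    te = np.sort(np.concatenate(test_rows))
    return dataset.subset(tr), dataset.subset(te)
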