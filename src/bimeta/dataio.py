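"""Readers, writers and preprocessing for the tabular formats the pipeline touches.

Expression matrices are genes x samples TSV (first column = gene id, header row =
sample ids). Clinical tables are sample-per-row TSV with ``sample_id``, ``time``,
``event`` plus free covariate columns. Mutation tables are MAF-like TSV; common
column-name dialects (``Hugo_Symbol``, ``Tumor_Sample_Barcode``, ...) are accepted.
Gene sets use the GMT format.

Preprocessing follows the usual bulk-expression conventions: log2(x+1) and/or
quantile normalization (every sample forced onto the mean quantile profile, tied
ranks receiving the mean of the tied quantile means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

#: Column-name synonyms accepted in MAF-like mutation tables, in lookup order.
MUTATION_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "Tumor_Sample_Barcode", "sample", "DepMap_ID"),
    "gene": ("gene", "Hugo_Symbol", "gene_symbol"),
    "variant_classification": (
        "variant_classification",
        "Variant_Classification",
        "variant_class",
    ),
}

#: Variant classes the study removes before any mutation-based analysis.
DEFAULT_EXCLUDED_CLASSES: frozenset[str] = frozenset({"Silent", "Intron", "IGR"})


@dataclass
class ExpressionDataset:
    """One cohort's genes x samples abundance matrix with preprocessing provenance."""

    cohort_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r} in cohort {self.cohort_id!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r} in cohort {self.cohort_id!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in cohort {self.cohort_id!r}") from None
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome (time, event) plus free covariates."""

    cohort_id: str
    data: pd.DataFrame  # indexed by sample_id; columns: time, event, covariates

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in clinical table")
        if (df["time"] < 0).any():
            bad = df.index[df["time"] < 0][0]
            raise DomainError(f"negative survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise FormatError(f"event must be 0/1; offending sample {bad!r}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class MutationTable:
    """Long-format (sample_id, gene, variant_classification) records."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "gene", "variant_classification")
                   if c not in self.data.columns]
        if missing:
            raise FormatError(f"mutation table missing column(s) {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def mutated_samples(self, gene: str) -> set[str]:
        """Samples carrying any retained mutation in *gene*."""
        sel = self.data["gene"] == gene
        return set(self.data.loc[sel, "sample_id"])

    def filter_classes(self, excluded_classes) -> "MutationTable":
        """Drop records whose variant class is excluded; monotone in the set."""
        excluded = set(excluded_classes)
        keep = ~self.data["variant_classification"].isin(excluded)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d mutation records in classes %s", n_dropped, sorted(excluded))
        return MutationTable(self.data[keep].reset_index(drop=True))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique set names, each set non-empty."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _first_duplicate(ids) -> str:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


# ---------------------------------------------------------------------------
# expression


def read_expression(path, cohort_id: str | None = None) -> ExpressionDataset:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header row has no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: repeated gene id {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: non-numeric or missing cell at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    return ExpressionDataset(
        cohort_id=cohort_id or str(path),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(ds: ExpressionDataset, path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def log2_transform(values: np.ndarray) -> np.ndarray:
    if np.any(values < 0):
        raise DomainError("log2(x+1) requested but matrix contains negative values")
    return np.log2(values + 1.0)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the mean quantile profile.

    Tied values within a column receive the mean of the quantile means of the
    tied positions, so the operation is idempotent and permutation-equivariant.
    """
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    mean_profile = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_rows)
        assigned[order] = mean_profile
        # average over runs of tied input values
        sorted_col = col[order]
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                assigned[order[i:k + 1]] = mean_profile[i:k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return out


def preprocess_expression(
    ds: ExpressionDataset, log2: bool = False, quantile: bool = False
) -> ExpressionDataset:
    """Apply log2(x+1) and/or quantile normalization, recording provenance."""
    values = ds.values
    if log2:
        values = log2_transform(values)
    if quantile:
        values = quantile_normalize(values)
    provenance = dict(ds.preprocessing)
    provenance["log2"] = bool(provenance.get("log2", False) or log2)
    provenance["quantile_normalized"] = bool(
        provenance.get("quantile_normalized", False) or quantile
    )
    return ExpressionDataset(
        cohort_id=ds.cohort_id,
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        values=values,
        preprocessing=provenance,
    )


# ---------------------------------------------------------------------------
# clinical


def read_clinical(path, cohort_id: str | None = None) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical table missing 'sample_id' column")
    df = df.set_index("sample_id")
    return ClinicalTable(cohort_id=cohort_id or str(path), data=df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# mutations


def read_mutations(
    path,
    excluded_classes=DEFAULT_EXCLUDED_CLASSES,
    column_map: dict[str, str] | None = None,
) -> MutationTable:
    """Read a MAF-like TSV and drop records in *excluded_classes*.

    ``column_map`` may override the canonical-name lookup (maps canonical name ->
    the column name used in the file). Any variant-classification string is
    accepted; the vocabulary is not validated against a fixed MAF enum.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename: dict[str, str] = {}
    for canonical, synonyms in MUTATION_COLUMN_SYNONYMS.items():
        source = None
        if column_map and canonical in column_map:
            source = column_map[canonical]
            if source not in df.columns:
                raise FormatError(f"{path}: mapped column {source!r} not present")
        else:
            source = next((s for s in synonyms if s in df.columns), None)
        if source is None:
            raise FormatError(f"{path}: no column found for {canonical!r}")
        rename[source] = canonical
    df = df.rename(columns=rename)[list(MUTATION_COLUMN_SYNONYMS)]
    table = MutationTable(df.reset_index(drop=True))
    return table.filter_classes(excluded_classes)


def write_mutations(table: MutationTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: each line = name, description, member genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen: set[str] = set()
            unique = [m for m in members if m and not (m in seen or seen.add(m))]
            if not unique:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
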