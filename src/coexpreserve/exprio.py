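"""Expression I/O, normalization and gene-set handling.

File formats (all plain text, tab-delimited, UTF-8, ``#`` comment lines ignored,
no quoting):

* **count TSV** — header row ``gene_id<TAB>sample1<TAB>...``; one gene per row,
  non-negative integer counts.
* **sample map TSV** — header ``sample_id<TAB>condition``; one sample per row.
* **GMT** — one gene set per line: name, description, then member gene IDs.
* **p-value TSV** — header ``gene_id<TAB>p_value`` (optional third column
  ``annotated`` with true/false).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_gene_sets",
    "write_gene_sets",
    "read_pvalue_table",
    "write_pvalue_table",
    "cpm",
    "cpm_log2",
    "filter_low_expression",
    "subset_to_gene_set",
]


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts with condition labels.

    ``counts`` is indexed by gene ID with sample IDs as columns;
    ``condition_of`` maps every sample ID to its condition label.
    """

    counts: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene IDs: {dups[:5]}")
        if cols.has_duplicates:
            raise DataError("duplicate sample IDs")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.number) or np.isnan(vals.astype(float)).any()):
            raise DataError("counts contain missing or non-numeric values")
        fvals = vals.astype(float)
        if vals.size and (fvals < 0).any():
            raise DataError("counts contain negative values")
        if vals.size and not np.array_equal(fvals, np.round(fvals)):
            raise DataError("counts contain fractional values")
        missing = [s for s in cols if s not in self.condition_of]
        if missing:
            raise DataError(f"samples without a condition label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance across samples."""
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of real-valued (typically log2-CPM) expression."""

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms) as read from a GMT file."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(counts_path: str | Path, sample_map_path: str | Path) -> CountMatrix:
    """Read a count TSV plus its sample->condition map into a validated CountMatrix."""
    counts_path, sample_map_path = Path(counts_path), Path(sample_map_path)
    try:
        df = pd.read_csv(counts_path, sep="\t", comment="#", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{counts_path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{counts_path}: need a gene_id column plus at least one sample")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{counts_path}: duplicated gene rows {dup[:5]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{counts_path}: non-numeric values in column {col!r}")
    if df.isna().to_numpy().any():
        raise ParseError(f"{counts_path}: missing values in count matrix")

    try:
        smap = pd.read_csv(sample_map_path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{sample_map_path}: {exc}") from exc
    if smap.shape[1] < 2:
        raise ParseError(f"{sample_map_path}: expected columns sample_id, condition")
    smap = smap.iloc[:, :2]
    smap.columns = ["sample_id", "condition"]
    if smap["sample_id"].duplicated().any():
        raise ParseError(f"{sample_map_path}: duplicated sample IDs")
    condition_of = dict(zip(smap["sample_id"], smap["condition"]))
    unmapped = [s for s in df.columns if s not in condition_of]
    if unmapped:
        raise ParseError(f"{sample_map_path}: samples missing from map: {unmapped}")
    condition_of = {s: condition_of[s] for s in df.columns}
    try:
        cm = CountMatrix(df, condition_of)
    except DataError as exc:
        raise ParseError(f"{counts_path}: {exc}") from exc
    return cm


def write_counts(cm: CountMatrix, counts_path: str | Path, sample_map_path: str | Path | None = None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    if sample_map_path is not None:
        pd.DataFrame(
            {"sample_id": cm.sample_ids, "condition": [cm.condition_of[s] for s in cm.sample_ids]}
        ).to_csv(sample_map_path, sep="\t", index=False)


def read_gene_sets(gmt_path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Member lists are deduplicated preserving order. A line with fewer than
    three fields is a parse error naming the line number.
    """
    gmt_path = Path(gmt_path)
    sets: dict[str, GeneSet] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{gmt_path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if name in sets:
                raise ParseError(f"{gmt_path}:{lineno}: duplicated set name {name!r}")
            sets[name] = GeneSet(name, desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_pvalue_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene p-value TSV (gene_id, p_value[, annotated])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "p_value" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id, p_value")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated gene IDs")
    p = df["p_value"].to_numpy(float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParseError(f"{path}: p-values must lie in [0, 1]")
    if "annotated" in df.columns:
        df["annotated"] = df["annotated"].astype(bool)
    return df


def write_pvalue_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("gene_id", "p_value", "annotated") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and subsetting


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Plain counts-per-million; each sample's CPM column sums to exactly 1e6."""
    lib = counts.library_sizes().to_numpy(float)
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
        raise DataError(f"zero library size for samples {bad}")
    vals = counts.counts.to_numpy(float) / lib * 1e6
    return ExpressionMatrix(pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns))


def cpm_log2(counts: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2-CPM with a prior count.

    value = log2((count + prior) / (library_size + 2*prior) * 1e6).  The prior
    (default 0.5) keeps zeros finite and damps the correlation noise of low
    counts before Pearson analysis.
    """
    if prior <= 0:
        raise ConfigurationError("prior must be positive; use cpm() for the prior-free variant")
    lib = counts.library_sizes().to_numpy(float)
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
        raise DataError(f"zero library size for samples {bad}")
    vals = np.log2((counts.counts.to_numpy(float) + prior) / (lib + 2.0 * prior) * 1e6)
    return ExpressionMatrix(pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns))


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to half the samples (rounded up). Gene order is
    preserved; condition labels carry over unchanged.
    """
    n_samples = len(counts.sample_ids)
    if min_samples is None:
        min_samples = math.ceil(n_samples / 2)
    if min_samples > n_samples:
        raise ConfigurationError(f"min_samples={min_samples} exceeds the {n_samples} available samples")
    cpm_vals = cpm(counts).data.to_numpy()
    keep = (cpm_vals > min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(counts.counts.loc[keep], dict(counts.condition_of))


def subset_to_gene_set(
    expr: ExpressionMatrix, gene_set: GeneSet | list[str] | tuple[str, ...]
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict an expression matrix to a gene set, preserving matrix row order.

    Returns the subset matrix and the list of set members absent from the
    matrix (e.g. annotated genes that did not pass the expression filter).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else tuple(gene_set)
    member_set = set(members)
    keep = [g for g in expr.gene_ids if g in member_set]
    if not keep:
        raise DataError("gene set has empty intersection with the expression matrix")
    absent = [g for g in members if g not in set(expr.gene_ids)]
    return ExpressionMatrix(expr.data.loc[keep]), absent
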