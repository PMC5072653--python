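"""Readers and writers for the external file formats.

Three inputs drive an analysis: a gene x sample expression matrix
(tab-separated, genes in rows, log-scale nonnegative values), a gene-set
collection in GMT format, and a two-column phenotype table assigning each
sample to the control or case group.  All result tables are written as TSV
with a fixed column order and floats rendered to 6 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("igsa")

CONTROL = "control"
CASE = "case"

#: case-insensitive synonyms accepted in phenotype files, normalized on read
GROUP_SYNONYMS = {
    "control": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
    "case": CASE,
    "tumor": CASE,
    "tumour": CASE,
    "disease": CASE,
    "cancer": CASE,
}


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample expression values.

    Values are expected on a log scale (e.g. log2 intensity) and
    nonnegative; the normalization step divides each gene's value by its
    row sum, which is only meaningful for nonnegative input.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeTable:
    """Mapping sample id -> canonical group label (control / case)."""

    group_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.group_of.values() if g not in (CONTROL, CASE)}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if not self.controls:
            raise ValidationError("at least one control required")
        if not self.cases:
            raise ValidationError("at least one case required")

    @property
    def controls(self) -> list[str]:
        return [s for s, g in self.group_of.items() if g == CONTROL]

    @property
    def cases(self) -> list[str]:
        return [s for s, g in self.group_of.items() if g == CASE]


@dataclass
class GeneSetCollection:
    """Named gene-identifier sets (e.g. KEGG pathways), GMT-style."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind}: {x!r}")
        seen.add(x)


def read_expression(
    path: str | Path, allow_negative: bool = False, log2p1: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header sample ids).

    ``log2p1`` applies log2(x + 1) after reading, as a convenience for raw
    intensity/count input; by default the file must already be log-scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    _check_unique(list(df.index.astype(str)), "gene id")
    _check_unique(list(df.columns.astype(str)), "sample id")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"non-finite value in {path}")
    if log2p1:
        if np.any(values < 0):
            raise ValidationError("negative values cannot be log2(x+1)-transformed")
        values = np.log2(values + 1.0)
    if not allow_negative and np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative value {values[i, j]} for gene {df.index[i]!r} in sample "
            f"{df.columns[j]!r}: input must be nonnegative log-scale expression "
            "(pass allow_negative to override)"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(matrix, path: str | Path) -> None:
    """Write an ExpressionMatrix-like object (anything with ``to_frame``) as TSV."""
    frame = matrix.to_frame()
    frame.index.name = "gene"
    write_table(frame.reset_index(), path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene1 TAB ..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique_genes = frozenset(g for g in genes if g)
            if not unique_genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = unique_genes
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s is empty", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_phenotypes(path: str | Path, samples: Iterable[str]) -> PhenotypeTable:
    """Read a two-column TSV (sample_id, group) covering all given samples."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df["group"].isna().any():
        raise ValidationError(f"{path}: every row needs a sample id and a group")
    # tolerate a header row
    first = str(df.iloc[0]["group"]).strip().lower()
    if first not in GROUP_SYNONYMS and str(df.iloc[0]["sample"]).lower() in (
        "sample",
        "sample_id",
        "id",
    ):
        df = df.iloc[1:]
    group_of: dict[str, str] = {}
    for _, row in df.iterrows():
        sample = str(row["sample"]).strip()
        raw = str(row["group"]).strip().lower()
        if raw not in GROUP_SYNONYMS:
            raise ValidationError(
                f"{path}: unknown group {row['group']!r} for sample {sample!r} "
                f"(accepted: {sorted(set(GROUP_SYNONYMS))})"
            )
        if sample in group_of:
            raise ValidationError(f"{path}: duplicate label for sample {sample!r}")
        group_of[sample] = GROUP_SYNONYMS[raw]
    samples = list(samples)
    missing = [s for s in samples if s not in group_of]
    if missing:
        raise ValidationError(f"{path}: unlabeled samples: {missing}")
    restricted = {s: group_of[s] for s in samples}
    if all(g == CASE for g in restricted.values()):
        raise ValidationError("at least one control required")
    if all(g == CONTROL for g in restricted.values()):
        raise ValidationError("at least one case required")
    return PhenotypeTable(group_of=restricted)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, group in pheno.group_of.items():
            fh.write(f"{sample}\t{group}\n")


def _format_cell(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_table(records, path: str | Path) -> None:
    """Write a DataFrame or list of mappings as TSV, floats to 6 sig digits.

    Row order is preserved as given (callers sort deterministically);
    an empty record list yields a header-only file when a DataFrame with
    columns is supplied.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame.from_records(records)
    formatted = df.map(_format_cell)
    formatted.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_score_matrix(path: str | Path) -> "pd.DataFrame":
    """Read a sets x samples score TSV (first column set name) back as a frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
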