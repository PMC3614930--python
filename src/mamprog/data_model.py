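"""Core domain types and TSV readers/writers.

The pipeline's data live in five containers: a developmental time-course
expression matrix with per-value detection calls, named gene sets, clinical
outcome tables, tumor log-ratio cohorts, and a mouse-to-human homolog map.
All on-disk formats are UTF-8 tab-delimited text; lines starting with ``#``
are comments, except the leading ``#scale=`` declaration on expression
matrices which records whether values are linear intensities or log2 ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mamprog")

PRESENT = "P"
ABSENT = "A"

#: Accepted levels per clinical factor column ("NA" is always allowed and
#: parsed as missing).
FACTOR_VOCABULARIES: dict[str, set[str]] = {
    "size_class": {"<2cm", "2-5cm", ">5cm"},
    "grade": {"1", "2", "3"},
    "er_status": {"positive", "negative"},
    "angioinvasion": {"0", "1"},
    "lymphocytic_infiltrate": {"0", "1"},
    "node_status": {"negative", "positive"},
}

FACTOR_COLUMNS = list(FACTOR_VOCABULARIES)


class DataModelError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass
class TimeCourseMatrix:
    """Genes x arrays expression with detection calls and a time design.

    Parameters
    ----------
    values : DataFrame
        Linear-scale positive intensities, genes in rows, arrays in columns.
    design : Series
        Maps each array id to a time-point label.
    timepoint_order : list of str
        Ordered time-point labels (developmental order).
    calls : DataFrame, optional
        Detection calls, same shape as ``values``, entries ``"P"``/``"A"``.
        Defaults to all-Present.
    """

    values: pd.DataFrame
    design: pd.Series
    timepoint_order: list[str]
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataModelError(f"duplicate gene ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataModelError(f"duplicate array ID: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataModelError("expression values must be finite (no missing cells)")
        missing = [a for a in self.values.columns if a not in self.design.index]
        if missing:
            raise DataModelError(f"array missing from design: {missing[0]!r}")
        extra = [a for a in self.design.index if a not in self.values.columns]
        if extra:
            raise DataModelError(f"design names unknown array: {extra[0]!r}")
        bad_tp = set(self.design) - set(self.timepoint_order)
        if bad_tp:
            raise DataModelError(f"design uses undeclared time point(s): {sorted(bad_tp)}")
        for tp in self.timepoint_order:
            if (self.design == tp).sum() < 1:
                raise DataModelError(f"time point {tp!r} has no arrays")
        if self.calls is not None:
            if (self.calls.shape != self.values.shape
                    or list(self.calls.index) != list(self.values.index)
                    or list(self.calls.columns) != list(self.values.columns)):
                raise DataModelError("call matrix does not align with expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def arrays_for(self, timepoint: str) -> list[str]:
        return [a for a in self.values.columns if self.design[a] == timepoint]

    def timepoint_means(self) -> pd.DataFrame:
        """Mean intensity per gene per time point, columns in design order."""
        groups = self.design.reindex(self.values.columns)
        means = self.values.T.groupby(groups).mean().T
        return means[self.timepoint_order]

    def present_fraction(self) -> pd.Series:
        """Fraction of arrays on which each gene is called Present."""
        if self.calls is None:
            return pd.Series(1.0, index=self.values.index)
        return (self.calls == PRESENT).mean(axis=1)

    def subset_genes(self, genes: Iterable[str]) -> "TimeCourseMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return TimeCourseMatrix(
            values=self.values.loc[keep],
            design=self.design,
            timepoint_order=self.timepoint_order,
            calls=None if self.calls is None else self.calls.loc[keep],
        )


@dataclass
class GeneSet:
    """A named collection of gene identifiers with provenance."""

    name: str
    ids: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ids

    def intersect(self, other: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.ids & frozenset(other), self.provenance)


@dataclass
class ClinicalTable:
    """Per-tumor outcome and risk-factor table.

    ``table`` is indexed by tumor id with columns ``metastasis`` (0/1),
    ``time_to_event`` (months), ``event`` (0/1) and the categorical factors
    of :data:`FACTOR_VOCABULARIES` (missing values as NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataModelError(f"duplicate tumor ID: {dup!r}")
        for col in ("metastasis", "time_to_event", "event"):
            if col not in self.table.columns:
                raise DataModelError(f"clinical table missing column {col!r}")
        if (self.table["time_to_event"] < 0).any():
            bad = self.table.index[self.table["time_to_event"] < 0][0]
            raise DataModelError(f"negative time_to_event for tumor {bad!r}")
        for col, vocab in FACTOR_VOCABULARIES.items():
            if col not in self.table.columns:
                continue
            levels = set(self.table[col].dropna().astype(str))
            unknown = levels - vocab
            if unknown:
                raise DataModelError(
                    f"unknown level {sorted(unknown)[0]!r} in factor {col!r}"
                )

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, tumor_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(tumor_ids)].copy())


@dataclass
class TumorCohort:
    """Genes x tumors log2-ratio matrix plus matching clinical table."""

    name: str
    log_ratios: pd.DataFrame
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if set(self.log_ratios.columns) != set(self.clinical.tumor_ids):
            raise DataModelError(
                f"cohort {self.name!r}: tumor IDs differ between matrix and clinical table"
            )
        if self.log_ratios.index.has_duplicates:
            dup = self.log_ratios.index[self.log_ratios.index.duplicated()][0]
            raise DataModelError(f"duplicate gene ID: {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log_ratios.index)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.log_ratios.columns)


@dataclass
class HomologMap:
    """Many-to-one map from source gene ids to target gene ids."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path: str | Path, expected_scale: str | None) -> pd.DataFrame:
    """Read a '#'-commented TSV matrix, checking its #scale= declaration."""
    path = Path(path)
    scale = None
    with open(path, encoding="utf-8") as fh:
        lines = []
        for line in fh:
            if line.startswith("#scale="):
                scale = line.strip().split("=", 1)[1]
            elif not line.startswith("#"):
                lines.append(line)
    if expected_scale is not None:
        if scale is None:
            raise DataModelError(f"{path}: missing '#scale=' declaration")
        if scale != expected_scale:
            raise DataModelError(
                f"{path}: scale is {scale!r}, expected {expected_scale!r}"
            )
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df


def read_expression(
    path: str | Path,
    design_path: str | Path,
    calls_path: str | Path | None = None,
) -> TimeCourseMatrix:
    """Read a linear-scale time-course matrix with its array design.

    The design file has columns ``array_id`` and ``time_point``; the order of
    first appearance of time points defines the developmental order.
    """
    values = _read_tsv(path, expected_scale="linear")
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise DataModelError(f"missing expression value in gene {gene!r}")
    design_df = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    if not {"array_id", "time_point"} <= set(design_df.columns):
        raise DataModelError("design file needs 'array_id' and 'time_point' columns")
    design = pd.Series(
        design_df["time_point"].values, index=design_df["array_id"].values
    )
    order = list(dict.fromkeys(design_df["time_point"]))
    calls = None
    if calls_path is not None:
        calls = _read_tsv(calls_path, expected_scale=None)
        bad = set(np.unique(calls.to_numpy(dtype=str))) - {PRESENT, ABSENT}
        if bad:
            raise DataModelError(f"unknown detection call(s): {sorted(bad)}")
    return TimeCourseMatrix(values=values, design=design, timepoint_order=order, calls=calls)


def write_expression(
    matrix: TimeCourseMatrix,
    path: str | Path,
    design_path: str | Path,
    calls_path: str | Path | None = None,
) -> None:
    """Write a TimeCourseMatrix back to its TSV trio (inverse of read)."""
    _write_matrix(matrix.values, path, scale="linear")
    with open(design_path, "w", encoding="utf-8") as fh:
        fh.write("array_id\ttime_point\n")
        order = {tp: i for i, tp in enumerate(matrix.timepoint_order)}
        arrays = sorted(matrix.array_ids, key=lambda a: (order[matrix.design[a]],
                                                         matrix.array_ids.index(a)))
        for a in arrays:
            fh.write(f"{a}\t{matrix.design[a]}\n")
    if calls_path is not None and matrix.calls is not None:
        with open(calls_path, "w", encoding="utf-8") as fh:
            matrix.calls.to_csv(fh, sep="\t", index_label="gene_id")


def _write_matrix(df: pd.DataFrame, path: str | Path, scale: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#scale={scale}\n")
        df.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_gene_set(path: str | Path, name: str, provenance: str = "") -> GeneSet:
    """Read a one-ID-per-line gene list; '#' lines and blanks are ignored."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    unique = frozenset(ids)
    dropped = len(ids) - len(unique)
    if dropped:
        logger.info("gene set %s: collapsed %d duplicate ID(s)", name, dropped)
    if not unique:
        logger.warning("gene set %s read from %s is empty", name, path)
    return GeneSet(name=name, ids=unique, provenance=provenance or str(path))


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(genes.ids):
            fh.write(gid + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV ('NA' = missing) into a typed ClinicalTable."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if "tumor_id" not in df.columns:
        raise DataModelError("clinical table needs a 'tumor_id' column")
    df = df.set_index("tumor_id")
    df.index.name = None
    for col in ("metastasis", "event"):
        if col in df.columns:
            df[col] = df[col].astype(float).astype("Int64")
    if "time_to_event" in df.columns:
        df["time_to_event"] = df["time_to_event"].astype(float)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.table.copy()
    with open(path, "w", encoding="utf-8") as fh:
        out.to_csv(fh, sep="\t", index_label="tumor_id", na_rep="NA",
                   lineterminator="\n")


def read_cohort(matrix_path: str | Path, clinical_path: str | Path,
                name: str) -> TumorCohort:
    """Read a log2-ratio tumor matrix and its clinical table as one cohort."""
    log_ratios = _read_tsv(matrix_path, expected_scale="log2")
    clinical = read_clinical(clinical_path)
    return TumorCohort(name=name, log_ratios=log_ratios, clinical=clinical)


def write_cohort(cohort: TumorCohort, matrix_path: str | Path,
                 clinical_path: str | Path) -> None:
    _write_matrix(cohort.log_ratios, matrix_path, scale="log2")
    write_clinical(cohort.clinical, clinical_path)


def read_homolog_map(path: str | Path) -> HomologMap:
    """Read a two-column (source, target) TSV homolog table."""
    pairs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataModelError(f"homolog map line is not two columns: {line!r}")
            src, dst = fields
            if src in pairs and pairs[src] != dst:
                raise DataModelError(f"source gene {src!r} maps to multiple targets")
            pairs[src] = dst
    return HomologMap(pairs=pairs)


def map_homologs(genes: GeneSet, homologs: HomologMap) -> GeneSet:
    """Image of a gene set under the homolog map; unmapped IDs are dropped."""
    mapped = {homologs.pairs[g] for g in genes.ids if g in homologs.pairs}
    n_dropped = sum(1 for g in genes.ids if g not in homologs.pairs)
    if n_dropped:
        logger.info("map_homologs: dropped %d unmapped ID(s) from %s",
                    n_dropped, genes.name)
    return GeneSet(name=genes.name, ids=frozenset(mapped),
                   provenance=f"{genes.provenance} (homolog-mapped)")
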