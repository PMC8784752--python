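"""Typed containers and TSV input/output for expression, annotation and clinical data.

All expression values entering the pipeline are non-negative, linear-scale
abundances (FPKM-like). Correlation and differential-expression statistics
operate on ``log2(x + 1)`` values; :func:`log_transform` performs that switch
exactly once, tracked by ``scale_tag``.

File conventions (all tab-delimited, UTF-8):

* expression: first column header ``gene_id``, remaining headers sample ids;
* annotation: columns ``gene_id``, ``symbol``, ``biotype``;
* clinical: columns ``sample_id``, ``time_days``, ``event``, ``stage``,
  ``t_stage``, ``n_stage``, ``m_stage``, ``age``, ``gender``; missing values
  written as empty string or ``NA``;
* immune-gene list: plain text, one gene symbol per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("irlpair")

LINEAR = "linear"
LOG2P1 = "log2p1"

#: values interpreted as missing in clinical/annotation tables
NA_VALUES = ["", "NA"]

#: clinical columns that must be present and complete for every retained sample
REQUIRED_CLINICAL = ("time_days", "event")


class DataError(ValueError):
    """Structured validation failure in input data."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise DataError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns.
    ``scale_tag`` is ``"linear"`` (non-negative) or ``"log2p1"``.
    """

    values: pd.DataFrame
    scale_tag: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale_tag not in (LINEAR, LOG2P1):
            raise DataError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.scale_tag == LINEAR:
            neg = arr < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise DataError(
                    f"negative expression at gene {self.values.index[i]!r}, "
                    f"sample {self.values.columns[j]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise DataError(f"unknown gene ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.scale_tag)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise DataError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale_tag)


@dataclass
class GeneAnnotation:
    """Gene metadata table with columns gene_id, symbol, biotype."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_id", "symbol", "biotype"):
            if col not in self.table.columns:
                raise DataError(f"annotation missing column {col!r}")
        _check_unique(self.table["gene_id"], "annotated gene")
        self.table = self.table.reset_index(drop=True)

    def ids_for_biotype(self, biotype: str) -> list[str]:
        mask = self.table["biotype"] == biotype
        return list(self.table.loc[mask, "gene_id"])

    def ids_for_symbols(self, symbols, biotype: str | None = None) -> list[str]:
        """Gene ids whose symbol is in ``symbols`` (optionally restricted by biotype)."""
        wanted = set(symbols)
        tab = self.table
        mask = tab["symbol"].isin(wanted)
        if biotype is not None:
            mask &= tab["biotype"] == biotype
        return list(tab.loc[mask, "gene_id"])


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table, indexed by sample_id.

    ``time_days`` must be strictly positive and ``event`` in {0, 1}; the
    remaining columns (stage, t_stage, n_stage, m_stage, age, gender, ...)
    are optional covariates and may contain missing values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in REQUIRED_CLINICAL:
            if col not in self.table.columns:
                raise DataError(f"clinical table missing column {col!r}")
        t = pd.to_numeric(self.table["time_days"], errors="coerce")
        if t.isna().any() or (t <= 0).any():
            bad = self.table.index[t.isna() | (t <= 0)][0]
            raise DataError(f"non-positive or missing time_days for sample {bad!r}")
        e = self.table["event"]
        if not e.isin([0, 1]).all():
            bad = self.table.index[~e.isin([0, 1])][0]
            raise DataError(f"event must be 0/1; offending sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> np.ndarray:
        return self.table["time_days"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def subset(self, sample_ids) -> "ClinicalTable":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise DataError(f"unknown clinical samples: {sorted(missing)[:5]}")
        return ClinicalTable(self.table.loc[list(sample_ids)])


@dataclass
class SampleGroups:
    """tumor/normal assignment per sample (pd.Series sample_id -> group)."""

    assignments: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.assignments.index, "sample")
        bad = ~self.assignments.isin(["tumor", "normal"])
        if bad.any():
            raise DataError(
                f"group must be tumor/normal; offending sample "
                f"{self.assignments.index[bad][0]!r}"
            )

    def samples(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, scale_tag: str = LINEAR) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    raw = pd.read_csv(path, sep="\t", dtype={0: str},
                      float_precision="round_trip")
    gene_col = raw.columns[0]
    _check_unique(raw[gene_col], "gene")
    _check_unique(raw.columns[1:], "sample")
    body = raw.set_index(gene_col)
    body.index.name = "gene_id"
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() & body[col].notna()
        if bad.any():
            raise DataError(
                f"non-numeric expression at gene {body.index[bad][0]!r}, "
                f"sample {col!r}"
            )
        if vals.isna().any():
            raise DataError(
                f"missing expression at gene {body.index[vals.isna()][0]!r}, "
                f"sample {col!r}"
            )
        body[col] = vals
    return ExpressionMatrix(body.astype(float), scale_tag)


def write_expression(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    tab = pd.read_csv(path, sep="\t", dtype=str, na_values=NA_VALUES,
                      keep_default_na=False)
    return GeneAnnotation(tab)


def write_annotation(annot: GeneAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    tab = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False,
                      float_precision="round_trip")
    if "sample_id" not in tab.columns:
        raise DataError("clinical table missing column 'sample_id'")
    _check_unique(tab["sample_id"], "sample")
    tab = tab.set_index("sample_id")
    tab["time_days"] = pd.to_numeric(tab["time_days"])
    tab["event"] = pd.to_numeric(tab["event"]).astype(int)
    if "age" in tab.columns:
        tab["age"] = pd.to_numeric(tab["age"], errors="coerce")
    return ClinicalTable(tab)


def write_clinical(clin: ClinicalTable, path) -> None:
    out = clin.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_gene_list(path) -> list[str]:
    """Plain-text gene-symbol list, one symbol per line (ImmPort-style)."""
    with open(path, encoding="utf-8") as fh:
        symbols = [line.strip() for line in fh]
    return [s for s in symbols if s]


def write_gene_list(symbols, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def read_groups(path) -> SampleGroups:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(tab.columns):
        raise DataError("groups table needs columns sample_id, group")
    return SampleGroups(tab.set_index("sample_id")["group"])


def write_groups(groups: SampleGroups, path) -> None:
    out = groups.assignments.rename("group").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def split_by_biotype(
    em: ExpressionMatrix, annot: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition genes into (lncRNA, protein_coding) sub-matrices.

    Genes absent from the annotation are dropped (count logged). An empty
    lncRNA partition is an error: the pipeline cannot proceed without it.
    """
    biotype = annot.table.set_index("gene_id")["biotype"]
    present = em.values.index[em.values.index.isin(biotype.index)]
    n_dropped = em.shape[0] - len(present)
    if n_dropped:
        logger.warning("split_by_biotype: dropped %d unannotated genes", n_dropped)
    bt = biotype.loc[present]
    lnc_ids = list(present[bt == "lncRNA"])
    pc_ids = list(present[bt == "protein_coding"])
    if not lnc_ids:
        raise DataError("no lncRNA-biotype genes present in the expression matrix")
    return (
        ExpressionMatrix(em.values.loc[lnc_ids], em.scale_tag),
        ExpressionMatrix(em.values.loc[pc_ids], em.scale_tag),
    )


def filter_clinical(
    clin: ClinicalTable, min_days: float = 30, max_missing_frac: float = 0.25
) -> ClinicalTable:
    """Apply the short-survivor exclusion and missing-covariate policy.

    Samples with ``time_days < min_days`` are excluded (boundary inclusive:
    exactly ``min_days`` is retained). Optional covariate columns whose
    cohort-wide missingness exceeds ``max_missing_frac`` are dropped as
    columns; samples missing any *retained* covariate are then excluded.
    Idempotent.
    """
    tab = clin.table
    tab = tab[tab["time_days"] >= min_days]
    if tab.empty:
        raise DataError(f"no samples with time_days >= {min_days}")
    optional = [c for c in tab.columns if c not in REQUIRED_CLINICAL]
    drop_cols = [c for c in optional if tab[c].isna().mean() > max_missing_frac]
    if drop_cols:
        logger.warning(
            "filter_clinical: dropping covariates %s (missingness > %.0f%%)",
            drop_cols, 100 * max_missing_frac,
        )
        tab = tab.drop(columns=drop_cols)
    tab = tab.dropna()
    if tab.empty:
        raise DataError("clinical filtering removed every sample")
    return ClinicalTable(tab)


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each value x by log2(x + 1); tag the result ``log2p1``."""
    if em.scale_tag != LINEAR:
        raise DataError("matrix is already log-transformed")
    return ExpressionMatrix(np.log2(em.values + 1.0), LOG2P1)
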