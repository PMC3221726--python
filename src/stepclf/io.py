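"""Reading, writing and alignment of paired clinical / molecular sample tables.

The package works with two feature spaces measured on (partially) the same
samples: a low-dimensional *clinical* table of mixed-type variables
(continuous, binary, nominal, ordinal) and a high-dimensional *molecular*
matrix of real-valued features (e.g. gene expression).  Molecular data may be
available for a subset of the samples only; that asymmetry is the premise of
the two-stage classifier.

All on-disk formats are tab-separated text with a single header row:

* clinical table   -- samples as rows, variables as columns;
* molecular matrix -- features as rows, samples as columns (the common
  expression-matrix convention; pass ``samples_as_columns=False`` to
  transpose);
* labels           -- two columns, sample id and class label;
* schema           -- one line per clinical column, ``name<TAB>kind`` with an
  optional third field ``a<b<c`` giving the ordinal level order.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stepclf")

KINDS = ("continuous", "binary", "nominal", "ordinal")
MISSING = "NA"


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ClinicalSchema:
    """Declares the measurement kind of every clinical column.

    ``ordinal_levels`` maps each ordinal column to its explicit level order
    (lowest first); levels of nominal/binary columns are inferred from data.
    """

    kinds: Mapping[str, str]
    ordinal_levels: Mapping[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, kind in self.kinds.items():
            if kind not in KINDS:
                raise DataError(f"unknown variable kind {kind!r} for column {col!r}")
            if kind == "ordinal" and col not in self.ordinal_levels:
                raise DataError(f"ordinal column {col!r} has no declared level order")
        for col in self.ordinal_levels:
            if self.kinds.get(col) != "ordinal":
                raise DataError(f"level order declared for non-ordinal column {col!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.kinds)


def read_schema(path: str | Path) -> ClinicalSchema:
    kinds: dict[str, str] = {}
    levels: dict[str, tuple[str, ...]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DataError(f"malformed schema line: {raw!r}")
        col, kind = parts[0], parts[1]
        kinds[col] = kind
        if kind == "ordinal":
            if len(parts) < 3:
                raise DataError(f"ordinal column {col!r} needs a level order field")
            levels[col] = tuple(parts[2].split("<"))
    return ClinicalSchema(kinds, levels)


def write_schema(schema: ClinicalSchema, path: str | Path) -> None:
    lines = []
    for col, kind in schema.kinds.items():
        if kind == "ordinal":
            lines.append(f"{col}\t{kind}\t{'<'.join(schema.ordinal_levels[col])}")
        else:
            lines.append(f"{col}\t{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ClinicalTable:
    """Mixed-type clinical covariates, samples as rows.

    Continuous columns are floats; the other kinds are stored as strings.
    Missing entries are NaN (continuous) or ``None`` (categorical).
    """

    data: pd.DataFrame
    schema: ClinicalSchema

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise DataError(f"duplicate sample IDs in clinical table: {dupes}")
        declared = set(self.schema.columns)
        present = set(self.data.columns)
        if declared - present:
            raise DataError(f"schema mentions unknown column(s): {sorted(declared - present)}")
        if present - declared:
            raise DataError(f"clinical column(s) lack a schema entry: {sorted(present - declared)}")
        # reorder columns to schema order, coerce dtypes
        self.data = self.data[list(self.schema.columns)]
        for col, kind in self.schema.kinds.items():
            if kind == "continuous":
                try:
                    self.data[col] = pd.to_numeric(self.data[col])
                except (ValueError, TypeError) as exc:
                    raise DataError(f"continuous column {col!r} has non-numeric values") from exc
            else:
                vals = self.data[col].astype("object")
                vals = vals.where(~pd.isna(vals), None)
                self.data[col] = vals.map(lambda v: None if v is None else str(v))
                observed = set(v for v in self.data[col] if v is not None)
                if kind == "binary" and len(observed) > 2:
                    raise DataError(
                        f"binary column {col!r} has {len(observed)} levels: {sorted(observed)}"
                    )
                if kind == "ordinal":
                    extra = observed - set(self.schema.ordinal_levels[col])
                    if extra:
                        raise DataError(
                            f"ordinal column {col!r} has undeclared level(s): {sorted(extra)}"
                        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(ids)].copy(), self.schema)


@dataclasses.dataclass
class MolecularMatrix:
    """Real-valued molecular features, samples as rows (in memory)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DataError("duplicate sample IDs in molecular matrix")
        if self.data.columns.duplicated().any():
            raise DataError("duplicate feature IDs in molecular matrix")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, ids: Sequence[str]) -> np.ndarray:
        out = self.data.loc[list(ids)].to_numpy(dtype=float)
        if not np.isfinite(out).all():
            raise DataError("molecular matrix contains non-finite values")
        return out

    def subset(self, ids: Sequence[str]) -> "MolecularMatrix":
        return MolecularMatrix(self.data.loc[[i for i in ids if i in self.data.index]].copy())


@dataclasses.dataclass
class LabeledDataset:
    """Aligned clinical + (optional) molecular data with optional binary labels.

    Sample order is the clinical-table order.  ``labels`` indexes a subset of
    the clinical samples; ``molecular`` may cover a subset of samples too.
    """

    clinical: ClinicalTable
    molecular: MolecularMatrix | None = None
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = set(self.clinical.sample_ids)
        if self.labels is not None:
            missing = set(self.labels.index) - ids
            if missing:
                raise DataError(f"labeled sample(s) absent from clinical table: {sorted(missing)}")
            classes = self.labels.dropna().unique()
            if len(classes) != 2:
                raise DataError(f"labels must have exactly 2 classes, found {len(classes)}")
        if self.molecular is not None:
            extra = set(self.molecular.sample_ids) - ids
            if extra:
                raise DataError(
                    f"molecular sample(s) absent from clinical table: {sorted(extra)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.clinical.sample_ids

    @property
    def molecular_ids(self) -> list[str]:
        return [] if self.molecular is None else self.molecular.sample_ids

    @property
    def train_ids(self) -> list[str]:
        """Samples usable for training: labeled and, if molecular data exists
        at all, covered by it (the method trains on samples with both types)."""
        if self.labels is None:
            return []
        labeled = [i for i in self.sample_ids if i in self.labels.index]
        if self.molecular is None:
            return labeled
        mol = set(self.molecular.sample_ids)
        return [i for i in labeled if i in mol]

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        assert self.labels is not None
        return self.labels.loc[list(ids)].to_numpy()

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        ids = list(ids)
        mol = self.molecular.subset(ids) if self.molecular is not None else None
        lab = None
        if self.labels is not None:
            keep = [i for i in ids if i in self.labels.index]
            lab = self.labels.loc[keep].copy()
        return LabeledDataset(self.clinical.subset(ids), mol, lab)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path, schema: ClinicalSchema | str | Path) -> ClinicalTable:
    if not isinstance(schema, ClinicalSchema):
        schema = read_schema(schema)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[MISSING, ""],
                        keep_default_na=False)
    frame.index = frame.index.astype(str)
    for col, kind in schema.kinds.items():
        if kind == "continuous" and col in frame.columns:
            frame[col] = frame[col].map(lambda v: float(v) if v is not None else np.nan,
                                        na_action="ignore")
    return ClinicalTable(frame, schema)


def read_molecular(path: str | Path, samples_as_columns: bool = True) -> MolecularMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""],
                        keep_default_na=False, float_precision="round_trip")
    if samples_as_columns:
        frame = frame.T
    frame.index = frame.index.astype(str)
    return MolecularMatrix(frame)


def read_labels(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, ""],
                        keep_default_na=False)
    if frame.shape[1] < 2:
        raise DataError("labels file needs two columns: sample id and class label")
    series = pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].astype(str))
    if series.index.duplicated().any():
        raise DataError("duplicate sample IDs in labels file")
    series = series.dropna()
    if series.nunique() != 2:
        raise DataError(f"labels must have exactly 2 classes, found {series.nunique()}")
    return series


def align_tables(
    clinical: ClinicalTable,
    molecular: MolecularMatrix | None,
    labels: pd.Series | None,
) -> tuple[LabeledDataset, dict[str, list[str]]]:
    """Align inputs on shared sample IDs, in clinical-table order.

    Returns the dataset and a report of dropped (unmatched) IDs per source.
    Molecular samples absent from the clinical table are dropped; clinical
    samples without molecular values are kept (molecular absent for them).
    """
    clin_ids = clinical.sample_ids
    dropped: dict[str, list[str]] = {}
    if molecular is not None:
        unmatched = [i for i in molecular.sample_ids if i not in set(clin_ids)]
        if unmatched:
            dropped["molecular"] = unmatched
        keep = [i for i in clin_ids if i in set(molecular.sample_ids)]
        molecular = molecular.subset(keep)
    if labels is not None:
        unmatched = [i for i in labels.index if i not in set(clin_ids)]
        if unmatched:
            dropped["labels"] = unmatched
            labels = labels.drop(unmatched)
        labels = labels.loc[[i for i in clin_ids if i in set(labels.index)]]
    for source, ids in dropped.items():
        warnings.warn(f"dropped {len(ids)} unmatched {source} sample ID(s): {ids}",
                      stacklevel=2)
    return LabeledDataset(clinical, molecular, labels), dropped


def read_dataset(
    clinical_path: str | Path,
    molecular_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    *,
    schema: ClinicalSchema | str | Path,
    molecular_samples_as_columns: bool = True,
) -> LabeledDataset:
    clinical = read_clinical(clinical_path, schema)
    molecular = (read_molecular(molecular_path, molecular_samples_as_columns)
                 if molecular_path is not None else None)
    labels = read_labels(labels_path) if labels_path is not None else None
    dataset, _ = align_tables(clinical, molecular, labels)
    return dataset


def write_dataset(dataset: LabeledDataset, directory: str | Path,
                  molecular_samples_as_columns: bool = True) -> dict[str, Path]:
    """Write clinical.tsv / molecular.tsv / labels.tsv / schema.txt."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    clin = dataset.clinical.data.copy()
    for col, kind in dataset.clinical.schema.kinds.items():
        if kind != "continuous":
            clin[col] = clin[col].map(lambda v: MISSING if v is None else v)
    paths["clinical"] = directory / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t", index_label="sample", na_rep=MISSING)

    paths["schema"] = directory / "schema.txt"
    write_schema(dataset.clinical.schema, paths["schema"])

    if dataset.molecular is not None:
        frame = dataset.molecular.data
        if molecular_samples_as_columns:
            frame = frame.T
        paths["molecular"] = directory / "molecular.tsv"
        frame.to_csv(paths["molecular"], sep="\t", index_label="feature")

    if dataset.labels is not None:
        paths["labels"] = directory / "labels.tsv"
        pd.DataFrame({"sample": dataset.labels.index, "label": dataset.labels.to_numpy()}
                     ).to_csv(paths["labels"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# numeric encoding
# ---------------------------------------------------------------------------


class ClinicalEncoder:
    """Turn a mixed-type clinical table into a numeric design matrix.

    Continuous columns pass through; ordinal columns become their level rank
    (1-based, in declared order); binary/nominal columns become integer
    category codes in order of first appearance among the fitting rows.
    Missing values are imputed with statistics of the *fitting* rows only:
    column median for continuous/ordinal, most frequent level otherwise.
    Category levels unseen at fit time fall back to the imputation level.
    """

    def __init__(self) -> None:
        self.schema: ClinicalSchema | None = None
        self.codebook: dict[str, dict[str, int]] = {}
        self.impute_: dict[str, float] = {}

    def fit(self, table: ClinicalTable, rows: Sequence[str] | None = None) -> "ClinicalEncoder":
        self.schema = table.schema
        frame = table.data if rows is None else table.data.loc[list(rows)]
        for col, kind in table.schema.kinds.items():
            values = frame[col]
            if kind == "continuous":
                observed = values.dropna()
                if observed.empty:
                    raise DataError(f"column {col!r} entirely missing in fitting rows")
                self.impute_[col] = float(observed.median())
            elif kind == "ordinal":
                levels = table.schema.ordinal_levels[col]
                codes = {lev: i + 1 for i, lev in enumerate(levels)}
                self.codebook[col] = codes
                obs = [codes[v] for v in values if v is not None]
                if not obs:
                    raise DataError(f"column {col!r} entirely missing in fitting rows")
                self.impute_[col] = float(np.median(obs))
            else:  # binary / nominal
                codes: dict[str, int] = {}
                for v in values:
                    if v is not None and v not in codes:
                        codes[v] = len(codes)
                if not codes:
                    raise DataError(f"column {col!r} entirely missing in fitting rows")
                self.codebook[col] = codes
                counts = values.value_counts()
                # most frequent level; ties broken by code order (deterministic)
                top = max(codes, key=lambda lev: (counts.get(lev, 0), -codes[lev]))
                self.impute_[col] = float(codes[top])
        return self

    def transform(self, table: ClinicalTable, rows: Sequence[str] | None = None) -> np.ndarray:
        if self.schema is None:
            raise RuntimeError("encoder not fitted")
        frame = table.data if rows is None else table.data.loc[list(rows)]
        cols = []
        for col, kind in self.schema.kinds.items():
            values = frame[col]
            if kind == "continuous":
                x = values.to_numpy(dtype=float)
                x = np.where(np.isnan(x), self.impute_[col], x)
            else:
                codes = self.codebook[col]
                x = np.array(
                    [codes.get(v, self.impute_[col]) if v is not None else self.impute_[col]
                     for v in values],
                    dtype=float,
                )
            cols.append(x)
        return np.column_stack(cols)

    def fit_transform(self, table: ClinicalTable, rows: Sequence[str] | None = None) -> np.ndarray:
        return self.fit(table, rows).transform(table)

    def decode(self, column: str, code: int) -> str:
        """Inverse lookup for categorical codes (round-trip support)."""
        inverse = {c: lev for lev, c in self.codebook[column].items()}
        return inverse[int(code)]


def encode_clinical(
    table: ClinicalTable, rows: Sequence[str] | None = None
) -> tuple[np.ndarray, ClinicalEncoder]:
    """Convenience wrapper: fit an encoder on ``rows`` and transform all rows."""
    enc = ClinicalEncoder().fit(table, rows)
    return enc.transform(table), enc
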