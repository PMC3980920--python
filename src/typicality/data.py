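"""Typed tabular data model and CSV/schema I/O.

A :class:`FeatureTable` is the universal input: an ``n x p`` grid of units
by features, each column tagged as continuous, ordinal, binary or nominal,
with an explicit missing-value mask. Continuous and ordinal cells are
floats; binary and nominal cells are category strings interned in
lexicographic order so that runs are byte-reproducible.

The one-class benchmark protocol needs a class-label column and a
target-class split; :func:`split_target` implements the repeated 50/50
split of the target class (training gets the extra unit when the count is
odd), with all nontarget units joining the test side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError, ParseError, SchemaError

VAR_TYPES = ("continuous", "binary", "ordinal", "nominal")
NUMERIC_TYPES = ("continuous", "ordinal")
CATEGORICAL_TYPES = ("binary", "nominal")


@dataclass
class Schema:
    """Column-type declaration for a CSV file.

    Parameters
    ----------
    types : mapping of column name -> type tag
        One of ``continuous``, ``binary``, ``ordinal``, ``nominal``.
    missing : str
        Sentinel string marking a missing cell (default ``"?"``, the UCI
        convention).
    label : str, optional
        Name of the class-label column; excluded from the features.
    target_level : str, optional
        Which label value is the target class in benchmark mode.
    """

    types: dict[str, str]
    missing: str = "?"
    label: str | None = None
    target_level: str | None = None

    def __post_init__(self) -> None:
        for col, tag in self.types.items():
            if tag not in VAR_TYPES:
                raise SchemaError(f"column {col!r}: unknown type tag {tag!r}")
        if self.label is not None and self.label in self.types:
            raise SchemaError(f"label column {self.label!r} must not be a feature")

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        """Load a schema from a YAML (or JSON) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            types=dict(raw["types"]),
            missing=raw.get("missing", "?"),
            label=raw.get("label"),
            target_level=raw.get("target_level"),
        )

    def to_file(self, path: str | Path) -> None:
        doc = {"types": self.types, "missing": self.missing}
        if self.label is not None:
            doc["label"] = self.label
        if self.target_level is not None:
            doc["target_level"] = self.target_level
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


class FeatureTable:
    """Units x typed features with a missing-value mask.

    Attributes
    ----------
    unit_ids : list of str
    column_names : list of str
    var_types : list of str, one tag per column
    values : (n, p) object ndarray
        Floats for continuous/ordinal columns, level strings for
        binary/nominal columns; missing cells hold ``None``.
    missing_mask : (n, p) bool ndarray
    levels : dict
        For each categorical column, the sorted list of observed levels.
    """

    def __init__(
        self,
        unit_ids: Sequence[str],
        values: np.ndarray,
        var_types: Sequence[str],
        missing_mask: np.ndarray,
        column_names: Sequence[str],
    ):
        values = np.asarray(values, dtype=object)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if values.ndim != 2:
            raise DataError("values must be a 2-D grid")
        n, p = values.shape
        if n < 1 or p < 1:
            raise DataError("need at least one unit and one feature")
        if missing_mask.shape != (n, p):
            raise DataError("missing_mask shape does not match values")
        if len(var_types) != p or len(column_names) != p:
            raise DataError("var_types/column_names length does not match values")
        if len(unit_ids) != n:
            raise DataError("unit_ids length does not match values")
        for tag in var_types:
            if tag not in VAR_TYPES:
                raise SchemaError(f"unknown variable type {tag!r}")

        self.unit_ids = [str(u) for u in unit_ids]
        self.column_names = list(column_names)
        self.var_types = list(var_types)
        self.values = values
        self.missing_mask = missing_mask
        self.levels: dict[str, list[str]] = {}

        for j, tag in enumerate(self.var_types):
            col = values[:, j]
            obs = ~missing_mask[:, j]
            if tag in NUMERIC_TYPES:
                for i in np.nonzero(obs)[0]:
                    v = col[i]
                    if not (isinstance(v, (int, float, np.floating, np.integer))
                            and np.isfinite(float(v))):
                        raise ParseError(
                            f"row {self.unit_ids[i]!r}, column "
                            f"{self.column_names[j]!r}: non-finite numeric cell {v!r}"
                        )
            else:
                lv = sorted({str(col[i]) for i in np.nonzero(obs)[0]})
                if tag == "binary" and len(lv) > 2:
                    raise ParseError(
                        f"binary column {self.column_names[j]!r} has "
                        f"{len(lv)} observed levels: {lv}"
                    )
                self.levels[self.column_names[j]] = lv

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        counts = {t: self.var_types.count(t) for t in VAR_TYPES if t in self.var_types}
        return f"FeatureTable(n={self.n}, p={self.p}, types={counts})"

    # -- views -----------------------------------------------------------
    def numeric(self) -> np.ndarray:
        """Return the table as a float matrix.

        Requires every column to be continuous or ordinal and no missing
        cells — the precondition of the non-Gower distances.
        """
        from .exceptions import MissingDataError

        bad = [c for c, t in zip(self.column_names, self.var_types)
               if t in CATEGORICAL_TYPES]
        if bad:
            raise SchemaError(
                f"categorical columns {bad} not supported by this distance; "
                "use the Gower distance for mixed data"
            )
        if self.missing_mask.any():
            raise MissingDataError(
                "missing values present; only the Gower distance handles them"
            )
        return self.values.astype(float)

    def encoded(self) -> tuple[np.ndarray, list[int], np.ndarray, list[int]]:
        """Split into numeric and categorical blocks for mixed-type distances.

        Returns ``(num, num_cols, codes, cat_cols)`` where ``num`` holds the
        continuous/ordinal columns as floats with NaN for missing, and
        ``codes`` holds categorical level codes (lexicographic order) with
        -1 for missing.
        """
        num_cols = [j for j, t in enumerate(self.var_types) if t in NUMERIC_TYPES]
        cat_cols = [j for j, t in enumerate(self.var_types) if t in CATEGORICAL_TYPES]
        num = np.full((self.n, len(num_cols)), np.nan)
        for k, j in enumerate(num_cols):
            obs = ~self.missing_mask[:, j]
            num[obs, k] = self.values[obs, j].astype(float)
        codes = np.full((self.n, len(cat_cols)), -1, dtype=int)
        for k, j in enumerate(cat_cols):
            lut = {lv: c for c, lv in enumerate(self.levels[self.column_names[j]])}
            for i in range(self.n):
                if not self.missing_mask[i, j]:
                    codes[i, k] = lut.get(str(self.values[i, j]), -2)
        return num, num_cols, codes, cat_cols

    def subset(self, rows: Sequence[int]) -> "FeatureTable":
        rows = np.asarray(rows, dtype=int)
        return FeatureTable(
            [self.unit_ids[i] for i in rows],
            self.values[rows],
            self.var_types,
            self.missing_mask[rows],
            self.column_names,
        )

    # -- conversion ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Schema) -> "FeatureTable":
        """Build from a string-typed DataFrame according to *schema*.

        The label column (if declared) is dropped from the features and
        stashed on the returned table as ``.labels``.
        """
        labels = None
        if schema.label is not None:
            if schema.label not in df.columns:
                raise SchemaError(f"label column {schema.label!r} not in data")
            labels = df[schema.label].astype(str).to_numpy()
            df = df.drop(columns=[schema.label])
        unknown = [c for c in df.columns if c not in schema.types]
        if unknown:
            raise SchemaError(f"columns {unknown} not covered by the schema")
        absent = [c for c in schema.types if c not in df.columns]
        if absent:
            raise SchemaError(f"schema columns {absent} absent from the data")

        cols = list(df.columns)
        n, p = df.shape
        values = np.empty((n, p), dtype=object)
        mask = np.zeros((n, p), dtype=bool)
        raw = df.astype(str).to_numpy()
        unit_ids = [str(i) for i in df.index]
        for j, c in enumerate(cols):
            tag = schema.types[c]
            for i in range(n):
                cell = raw[i, j].strip()
                if cell == schema.missing or cell == "":
                    mask[i, j] = True
                    values[i, j] = None
                elif tag in NUMERIC_TYPES:
                    try:
                        values[i, j] = float(cell)
                    except ValueError as exc:
                        raise ParseError(
                            f"row {unit_ids[i]!r}, column {c!r}: "
                            f"cannot parse {cell!r} as a number"
                        ) from exc
                else:
                    values[i, j] = cell
        table = cls(unit_ids, values, [schema.types[c] for c in cols], mask, cols)
        table_labels = labels
        table.labels = table_labels  # type: ignore[attr-defined]
        return table

    def to_dataframe(self, missing: str = "?") -> pd.DataFrame:
        out = pd.DataFrame(index=self.unit_ids, columns=self.column_names,
                           dtype=object)
        for j, c in enumerate(self.column_names):
            col = []
            for i in range(self.n):
                if self.missing_mask[i, j]:
                    col.append(missing)
                elif self.var_types[j] in NUMERIC_TYPES:
                    col.append(repr(float(self.values[i, j])))
                else:
                    col.append(str(self.values[i, j]))
            out[c] = col
        return out


def read_table(path: str | Path, schema: Schema) -> FeatureTable:
    """Read a CSV file (header row required) into a :class:`FeatureTable`.

    Cells equal to the schema's missing sentinel become masked. If the
    schema declares a label column its values are attached as ``.labels``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=False)
    return FeatureTable.from_dataframe(df, schema)


def write_table(table: FeatureTable, path: str | Path, schema: Schema,
                labels: np.ndarray | None = None) -> None:
    """Write a table (and optional labels) as CSV round-trippable by
    :func:`read_table` under the same schema."""
    df = table.to_dataframe(missing=schema.missing)
    if labels is not None and schema.label is not None:
        df[schema.label] = list(labels)
    df.to_csv(path, index=False)


def split_target(
    table: FeatureTable,
    labels: np.ndarray,
    target_level: str,
    fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[FeatureTable, FeatureTable, np.ndarray]:
    """Split the target class between training and test sets.

    ``ceil(fraction * n_target)`` target units (uniformly at random, so
    training gets the extra unit for an odd count at fraction 0.5) go to
    training; the remaining target units plus ALL nontarget units form the
    test set. Returns ``(train_table, test_table, test_labels)``.
    """
    labels = np.asarray(labels).astype(str)
    if len(labels) != table.n:
        raise DataError("labels length does not match the table")
    target_idx = np.nonzero(labels == str(target_level))[0]
    if len(target_idx) < 2:
        raise DataError(
            f"need at least 2 target units, got {len(target_idx)} "
            f"for level {target_level!r}"
        )
    if not (0 < fraction < 1):
        raise DataError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.ceil(fraction * len(target_idx)))
    perm = rng.permutation(len(target_idx))
    train_idx = np.sort(target_idx[perm[:n_train]])
    held_out = np.sort(target_idx[perm[n_train:]])
    nontarget_idx = np.nonzero(labels != str(target_level))[0]
    test_idx = np.sort(np.concatenate([held_out, nontarget_idx])).astype(int)
    return (
        table.subset(train_idx),
        table.subset(test_idx),
        labels[test_idx],
    )


@dataclass
class RunConfig:
    """Resolved configuration of a benchmark run.

    ``alpha`` is the nominal false alarm rate (fraction of true target
    units rejected); ``n_boot`` the bootstrap sample size for the
    typicality null; ``repeats`` the number of random target splits.
    """

    distance: str = "euclidean"
    alpha: float = 0.1
    n_boot: int = 1000
    repeats: int = 10
    seed: int = 0
    method: str = "typicality"
    distance_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise DataError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise DataError("n_boot must be >= 1")
        if self.repeats < 1:
            raise DataError("repeats must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "distance": self.distance,
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "repeats": self.repeats,
            "seed": self.seed,
            "method": self.method,
            "distance_params": dict(self.distance_params),
        }


def write_results(result, path: str | Path) -> None:
    """Write an evaluation result as a CSV table plus a JSON sidecar.

    ``path`` names the CSV file; the JSON (same stem, ``.json``) carries the
    full per-repeat AUC vectors and any confusion tables so the result
    round-trips losslessly via :func:`read_results`.
    """
    path = Path(path)
    df = result.to_frame()
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_results(path: str | Path):
    from .evaluation import EvalResult

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        return EvalResult.from_dict(json.load(fh))
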