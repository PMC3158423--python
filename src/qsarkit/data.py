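"""Tabular dataset container with a typed schema, CSV I/O and domain harmonization.

A :class:`Dataset` is an examples x variables table. Each variable carries a
:class:`VariableSchema` declaring its kind (``continuous`` or ``enumerated``),
its role (``feature``, ``response`` or ``meta``) and, for enumerated
variables, an ordered list of category labels. Continuous cells are floats,
enumerated cells are level indices; missing cells are NaN throughout and are
rendered as ``?`` in CSV.

Meta variables (SMILES strings, compound identifiers) travel with the table
but are never consumed by learners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import NoDataError, NoResponseError, SchemaConflictError

MISSING_TOKEN = "?"

CONTINUOUS = "continuous"
ENUMERATED = "enumerated"

FEATURE = "feature"
RESPONSE = "response"
META = "meta"


@dataclass(frozen=True)
class VariableSchema:
    """Declared type and role of one table column."""

    name: str
    kind: str = CONTINUOUS
    levels: tuple[str, ...] = ()
    role: str = FEATURE

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, ENUMERATED):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.role not in (FEATURE, RESPONSE, META):
            raise ValueError(f"unknown variable role {self.role!r}")
        if self.kind == ENUMERATED:
            if len(set(self.levels)) != len(self.levels) or not self.levels:
                raise ValueError(
                    f"enumerated variable {self.name!r} needs unique, non-empty levels"
                )
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": list(self.levels),
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(d["name"], d["kind"], tuple(d.get("levels", ())), d.get("role", FEATURE))


class Dataset:
    """Schema-typed table of examples.

    Parameters
    ----------
    schema
        One :class:`VariableSchema` per column, in column order.
    values
        DataFrame whose columns match the schema names/order. Continuous and
        enumerated columns are stored as float64 (enumerated cells hold level
        indices); meta columns keep their raw objects. NaN marks missing.
    """

    def __init__(self, schema: Sequence[VariableSchema], values: pd.DataFrame):
        schema = list(schema)
        names = [v.name for v in schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        if list(values.columns) != names:
            values = values.loc[:, names]
        df = pd.DataFrame(index=range(len(values)))
        for var in schema:
            col = values[var.name].reset_index(drop=True)
            if var.role == META:
                df[var.name] = col.astype(object)
            else:
                arr = pd.to_numeric(col, errors="coerce").astype(np.float64)
                if var.kind == ENUMERATED:
                    with np.errstate(invalid="ignore"):
                        bad = arr.to_numpy() >= len(var.levels)
                    if np.any(bad & ~np.isnan(arr.to_numpy())):
                        raise ValueError(
                            f"enumerated cell index out of range for {var.name!r}"
                        )
                df[var.name] = arr
        self.schema = schema
        self.df = df

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"Dataset({len(self)} examples, {self.n_attr} features)"

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]

    def var(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def feature_schemas(self) -> list[VariableSchema]:
        return [v for v in self.schema if v.role == FEATURE]

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.feature_schemas]

    @property
    def n_attr(self) -> int:
        return len(self.feature_schemas)

    @property
    def response_schema(self) -> VariableSchema | None:
        resp = [v for v in self.schema if v.role == RESPONSE]
        if len(resp) > 1:
            raise ValueError("more than one response variable")
        return resp[0] if resp else None

    @property
    def task(self) -> str:
        resp = self.response_schema
        if resp is None:
            raise NoResponseError("dataset has no response variable")
        return "classification" if resp.kind == ENUMERATED else "regression"

    # -- views ---------------------------------------------------------------

    def X(self) -> pd.DataFrame:
        """Feature columns as a float frame (enumerated cells are level codes)."""
        return self.df[self.feature_names]

    def y(self) -> pd.Series:
        resp = self.response_schema
        if resp is None:
            raise NoResponseError("dataset has no response variable")
        return self.df[resp.name]

    def subset(self, rows: Iterable[int]) -> "Dataset":
        rows = np.asarray(list(rows), dtype=int)
        return Dataset(list(self.schema), self.df.iloc[rows].reset_index(drop=True))

    def select_features(self, keep: Sequence[str]) -> "Dataset":
        """Restrict the feature set, preserving response and meta columns."""
        keep = set(keep)
        schema = [v for v in self.schema if v.role != FEATURE or v.name in keep]
        return Dataset(schema, self.df[[v.name for v in schema]])

    def drop_response(self) -> "Dataset":
        schema = [v for v in self.schema if v.role != RESPONSE]
        return Dataset(schema, self.df[[v.name for v in schema]])

    def copy(self) -> "Dataset":
        return Dataset(list(self.schema), self.df.copy())

    def response_labels(self) -> pd.Series:
        """Response as level labels (classification) or floats (regression)."""
        resp = self.response_schema
        y = self.y()
        if resp.kind == ENUMERATED:
            return y.map(lambda c: resp.levels[int(c)] if not pd.isna(c) else np.nan)
        return y

    # -- construction --------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray | None = None,
        feature_names: Sequence[str] | None = None,
        response_name: str = "response",
        class_labels: Sequence[str] | None = None,
    ) -> "Dataset":
        """Build a dataset from numeric arrays.

        ``class_labels`` given makes the response enumerated with those level
        labels and ``y`` interpreted as level indices; otherwise ``y`` is a
        continuous response.
        """
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        schema = [VariableSchema(nm) for nm in feature_names]
        df = pd.DataFrame(X, columns=list(feature_names))
        if y is not None:
            if class_labels is not None:
                schema.append(
                    VariableSchema(response_name, ENUMERATED, tuple(class_labels), RESPONSE)
                )
            else:
                schema.append(VariableSchema(response_name, CONTINUOUS, role=RESPONSE))
            df[response_name] = np.asarray(y, dtype=float)
        return cls(schema, df)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str | None = None,
        meta: Sequence[str] = (),
    ) -> "Dataset":
        """Infer a schema from a raw frame of labels/strings/numbers.

        Columns whose non-missing values all parse as numbers become
        continuous; the rest become enumerated with levels in order of first
        appearance. A column literally named like ``smiles`` defaults to meta.
        """
        meta = set(meta) | {c for c in df.columns if str(c).lower() == "smiles"}
        schema: list[VariableSchema] = []
        out = {}
        for colname in df.columns:
            raw = df[colname]
            role = META if colname in meta else (RESPONSE if colname == response else FEATURE)
            if role == META:
                schema.append(VariableSchema(colname, CONTINUOUS, role=META))
                out[colname] = raw.astype(object)
                continue
            cleaned = raw.replace(MISSING_TOKEN, np.nan)
            numeric = pd.to_numeric(cleaned, errors="coerce")
            n_values = cleaned.notna().sum()
            if n_values and numeric.notna().sum() == n_values:
                schema.append(VariableSchema(colname, CONTINUOUS, role=role))
                out[colname] = numeric.astype(float)
            else:
                levels = list(dict.fromkeys(str(v) for v in cleaned.dropna()))
                schema.append(VariableSchema(colname, ENUMERATED, tuple(levels), role))
                idx = {lv: i for i, lv in enumerate(levels)}
                out[colname] = cleaned.map(lambda v: idx[str(v)] if not pd.isna(v) else np.nan)
        return cls(schema, pd.DataFrame(out))


# -- CSV I/O -----------------------------------------------------------------


def schema_sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".schema.json")


def write_csv(data: Dataset, path: str | Path, sidecar: bool = True) -> Path:
    """Write a dataset as comma-separated text; missing cells become ``?``.

    A JSON sidecar recording the full schema (kinds, level order, roles) is
    written next to the CSV so a round-trip preserves typing exactly.
    """
    path = Path(path)
    out = pd.DataFrame(index=range(len(data)))
    for var in data.schema:
        col = data.df[var.name]
        if var.role == META:
            out[var.name] = col.fillna(MISSING_TOKEN)
        elif var.kind == ENUMERATED:
            out[var.name] = col.map(
                lambda c: var.levels[int(c)] if not pd.isna(c) else MISSING_TOKEN
            )
        else:
            out[var.name] = col.map(
                lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v))
            )
    out.to_csv(path, index=False)
    if sidecar:
        schema_sidecar_path(path).write_text(
            json.dumps([v.to_dict() for v in data.schema], indent=1)
        )
    return path


def read_csv(
    path: str | Path,
    response: str | None = None,
    meta: Sequence[str] = (),
) -> Dataset:
    """Read a dataset from CSV, honoring a schema sidecar when present.

    ``?`` and empty cells are missing. Without a sidecar the schema is
    inferred per :meth:`Dataset.from_dataframe`; explicit ``response``/``meta``
    arguments override sidecar roles.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["", MISSING_TOKEN])
    if raw.empty:
        raise NoDataError(f"{path} holds no examples")
    sidecar = schema_sidecar_path(path)
    if sidecar.exists():
        schema = [VariableSchema.from_dict(d) for d in json.loads(sidecar.read_text())]
        if response is not None or meta:
            meta = set(meta)
            schema = [
                replace(
                    v,
                    role=(
                        RESPONSE
                        if v.name == response
                        else META
                        if v.name in meta
                        else FEATURE
                        if v.role == RESPONSE and response is not None
                        else v.role
                    ),
                )
                for v in schema
            ]
        cols = {}
        for var in schema:
            col = raw[var.name]
            if var.role == META:
                cols[var.name] = col.astype(object)
            elif var.kind == ENUMERATED:
                idx = {lv: i for i, lv in enumerate(var.levels)}
                unknown = {str(v) for v in col.dropna()} - set(var.levels)
                if unknown:
                    raise SchemaConflictError(
                        f"values {sorted(unknown)} of {var.name!r} not in declared levels"
                    )
                cols[var.name] = col.map(lambda v: idx[str(v)] if not pd.isna(v) else np.nan)
            else:
                cols[var.name] = pd.to_numeric(col, errors="coerce")
        return Dataset(schema, pd.DataFrame(cols))
    return Dataset.from_dataframe(raw, response=response, meta=meta)


# -- harmonization -----------------------------------------------------------


def _levels_as_numbers(levels: Sequence[str]) -> list[float] | None:
    try:
        return [float(v) for v in levels]
    except ValueError:
        return None


def _convert_to_continuous(data: Dataset, name: str, report: list[str]) -> Dataset:
    var = data.var(name)
    nums = _levels_as_numbers(var.levels)
    if nums is None:
        raise SchemaConflictError(
            f"variable {var.name!r}: levels {list(var.levels)} cannot be read as numbers"
        )
    df = data.df.copy()
    df[name] = data.df[name].map(lambda c: nums[int(c)] if not pd.isna(c) else np.nan)
    schema = [
        replace(v, kind=CONTINUOUS, levels=()) if v.name == name else v for v in data.schema
    ]
    report.append(f"converted {name!r} from enumerated to continuous")
    return Dataset(schema, df)


def _reorder_levels(data: Dataset, name: str, levels: tuple[str, ...], report: list[str]) -> Dataset:
    var = data.var(name)
    if var.levels == levels:
        return data
    mapping = {}
    target = {lv: i for i, lv in enumerate(levels)}
    for i, lv in enumerate(var.levels):
        mapping[i] = target[lv]
    df = data.df.copy()
    df[name] = data.df[name].map(lambda c: mapping[int(c)] if not pd.isna(c) else np.nan)
    schema = [replace(v, levels=levels) if v.name == name else v for v in data.schema]
    report.append(
        f"reordered levels of {name!r} from {list(var.levels)} to {list(levels)}"
    )
    return Dataset(schema, df)


def harmonize(a: Dataset, b: Dataset) -> tuple[Dataset, Dataset, list[str]]:
    """Reconcile the schemas of two datasets sharing variable names.

    Same-named variables end up with identical kind and identical level order
    in both outputs; variables present in only one input are untouched. Text
    (enumerated) columns whose levels all parse as numbers are converted to
    continuous when the counterpart is continuous. When both are enumerated,
    the first argument's level order wins; levels unique to either side are
    appended. Returns the two aligned datasets and a report of every
    conversion performed.
    """
    if len(a) == 0 or len(b) == 0:
        raise NoDataError("harmonize requires non-empty datasets")
    report: list[str] = []
    for name in [v.name for v in a.schema if any(w.name == v.name for w in b.schema)]:
        va, vb = a.var(name), b.var(name)
        if va.kind == CONTINUOUS and vb.kind == CONTINUOUS:
            continue
        if va.kind != vb.kind:
            if va.kind == ENUMERATED:
                a = _convert_to_continuous(a, name, report)
            else:
                b = _convert_to_continuous(b, name, report)
            continue
        # both enumerated: first argument's order, then b's extras
        merged = tuple(dict.fromkeys(list(va.levels) + list(vb.levels)))
        if va.levels != merged:
            a = _reorder_levels(a, name, merged, report)
        b = _reorder_levels(b, name, merged, report)
    return a, b, report


def harmonize_to_schema(data: Dataset, ref: Sequence[VariableSchema]) -> tuple[Dataset, list[str]]:
    """Align a prediction dataset to a model's training schema.

    Every reference feature must be present; extra variables in ``data`` are
    ignored (their columns are dropped from the returned view). Kind
    mismatches are resolved toward the reference; enumerated levels are
    remapped to the reference order, with unseen labels mapped to missing (to
    be imputed downstream).
    """
    report: list[str] = []
    ref_features = [v for v in ref if v.role == FEATURE]
    missing = [v.name for v in ref_features if v.name not in data.names]
    if missing:
        raise SchemaConflictError(
            f"prediction data lacks training feature(s): {', '.join(missing)}"
        )
    for rv in ref_features:
        dv = data.var(rv.name)
        if rv.kind == CONTINUOUS and dv.kind == ENUMERATED:
            data = _convert_to_continuous(data, rv.name, report)
        elif rv.kind == ENUMERATED:
            if dv.kind == CONTINUOUS:
                raise SchemaConflictError(
                    f"variable {rv.name!r} is continuous but the model expects levels "
                    f"{list(rv.levels)}"
                )
            dv = data.var(rv.name)
            unseen = [lv for lv in dv.levels if lv not in rv.levels]
            if unseen:
                df = data.df.copy()
                drop = {i for i, lv in enumerate(dv.levels) if lv in unseen}
                df[rv.name] = data.df[rv.name].map(
                    lambda c: np.nan if pd.isna(c) or int(c) in drop else c
                )
                kept = tuple(lv for lv in dv.levels if lv not in unseen)
                schema = [
                    replace(v, levels=kept) if v.name == rv.name else v for v in data.schema
                ]
                remap = {i: kept.index(lv) for i, lv in enumerate(dv.levels) if lv in kept}
                df[rv.name] = df[rv.name].map(
                    lambda c: remap[int(c)] if not pd.isna(c) else np.nan
                )
                data = Dataset(schema, df)
                report.append(
                    f"mapped unseen level(s) {unseen} of {rv.name!r} to missing"
                )
            data = _reorder_levels(data, rv.name, rv.levels, report)
    # project onto the reference feature order (+ any response/meta present)
    keep = [v for v in data.schema if v.role != FEATURE]
    ordered = [data.var(v.name) for v in ref_features] + keep
    return Dataset(ordered, data.df[[v.name for v in ordered]]), report
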