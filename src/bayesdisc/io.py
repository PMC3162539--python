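"""Table and model I/O plus applying learned interval boundaries to data.

Reads delimited text tables (comma or tab, dialect sniffed from the header),
maps target levels to class indices in first-appearance order, serializes
per-variable discretization models to JSON, and codes raw values into
interval indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DiscretizationModel, EBDParams

__all__ = [
    "InputError",
    "RawDataset",
    "DiscretizedTable",
    "read_table",
    "apply_model",
    "transform",
    "write_models",
    "read_models",
]

_KNOWN_METHODS = {"ebd", "fi"}


class InputError(ValueError):
    """Malformed or inconsistent user input (maps to CLI exit code 2)."""


@dataclass
class RawDataset:
    """A parsed table: numeric predictors plus an integer-coded target."""

    X: pd.DataFrame
    y: np.ndarray
    target_levels: list[str]
    target_name: str

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def n_classes(self) -> int:
        return len(self.target_levels)


@dataclass
class DiscretizedTable:
    """Per-variable interval codes for a set of instances.

    ``codes[i, v]`` is the interval index of instance i under variable v's
    model; ``widths[v]`` is that model's interval count W.
    """

    codes: np.ndarray
    variables: list[str]
    widths: list[int]
    y: np.ndarray | None = None
    n_classes: int | None = None

    @property
    def n(self) -> int:
        return int(self.codes.shape[0])


def read_table(path: str | Path, target_column: str) -> RawDataset:
    """Read a CSV/TSV with a header row into a :class:`RawDataset`.

    Predictor columns must parse as numbers with no missing cells (the
    Bayesian score's closed form assumes complete data); target levels are
    mapped to 0..J-1 in order of first appearance.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty") from None
    except Exception as exc:  # malformed delimited text
        raise InputError(f"{path}: cannot parse table ({exc})") from None
    if df.empty:
        raise InputError(f"{path}: table has no data rows")
    if target_column not in df.columns:
        raise InputError(
            f"{path}: target column {target_column!r} not found "
            f"(columns: {', '.join(map(str, df.columns))})"
        )
    target_raw = df[target_column]
    if target_raw.isna().any():
        row = int(target_raw.isna().idxmax())
        raise InputError(f"{path}: missing target value at row {row}")
    levels = [str(v) for v in pd.unique(target_raw)]
    level_index = {lvl: i for i, lvl in enumerate(levels)}
    y = np.array([level_index[str(v)] for v in target_raw], dtype=np.int64)

    predictors = [c for c in df.columns if c != target_column]
    if not predictors:
        raise InputError(f"{path}: no predictor columns besides the target")
    X = pd.DataFrame(index=df.index)
    for col in predictors:
        raw = df[col]
        if raw.isna().any():
            row = int(raw.isna().idxmax())
            raise InputError(
                f"{path}: missing value at row {row}, column {col!r} "
                "(complete data required)"
            )
        numeric = pd.to_numeric(raw, errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise InputError(
                f"{path}: non-numeric predictor cell at row {row}, column {col!r}: "
                f"{raw.iloc[row]!r}"
            )
        X[col] = numeric.astype(float)
    return RawDataset(X=X, y=y, target_levels=levels, target_name=target_column)


def apply_model(model: DiscretizationModel, values: Sequence[float]) -> np.ndarray:
    """Code values into interval indices 0..W-1.

    A value equal to a cut point belongs to the upper interval; values
    outside the training range clamp to the first or last interval.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("cannot code non-finite predictor values")
    return np.searchsorted(model.cut_values, v, side="right").astype(np.int64)


def transform(
    X: pd.DataFrame,
    models: Mapping[str, DiscretizationModel],
    y: np.ndarray | None = None,
    n_classes: int | None = None,
) -> DiscretizedTable:
    """Apply per-variable models to every column they cover."""
    variables = [v for v in models if v in X.columns]
    missing = [v for v in models if v not in X.columns]
    if missing:
        raise InputError(f"models reference absent columns: {', '.join(missing)}")
    codes = np.column_stack(
        [apply_model(models[v], X[v].to_numpy()) for v in variables]
    ) if variables else np.empty((len(X), 0), dtype=np.int64)
    widths = [models[v].W for v in variables]
    return DiscretizedTable(
        codes=codes, variables=variables, widths=widths, y=y, n_classes=n_classes
    )


def write_models(
    path: str | Path,
    models: Mapping[str, DiscretizationModel],
    params: EBDParams | None = None,
    target_levels: Sequence[str] | None = None,
) -> None:
    """Serialize per-variable models to JSON with full-precision cut values."""
    doc: dict = {"format": "bayesdisc-models", "version": 1}
    if params is not None:
        alpha = np.atleast_1d(np.asarray(params.alpha, dtype=float))
        doc["lambda"] = params.lam
        doc["alpha"] = float(alpha[0]) if alpha.size == 1 else alpha.tolist()
    if target_levels is not None:
        doc["target_levels"] = list(target_levels)
    doc["models"] = {
        name: {
            "method": m.method,
            "n_intervals": m.W,
            "boundaries": list(m.boundaries),
            "cut_values": [float(c) for c in m.cut_values],
            "interval_counts": m.interval_counts.astype(int).tolist(),
            "log_score": None if m.log_score is None else float(m.log_score),
        }
        for name, m in models.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_models(
    path: str | Path,
) -> tuple[dict[str, DiscretizationModel], EBDParams | None, list[str] | None]:
    """Round-trip counterpart of :func:`write_models`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(
            f"{path}: malformed model file at line {exc.lineno}, column {exc.colno}"
        ) from None
    if not isinstance(doc, dict) or doc.get("format") != "bayesdisc-models":
        raise InputError(f"{path}: not a bayesdisc model file")
    params = None
    if "lambda" in doc:
        params = EBDParams(lam=doc["lambda"], alpha=doc.get("alpha", 1.0))
    levels = doc.get("target_levels")
    models: dict[str, DiscretizationModel] = {}
    for name, rec in doc.get("models", {}).items():
        method = rec.get("method")
        if method not in _KNOWN_METHODS:
            raise InputError(
                f"{path}: unknown method tag {method!r} for variable {name!r}"
            )
        models[name] = DiscretizationModel(
            boundaries=tuple(int(b) for b in rec["boundaries"]),
            cut_values=np.asarray(rec["cut_values"], dtype=float),
            interval_counts=np.asarray(rec["interval_counts"], dtype=np.int64),
            log_score=rec.get("log_score"),
            method=method,
        )
    return models, params, levels
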