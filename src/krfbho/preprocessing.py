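"""Tabular and image preprocessing for clinical prediction.

Provides the :class:`FeatureTable` container used across the package, CSV
input/output for fused sensor tables, k-nearest-neighbour imputation of
missing cells, min-max and z-score scaling, correlation-based redundancy
removal, binary presence encoding, and flattening of class-labelled image
directories into 64x64 grayscale feature rows.

Missing values are represented by NaN throughout.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EncodingError, ImputationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
DISCRETE = "discrete"

#: side length of the square grayscale raster every image is resized to
IMAGE_SIDE = 64


@dataclass
class FeatureTable:
    """Named, typed feature columns for one subject per row.

    ``values`` is an ``(n_samples, n_features)`` float array with NaN as the
    missing marker. ``column_kinds`` tags each column ``"continuous"`` or
    ``"discrete"``; discrete columns may contain only integer values or NaN.
    ``target`` is an optional per-row binary label in {0, 1}.
    """

    column_names: list[str]
    column_kinds: list[str]
    values: np.ndarray
    target: Optional[np.ndarray] = None
    target_name: str = "target"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValidationError("column names must be unique")
        if len(self.column_names) != self.values.shape[1]:
            raise ValidationError("column_names length must match values width")
        if len(self.column_kinds) != len(self.column_names):
            raise ValidationError("column_kinds length must match column_names")
        for kind in self.column_kinds:
            if kind not in (CONTINUOUS, DISCRETE):
                raise ValidationError(f"unknown column kind {kind!r}")
        if self.target is not None:
            self.target = np.asarray(self.target)
            if self.target.shape != (self.values.shape[0],):
                raise ValidationError("target length must equal n_samples")
            if self.target.size and not np.isin(self.target, (0, 1)).all():
                raise ValidationError("target values must be binary {0,1}")
            self.target = self.target.astype(int)
        for j, kind in enumerate(self.column_kinds):
            if kind == DISCRETE:
                col = self.values[:, j]
                observed = col[~np.isnan(col)]
                if observed.size and not np.all(observed == np.round(observed)):
                    raise ValidationError(
                        f"discrete column {self.column_names[j]!r} has "
                        "non-integer entries"
                    )

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.column_names),
            list(self.column_kinds),
            self.values.copy(),
            None if self.target is None else self.target.copy(),
            self.target_name,
        )

    def select_columns(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            [self.column_names[j] for j in idx],
            [self.column_kinds[j] for j in idx],
            self.values[:, idx].copy(),
            None if self.target is None else self.target.copy(),
            self.target_name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.target is not None:
            df[self.target_name] = self.target
        return df


def _infer_kinds(values: np.ndarray) -> list[str]:
    kinds = []
    for j in range(values.shape[1]):
        col = values[:, j]
        observed = col[~np.isnan(col)]
        if observed.size and np.all(observed == np.round(observed)):
            kinds.append(DISCRETE)
        else:
            kinds.append(CONTINUOUS)
    return kinds


def read_fused_csv(
    path: str | Path,
    target_column: Optional[str] = None,
    missing_sentinels: Sequence[str] = ("NA",),
) -> FeatureTable:
    """Read a comma-separated table with a header row into a FeatureTable.

    Empty fields and any string in ``missing_sentinels`` become the missing
    marker. When ``target_column`` is given, that column is removed from the
    features and stored as the binary target.
    """
    path = Path(path)
    sentinels = set(missing_sentinels) | {""}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty, header row required")
        header = [h.strip() for h in header]
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"{path}: row {lineno} has {len(rec)} fields, "
                    f"expected {len(header)}"
                )
            parsed = []
            for name, fieldval in zip(header, rec):
                fieldval = fieldval.strip()
                if fieldval in sentinels:
                    parsed.append(math.nan)
                else:
                    try:
                        parsed.append(float(fieldval))
                    except ValueError:
                        raise ParseError(
                            f"{path}: row {lineno}, column {name!r}: "
                            f"non-numeric field {fieldval!r}"
                        ) from None
            rows.append(parsed)

    values = np.array(rows, dtype=float) if rows else np.empty((0, len(header)))
    target = None
    names = header
    if target_column is not None:
        if target_column not in header:
            raise ValidationError(
                f"target column {target_column!r} not in header {header}"
            )
        tcol = header.index(target_column)
        target = values[:, tcol]
        if np.isnan(target).any():
            raise ValidationError("target column contains missing values")
        if target.size and not np.isin(target, (0.0, 1.0)).all():
            bad = sorted(set(target[~np.isin(target, (0.0, 1.0))]))
            raise ValidationError(f"target column contains non-binary values {bad}")
        values = np.delete(values, tcol, axis=1)
        names = [h for i, h in enumerate(header) if i != tcol]

    table = FeatureTable(
        names,
        _infer_kinds(values),
        values,
        None if target is None else target.astype(int),
        target_name=target_column or "target",
    )
    return table


def _format_cell(v: float, kind: str) -> str:
    if math.isnan(v):
        return ""
    if kind == DISCRETE:
        return str(int(round(v)))
    return repr(float(v))


def write_fused_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as CSV; ``read_fused_csv`` round-trips it."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = list(table.column_names)
        if table.target is not None:
            header.append(table.target_name)
        writer.writerow(header)
        for i in range(table.n_samples):
            row = [
                _format_cell(table.values[i, j], table.column_kinds[j])
                for j in range(table.n_features)
            ]
            if table.target is not None:
                row.append(str(int(table.target[i])))
            writer.writerow(row)


def impute_missing_knn(table: FeatureTable, k: int) -> FeatureTable:
    """Fill missing cells from the k nearest fully observed rows.

    Distance to a candidate row is Euclidean over the columns observed in the
    query row; candidates are restricted to fully observed rows; ties are
    broken by lower row index. Each missing cell becomes the mean of that
    column over the k selected neighbours; in discrete columns the mean is
    rounded to the nearest integer code so the column stays integer-valued.
    ``k`` is clamped to the number of complete rows. Observed cells are never
    modified.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    values = table.values
    missing = np.isnan(values)
    if not missing.any():
        return table.copy()
    complete_rows = np.flatnonzero(~missing.any(axis=1))
    if complete_rows.size == 0:
        raise ImputationError("no fully observed row exists; cannot impute")
    k_eff = min(k, complete_rows.size)
    out = values.copy()
    for r in np.flatnonzero(missing.any(axis=1)):
        observed = ~missing[r]
        diffs = values[complete_rows][:, observed] - values[r, observed]
        dists = np.sqrt((diffs**2).sum(axis=1))
        # stable sort on distance keeps lower row index first on ties
        order = np.argsort(dists, kind="stable")[:k_eff]
        neighbours = complete_rows[order]
        for c in np.flatnonzero(missing[r]):
            fill = values[neighbours, c].mean()
            if table.column_kinds[c] == DISCRETE:
                fill = np.round(fill)
            out[r, c] = fill
    result = table.copy()
    result.values = out
    return result


def normalize_minmax(column: np.ndarray) -> np.ndarray:
    """Min-max scale a column to [0, 1]; a constant column maps to zeros."""
    col = np.asarray(column, dtype=float)
    if np.isnan(col).any():
        raise ValidationError("normalize_minmax requires no missing values")
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def standardize_zscore(column: np.ndarray) -> np.ndarray:
    """Center and scale by the population standard deviation.

    A constant column (zero variance) maps to zeros.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        raise ValidationError("standardize_zscore requires at least 2 elements")
    if np.isnan(col).any():
        raise ValidationError("standardize_zscore requires no missing values")
    mu = col.mean()
    sigma = col.std(ddof=0)
    if sigma == 0.0:
        return np.zeros_like(col)
    return (col - mu) / sigma


def remove_redundant_features(
    table: FeatureTable, threshold: float = 0.95
) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Drop the later of any feature pair with |Pearson r| above threshold.

    Exact duplicate columns are always dropped regardless of threshold.
    Returns the reduced table and a report of (kept, dropped, correlation)
    triples. Idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    X = table.values
    if np.isnan(X).any():
        raise ValidationError("remove_redundant_features requires no missing values")
    kept: list[int] = []
    report: list[tuple[str, str, float]] = []
    for j in range(table.n_features):
        dropped = False
        for i in kept:
            xi, xj = X[:, i], X[:, j]
            if np.array_equal(xi, xj):
                report.append((table.column_names[i], table.column_names[j], 1.0))
                dropped = True
                break
            si, sj = xi.std(), xj.std()
            if si == 0.0 or sj == 0.0:
                continue  # correlation undefined against a constant column
            r = float(np.corrcoef(xi, xj)[0, 1])
            if abs(r) > threshold:
                report.append((table.column_names[i], table.column_names[j], r))
                dropped = True
                break
        if not dropped:
            kept.append(j)
    return table.select_columns(kept), report


def encode_presence(
    column: Sequence, absence=None
) -> tuple[np.ndarray, dict]:
    """Map a two-level column onto {0, 1}.

    ``absence`` designates the level coded 0; by default the smaller value
    (sorted order) is absence. Columns already in {0, 1} pass through
    unchanged. Missing entries (NaN) are preserved. Returns the encoded
    column and the mapping used.
    """
    arr = np.asarray(column, dtype=object)

    def _is_missing(v) -> bool:
        return isinstance(v, float) and math.isnan(v)

    levels = sorted({v for v in arr.ravel() if not _is_missing(v)}, key=str)
    if len(levels) > 2:
        raise EncodingError(f"column has {len(levels)} distinct values, expected <= 2")
    if set(levels) <= {0, 1, 0.0, 1.0}:
        out = np.array(
            [math.nan if _is_missing(v) else float(v) for v in arr], dtype=float
        )
        return out, {0: 0, 1: 1}
    if absence is None:
        absence = levels[0]
    elif absence not in levels:
        raise EncodingError(f"absence value {absence!r} not found in column")
    mapping = {lv: (0 if lv == absence else 1) for lv in levels}
    out = np.array(
        [math.nan if _is_missing(v) else float(mapping[v]) for v in arr],
        dtype=float,
    )
    return out, mapping


def load_image_dir(root: str | Path) -> FeatureTable:
    """Flatten a directory of class-labelled images into a FeatureTable.

    ``root`` must contain one subdirectory per class. Every image is
    converted to grayscale, resized to 64x64, flattened row-major and scaled
    to [0, 1], giving 4096 features per row. Class codes follow sorted
    subdirectory name order. Unreadable files are skipped with a warning.
    """
    from PIL import Image, UnidentifiedImageError

    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValidationError(f"{root} contains no class subdirectories")
    rows: list[np.ndarray] = []
    targets: list[int] = []
    for code, cdir in enumerate(class_dirs):
        for f in sorted(p for p in cdir.iterdir() if p.is_file()):
            try:
                with Image.open(f) as img:
                    gray = img.convert("L").resize((IMAGE_SIDE, IMAGE_SIDE))
                    rows.append(np.asarray(gray, dtype=float).ravel() / 255.0)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping unreadable image %s: %s", f, exc)
                continue
            targets.append(code)
    if not rows:
        raise ValidationError(f"no readable images under {root}")
    n_px = IMAGE_SIDE * IMAGE_SIDE
    names = [f"px{i:04d}" for i in range(n_px)]
    return FeatureTable(
        names,
        [CONTINUOUS] * n_px,
        np.vstack(rows),
        np.array(targets, dtype=int),
    )
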