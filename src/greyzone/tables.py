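"""Agreement-table data model, validation, and file I/O.

An agreement table cross-classifies the ratings of two raters who assign the
same ``n`` subjects to ``R`` ordered levels.  Rows index Rater I, columns
Rater II; cell ``(i, j)`` counts the subjects placed at level ``i`` by
Rater I and level ``j`` by Rater II.  All public reporting uses 1-based
``(i, j)`` cell indices, with level labels shown when provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import TableValidationError

__all__ = ["AgreementTable", "from_counts", "read_table", "write_table"]


@dataclass(frozen=True)
class AgreementTable:
    """A validated R x R table of cross-classified counts.

    Attributes
    ----------
    counts
        Integer count matrix ``n_ij`` (rows = Rater I, columns = Rater II).
    labels
        Ordered level names, or ``None`` when the levels are anonymous
        ordinal positions ``1..R``.
    """

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts))

    @property
    def R(self) -> int:
        """Number of ordinal levels."""
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Total number of rated subjects."""
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        """Cell proportions ``p_ij = n_ij / n``."""
        return self.counts / self.n

    @property
    def row_margins(self) -> np.ndarray:
        """Marginal proportions of Rater I, ``p_i.``."""
        return self.p.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Marginal proportions of Rater II, ``p_.j``."""
        return self.p.sum(axis=0)

    def level_name(self, position: int) -> str:
        """Human-readable name of a 1-based level position."""
        if self.labels is not None:
            return str(self.labels[position - 1])
        return str(position)

    def transpose(self) -> "AgreementTable":
        """Swap the two raters."""
        return AgreementTable(self.counts.T.copy(), self.labels)


def from_counts(
    matrix: Sequence[Sequence[int]] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> AgreementTable:
    """Build and validate an :class:`AgreementTable` from a count grid.

    Raises
    ------
    TableValidationError
        If the grid is not square with R >= 2, contains negative or
        non-integer entries, is all zero, or the label list does not
        match the grid size.
    """
    arr = np.asarray(matrix)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise TableValidationError(
            f"agreement table must be square, got shape {arr.shape}"
        )
    if arr.shape[0] < 2:
        raise TableValidationError("agreement table needs at least 2 levels")
    if not np.issubdtype(arr.dtype, np.number):
        raise TableValidationError("agreement table entries must be numeric")
    if np.any(~np.isfinite(arr.astype(float))):
        raise TableValidationError("agreement table entries must be finite")
    if np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise TableValidationError("agreement table entries must be integers")
    arr = arr.astype(np.int64)
    if np.any(arr < 0):
        bad = np.argwhere(arr < 0)[0]
        raise TableValidationError(
            f"negative count at cell ({bad[0] + 1}, {bad[1] + 1})"
        )
    if arr.sum() == 0:
        raise TableValidationError("agreement table is all zero (n must be > 0)")
    if labels is not None:
        labels = tuple(str(x) for x in labels)
        if len(labels) != arr.shape[0]:
            raise TableValidationError(
                f"{len(labels)} labels supplied for a {arr.shape[0]}-level table"
            )
    return AgreementTable(arr, labels)


def _sorted_levels(keys: set) -> list:
    """Sort level keys numerically when possible, else lexicographically."""
    try:
        return sorted(keys, key=float)
    except (TypeError, ValueError):
        return sorted(keys, key=str)


def read_table(
    path: str | Path,
    format: str = "matrix-csv",
    labels: Sequence[str] | None = None,
) -> AgreementTable:
    """Read an agreement table from disk.

    ``matrix-csv`` is a square numeric grid with an optional header row and
    label column (auto-detected by non-numeric content).  ``long-csv`` has
    columns ``rater1,rater2,count``; duplicate (rater1, rater2) pairs are
    summed and levels are ordered by sorted label unless an explicit
    ``labels`` order is given.
    """
    path = Path(path)
    if format in ("matrix-csv", "matrix"):
        return _read_matrix_csv(path, labels)
    if format in ("long-csv", "long"):
        return _read_long_csv(path, labels)
    raise TableValidationError(f"unknown table format: {format!r}")


def _is_numeric(values) -> bool:
    try:
        np.asarray(values, dtype=float)
        return True
    except (TypeError, ValueError):
        return False


def _read_matrix_csv(path: Path, labels: Sequence[str] | None) -> AgreementTable:
    try:
        raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    # a blank corner cell marks a header row plus a label column
    corner_blank = bool(pd.isna(raw.iat[0, 0]))
    if corner_blank:
        has_header = has_index = True
    else:
        has_header = not _is_numeric(raw.iloc[0].dropna().tolist())
        first_body = raw.iloc[1:] if has_header else raw
        has_index = not _is_numeric(first_body.iloc[:, 0].dropna().tolist())
    body = raw.iloc[1:] if has_header else raw
    file_labels = None
    if has_index:
        file_labels = [str(x) for x in body.iloc[:, 0]]
        body = body.iloc[:, 1:]
    elif has_header:
        file_labels = [str(x) for x in raw.iloc[0].dropna()]
    if body.isna().any().any():
        raise TableValidationError(f"ragged or incomplete rows in {path}")
    if not _is_numeric(body.to_numpy().ravel().tolist()):
        raise TableValidationError(f"non-numeric cell in matrix CSV {path}")
    counts = body.to_numpy(dtype=float)
    return from_counts(counts, labels if labels is not None else file_labels)


def _read_long_csv(path: Path, labels: Sequence[str] | None) -> AgreementTable:
    try:
        df = pd.read_csv(path, dtype={"rater1": str, "rater2": str})
    except Exception as exc:  # pragma: no cover
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    required = {"rater1", "rater2", "count"}
    if not required.issubset(df.columns):
        raise TableValidationError(
            f"long-csv needs columns rater1,rater2,count; found {list(df.columns)}"
        )
    agg = df.groupby(["rater1", "rater2"], sort=False)["count"].sum()
    if labels is not None:
        order = [str(x) for x in labels]
        seen = set(df["rater1"]) | set(df["rater2"])
        missing = seen - set(order)
        if missing:
            raise TableValidationError(
                f"levels {sorted(missing)} in file are absent from the label order"
            )
    else:
        order = [str(x) for x in _sorted_levels(set(df["rater1"]) | set(df["rater2"]))]
    R = len(order)
    pos = {lab: k for k, lab in enumerate(order)}
    counts = np.zeros((R, R), dtype=np.int64)
    for (a, b), c in agg.items():
        counts[pos[str(a)], pos[str(b)]] += int(c)
    return from_counts(counts, order)


def write_table(
    table: AgreementTable, path: str | Path, format: str = "matrix-csv"
) -> None:
    """Serialize a table so that :func:`read_table` round-trips the counts."""
    path = Path(path)
    labels = list(table.labels) if table.labels is not None else None
    if format in ("matrix-csv", "matrix"):
        df = pd.DataFrame(table.counts)
        if labels is not None:
            df.index = labels
            df.columns = labels
            df.to_csv(path)
        else:
            df.to_csv(path, header=False, index=False)
    elif format in ("long-csv", "long"):
        names = labels if labels is not None else [str(i + 1) for i in range(table.R)]
        rows = [
            {"rater1": names[i], "rater2": names[j], "count": int(table.counts[i, j])}
            for i in range(table.R)
            for j in range(table.R)
            if table.counts[i, j] > 0
        ]
        pd.DataFrame(rows, columns=["rater1", "rater2", "count"]).to_csv(
            path, index=False
        )
    else:
        raise TableValidationError(f"unknown table format: {format!r}")
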