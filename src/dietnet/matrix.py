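"""Diet matrices, validation, readers/writers and the minimum-prey filter.

The central object is the :class:`DietMatrix`: a non-negative integer count
matrix with individual foragers as rows and prey taxa as columns, one matrix
per season.  All downstream statistics (overlap, clustering, nestedness,
checkerboard) operate on this object or on its presence/absence reduction,
the :class:`BinaryMatrix`.

Orientation is a documented contract: rows are individuals, columns are taxa.
Transposed input is not auto-detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DietMatrix",
    "BinaryMatrix",
    "CovariateTable",
    "DietMatrixError",
    "ParseError",
    "ValidationError",
    "DegenerateMatrixError",
    "read_diet_matrix",
    "write_diet_matrix",
    "filter_min_prey",
    "to_binary",
    "export_pajek_net",
    "export_pajek_partition",
]


class DietMatrixError(Exception):
    """Base class for diet-matrix errors."""


class ParseError(DietMatrixError):
    """A cell failed to parse as a non-negative integer."""


class ValidationError(DietMatrixError):
    """Labels or counts violate the DietMatrix invariants."""


class DegenerateMatrixError(DietMatrixError):
    """Fewer than 2 rows or 2 columns remain after filtering."""


@dataclass(frozen=True)
class DietMatrix:
    """Individuals x prey-taxa count matrix for one season.

    Invariants (enforced by :meth:`validated`): counts are non-negative
    integers, at least 2 rows and 2 columns, no all-zero row or column, and
    unique id lists matching the matrix dimensions.
    """

    counts: np.ndarray
    individual_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    season: str = ""

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.individual_ids), columns=list(self.taxon_ids)
        )

    @classmethod
    def validated(
        cls,
        counts: np.ndarray | Sequence[Sequence[int]],
        individual_ids: Iterable[str],
        taxon_ids: Iterable[str],
        season: str = "",
        drop_empty: bool = True,
    ) -> "DietMatrix":
        """Build a DietMatrix, dropping all-zero rows/columns with a warning.

        Raises ValidationError on negative counts or duplicate/mismatched
        labels and DegenerateMatrixError if fewer than 2 rows or columns
        survive.
        """
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.all(np.isfinite(counts)) or np.any(np.abs(counts - rounded) > 0):
                raise ValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        counts = counts.astype(np.int64, copy=True)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(f"negative count at row {i}, column {j}")

        ind = [str(x) for x in individual_ids]
        tax = [str(x) for x in taxon_ids]
        if len(set(ind)) != len(ind):
            dupes = sorted({x for x in ind if ind.count(x) > 1})
            raise ValidationError(f"duplicate individual ids: {dupes}")
        if len(set(tax)) != len(tax):
            dupes = sorted({x for x in tax if tax.count(x) > 1})
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        if counts.shape != (len(ind), len(tax)):
            raise ValidationError(
                f"label lists ({len(ind)} x {len(tax)}) do not match matrix shape {counts.shape}"
            )

        if drop_empty:
            row_keep = counts.sum(axis=1) > 0
            if not row_keep.all():
                dropped = [ind[i] for i in np.flatnonzero(~row_keep)]
                logger.warning("dropping all-zero rows: %s", dropped)
                counts = counts[row_keep]
                ind = [x for x, k in zip(ind, row_keep) if k]
            col_keep = counts.sum(axis=0) > 0
            if not col_keep.all():
                dropped = [tax[j] for j in np.flatnonzero(~col_keep)]
                logger.warning("dropping all-zero columns: %s", dropped)
                counts = counts[:, col_keep]
                tax = [x for x, k in zip(tax, col_keep) if k]
        else:
            if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
                raise ValidationError("all-zero row or column present")

        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise DegenerateMatrixError(
                f"matrix degenerate after validation: shape {counts.shape} "
                "(need at least 2 individuals and 2 taxa)"
            )
        counts.setflags(write=False)
        return cls(counts, tuple(ind), tuple(tax), season)


@dataclass(frozen=True)
class BinaryMatrix:
    """Presence/absence matrix derived from a DietMatrix (or any 0/1 grid)."""

    cells: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    season: str = ""

    @property
    def row_totals(self) -> np.ndarray:
        """Marginal totals (number of presences per row)."""
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def fill(self) -> int:
        """Total number of presences."""
        return int(self.cells.sum())

    @property
    def is_square_symmetric(self) -> bool:
        c = self.cells
        return (
            c.shape[0] == c.shape[1]
            and self.row_ids == self.col_ids
            and bool(np.array_equal(c, c.T))
        )

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells).astype(np.int8)
        if not np.isin(cells, (0, 1)).all():
            raise ValidationError("binary matrix cells must be 0 or 1")
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)


@dataclass
class CovariateTable:
    """Per-individual and per-taxon covariates used by the factor tests.

    mass_mg: individual -> body mass (mg).
    nest_xy_cm: individual -> (x, y) nest coordinates (cm).
    capture_days: individual -> list of per-prey capture-day scores (1..17,
        1 = first observation day, 17 = last).
    availability: taxon -> environmental availability count for the season.
    taxon_mass_mg: taxon -> mean prey body mass (mg).
    """

    mass_mg: dict[str, float] = field(default_factory=dict)
    nest_xy_cm: dict[str, tuple[float, float]] = field(default_factory=dict)
    capture_days: dict[str, list[int]] = field(default_factory=dict)
    availability: dict[str, float] = field(default_factory=dict)
    taxon_mass_mg: dict[str, float] = field(default_factory=dict)

    def validate(self, day_range: tuple[int, int] = (1, 17)) -> None:
        for k, v in self.mass_mg.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"mass for {k!r} must be non-negative, got {v}")
        for k, v in self.availability.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"availability for {k!r} must be non-negative, got {v}")
        for k, (x, y) in self.nest_xy_cm.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValidationError(f"non-finite nest coordinates for {k!r}")
        lo, hi = day_range
        for k, days in self.capture_days.items():
            for d in days:
                if not lo <= d <= hi:
                    raise ValidationError(
                        f"capture-day score {d} for {k!r} outside {lo}..{hi}"
                    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DIALECT_SEPS = {"csv": ",", "tsv": "\t"}


def read_diet_matrix(
    path: str | Path,
    dialect: str | None = None,
    sheet: str | int = 0,
    season: str | None = None,
) -> DietMatrix:
    """Read a diet matrix from delimited text (CSV/TSV) or an Excel sheet.

    Layout contract: first row = taxon labels, first column = individual
    labels, cells = integer prey counts.  All-zero rows/columns are dropped
    with a logged warning.  ``dialect`` is one of ``csv``, ``tsv`` or
    ``excel``; by default it is inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {
            ".csv": "csv",
            ".tsv": "tsv",
            ".txt": "tsv",
            ".xlsx": "excel",
            ".xls": "excel",
        }.get(suffix, "csv")
    if dialect == "excel":
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    elif dialect in _DIALECT_SEPS:
        df = pd.read_csv(path, sep=_DIALECT_SEPS[dialect], index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    counts = np.zeros(df.shape, dtype=np.int64)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            try:
                value = int(cell)
                if value != float(cell):
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"cell at row {df.index[i]!r}, column {df.columns[j]!r} "
                    f"does not parse as an integer: {cell!r}"
                ) from None
            counts[i, j] = value

    return DietMatrix.validated(
        counts,
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
        season=season if season is not None else path.stem,
    )


def write_diet_matrix(m: DietMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Write a DietMatrix back to delimited text (round-trip safe)."""
    sep = _DIALECT_SEPS.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    m.to_frame().to_csv(path, sep=sep)


def filter_min_prey(m: DietMatrix, threshold: int = 4) -> DietMatrix:
    """Drop individuals with fewer than ``threshold`` prey items.

    The study design excludes poorly sampled foragers before any network
    statistic is computed (default: at least 4 prey per individual).  Columns
    that become all-zero are dropped as well.  Idempotent.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    keep = m.row_totals >= threshold
    if keep.sum() < 2:
        raise DegenerateMatrixError(
            f"only {int(keep.sum())} individuals have >= {threshold} prey"
        )
    return DietMatrix.validated(
        m.counts[keep],
        [x for x, k in zip(m.individual_ids, keep) if k],
        m.taxon_ids,
        season=m.season,
    )


def to_binary(m: DietMatrix) -> BinaryMatrix:
    """Presence/absence reduction: cell = 1 iff count >= 1."""
    return BinaryMatrix(
        (m.counts >= 1).astype(np.int8), m.individual_ids, m.taxon_ids, m.season
    )


# ---------------------------------------------------------------------------
# Pajek export
# ---------------------------------------------------------------------------


def _format_weight(w: float) -> str:
    if float(w) == int(w):
        return str(int(w))
    return repr(round(float(w), 10))


def export_pajek_net(graph, path: str | Path) -> None:
    """Export a graph as a Pajek .net file.

    Accepts an overlap network (``node_ids`` + ``weights`` attributes), a
    square symmetric BinaryMatrix (one-mode graph), or a rectangular
    BinaryMatrix (two-mode graph, ``*Vertices total n_rows``).  Vertices are
    1-based with quoted labels; edges are written as ``i j w`` with i < j.
    """
    lines: list[str] = []
    if hasattr(graph, "weights") and hasattr(graph, "node_ids"):
        ids = list(graph.node_ids)
        w = np.asarray(graph.weights, dtype=float)
        n = len(ids)
        lines.append(f"*Vertices {n}")
        for i, label in enumerate(ids, start=1):
            lines.append(f'{i} "{label}"')
        lines.append("*Edges")
        for i in range(n):
            for j in range(i + 1, n):
                lines.append(f"{i + 1} {j + 1} {_format_weight(w[i, j])}")
    elif isinstance(graph, BinaryMatrix):
        if graph.is_square_symmetric:
            ids = list(graph.row_ids)
            n = len(ids)
            lines.append(f"*Vertices {n}")
            for i, label in enumerate(ids, start=1):
                lines.append(f'{i} "{label}"')
            lines.append("*Edges")
            for i in range(n):
                for j in range(i + 1, n):
                    if graph.cells[i, j]:
                        lines.append(f"{i + 1} {j + 1} 1")
        else:
            rows, cols = list(graph.row_ids), list(graph.col_ids)
            nr, nc = len(rows), len(cols)
            lines.append(f"*Vertices {nr + nc} {nr}")
            for i, label in enumerate(rows + cols, start=1):
                lines.append(f'{i} "{label}"')
            lines.append("*Edges")
            for i in range(nr):
                for j in range(nc):
                    if graph.cells[i, j]:
                        lines.append(f"{i + 1} {nr + j + 1} 1")
    else:
        raise TypeError(f"cannot export {type(graph).__name__} as Pajek")
    Path(path).write_text("\n".join(lines) + "\n")


def export_pajek_partition(labels: Sequence[int], path: str | Path) -> None:
    """Write a Pajek .clu partition file (one cluster number per vertex)."""
    lines = [f"*Vertices {len(labels)}"] + [str(int(c)) for c in labels]
    Path(path).write_text("\n".join(lines) + "\n")
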