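"""Core data model and I/O for per-cell score tables, count matrices and survival tables.

The central container is :class:`CellTable`, a thin validated wrapper around a
:class:`pandas.DataFrame` holding one row per cell: an identifier, spatial
coordinates (any uniform length unit — pixels or µm), the raw
disease-association (DA) score, and optional sample / field-of-view (FOV) /
cell-type annotations. Coordinates are continuous real positions; no pixel
indexing convention applies.

Expression data travel as :class:`ExpressionMatrix`: a sparse genes x cells
count matrix with gene and cell identifier lists, read from / written to
MatrixMarket plus one-id-per-line text files (the 10x triplet convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: canonical column order for cell-table output
_CELL_COLUMNS = ("cell_id", "x", "y", "score_raw")
_OPTIONAL_COLUMNS = ("score_scaled", "sample_id", "fov_id", "cell_type")
_RESULT_COLUMNS = ("score_smoothed", "n_estimates", "covered")


@dataclass
class CellTable:
    """Validated per-cell table.

    Attributes
    ----------
    df
        One row per cell with at least ``cell_id, x, y, score_raw``;
        optionally ``score_scaled`` (in [-1, 1]), ``sample_id``, ``fov_id``,
        ``cell_type``. Row order is preserved by every operation.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _CELL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cell table missing required column(s): {missing}")
        if len(df) == 0:
            raise EmptyInputError("cell table has zero rows")
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
            raise FormatError(f"duplicate cell_id values (e.g. {list(dupes)})")
        for col in ("x", "y", "score_raw"):
            vals = df[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.number) or not np.isfinite(vals).all():
                raise FormatError(f"column {col!r} contains non-finite or non-numeric values")
        if "score_scaled" in df.columns:
            s = df["score_scaled"].to_numpy(dtype=float)
            if np.nanmin(s) < -1 - 1e-9 or np.nanmax(s) > 1 + 1e-9:
                raise FormatError("score_scaled outside [-1, 1]")
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates, input order."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the cell positions."""
        x = self.df["x"].to_numpy(dtype=float)
        y = self.df["y"].to_numpy(dtype=float)
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())

    def with_columns(self, **cols) -> "CellTable":
        """Return a copy with the given columns added/replaced."""
        df = self.df.copy()
        for name, values in cols.items():
            df[name] = values
        return CellTable(df)


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells count matrix with identifier lists."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given cell ids; errors on unknown ids."""
        lookup = {c: i for i, c in enumerate(self.cells)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:
            raise FormatError(f"cell id {exc.args[0]!r} not present in expression matrix") from exc


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cell_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> CellTable:
    """Read a delimited cell table into a validated :class:`CellTable`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row. Delimiter is auto-detected from the
        extension (override with ``sep``).
    column_map
        Maps canonical names (``cell_id, x, y, score_raw`` and optionally
        ``score_scaled, sample_id, fov_id, cell_type``) to the column names
        used in the file. Unmapped canonical names default to themselves.

    Rows with non-finite coordinates or scores are dropped with a logged count;
    zero valid rows is an error.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=_detect_sep(path, sep), float_precision="round_trip")

    rename = {}
    for canonical in _CELL_COLUMNS + _OPTIONAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical in _CELL_COLUMNS:
            raise FormatError(
                f"missing required column {source!r} (mapped to {canonical!r}) in {path.name}"
            )
    df = df.rename(columns=rename)
    keep = [c for c in _CELL_COLUMNS + _OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep]

    n_in = len(df)
    for col in ("x", "y", "score_raw", "score_scaled"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    numeric = [c for c in ("x", "y", "score_raw") if c in df.columns]
    valid = np.isfinite(df[numeric].to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropped %d of %d rows with non-finite coordinates/scores", n_dropped, n_in)
    df = df.loc[valid].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"no valid rows in {path.name} ({n_in} read, {n_dropped} dropped)")
    df["cell_id"] = df["cell_id"].astype(str)
    return CellTable(df)


def write_cell_table(table, path: str | Path, sep: str | None = None) -> None:
    """Write a :class:`CellTable` (or a smoothed result's table) as delimited text.

    Numeric fields are serialized with shortest-roundtrip precision, so a
    write → read cycle reproduces values exactly (well under the 1e-12
    relative tolerance the format contract promises).
    """
    path = Path(path)
    df = table.df if hasattr(table, "df") else table
    ordered = [c for c in _CELL_COLUMNS + _OPTIONAL_COLUMNS + _RESULT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, sep=_detect_sep(path, sep), index=False)


def read_expression_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket count matrix with gene and cell id sidecar files."""
    mat = scipy.io.mmread(str(matrix_path))
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix header declares {mat.shape} but id files list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    return ExpressionMatrix(genes=genes, cells=cells, counts=mat)


def write_expression_mtx(
    expr: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write an :class:`ExpressionMatrix` in MatrixMarket + sidecar form."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(expr.counts))
    Path(genes_path).write_text("\n".join(expr.genes) + "\n")
    Path(cells_path).write_text("\n".join(expr.cells) + "\n")


def read_survival_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a patient survival table: patient_id, time, event[, score].

    ``time`` is a nonnegative duration in the unit the caller declares
    (typically months); ``event`` is 1 for an observed death, 0 censored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), float_precision="round_trip")
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"survival table missing column(s): {sorted(missing)}")
    if (df["time"] < 0).any():
        raise FormatError("survival times must be nonnegative")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event must be 0 (censored) or 1 (death observed)")
    return df
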