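"""Spatial smoothing of per-cell disease-association scores.

Imaging-based spatial transcriptomics platforms produce per-cell scores that
can jump abruptly between adjacent cells because of technical noise and local
variability in transcript capture. This module post-processes such scores with
two closely related estimators:

SWiS (Spatial Window Smoothing)
    A rectangular window of width ``a`` and height ``b`` slides over the
    tissue with stride ``c`` along both axes. Inside each window, only cells
    in the *core* — the window minus an internal margin of width ``p``
    (padding) — receive an estimate, and only if the core holds at least
    ``n_min`` cells; each core cell's local estimate is the unweighted mean of
    the scaled scores of its ``k`` nearest neighbours (Euclidean distance)
    inside the window, excluding the cell itself. Because windows overlap, a
    cell can collect several local estimates; its final smoothed score is
    their arithmetic mean. Cells that land in no core keep their scaled score
    (default) or are excluded, per ``uncovered_policy``.

FoVS (Field-of-View Smoothing)
    For platforms whose tissue is tiled into native fields of view (FOVs,
    e.g. CosMx), each FOV plays the role of one window with no padding: the
    whole FOV is its own core, kNN runs FOV-locally, and every smoothed cell
    has exactly one estimate. Results across FOVs are concatenated to
    reconstruct the full tissue.

Both estimators are fully deterministic: kNN ties at the k-th neighbour are
broken by ascending cell index, and no randomness enters anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidBoundsError, PreconditionError
from .io_spatial import CellTable

logger = logging.getLogger(__name__)

#: defaults used for the Xenium analyses: 1000 x 1000 unit windows, stride 500,
#: padding 100, at least 50 core cells, 5 nearest neighbours.
XENIUM_DEFAULTS = dict(width=1000.0, height=1000.0, stride=500.0, padding=100.0, n_min=50, k=5)

#: neighbour count used for FOV-based smoothing of CosMx data.
COSMX_FOV_K = 50


@dataclass(frozen=True)
class SmoothingParams:
    """Window geometry and neighbourhood parameters for SWiS.

    Parameters
    ----------
    width, height
        Window extent along x and y, in the coordinate unit of the data.
    stride
        Shift between consecutive window origins along both axes.
    padding
        Internal margin excluded from the core on every side; must satisfy
        ``2 * padding < width`` and ``2 * padding < height``.
    n_min
        Minimum number of core cells for a window to contribute estimates.
    k
        Number of nearest neighbours averaged per core cell.
    neighbor_pool
        ``"window"`` (default): neighbours are searched among all window
        members; ``"core"``: restricted to core cells.
    uncovered_policy
        ``"raw_score"`` (default): cells covered by no core keep their scaled
        score; ``"exclude"``: they are dropped from the output.
    """

    width: float = 1000.0
    height: float = 1000.0
    stride: float = 500.0
    padding: float = 100.0
    n_min: int = 50
    k: int = 5
    neighbor_pool: str = "window"
    uncovered_policy: str = "raw_score"

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.stride > 0):
            raise PreconditionError("width, height and stride must be positive")
        if self.padding < 0:
            raise PreconditionError("padding must be nonnegative")
        if not (2 * self.padding < self.width and 2 * self.padding < self.height):
            raise PreconditionError("padding must satisfy 2p < width and 2p < height")
        if self.n_min < 1 or self.k < 1:
            raise PreconditionError("n_min and k must be >= 1")
        if self.neighbor_pool not in ("window", "core"):
            raise PreconditionError("neighbor_pool must be 'window' or 'core'")
        if self.uncovered_policy not in ("raw_score", "exclude"):
            raise PreconditionError("uncovered_policy must be 'raw_score' or 'exclude'")


@dataclass
class Window:
    """One placed window: origin, member cells and core cells.

    Membership uses half-open intervals ``[x0, x0+width) x [y0, y0+height)``
    (and likewise for the core, shrunk by the padding), so that a cell sitting
    exactly on the lower data bound is never lost. ``member_idx`` and
    ``core_idx`` are positional indices into the cell table, ascending.
    """

    x0: float
    y0: float
    index: int
    member_idx: np.ndarray = field(repr=False)
    core_idx: np.ndarray = field(repr=False)


@dataclass
class SmoothedResult:
    """Output of a smoothing run.

    ``df`` carries the input columns plus ``score_smoothed``, ``n_estimates``
    (how many window cores contributed) and ``covered`` (at least one
    estimate). Input row order is preserved; with ``uncovered_policy =
    "exclude"`` uncovered rows are absent.
    """

    df: pd.DataFrame = field(repr=False)
    n_windows: int = 0
    n_windows_skipped: int = 0
    n_under_k: int = 0  # estimates computed from fewer than k neighbours

    @property
    def n_covered(self) -> int:
        return int(self.df["covered"].sum())

    @property
    def n_fallback(self) -> int:
        return int((~self.df["covered"]).sum())


def scale_scores(score_raw: Iterable[float]) -> np.ndarray:
    """Min-max scale raw scores linearly onto [-1, 1].

    ``s' = 2 (s - min) / (max - min) - 1``; a constant vector maps to all
    zeros. Order-preserving, endpoints map to -1 and +1 exactly.
    """
    s = np.asarray(list(score_raw) if not isinstance(score_raw, np.ndarray) else score_raw, dtype=float)
    if s.size == 0:
        raise EmptyInputError("cannot scale an empty score vector")
    if not np.isfinite(s).all():
        raise PreconditionError("scores must be finite")
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.zeros_like(s)
    return 2.0 * (s - lo) / (hi - lo) - 1.0


def _axis_origins(lo: float, hi: float, extent: float, stride: float) -> list[float]:
    """Regular grid of origins plus a clamp-to-cover terminal origin.

    Origins ``lo + m*stride`` are kept while the window still fits
    (``origin + extent <= hi``); if the last regular window's far edge stops
    short of ``hi`` — or the window is larger than the data extent — one final
    origin at ``max(lo, hi - extent)`` is appended so every cell strip is
    reachable.
    """
    origins: list[float] = []
    m = 0
    while lo + m * stride + extent <= hi:
        origins.append(lo + m * stride)
        m += 1
    if not origins or origins[-1] + extent < hi:
        origins.append(max(lo, hi - extent))
    return origins


def enumerate_windows(
    bounds: tuple[float, float, float, float], params: SmoothingParams
) -> list[tuple[float, float]]:
    """Window origins covering the bounding box, row-major (y outer, x inner).

    ``bounds`` is ``(xmin, xmax, ymin, ymax)`` from the cell table. At least
    one origin is returned for any non-inverted bounds.
    """
    xmin, xmax, ymin, ymax = bounds
    if xmax < xmin or ymax < ymin:
        raise InvalidBoundsError(f"inverted bounds: {bounds}")
    xs = _axis_origins(xmin, xmax, params.width, params.stride)
    ys = _axis_origins(ymin, ymax, params.height, params.stride)
    return [(x0, y0) for y0 in ys for x0 in xs]


def assign_window(
    table: CellTable, origin: tuple[float, float], params: SmoothingParams, index: int = 0
) -> Window:
    """Compute member and core cell sets for the window at ``origin``."""
    x0, y0 = origin
    x = table.df["x"].to_numpy(dtype=float)
    y = table.df["y"].to_numpy(dtype=float)
    a, b, p = params.width, params.height, params.padding
    member = (x >= x0) & (x < x0 + a) & (y >= y0) & (y < y0 + b)
    core = member & (x >= x0 + p) & (x < x0 + a - p) & (y >= y0 + p) & (y < y0 + b - p)
    return Window(
        x0=x0,
        y0=y0,
        index=index,
        member_idx=np.flatnonzero(member),
        core_idx=np.flatnonzero(core),
    )


def local_knn_estimates(
    xy: np.ndarray,
    scores: np.ndarray,
    core_idx: np.ndarray,
    pool_idx: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-core-cell kNN mean of scaled scores within a neighbour pool.

    For each core cell, the estimate is the unweighted mean over its ``k``
    nearest pool cells (Euclidean distance, self excluded). Distance ties are
    broken by ascending cell index. Cells with fewer than ``k`` available
    neighbours use all of them (counted in the third return value); a core
    cell with an empty pool besides itself gets no estimate.

    Returns
    -------
    (estimated_core_idx, estimates, n_under_k)
    """
    if len(core_idx) == 0:
        return core_idx, np.empty(0), 0
    pool_xy = xy[pool_idx]
    pool_scores = scores[pool_idx]
    est_idx: list[int] = []
    est_val: list[float] = []
    n_under_k = 0
    # pool_idx is ascending, so a stable argsort on distance breaks exact
    # distance ties by ascending cell index.
    for ci in core_idx:
        d = np.hypot(pool_xy[:, 0] - xy[ci, 0], pool_xy[:, 1] - xy[ci, 1])
        d[pool_idx == ci] = np.inf  # self-exclusion (id-based, duplicates at
        # identical coordinates remain eligible neighbours)
        order = np.argsort(d, kind="stable")
        n_avail = int(np.isfinite(d).sum())
        if n_avail == 0:
            continue
        if n_avail < k:
            n_under_k += 1
        take = order[: min(k, n_avail)]
        est_idx.append(int(ci))
        est_val.append(float(pool_scores[take].mean()))
    return np.array(est_idx, dtype=int), np.array(est_val), n_under_k


def _require_scaled(table: CellTable) -> np.ndarray:
    if "score_scaled" not in table.df.columns:
        raise PreconditionError(
            "score_scaled missing: call scale_scores / add a score_scaled column first"
        )
    return table.df["score_scaled"].to_numpy(dtype=float)


def _finalize(
    table: CellTable,
    est_sum: np.ndarray,
    est_count: np.ndarray,
    scaled: np.ndarray,
    uncovered_policy: str,
    **counters,
) -> SmoothedResult:
    covered = est_count > 0
    smoothed = np.where(covered, est_sum / np.maximum(est_count, 1), scaled)
    df = table.df.copy()
    df["score_scaled"] = scaled
    df["score_smoothed"] = smoothed
    df["n_estimates"] = est_count
    df["covered"] = covered
    if uncovered_policy == "exclude":
        if not covered.any():
            logger.warning("all cells uncovered and uncovered_policy='exclude': empty result")
        df = df.loc[covered].reset_index(drop=True)
    return SmoothedResult(df=df, **counters)


def swis_smooth(table: CellTable, params: SmoothingParams | None = None) -> SmoothedResult:
    """Run the full sliding-window smoothing pass over a cell table.

    Requires ``score_scaled`` (see :func:`scale_scores`). Enumerates windows
    over the data bounding box, skips windows whose core holds fewer than
    ``params.n_min`` cells, computes per-window kNN estimates for core cells,
    and averages each cell's estimates across the windows that produced one.
    Output row order matches input order.
    """
    params = params or SmoothingParams()
    scaled = _require_scaled(table)
    xy = table.xy
    logger.info(
        "SWiS: width=%g height=%g stride=%g padding=%g n_min=%d k=%d pool=%s",
        params.width, params.height, params.stride, params.padding,
        params.n_min, params.k, params.neighbor_pool,
    )
    origins = enumerate_windows(table.bounds(), params)
    est_sum = np.zeros(table.n)
    est_count = np.zeros(table.n, dtype=int)
    n_skipped = 0
    n_under_k = 0
    for j, origin in enumerate(origins):
        win = assign_window(table, origin, params, index=j)
        if len(win.core_idx) < params.n_min:
            n_skipped += 1
            continue
        pool = win.member_idx if params.neighbor_pool == "window" else win.core_idx
        idx, vals, under_k = local_knn_estimates(xy, scaled, win.core_idx, pool, params.k)
        n_under_k += under_k
        est_sum[idx] += vals
        est_count[idx] += 1
    return _finalize(
        table, est_sum, est_count, scaled, params.uncovered_policy,
        n_windows=len(origins), n_windows_skipped=n_skipped, n_under_k=n_under_k,
    )


def fovs_smooth(
    table: CellTable,
    k: int = COSMX_FOV_K,
    n_min: int = 1,
    uncovered_policy: str = "raw_score",
) -> SmoothedResult:
    """Smooth within each native field of view instead of sliding windows.

    Each FOV is one window with no padding, so its full cell set is its own
    core; FOVs with fewer than ``n_min`` cells are skipped and their cells
    fall under ``uncovered_policy``. Every smoothed cell has exactly one
    estimate, so the cross-window averaging stage is the identity. Equivalent
    to running :func:`swis_smooth` separately per FOV with padding 0 and a
    single all-covering window.
    """
    if "fov_id" not in table.df.columns or table.df["fov_id"].isna().any():
        raise PreconditionError("fovs_smooth requires a complete fov_id column")
    if k < 1 or n_min < 1:
        raise PreconditionError("k and n_min must be >= 1")
    scaled = _require_scaled(table)
    xy = table.xy
    est_sum = np.zeros(table.n)
    est_count = np.zeros(table.n, dtype=int)
    n_skipped = 0
    n_under_k = 0
    groups = table.df.groupby("fov_id", sort=False, observed=True).indices
    for fov, idx in groups.items():
        idx = np.sort(np.asarray(idx, dtype=int))
        if len(idx) < n_min:
            n_skipped += 1
            logger.warning("FOV %r skipped: %d cells < n_min=%d", fov, len(idx), n_min)
            continue
        got, vals, under_k = local_knn_estimates(xy, scaled, idx, idx, k)
        n_under_k += under_k
        est_sum[got] += vals
        est_count[got] += 1
    return _finalize(
        table, est_sum, est_count, scaled, uncovered_policy,
        n_windows=len(groups), n_windows_skipped=n_skipped, n_under_k=n_under_k,
    )


def smooth_cell_table(
    table: CellTable,
    mode: str = "swis",
    params: SmoothingParams | None = None,
    fov_k: int = COSMX_FOV_K,
    fov_n_min: int = 1,
) -> SmoothedResult:
    """Scale raw scores if needed, then dispatch to SWiS or FoVS."""
    if "score_scaled" not in table.df.columns:
        table = table.with_columns(score_scaled=scale_scores(table.df["score_raw"].to_numpy()))
    if mode == "swis":
        return swis_smooth(table, params)
    if mode == "fovs":
        policy = (params or SmoothingParams()).uncovered_policy
        return fovs_smooth(table, k=fov_k, n_min=fov_n_min, uncovered_policy=policy)
    raise PreconditionError(f"unknown smoothing mode {mode!r}")
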