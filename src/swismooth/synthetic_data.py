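"""Synthetic spatial-transcriptomics fixtures with known ground truth.

Real per-cell disease-association scores are a smooth tissue-level signal
buried in cell-level technical noise. The generator emulates exactly that: a
uniform spatial point pattern over a rectangular tissue, a smooth latent risk
field built from Gaussian bumps (so smoothing has a genuine bias–variance
trade-off, unlike a step function), additive iid Gaussian noise per cell,
an optional regular FOV tiling, and a negative-binomial count matrix with
differential-expression genes planted between high- and low-field regions.

One integer seed drives everything through independent spawned substreams
(coordinates, noise, counts), so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InvalidBoundsError, PreconditionError
from .io_spatial import CellTable, ExpressionMatrix

#: default tissue rectangle, in the same arbitrary unit as the window geometry;
#: spans several default-sized windows in each direction.
DEFAULT_BOUNDS = (0.0, 4000.0, 0.0, 3000.0)


@dataclass(frozen=True)
class GaussianBumpField:
    """Smooth latent risk field: a sum of isotropic Gaussian bumps.

    ``field(x, y) = sum_m amplitude_m * exp(-((x-cx_m)^2+(y-cy_m)^2) / (2 ls_m^2))``

    The default bumps are placed so pre-noise field values span roughly
    [-1, 1] across the default tissue rectangle, mimicking scaled
    disease-association scores with both a high-risk and a low-risk region.
    """

    centers: tuple[tuple[float, float], ...] = ((1000.0, 1000.0), (3000.0, 2200.0), (3400.0, 600.0))
    amplitudes: tuple[float, ...] = (1.0, -1.0, 0.7)
    length_scales: tuple[float, ...] = (700.0, 800.0, 450.0)

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.amplitudes) == len(self.length_scales)):
            raise PreconditionError("centers, amplitudes and length_scales must align")
        if any(ls <= 0 for ls in self.length_scales):
            raise PreconditionError("length scales must be positive")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), amp, ls in zip(self.centers, self.amplitudes, self.length_scales):
            out += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * ls**2))
        return out


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic instance."""

    field_values: np.ndarray = field(repr=False)
    field_spec: GaussianBumpField = field(default_factory=GaussianBumpField)
    noise_sd: float = 0.3
    de_gene_idx: np.ndarray | None = None
    effect: float = 0.0
    seed: int = 0


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cells(
    n: int,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    field_spec: GaussianBumpField | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[CellTable, SyntheticTruth]:
    """Uniform random cells with ``score_raw = field(x, y) + N(0, noise_sd)``.

    Returns the cell table and a :class:`SyntheticTruth` carrying the exact
    field value at every cell, for evaluating smoothing error against truth.
    """
    if n < 1:
        raise PreconditionError("need at least one cell")
    xmin, xmax, ymin, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise InvalidBoundsError(f"degenerate bounds {bounds}")
    field_spec = field_spec or GaussianBumpField()
    rng_xy, rng_noise, _ = _substreams(seed, 3)
    x = rng_xy.uniform(xmin, xmax, size=n)
    y = rng_xy.uniform(ymin, ymax, size=n)
    truth_vals = field_spec(x, y)
    noise = rng_noise.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    table = CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"cell_{i:06d}" for i in range(n)],
                "x": x,
                "y": y,
                "score_raw": truth_vals + noise,
                "sample_id": sample_id,
            }
        )
    )
    truth = SyntheticTruth(
        field_values=truth_vals, field_spec=field_spec, noise_sd=noise_sd, seed=seed
    )
    return table, truth


def assign_fov_grid(table: CellTable, n_cols: int, n_rows: int) -> CellTable:
    """Tile the bounding box into an even ``n_cols x n_rows`` FOV grid.

    Tiles are half-open; cells on the far bounding edge are clipped into the
    last tile so every cell receives exactly one ``fov_id``.
    """
    if n_cols < 1 or n_rows < 1:
        raise PreconditionError("grid dimensions must be >= 1")
    xmin, xmax, ymin, ymax = table.bounds()
    w = (xmax - xmin) or 1.0
    h = (ymax - ymin) or 1.0
    col = np.clip(((table.df["x"] - xmin) / w * n_cols).astype(int), 0, n_cols - 1)
    row = np.clip(((table.df["y"] - ymin) / h * n_rows).astype(int), 0, n_rows - 1)
    fov = (row * n_cols + col).astype(int)
    return table.with_columns(fov_id=[f"F{i:03d}" for i in fov])


def simulate_expression(
    table: CellTable,
    truth: SyntheticTruth,
    n_genes: int = 100,
    frac_de: float = 0.2,
    effect: float = 2.0,
    baseline_mean: float = 1.0,
    dispersion: float = 2.0,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Negative-binomial counts with DE genes planted in the high-field region.

    Every gene shares one baseline mean; for each planted gene the mean is
    multiplied by ``2**effect`` in cells whose true field value lies in the
    top quartile. Counts are NB with ``variance = mu + mu^2 / dispersion``
    (i.e. NB(size=dispersion, p=dispersion/(dispersion+mu))).

    Returns the matrix and the planted gene indices; the indices are also
    recorded on ``truth``.
    """
    if not 0.0 <= frac_de <= 1.0:
        raise PreconditionError("frac_de must lie in [0, 1]")
    if baseline_mean <= 0 or dispersion <= 0:
        raise PreconditionError("baseline_mean and dispersion must be positive")
    seed = truth.seed if seed is None else seed
    _, _, rng_counts = _substreams(seed, 3)
    n_cells = table.n
    n_de = int(round(frac_de * n_genes))
    de_idx = rng_counts.choice(n_genes, size=n_de, replace=False) if n_de else np.empty(0, int)
    de_idx = np.sort(de_idx)

    hi_threshold = np.quantile(truth.field_values, 0.75)
    hi_cells = truth.field_values >= hi_threshold

    mu = np.full((n_genes, n_cells), float(baseline_mean))
    mu[np.ix_(de_idx, np.flatnonzero(hi_cells))] *= 2.0**effect
    p = dispersion / (dispersion + mu)
    counts = rng_counts.negative_binomial(dispersion, p)
    expr = ExpressionMatrix(
        genes=[f"gene_{g:04d}" for g in range(n_genes)],
        cells=list(table.df["cell_id"]),
        counts=sp.csr_matrix(counts),
    )
    truth.de_gene_idx = de_idx
    truth.effect = effect
    return expr, de_idx


def simulate_survival(
    n_patients: int = 100,
    horizon: float = 36.0,
    auc_strength: float = 1.5,
    censor_frac: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient survival table whose risk score is informative of early death.

    Event times are exponential with a rate increasing in a standard-normal
    patient score (rate multiplied by ``exp(auc_strength * score)``); a
    fraction of patients is censored uniformly before their event. Used to
    exercise horizon binarization and ROC-AUC end to end.
    """
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n_patients)
    base_rate = np.log(2.0) / horizon  # median survival at the horizon for score 0
    time = rng.exponential(1.0 / (base_rate * np.exp(auc_strength * score)))
    event = np.ones(n_patients, dtype=int)
    censored = rng.random(n_patients) < censor_frac
    time = np.where(censored, time * rng.random(n_patients), time)
    event[censored] = 0
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "time": time,
            "event": event,
            "score": score,
        }
    )
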