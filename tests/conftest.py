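import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from swismooth import CellTable, scale_scores


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_table():
    """Deterministic 12-cell table on a 40 x 30 rectangle with scaled scores."""
    rng = np.random.default_rng(7)
    n = 12
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": rng.uniform(0, 40, n),
            "y": rng.uniform(0, 30, n),
            "score_raw": rng.normal(size=n),
        }
    )
    table = CellTable(df)
    return table.with_columns(score_scaled=scale_scores(df["score_raw"].to_numpy()))


def random_instance(rng, n=None):
    """A random cell table + smoothing parameter dict spanning edge cases.

    Parameter draws intentionally include windows larger than the tissue,
    k exceeding window populations, and n_min values that skip windows.
    """
    n = n or int(rng.integers(5, 600))
    span_x = float(rng.uniform(20, 2500))
    span_y = float(rng.uniform(20, 2500))
    xy = np.column_stack([rng.uniform(0, span_x, n), rng.uniform(0, span_y, n)])
    width = float(rng.uniform(span_x / 6, span_x * 1.3))
    height = float(rng.uniform(span_y / 6, span_y * 1.3))
    params = dict(
        width=width,
        height=height,
        stride=float(rng.uniform(min(width, height) / 4, max(width, height))),
        padding=float(rng.uniform(0, 0.45) * min(width, height)),
        n_min=int(rng.integers(1, 30)),
        k=int(rng.choice([1, 2, 5, 50])),
        neighbor_pool=str(rng.choice(["window", "core"])),
    )
    scores = rng.uniform(-1, 1, n)
    return xy, scores, params
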