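"""Small shared helpers for building in-memory fixtures."""

import numpy as np
import pandas as pd

from swismooth import CellTable


def make_table(xy, scaled_scores, ids=None, raw=None) -> CellTable:
    """CellTable from coordinates and already-scaled scores."""
    xy = np.asarray(xy, dtype=float)
    scaled = np.asarray(scaled_scores, dtype=float)
    n = len(xy)
    if ids is None:
        ids = range(n)
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"cell_{i}" for i in ids],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "score_raw": scaled if raw is None else np.asarray(raw, dtype=float),
                "score_scaled": scaled,
            }
        )
    )
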