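"""Sliding-window smoothing of noisy per-cell scores on a synthetic tissue.

Simulates 5,000 cells on a 4000 x 3000 rectangle whose true risk field is a
sum of Gaussian bumps, adds per-cell Gaussian noise (SD 0.3), scales the
noisy scores to [-1, 1], and smooths them with the default window settings
(1000 x 1000 windows, stride 500, padding 100, >= 50 core cells, 5 nearest
neighbours). The printed mean-squared errors are measured against the true
field mapped through the same scaling: smoothing should cut the MSE roughly
threefold, showing that window-local kNN averaging removes cell-level noise
while keeping the regional signal.
"""

import numpy as np

from swismooth import SmoothingParams, scale_scores, simulate_cells, swis_smooth

table, truth = simulate_cells(n=5000, noise_sd=0.3, seed=42)
raw = table.df["score_raw"].to_numpy()
lo, hi = raw.min(), raw.max()
truth_scaled = 2 * (truth.field_values - lo) / (hi - lo) - 1

table = table.with_columns(score_scaled=scale_scores(raw))
result = swis_smooth(table, SmoothingParams())

mse_raw = np.mean((table.df["score_scaled"].to_numpy() - truth_scaled) ** 2)
mse_smooth = np.mean((result.df["score_smoothed"].to_numpy() - truth_scaled) ** 2)

print(f"windows placed:   {result.n_windows} ({result.n_windows_skipped} skipped)")
print(f"cells covered:    {result.n_covered} of {table.n} "
      f"({result.n_fallback} keep their scaled score)")
print(f"MSE vs truth:     raw {mse_raw:.4f} -> smoothed {mse_smooth:.4f} "
      f"(ratio {mse_smooth / mse_raw:.2f})")
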