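# Methods

## Model and procedure

The input is a per-cell table from an imaging-based spatial transcriptomics
experiment: cell id, planar coordinates (xᵢ, yᵢ) in a uniform unit (pixels or
µm — the algorithm only compares distances, so the unit is arbitrary but must
match the window parameters), and a raw per-cell disease-association score
produced upstream by a transfer-learning model. Scores are first min–max
scaled onto [−1, 1] (a constant vector maps to all zeros); scaling is
order-preserving, so quantile-based stratification is unaffected by it.

**SWiS.** Windows of width `a` and height `b` are placed on a grid of
origins starting at (xmin, ymin) with stride `c` along both axes. Origins
are kept while the window still fits inside the data range; if the last
regular window stops short of the data maximum on an axis (or the window is
larger than the tissue), one final origin clamped to `max(min, max − extent)`
is appended so no strip of cells is unreachable. Within a window, the *core*
excludes an internal margin of width `p` on every side; windows whose core
holds fewer than `n_min` cells contribute nothing. Each core cell's local
estimate is the unweighted mean of the scaled scores of its `k` nearest
window members (Euclidean distance, self excluded); a cell's final smoothed
score is the arithmetic mean of its estimates across all windows that
produced one. Cells never covered by a core keep their scaled score and are
flagged, or are dropped when the exclude policy is selected.

**FoVS.** When the platform tiles the tissue into fields of view, each FOV
is treated as one window with `p = 0` (the whole FOV is its own core), kNN
runs on FOV-local coordinates, and every smoothed cell has exactly one
estimate, making the final averaging the identity. FoVS is therefore exactly
SWiS applied per FOV with a single all-covering window — a property the test
suite checks bitwise.

**Downstream statistics.** Low/high-risk cells are those strictly below /
above the 25th / 75th empirical percentile of the smoothed score (thresholds
computable pooled, per sample, or on a reference sample applied to others —
published section-pair counts are not always consistent with pure per-sample
quartiles, so the scope is explicit rather than guessed). Differential
expression between strata: genes expressed in at least `ceil(0.10·n)` cells,
per-cell library-size scaling to the median total count then log1p,
two-sided Wilcoxon rank-sum per gene, Benjamini–Hochberg across the filtered
family, log2 fold changes `log2((μ_high+1)/(μ_low+1))` (and high vs
remaining cells) with pseudo-count 1 to tolerate zero means. Sample
comparisons use the Wilcoxon rank-sum test on all cells; risk-cell counts
between two samples use the 1-df Pearson chi-square with Yates continuity
correction (the published statistic for the liver section pair, 34873.64,
matches the corrected value of the printed counts; a flag disables the
correction). Patient-level evaluation binarizes overall survival at a
horizon (default 36 months): death at or before the horizon → 1, follow-up
beyond it → 0, censored at or before it → excluded as uninformative; the
ROC-AUC of patient scores is the usual pair-counting probability with ties
counted half.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `width`, `height` (`a`, `b`) | 1000 | window extent, coordinate units; sets the spatial scale below which structure is averaged away |
| `stride` (`c`) | 500 | origin spacing; `a/c = 2` gives up to 4 overlapping cores per cell |
| `padding` (`p`) | 100 | core margin; guarantees core cells a complete in-window neighbourhood |
| `n_min` | 50 | minimum core population; guards kNN against sparse windows |
| `k` | 5 (SWiS), 50 (FoVS) | neighbourhood size; larger k = stronger smoothing |
| `q_low`/`q_high` | 0.25 / 0.75 | risk quantiles (type-7 empirical quantiles, strict inequalities) |
| `min_frac` | 0.10 | gene filter fraction |
| `horizon` | 36 months | survival binarization horizon |

## Numerical and design choices

* **Boundary convention.** Window and core membership use half-open
  intervals `[x₀, x₀+a) × [y₀, y₀+b)`. A strict-on-both-sides convention
  would silently drop cells sitting exactly on the lower data bound (always
  the case for grid-aligned data); the half-open choice keeps them. The
  cell at the exact data maximum can still be uncovered and then falls back
  to its scaled score — measure-zero for continuous coordinates.
* **Neighbour pool.** The neighbour search pool defaults to all window
  members: the padding exists precisely so that core cells have a full
  neighbourhood inside the window. `neighbor_pool="core"` restricts the
  search to core cells for sensitivity analysis.
* **Determinism.** kNN distance ties are broken by ascending cell index
  (stable sort on distance over an index-ordered pool); self-exclusion is by
  identity, so coincident duplicate coordinates remain eligible neighbours;
  cells with fewer than `k` available neighbours use all of them (counted in
  the run summary) rather than being dropped — `n_min` already guards
  against sparse windows. Smoothing contains no randomness.
* **Wilcoxon p-value paths.** Combined n ≤ 12: exact enumeration of all
  splits of the (midranked) combined sample, with two-sided
  p = P(|W − E W| ≥ |obs − E W|) — on tie-free data this equals the classic
  twice-the-smaller-tail exact value, and it remains valid under ties
  (identical samples give p = 1). Tie-free combined n ≤ 50: the exact
  Mann–Whitney distribution. Otherwise: normal approximation with tie
  correction and continuity correction.
* **Quantiles** are pinned to linear interpolation between order statistics
  (NumPy default, R type 7) so stratum counts reproduce across languages.
* **DE test choice.** The per-gene test is the Wilcoxon rank-sum, consistent
  with the package's other comparisons and standard single-cell practice;
  the normalization (median-library-size + log1p) is isolated in
  `normalize_counts` so an alternative convention can be swapped in.

## What the synthetic generator emulates — and what it does not

`simulate_cells` draws uniform cell positions on a rectangle and adds iid
Gaussian noise (default SD 0.3) to a smooth latent risk field built from
Gaussian bumps whose amplitudes span roughly [−1, 1] — a smooth field rather
than a step function, so smoothing error shows a genuine bias–variance
trade-off. `simulate_expression` draws negative-binomial counts
(variance = μ + μ²/dispersion; NB(size = dispersion,
p = dispersion/(dispersion+μ))) with one shared baseline mean and planted DE
genes whose mean is multiplied by 2^effect in top-field-quartile cells. One
seed drives coordinates, noise and counts through independently spawned
substreams.

Not emulated: cell-type niches and segmentation artifacts, spatially
correlated noise, gene–gene correlation, per-cell capture-efficiency
gradients, and irregular (non-grid) FOV geometries. Passing tests therefore
demonstrate correctness of the algorithms and recovery under the stated
noise model, not performance on any particular tissue.

Problem sizes used by the test and acceptance runs — 5,000 cells for noise
reduction (10 seeds), 2,000 cells × 100–500 genes for the DE properties
(5 seeds each), ≤1,000 cells for brute-force equivalence — were chosen as
the smallest sizes at which the measured properties are stable across seeds.

## Known limitations

* Windows are axis-aligned rectangles on a regular grid; no support for
  rotated tissues or irregular FOV polygons (FOV membership is taken from
  the `fov_id` column as given).
* The brute-force-verified implementation is O(cells-per-window² ) per
  window in the worst case; it is intended for the per-window populations
  typical of imaging platforms (hundreds to a few thousand cells), not for
  a single window containing millions of cells.
* Risk thresholds are empirical quantiles of the analyzed data; they are not
  transferable between experiments unless the reference-sample scope is used
  deliberately.
* The DA scores themselves are taken as given; their calibration and the
  upstream model's preprocessing are outside this package.
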