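# swismooth

Spatial post-processing of per-cell disease-association scores from
imaging-based single-cell spatial transcriptomics (Xenium, CosMx, ...).

Transfer-learning models such as DEGAS assign each cell a scalar
disease-association (DA) score from its expression profile alone. Adjacent
cells in the same biological niche can nonetheless show abruptly different
scores because of technical noise and uneven transcript capture. This
package smooths those scores using the tissue's spatial coordinates and runs
the downstream risk-cell statistics:

* **SWiS — sliding-window kNN smoothing.** Scores are min–max scaled to
  [−1, 1]. A window of width *a* and height *b* slides over the tissue with
  stride *c*; inside each window, cells in the *core* (window minus an
  internal padding *p*) — and only when the core holds at least *n*<sub>min</sub>
  cells — receive a local estimate: the unweighted mean of the scaled scores
  of their *k* nearest neighbours within the window (self excluded),

  S̃ᵢ⁽ʲ⁾ = (1/k) Σ_{cₗ ∈ Nₖ(cᵢ)} Sₗˢᶜᵃˡᵉᵈ.

  Overlapping windows give a cell several estimates; its final score is
  their arithmetic mean, S̃ᵢ = (1/|Sᵢ|) Σⱼ S̃ᵢ⁽ʲ⁾. Cells covered by no core
  keep their scaled score (or are excluded, by policy). Defaults:
  *a* = *b* = 1000, *c* = 500, *p* = 100, *n*<sub>min</sub> = 50, *k* = 5.
* **FoVS — field-of-view smoothing.** For platforms with native tissue
  tiles, each FOV is one window with no padding (*k* = 50 by default).
* **Risk stratification and statistics.** Cells below the 25th percentile of
  the smoothed score are low-risk, above the 75th high-risk; differential
  expression between strata (≥10%-of-cells gene filter, library-size + log1p
  normalization, two-sided Wilcoxon rank-sum, Benjamini–Hochberg); 2×2
  Yates-corrected chi-square of risk-cell counts between samples; per-cell-type
  mean scores; 3-year survival binarization (censored-before-horizon patients
  excluded) with ROC-AUC.
* **Synthetic data.** Point patterns over a rectangular tissue with a known
  Gaussian-bump risk field plus iid noise, optional FOV tiling, and
  negative-binomial counts with planted DE genes — so every stage is
  testable against ground truth without external datasets.

## Worked example

```bash
python examples/smooth_synthetic_tissue.py
```

```
windows placed:   35 (0 skipped)
cells covered:    4451 of 5000 (549 keep their scaled score)
MSE vs truth:     raw 0.0330 -> smoothed 0.0097 (ratio 0.29)
```

5,000 synthetic cells with noise SD 0.3 are smoothed with the default window
settings: the mean-squared error against the true latent field drops to
about 29% of the raw scores' error. The 549 fallback cells sit in the
padding band along the tissue boundary, which no window core reaches; they
keep their scaled score and are flagged `covered=False`.

Other examples: `fov_smoothing.py` (FoVS and its exact reduction to
per-FOV SWiS), `risk_strata_and_de.py` (quartile strata; recovers 20/20
planted DE genes at BH-adjusted p ≤ 0.05), `group_stats_and_survival.py`
(two-sample Wilcoxon, risk-count chi-square, survival AUC).

The same workflow is scriptable from a shell:

```bash
swismooth simulate --n-cells 5000 --seed 1 --outdir run/
swismooth smooth run/cells.csv --outdir run/         # SWiS defaults
swismooth risk run/smoothed.csv --outdir run/
swismooth de run/risk_labeled.csv --mtx run/counts.mtx \
    --genes run/genes.txt --barcodes run/barcodes.txt --outdir run/
swismooth report run/risk_labeled.csv --out run/report.json
```

Each stage writes a JSON manifest of its parameters and warning counters;
re-running with the same inputs reproduces byte-identical outputs.

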