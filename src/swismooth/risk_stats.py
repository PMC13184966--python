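"""Risk-cell stratification and downstream statistics.

After smoothing, cells are split into low-, mid- and high-risk strata by
empirical quartiles of the smoothed disease-association score (below the 25th
percentile = low, above the 75th = high; strict inequalities on both sides).
This module also carries the statistics run on those strata:

* a gene filter keeping genes expressed in at least 10% of cells,
* per-gene differential expression between the high and low strata
  (library-size normalization + log1p, two-sided Wilcoxon rank-sum,
  Benjamini–Hochberg adjustment, log2 fold changes),
* the Wilcoxon rank-sum test for score comparisons between samples/groups,
* a 2x2 chi-square (Yates-corrected by default) comparing low/high risk-cell
  counts between samples,
* per-cell-type mean association scores,
* 3-year (or arbitrary-horizon) survival binarization with exclusion of
  uninformatively censored patients, and the patient-level ROC-AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, PreconditionError
from .io_spatial import ExpressionMatrix

logger = logging.getLogger(__name__)

#: combined sample size up to which the rank-sum null is enumerated exactly
EXACT_ENUM_MAX_N = 12
#: combined sample size up to which a tie-free exact distribution is used
EXACT_MAX_N = 50


@dataclass
class RiskLabels:
    """Per-cell risk stratum assignment with the thresholds that produced it.

    ``stratum`` holds ``"low"``, ``"mid"`` or ``"high"`` per cell (input
    order); ``thresholds`` maps each grouping unit to its
    ``(q_low_value, q_high_value)`` pair; ``scope`` records how thresholds
    were computed.
    """

    stratum: pd.Series = field(repr=False)
    thresholds: dict = field(default_factory=dict)
    scope: str = "pooled"

    def mask(self, which: str) -> np.ndarray:
        return (self.stratum == which).to_numpy()


def classify_risk(
    scores: Sequence[float],
    groups: Sequence | None = None,
    q_low: float = 0.25,
    q_high: float = 0.75,
    scope: str = "pooled",
    reference: object | None = None,
) -> RiskLabels:
    """Stratify cells into low/mid/high risk by empirical score quantiles.

    Quantiles use linear interpolation between order statistics (NumPy's
    default, R type 7), pinned so threshold counts reproduce across
    implementations. A cell is *low* iff its score is strictly below the
    ``q_low`` quantile and *high* iff strictly above the ``q_high`` quantile;
    everything else (including all cells when scores are constant) is *mid*.

    ``scope`` controls where quantiles are computed: ``"pooled"`` over all
    cells, ``"per_sample"`` within each unit of ``groups``, or
    ``"reference_sample"`` on the cells of ``reference`` only, applied to all.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise EmptyInputError("no scores to classify")
    if scope in ("per_sample", "reference_sample") and groups is None:
        raise PreconditionError(f"scope={scope!r} requires group labels")
    g = pd.Series(groups) if groups is not None else pd.Series(["all"] * s.size)

    def thresholds_of(values: np.ndarray) -> tuple[float, float]:
        if len(values) < 4:
            raise PreconditionError("need at least 4 cells per grouping unit")
        return float(np.quantile(values, q_low)), float(np.quantile(values, q_high))

    stratum = np.full(s.size, "mid", dtype=object)
    thresholds: dict = {}
    if scope == "per_sample":
        for unit, idx in g.groupby(g, sort=False).groups.items():
            idx = np.asarray(idx)
            t_lo, t_hi = thresholds_of(s[idx])
            thresholds[unit] = (t_lo, t_hi)
            stratum[idx[s[idx] < t_lo]] = "low"
            stratum[idx[s[idx] > t_hi]] = "high"
    else:
        if scope == "reference_sample":
            ref_mask = (g == reference).to_numpy()
            if not ref_mask.any():
                raise PreconditionError(f"reference sample {reference!r} not found")
            t_lo, t_hi = thresholds_of(s[ref_mask])
        elif scope == "pooled":
            t_lo, t_hi = thresholds_of(s)
        else:
            raise PreconditionError(f"unknown scope {scope!r}")
        thresholds["(all)"] = (t_lo, t_hi)
        stratum[s < t_lo] = "low"
        stratum[s > t_hi] = "high"
    if all(lo == hi for lo, hi in thresholds.values()):
        logger.warning("degenerate quantiles (constant scores): every cell is 'mid'")
    return RiskLabels(stratum=pd.Series(stratum), thresholds=thresholds, scope=scope)


# --------------------------------------------------------------------------
# differential expression
# --------------------------------------------------------------------------

def gene_filter(
    expr: ExpressionMatrix, cell_idx: np.ndarray | None = None, min_frac: float = 0.10
) -> np.ndarray:
    """Indices of genes expressed (count > 0) in >= ceil(min_frac * n) of the cells.

    ``cell_idx`` restricts the computation to a cell subset (default: all).
    """
    counts = expr.counts if cell_idx is None else expr.counts[:, cell_idx]
    n_cells = counts.shape[1]
    if n_cells == 0:
        raise EmptyInputError("gene filter over an empty cell subset")
    n_pos = counts.getnnz(axis=1)  # counts are nonnegative, so nnz == #(>0)
    return np.flatnonzero(n_pos >= math.ceil(min_frac * n_cells))


def normalize_counts(expr: ExpressionMatrix) -> sp.csr_matrix:
    """Library-size normalization to the median total count, then log1p.

    Standard convention for count matrices ahead of rank-based testing; kept
    in one place so an alternative normalization can be swapped in.
    """
    totals = np.asarray(expr.counts.sum(axis=0)).ravel()
    target = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals, dtype=float), where=totals > 0)
    normed = expr.counts.multiply(sp.csr_matrix(scale[None, :])).tocsr()
    normed.data = np.log1p(normed.data)
    return normed


def differential_expression(
    expr: ExpressionMatrix,
    labels: RiskLabels,
    min_frac: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene high- vs low-risk differential expression.

    Genes failing the expression filter (>= ``min_frac`` of all cells in the
    matrix) are dropped before testing, so the multiple-testing family is the
    filtered gene set. Each kept gene gets a two-sided Wilcoxon rank-sum test
    of normalized expression between the high and low strata, BH adjustment
    across kept genes, and log2 fold changes of mean normalized expression
    with pseudo-count 1 — high vs low and high vs the remaining (mid) cells.

    Returns a DataFrame sorted by (p_adj, -|log2fc_high_vs_low|) with columns:
    gene, mean_high, mean_low, mean_rest, log2fc_high_vs_low,
    log2fc_high_vs_rest, stat, p_raw, p_adj, pass.
    """
    high = labels.mask("high")
    low = labels.mask("low")
    rest = labels.mask("mid")
    if high.sum() < 3 or low.sum() < 3:
        raise PreconditionError(
            f"need >=3 cells per stratum (high={int(high.sum())}, low={int(low.sum())})"
        )
    keep = gene_filter(expr, min_frac=min_frac)
    if keep.size == 0:
        raise EmptyInputError("no genes pass the expression filter")
    normed = normalize_counts(expr)

    rows = []
    for gi in keep:
        vals = np.asarray(normed[gi].todense()).ravel()
        xh, xl = vals[high], vals[low]
        mu_h, mu_l = float(xh.mean()), float(xl.mean())
        mu_r = float(vals[rest].mean()) if rest.any() else float("nan")
        stat, p = wilcoxon_rank_sum(xh, xl)
        rows.append(
            dict(
                gene=expr.genes[gi],
                mean_high=mu_h,
                mean_low=mu_l,
                mean_rest=mu_r,
                log2fc_high_vs_low=math.log2((mu_h + 1) / (mu_l + 1)),
                log2fc_high_vs_rest=math.log2((mu_h + 1) / (mu_r + 1)) if rest.any() else float("nan"),
                stat=stat,
                p_raw=p,
            )
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["pass"] = out["p_adj"] <= alpha
    out = out.sort_values(
        ["p_adj", "log2fc_high_vs_low"],
        key=lambda c: c if c.name == "p_adj" else -c.abs(),
    ).reset_index(drop=True)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise PreconditionError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# two-sample and contingency statistics
# --------------------------------------------------------------------------

def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Rank sum of x in the combined sample, midranks for ties."""
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by enumerating every split of the combined sample.

    Midranks make this valid under ties. The two-sided p is
    P(|W - E[W]| >= |W_obs - E[W]|), which on tie-free data coincides with
    the classic twice-the-smaller-tail value.
    """
    nx = len(x)
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    w_obs = float(ranks[:nx].sum())
    e_w = nx * (len(combined) + 1) / 2.0
    all_w = np.array([sum(c) for c in combinations(ranks, nx)])
    eps = 1e-9
    if alternative == "less":
        return float(np.mean(all_w <= w_obs + eps))
    if alternative == "greater":
        return float(np.mean(all_w >= w_obs - eps))
    return float(np.mean(np.abs(all_w - e_w) >= abs(w_obs - e_w) - eps))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum statistic of x, p-value).

    The p-value path depends on sample size: full enumeration of all splits
    for combined n <= 12 (valid under ties), the tie-free exact Mann–Whitney
    distribution for combined n <= 50 without ties, and the tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise PreconditionError(f"unknown alternative {alternative!r}")
    n = x.size + y.size
    w = _rank_sum_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < n
    if n <= EXACT_ENUM_MAX_N:
        return w, _exact_enumeration_p(x, y, alternative)
    method = "exact" if (n <= EXACT_MAX_N and not has_ties) else "asymptotic"
    p = scipy.stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue
    return w, float(p)


def chi_square_2x2(
    table: Sequence[Sequence[int]], continuity_correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, 1 df.

    Rows are samples/groups, columns the low/high risk strata. The Yates
    continuity correction is applied by default.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise PreconditionError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise PreconditionError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise PreconditionError("zero marginal: chi-square statistic undefined")
    res = scipy.stats.chi2_contingency(t, correction=continuity_correction)
    return float(res[0]), float(res[1])


def group_mean_scores(scores: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Mean score and cell count per group, sorted descending by mean."""
    df = pd.DataFrame({"group": list(groups), "score": np.asarray(scores, dtype=float)})
    if len(df) == 0:
        raise EmptyInputError("no scores")
    out = (
        df.groupby("group", sort=False)["score"]
        .agg(mean_score="mean", n_cells="size")
        .reset_index()
        .sort_values("mean_score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return out


# --------------------------------------------------------------------------
# patient-level survival evaluation
# --------------------------------------------------------------------------

def binarize_survival(records: pd.DataFrame, horizon: float = 36.0) -> pd.DataFrame:
    """Binary survival labels at a horizon, excluding uninformative censoring.

    Label 1: death observed (event=1) at or before ``horizon``. Label 0:
    followed beyond the horizon (surviving past it is observed regardless of
    later censoring). Patients censored (event=0) at or before the horizon
    carry no information about horizon status and are excluded.

    ``horizon`` is in the unit of ``records["time"]`` (36 months = 3 years).
    """
    if horizon <= 0:
        raise PreconditionError("horizon must be positive")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy()
    label = np.where(t > horizon, 0, np.where(e == 1, 1, -1))
    out = records.loc[label >= 0].copy()
    out["label"] = label[label >= 0]
    n_excluded = int((label < 0).sum())
    if n_excluded:
        logger.info("excluded %d patient(s) censored before the horizon", n_excluded)
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC of scores against binary labels.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all
    positive–negative pairs.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise PreconditionError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
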