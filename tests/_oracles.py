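"""Independent reference implementations used as oracles by the test suite.

These deliberately re-derive each quantity from its definition (explicit
window materialization, all-pairs distances, exhaustive enumeration,
pair counting) without calling the package's own code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.stats


def brute_force_swis(
    xy: np.ndarray,
    scaled: np.ndarray,
    width: float,
    height: float,
    stride: float,
    padding: float,
    n_min: int,
    k: int,
    neighbor_pool: str = "window",
):
    """Reference SWiS: materialize every window, all-pairs kNN, explicit averaging.

    Conventions mirror the documented contract: half-open window intervals,
    clamp-to-cover terminal origin per axis, self-exclusion, distance ties
    broken by ascending cell index, fewer-than-k fallback to all available
    neighbours. Returns (smoothed, n_estimates, covered); uncovered cells
    keep their scaled score.
    """
    n = len(xy)
    x, y = xy[:, 0], xy[:, 1]

    def axis_origins(lo, hi, extent, step):
        out, m = [], 0
        while lo + m * step + extent <= hi:
            out.append(lo + m * step)
            m += 1
        if not out or out[-1] + extent < hi:
            out.append(max(lo, hi - extent))
        return out

    estimates: list[list[float]] = [[] for _ in range(n)]
    for y0 in axis_origins(y.min(), y.max(), height, stride):
        for x0 in axis_origins(x.min(), x.max(), width, stride):
            member = [
                i for i in range(n)
                if x0 <= x[i] < x0 + width and y0 <= y[i] < y0 + height
            ]
            core = [
                i for i in member
                if x0 + padding <= x[i] < x0 + width - padding
                and y0 + padding <= y[i] < y0 + height - padding
            ]
            if len(core) < n_min:
                continue
            pool = member if neighbor_pool == "window" else core
            for ci in core:
                cand = [
                    (np.hypot(x[j] - x[ci], y[j] - y[ci]), j) for j in pool if j != ci
                ]
                if not cand:
                    continue
                cand.sort()  # (distance, index): ties break by ascending index
                neigh = [j for _, j in cand[: min(k, len(cand))]]
                estimates[ci].append(float(np.mean(scaled[neigh])))

    smoothed = np.empty(n)
    n_est = np.array([len(e) for e in estimates])
    for i in range(n):
        smoothed[i] = sum(estimates[i]) / len(estimates[i]) if estimates[i] else scaled[i]
    return smoothed, n_est, n_est > 0


def exact_wilcoxon_enumeration(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p over all C(n, nx) splits of the combined sample."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    e_w = nx * (len(combined) + 1) / 2.0
    sums = np.array([sum(c) for c in combinations(ranks, nx)])
    eps = 1e-9
    if alternative == "less":
        return float(np.mean(sums <= w_obs + eps))
    if alternative == "greater":
        return float(np.mean(sums >= w_obs - eps))
    return float(np.mean(np.abs(sums - e_w) >= abs(w_obs - e_w) - eps))


def bh_textbook(p) -> np.ndarray:
    """Step-up BH from the definition: p_(i) * m / i with running minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def auc_pair_counting(scores, labels) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) over all pos-neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def chi2_yates_closed_form(table) -> float:
    """N (|ad - bc| - N/2)^2 / (R1 R2 C1 C2), clipped at zero inside the |.|."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return float(n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d)))
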