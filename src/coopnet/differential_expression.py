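"""Permutation differential expression with the SAM regularised d statistic.

Each post-stimulation time point is compared with the basal state within
one condition.  The statistic is ``d = (mean2 - mean1) / (s + s0)`` with
``s`` the pooled standard error and ``s0`` a small exchangeability
constant chosen by the Tusher procedure (the percentile of the ``s``
distribution minimising the coefficient of variation of the median |d|
across s-quantile windows).  Gene-wise FDR comes from label
permutations: at each |d| threshold the estimated false calls are the
median permutation count of exceedances, divided by the observed calls.
When the design admits fewer distinct label permutations than requested,
all of them are enumerated and the estimate is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .formats_io import ExpressionMatrix

__all__ = ["DeResult", "sam_d", "sam_test"]


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    d: float
    fold_change: float  # difference of log2 group means
    q: float
    direction: str  # up / down / ns


def _pooled_se(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Gene-wise pooled standard error (SAM's s_i); inputs genes x reps."""
    n1, n2 = g1.shape[1], g2.shape[1]
    ss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g2 - g2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return np.sqrt(a * ss)


def sam_d(group1, group2, s0: float = 0.0) -> float:
    """SAM d statistic for one gene: (mean2 - mean1) / (s + s0)."""
    g1 = np.asarray(group1, float)[None, :]
    g2 = np.asarray(group2, float)[None, :]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    s = _pooled_se(g1, g2)[0]
    return float((g2.mean() - g1.mean()) / (s + s0))


def _d_vector(g1: np.ndarray, g2: np.ndarray, s0: float) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (g2.mean(axis=1) - g1.mean(axis=1)) / (_pooled_se(g1, g2) + s0)
    return np.nan_to_num(d, nan=0.0)  # 0/0 (identical constant groups) scores 0


def _choose_s0(g1: np.ndarray, g2: np.ndarray) -> float:
    """Tusher s0: percentile of s minimising the CV of window-median |d|."""
    s = _pooled_se(g1, g2)
    diff = g2.mean(axis=1) - g1.mean(axis=1)
    # windows of s-quantiles within which the median |d| is tracked
    qs = np.quantile(s, np.linspace(0, 1, 101))
    best_s0, best_cv = 0.0, np.inf
    for pct in range(0, 101, 5):
        s0 = float(np.percentile(s, pct))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(np.nan_to_num(diff / (s + s0), nan=0.0))
        meds = []
        for i in range(0, 100, 5):
            m = (s >= qs[i]) & (s <= qs[i + 5])
            if m.sum() >= 2:
                meds.append(np.median(d[m]))
        meds = np.asarray(meds)
        if len(meds) < 2 or meds.mean() == 0:
            continue
        cv = meds.std() / meds.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def sam_test(
    expr: ExpressionMatrix,
    condition: str,
    time_b: float,
    time_a: float = 0.0,
    n_perm: int = 200,
    fdr_cut: float = 0.05,
    seed: int = 0,
) -> list[DeResult]:
    """SAM two-class comparison of ``time_b`` vs basal ``time_a``.

    Returns one :class:`DeResult` per gene, with q the estimated FDR at
    the gene's own |d| threshold and direction split by the sign of the
    fold change among q <= fdr_cut calls.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives unstable FDR estimates", stacklevel=2)
    sub_a = expr.select(condition=condition, time_h=time_a)
    sub_b = expr.select(condition=condition, time_h=time_b)
    g1 = sub_a.data.to_numpy(dtype=float)
    g2 = sub_b.data.to_numpy(dtype=float)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    genes = expr.genes
    n1, n2 = g1.shape[1], g2.shape[1]
    joint = np.hstack([g1, g2])
    n = n1 + n2

    s0 = _choose_s0(g1, g2)
    d_obs = _d_vector(g1, g2, s0)

    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        label_sets = [set(c) for c in combinations(range(n), n1)]
    else:
        rng = np.random.default_rng(seed)
        label_sets = [set(rng.choice(n, size=n1, replace=False).tolist()) for _ in range(n_perm)]
    perm_d = np.empty((len(label_sets), len(genes)))
    for i, idx in enumerate(label_sets):
        a_cols = sorted(idx)
        b_cols = [j for j in range(n) if j not in idx]
        perm_d[i] = _d_vector(joint[:, a_cols], joint[:, b_cols], s0)

    abs_obs = np.abs(d_obs)
    abs_perm_sorted = np.sort(np.abs(perm_d), axis=1)
    n_genes = len(genes)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]  # descending
    # false calls at each threshold: per permutation, #{|d*| >= thr};
    # rows are sorted ascending so a searchsorted per row covers all
    # thresholds at once
    exceed = n_genes - np.vstack(
        [np.searchsorted(row, thresholds, side="left") for row in abs_perm_sorted]
    )
    median_false = np.median(exceed, axis=0)
    observed_calls = np.arange(1, n_genes + 1)
    q_ranked = np.minimum(1.0, median_false / observed_calls)
    # step-up monotonicity: a larger |d| never gets a larger q
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = q_ranked

    fc = g2.mean(axis=1) - g1.mean(axis=1)
    out = []
    for i, g in enumerate(genes):
        if q[i] <= fdr_cut and fc[i] > 0:
            direction = "up"
        elif q[i] <= fdr_cut and fc[i] < 0:
            direction = "down"
        else:
            direction = "ns"
        out.append(DeResult(g, float(d_obs[i]), float(fc[i]), float(q[i]), direction))
    return out
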