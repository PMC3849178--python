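"""Cooperative TF-pair test on expression correlations of shared targets.

Two TFs that act as a physical complex should drive their shared target
genes coherently, so pairs of genes bound by *both* TFs should be more
correlated than pairs of genes bound by either TF alone.  The test pools
within-class gene pairs (both-bound pairs vs single-bound pairs), ranks
the pool by Pearson correlation, and asks whether both-bound pairs are
over-represented in the top fraction of the ranking.  Under the null the
class composition of the top set is multivariate hypergeometric; the
reported p-value is the upper-tail marginal for the both-bound class
(marginals of a multivariate hypergeometric are hypergeometric).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import ExpressionMatrix, Peak, Pwm, TssRecord
from .motif_scan import contains_motif
from .peak_annotation import BindingMatrix, promoter_binding

__all__ = [
    "CoopTestResult",
    "pair_correlations",
    "coop_test",
    "coop_sensitivity",
    "known_partner_screen",
]


@dataclass(frozen=True)
class CoopTestResult:
    tf_a: str
    tf_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_pairs_both: int
    n_pairs_single: int
    top_k: int
    x_observed: int
    p_value: float
    degenerate: bool = False
    status: str = "ok"


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    return np.corrcoef(values)


def pair_correlations(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    condition: str | None = None,
    method: str = "pearson",
) -> dict[frozenset[str], float]:
    """Correlation of every unordered gene pair across the samples of one
    condition (all samples if ``condition`` is None).

    Constant-expression genes are excluded with a warning; self-pairs are
    never reported.
    """
    sub = expr.select(condition=condition) if condition is not None else expr
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in sub.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    vals = sub.data.loc[genes].to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"constant-expression genes excluded: {dropped}", stacklevel=2)
        genes = [g for g, k in zip(genes, keep) if k]
        vals = vals[keep]
    if len(genes) < 2:
        raise ValueError("fewer than 2 usable genes")
    if method == "spearman":
        vals = np.apply_along_axis(stats.rankdata, 1, vals)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    corr = _pearson_matrix(vals)
    out: dict[frozenset[str], float] = {}
    for i, j in combinations(range(len(genes)), 2):
        out[frozenset((genes[i], genes[j]))] = float(corr[i, j])
    return out


def coop_test(
    binding: BindingMatrix,
    expr: ExpressionMatrix,
    tf_a: str | None = None,
    tf_b: str | None = None,
    top_fraction: float = 0.05,
    condition: str | None = None,
    method: str = "pearson",
) -> CoopTestResult:
    """Hypergeometric cooperativity test for a TF pair.

    The pair pool is P_both (pairs within the both-bound gene set) plus
    P_single (pairs within the A-only set and pairs within the B-only
    set); cross-class pairs are excluded.  The pool is ranked by
    correlation descending (ties by lexicographic pair id) and the top
    ``k = ceil(top_fraction * N)`` pairs are tested for over-representation
    of P_both.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must be in (0, 1)")
    if tf_a is None or tf_b is None:
        if len(binding.tfs) != 2:
            raise ValueError("specify tf_a and tf_b unless the binding matrix has exactly 2 TFs")
        tf_a, tf_b = binding.tfs
    both, a_only, b_only = binding.classes(tf_a, tf_b)

    def usable(gs: set[str]) -> list[str]:
        present = sorted(g for g in gs if g in expr.data.index)
        dropped = gs - set(present)
        if dropped:
            warnings.warn(
                f"bound genes missing from expression matrix dropped: {sorted(dropped)}",
                stacklevel=3,
            )
        return present

    both_l, a_l, b_l = usable(both), usable(a_only), usable(b_only)
    base = dict(
        tf_a=tf_a, tf_b=tf_b, n_both=len(both_l), n_a_only=len(a_l), n_b_only=len(b_l)
    )
    if len(both_l) < 2:
        return CoopTestResult(
            **base, n_pairs_both=0, n_pairs_single=0, top_k=0, x_observed=0,
            p_value=1.0, degenerate=True,
        )
    all_genes = both_l + a_l + b_l
    corr = pair_correlations(expr, all_genes, condition=condition, method=method)
    kept = {g for pair in corr for g in pair}
    both_l = [g for g in both_l if g in kept]
    a_l = [g for g in a_l if g in kept]
    b_l = [g for g in b_l if g in kept]

    pairs_both = [frozenset(p) for p in combinations(both_l, 2)]
    pairs_single = [frozenset(p) for p in combinations(a_l, 2)] + [
        frozenset(p) for p in combinations(b_l, 2)
    ]
    n_b, n_s = len(pairs_both), len(pairs_single)
    if n_b == 0:
        return CoopTestResult(
            **base, n_pairs_both=0, n_pairs_single=n_s, top_k=0, x_observed=0,
            p_value=1.0, degenerate=True,
        )
    pool = [(p, corr[p], True) for p in pairs_both] + [
        (p, corr[p], False) for p in pairs_single
    ]
    # rank by r descending; ties by lexicographic pair id
    pool.sort(key=lambda t: (-t[1], tuple(sorted(t[0]))))
    N = len(pool)
    k = math.ceil(top_fraction * N)
    x = sum(1 for _, _, is_both in pool[:k] if is_both)
    p_value = float(stats.hypergeom.sf(x - 1, N, n_b, k))
    return CoopTestResult(
        **base, n_pairs_both=n_b, n_pairs_single=n_s, top_k=k, x_observed=x,
        p_value=min(1.0, p_value),
    )


def coop_sensitivity(
    binding: BindingMatrix,
    expr: ExpressionMatrix,
    tf_a: str | None = None,
    tf_b: str | None = None,
    top_fractions: Sequence[float] = (0.01, 0.05, 0.10),
    condition: str | None = None,
) -> pd.DataFrame:
    """p-value of the cooperativity test across top-fraction cuts.

    The fraction of pairs called "most correlated" is the test's one free
    tuning constant; this report shows how sensitive the conclusion is
    to it.
    """
    rows = []
    for q in top_fractions:
        r = coop_test(binding, expr, tf_a, tf_b, top_fraction=q, condition=condition)
        rows.append({"top_fraction": q, "p_value": r.p_value, "top_k": r.top_k,
                     "x_observed": r.x_observed})
    return pd.DataFrame(rows)


def known_partner_screen(
    primary_tf: str,
    primary_pwm: Pwm,
    partner_pwms: Sequence[Pwm],
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    tss_records: Sequence[TssRecord],
    expr: ExpressionMatrix,
    top_fraction: float = 0.05,
    condition: str | None = None,
    promoter_half_width: int = 500,
    presence_fraction: float = 0.7,
) -> pd.DataFrame:
    """Screen candidate partner TFs for cooperativity with the primary TF.

    For each partner motif, peaks whose sequence contains the partner
    motif define the partner's binding; promoter (+/-500 bp) indicators
    against the primary TF's binding feed the cooperativity test.
    Partners whose motif occurs under no peak are reported with status
    ``"no binding sites"`` rather than a p-value.
    """
    primary_peaks = [
        p for p in peaks
        if p.name in sequences and contains_motif(sequences[p.name], primary_pwm, presence_fraction)
    ]
    rows = []
    for partner in partner_pwms:
        partner_peaks = [
            p for p in peaks
            if p.name in sequences and contains_motif(sequences[p.name], partner, presence_fraction)
        ]
        if not partner_peaks:
            rows.append({
                "tf_a": primary_tf, "tf_b": partner.name, "motif_id": partner.motif_id,
                "status": "no binding sites", "p_value": np.nan,
                "n_both": 0, "n_a_only": 0, "n_b_only": 0, "x_observed": 0, "top_k": 0,
            })
            continue
        binding = promoter_binding(
            {primary_tf: primary_peaks, partner.name: partner_peaks},
            tss_records,
            half_width=promoter_half_width,
        )
        res = coop_test(
            binding, expr, tf_a=primary_tf, tf_b=partner.name,
            top_fraction=top_fraction, condition=condition,
        )
        rows.append({
            "tf_a": res.tf_a, "tf_b": res.tf_b, "motif_id": partner.motif_id,
            "status": "degenerate" if res.degenerate else "ok",
            "p_value": res.p_value, "n_both": res.n_both,
            "n_a_only": res.n_a_only, "n_b_only": res.n_b_only,
            "x_observed": res.x_observed, "top_k": res.top_k,
        })
    return pd.DataFrame(rows)
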