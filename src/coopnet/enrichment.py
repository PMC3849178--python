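"""Preranked GSEA with permutation FWER, and direction-separated
hypergeometric over-representation.

The GSEA enrichment score is the extreme deviation of the weighted
Kolmogorov-Smirnov running sum over the ranked gene list: hit increments
are ``|metric|^p`` normalised over the set, miss decrements ``1/(N - N_H)``.
The null is random same-size gene-label sets (the only valid null for a
preranked metric); NES is sign-stratified, and the family-wise error rate
uses the permutation distribution of the maximum |NES| over the set
collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import GeneSet

__all__ = ["GseaResult", "OverrepResult", "es_score", "gsea_preranked", "fisher_overrep"]


@dataclass(frozen=True)
class GseaResult:
    set_id: str
    es: float
    nes: float
    p_nominal: float
    fwer: float
    n_members: int


@dataclass(frozen=True)
class OverrepResult:
    set_id: str
    direction: str
    k_overlap: int
    n_set: int
    n_de: int
    n_universe: int
    odds_ratio: float
    p: float


def es_score(
    ranked_genes: Sequence[str],
    metric: Sequence[float],
    gene_set: frozenset[str] | set[str],
    weight_p: float = 1.0,
    return_profile: bool = False,
):
    """Weighted KS enrichment score of a gene set on a ranked list.

    ``ranked_genes``/``metric`` must already be sorted by metric
    descending.  Returns the signed extreme deviation of the running sum
    (and optionally the full profile).
    """
    genes = list(ranked_genes)
    metric = np.asarray(metric, float)
    N = len(genes)
    in_set = np.fromiter((g in gene_set for g in genes), dtype=bool, count=N)
    N_H = int(in_set.sum())
    if N_H == 0:
        raise ValueError("gene set has no members in the ranked list")
    if N_H == N:
        raise ValueError("gene set covers the whole universe (miss denominator zero)")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = in_set.astype(float)
        denom = float(N_H)
    steps = hit_w / denom - (~in_set) / (N - N_H)
    profile = np.cumsum(steps)
    i = int(np.argmax(np.abs(profile)))
    es = float(profile[i])
    return (es, profile) if return_profile else es


def _es_batch(in_set_matrix: np.ndarray, w: np.ndarray, N_H: int) -> np.ndarray:
    """ES for many indicator rows at once (shared weights)."""
    n_rows, N = in_set_matrix.shape
    hit_w = in_set_matrix * w[None, :]
    denom = hit_w.sum(axis=1, keepdims=True)
    denom[denom == 0] = N_H
    steps = hit_w / denom - (~in_set_matrix) / (N - N_H)
    prof = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(prof), axis=1)
    return prof[np.arange(n_rows), idx]


def gsea_preranked(
    scores: Mapping[str, float] | Sequence[tuple[str, float]],
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GseaResult]:
    """Preranked GSEA over a collection of gene sets.

    ``scores`` maps gene id to the ranking metric.  Sets are size-filtered
    on their membership within the ranked universe.  For each permutation
    a random same-size gene set is drawn per set; NES divides ES by the
    mean |null ES| of the same sign, and FWER is the fraction of
    permutations whose maximum |null NES| over the collection reaches the
    observed |NES|.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse FWER estimates", stacklevel=2)
    items = list(scores.items()) if isinstance(scores, Mapping) else list(scores)
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    metric = np.array([v for _, v in items], float)
    N = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    w = np.abs(metric) ** weight_p

    kept = []
    for gs in gene_sets:
        members = [g for g in gs.genes if g in gene_index]
        if min_size <= len(members) <= min(max_size, N - 1):
            kept.append((gs.set_id, members))
    if not kept:
        raise ValueError("no gene set passes the size filter")

    rng = np.random.default_rng(seed)
    observed_es = np.empty(len(kept))
    null_nes = np.empty((n_perm, len(kept)))
    nes_obs = np.empty(len(kept))
    p_nom = np.empty(len(kept))
    for si, (set_id, members) in enumerate(kept):
        N_H = len(members)
        in_set = np.zeros(N, dtype=bool)
        in_set[[gene_index[g] for g in members]] = True
        observed_es[si] = _es_batch(in_set[None, :], w, N_H)[0]
        null_idx = np.zeros((n_perm, N), dtype=bool)
        for p in range(n_perm):
            null_idx[p, rng.choice(N, size=N_H, replace=False)] = True
        null_es = _es_batch(null_idx, w, N_H)
        pos = null_es[null_es > 0]
        neg = null_es[null_es < 0]
        mean_pos = pos.mean() if pos.size else 1.0
        mean_neg = np.abs(neg).mean() if neg.size else 1.0
        es = observed_es[si]
        if es >= 0:
            nes_obs[si] = es / mean_pos
            p_nom[si] = float((pos >= es).sum()) / max(pos.size, 1)
        else:
            nes_obs[si] = es / mean_neg
            p_nom[si] = float((neg <= es).sum()) / max(neg.size, 1)
        null_nes[:, si] = np.where(null_es >= 0, null_es / mean_pos, null_es / mean_neg)

    max_null = np.abs(null_nes).max(axis=1)
    results = []
    for si, (set_id, members) in enumerate(kept):
        fwer = float((max_null >= abs(nes_obs[si])).mean())
        results.append(
            GseaResult(
                set_id=set_id,
                es=float(observed_es[si]),
                nes=float(nes_obs[si]),
                p_nominal=float(p_nom[si]),
                fwer=fwer,
                n_members=len(members),
            )
        )
    results.sort(key=lambda r: (r.fwer, r.p_nominal, r.set_id))
    return results


def fisher_overrep(
    gene_set: GeneSet | frozenset[str] | set[str],
    de_genes: set[str],
    universe: set[str],
    direction: str = "up",
) -> OverrepResult:
    """Hypergeometric upper-tail over-representation of a gene set among
    DE genes, within a fixed universe.

    The odds ratio comes from the 2x2 table with a Haldane 0.5 correction
    when any cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    set_id = gene_set.set_id if isinstance(gene_set, GeneSet) else ""
    members = members & universe
    de = de_genes & universe
    k = len(members & de)
    n_set, n_de, n_u = len(members), len(de), len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_set, n_de))
    a, b = k, n_set - k
    c, d = n_de - k, n_u - n_set - n_de + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return OverrepResult(
        set_id=set_id, direction=direction, k_overlap=k, n_set=n_set,
        n_de=n_de, n_universe=n_u, odds_ratio=float(odds), p=min(1.0, p),
    )
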