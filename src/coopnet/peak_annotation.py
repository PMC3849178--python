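"""Peak-to-gene association and ChIP-seq library QC.

Peaks are assigned to the nearest TSS (by peak midpoint, unstranded)
within a symmetric window, defaulting to +/-20 kb.  Promoter binding
indicators use a +/-500 bp window around the TSS.  Library similarity is
summarised by Pearson correlation of log2 read counts with
average-linkage clustering.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats_io import Peak, TssRecord

__all__ = [
    "PeakGeneAssignment",
    "BindingMatrix",
    "filter_peaks",
    "assign_peaks",
    "promoter_binding",
    "correlation_clusters",
]


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: Peak
    gene_id: str
    distance: int


@dataclass
class BindingMatrix:
    """Binary genes x TFs indicator of promoter binding."""

    indicator: pd.DataFrame  # genes x tfs, values in {0, 1}

    @property
    def genes(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.indicator.columns)

    def bound_genes(self, tf: str) -> set[str]:
        col = self.indicator[tf]
        return set(col.index[col == 1])

    def classes(self, tf_a: str, tf_b: str) -> tuple[set[str], set[str], set[str]]:
        """(both, a_only, b_only) gene sets for a TF pair."""
        a, b = self.bound_genes(tf_a), self.bound_genes(tf_b)
        return a & b, a - b, b - a


def filter_peaks(peaks: Iterable[Peak], min_posterior: float = 0.9) -> list[Peak]:
    """Keep peaks with posterior strictly greater than ``min_posterior``."""
    return [p for p in peaks if p.posterior > min_posterior]


def assign_peaks(
    peaks: Sequence[Peak],
    tss_records: Sequence[TssRecord],
    window_bp: int = 20_000,
) -> list[PeakGeneAssignment]:
    """Map each peak to the nearest TSS within ``window_bp`` of its midpoint.

    Peaks with no TSS in range are omitted.  Equidistant TSSs resolve to
    the lexicographically smallest gene id.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not tss_records:
        raise ValueError("empty TSS annotation")
    by_chrom: dict[str, list[TssRecord]] = defaultdict(list)
    for r in tss_records:
        by_chrom[r.chrom].append(r)
    index: dict[str, tuple[np.ndarray, list[TssRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.tss, r.gene_id))
        index[chrom] = (np.array([r.tss for r in recs]), recs)

    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        if peak.chrom not in index:
            continue
        positions, recs = index[peak.chrom]
        mid = peak.midpoint
        i = int(np.searchsorted(positions, mid))
        best_d = window_bp + 1
        for j in (i - 1, i):
            if 0 <= j < len(recs):
                best_d = min(best_d, abs(mid - int(positions[j])))
        if best_d > window_bp:
            continue
        # all TSSs at exactly best_d (several genes can share a position)
        candidates: list[TssRecord] = []
        for pos in {mid - best_d, mid + best_d}:
            lo = int(np.searchsorted(positions, pos, side="left"))
            hi = int(np.searchsorted(positions, pos, side="right"))
            candidates.extend(recs[lo:hi])
        best = min(candidates, key=lambda r: r.gene_id)
        out.append(PeakGeneAssignment(peak, best.gene_id, best_d))
    return out


def assignments_to_frame(assignments: Iterable[PeakGeneAssignment]) -> pd.DataFrame:
    rows = [
        {
            "peak": a.peak.name,
            "chrom": a.peak.chrom,
            "start": a.peak.start,
            "end": a.peak.end,
            "gene_id": a.gene_id,
            "distance": a.distance,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["peak", "chrom", "start", "end", "gene_id", "distance"])


def promoter_binding(
    tf_to_peaks: Mapping[str, Sequence[Peak]],
    tss_records: Sequence[TssRecord],
    half_width: int = 500,
) -> BindingMatrix:
    """Binary indicator of TF binding in gene promoters.

    ``indicator[g, tf] = 1`` iff some peak attributed to ``tf`` overlaps
    the window ``[tss - half_width, tss + half_width]`` (inclusive of the
    edge base) by at least 1 bp.  Peak lists are expected to be already
    restricted to peaks containing the TF's motif.
    """
    genes = sorted({r.gene_id for r in tss_records})
    tfs = sorted(tf_to_peaks)
    ind = pd.DataFrame(0, index=genes, columns=tfs, dtype=int)
    by_chrom: dict[str, list[TssRecord]] = defaultdict(list)
    for r in tss_records:
        by_chrom[r.chrom].append(r)
    for tf in tfs:
        for peak in tf_to_peaks[tf]:
            for r in by_chrom.get(peak.chrom, ()):
                # window is [tss - hw, tss + hw + 1) half-open
                if peak.start < r.tss + half_width + 1 and peak.end > r.tss - half_width:
                    ind.loc[r.gene_id, tf] = 1
    return BindingMatrix(ind)


def correlation_clusters(
    read_count_table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of libraries on log2(count + 1), plus the
    average-linkage dendrogram leaf order.

    ``read_count_table`` is peaks x libraries with non-negative counts.
    Returns (correlation matrix, ordered library labels).
    """
    if read_count_table.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    counts = read_count_table.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    logc = np.log2(counts + 1.0)
    sd = logc.std(axis=0)
    zero = [str(c) for c, s in zip(read_count_table.columns, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance libraries (correlation undefined): {zero}")
    corr = np.corrcoef(logc, rowvar=False)
    labels = list(read_count_table.columns)
    cmat = pd.DataFrame(corr, index=labels, columns=labels)
    dist = squareform(1.0 - corr, checks=False)
    linkage = hierarchy.average(dist)
    order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    return cmat, order
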