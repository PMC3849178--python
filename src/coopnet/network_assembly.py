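"""Assembly of the TF-centred regulatory network.

Partner TFs retained by both the spacing analysis (Bonferroni-adjusted
p below alpha) and the expression integration (GSEA FWER below the cut)
become partner nodes, linked to the primary dimer by ``dimer-partner``
edges; the union of their target-set members becomes the target layer,
linked by ``complex-target`` edges and flagged with the per-time-point
differential-expression direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .enrichment import GseaResult, OverrepResult
from .formats_io import GeneSet, write_network
from .motif_spacing import SpacingResult

__all__ = ["RegulatoryNetwork", "assemble"]


@dataclass
class RegulatoryNetwork:
    primary_tf: str
    partners: dict[str, dict]          # set_id -> evidence (spacing p_adj, fwer)
    targets: dict[str, dict]           # gene_id -> {de direction per time point}
    edges: list[dict]                  # write_network-ready mappings

    @property
    def n_partners(self) -> int:
        return len(self.partners)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def write(self, path) -> None:
        write_network(self.edges, path)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(self.primary_tf, kind="dimer")
        for tf, ev in self.partners.items():
            g.add_node(tf, kind="partner", **ev)
        for gene, flags in self.targets.items():
            g.add_node(gene, kind="target", **flags)
        for e in self.edges:
            g.add_edge(e["source"], e["target"], edge_type=e["edge_type"])
        return g


def assemble(
    spacing_results: Sequence[SpacingResult],
    gsea_results: Sequence[GseaResult],
    overrep_results: Sequence[OverrepResult],
    target_sets: Sequence[GeneSet],
    de_direction: Mapping[str, str] | None = None,
    primary_tf: str = "primary",
    alpha: float = 0.01,
    fwer_cut: float = 0.05,
    fisher_cut: float = 0.05,
) -> RegulatoryNetwork:
    """Combine stage outputs into the partner/target network.

    All inputs are keyed by consistent set ids (one target set per
    candidate partner TF).  ``de_direction`` optionally maps gene id to
    its DE direction for the dark-node annotation.
    """
    sets_by_id = {s.set_id: s for s in target_sets}
    best_spacing: dict[str, float] = {}
    for r in spacing_results:
        best_spacing[r.secondary_id] = min(best_spacing.get(r.secondary_id, 1.0), r.p_adj)
    gsea_by_id = {r.set_id: r for r in gsea_results}
    orphans = sorted(
        set(gsea_by_id) - set(sets_by_id)
    )
    if orphans:
        raise ValueError(f"GSEA results with no matching target set: {orphans}")
    overrep_by_id: dict[str, list[OverrepResult]] = {}
    for r in overrep_results:
        overrep_by_id.setdefault(r.set_id, []).append(r)

    partners: dict[str, dict] = {}
    for set_id, gr in gsea_by_id.items():
        sp = best_spacing.get(set_id)
        if sp is None:
            continue
        if sp < alpha and gr.fwer < fwer_cut:
            fisher = overrep_by_id.get(set_id, [])
            best_f = min((f.p for f in fisher), default=None)
            partners[set_id] = {
                "spacing_p_adj": sp,
                "fwer": gr.fwer,
                "fisher_p": best_f,
                "fisher_significant": bool(best_f is not None and best_f < fisher_cut),
            }

    de_direction = de_direction or {}
    targets: dict[str, dict] = {}
    edges: list[dict] = []
    for tf, ev in sorted(partners.items()):
        edges.append({
            "source": primary_tf, "target": tf, "edge_type": "dimer-partner",
            "fwer": ev["fwer"], "fisher_p": ev["fisher_p"] if ev["fisher_p"] is not None else "",
            "direction": "",
        })
        for gene in sorted(sets_by_id[tf].genes):
            direction = de_direction.get(gene, "")
            targets.setdefault(gene, {"de_direction": direction})
            edges.append({
                "source": tf, "target": gene, "edge_type": "complex-target",
                "fwer": "", "fisher_p": "", "direction": direction,
            })
    return RegulatoryNetwork(
        primary_tf=primary_tf, partners=partners, targets=targets, edges=edges
    )
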