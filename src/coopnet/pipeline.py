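"""End-to-end orchestration: simulate -> spacing -> rank -> GSEA -> DE ->
over-representation -> network.

``run_all`` executes the canonical recipe on a run directory, writing
every intermediate table as TSV plus a JSON run report with the counts
at each stage.  All randomness funnels through one seed recorded in the
report, so a rerun with the same seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import formats_io as fio
from .cooperativity import coop_test
from .differential_expression import sam_test
from .enrichment import fisher_overrep, gsea_preranked
from .motif_scan import contains_motif
from .motif_spacing import spacing_enrichment
from .network_assembly import assemble
from .peak_annotation import (
    assign_peaks,
    assignments_to_frame,
    filter_peaks,
    promoter_binding,
)
from .synthetic_data import (
    DECOY_LIBRARY,
    PARTNER_LIBRARY,
    PlantedPartner,
    ScenarioConfig,
    generate_scenario,
)
from .target_ranking import rank_genes

logger = logging.getLogger("coopnet")

__all__ = ["RunConfig", "run_all", "default_scenario"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    outdir: str = "coopnet_run"
    peaks_bed: str = ""
    peaks_fasta: str = ""
    tss: str = ""
    expression: str = ""
    samplesheet: str = ""
    motifs: str = ""          # MEME minimal file: primary first, then candidates
    primary_motif_id: str = "TRE"
    tf_gene: str = "JunD"
    condition: str = "WKY"
    basal_time: float = 0.0
    seed: int = 0

    min_posterior: float = 0.9
    window_bp: int = 20_000
    promoter_half_width: int = 500
    margin: int = 50
    spacing_alpha: float = 0.01
    gsea_fwer: float = 0.05
    de_fdr: float = 0.05
    fisher_alpha: float = 0.05
    top_fraction: float = 0.05
    presence_fraction: float = 0.7
    gsea_nperm: int = 1000
    # classic (unweighted) KS statistic: the likelihood-ratio metric is
    # zero-inflated, and with metric weighting a random set containing a
    # single high-score gene saturates the running sum
    gsea_weight: float = 0.0
    de_nperm: int = 200

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("min_posterior", self.min_posterior, 0.0, 1.0),
            ("spacing_alpha", self.spacing_alpha, 0.0, 1.0),
            ("gsea_fwer", self.gsea_fwer, 0.0, 1.0),
            ("de_fdr", self.de_fdr, 0.0, 1.0),
            ("fisher_alpha", self.fisher_alpha, 0.0, 1.0),
            ("top_fraction", self.top_fraction, 0.0, 1.0),
            ("presence_fraction", self.presence_fraction, 0.0, 1.0),
        ]:
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.window_bp <= 0 or self.promoter_half_width <= 0 or self.margin <= 0:
            raise ValueError("window sizes must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The bundled small scenario: 5 planted partner TFs, 120 planted
    targets among 200 genes, ~300 peaks."""
    partners = [
        PlantedPartner(PARTNER_LIBRARY["PTN1"], gap=10, quadrant="same-strand-right"),
        PlantedPartner(PARTNER_LIBRARY["PTN2"], gap=5, quadrant="same-strand-left"),
        PlantedPartner(PARTNER_LIBRARY["PTN3"], gap=15, quadrant="opposite-right"),
        PlantedPartner(PARTNER_LIBRARY["PTN4"], gap=8, quadrant="same-strand-right"),
        PlantedPartner(PARTNER_LIBRARY["PTN5"], gap=20, quadrant="opposite-left"),
    ]
    return ScenarioConfig(seed=seed, planted_partners=partners)


def run_all(
    config: RunConfig, simulate: bool = False, scenario: ScenarioConfig | None = None
) -> dict:
    """Execute the full recipe; returns the run report dict.

    With ``simulate=True`` the bundled synthetic scenario (or the given
    ``scenario``) is generated into ``outdir/data`` first and its paths
    override the config's.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name: str, **counts) -> None:
        report["stages"][name] = counts
        logger.info("[%.1fs] %s: %s", time.time() - t_start, name, counts)

    if simulate:
        scen = scenario if scenario is not None else default_scenario(seed=config.seed)
        paths = generate_scenario(scen, outdir / "data")
        config.peaks_bed = str(paths["peaks_bed"])
        config.peaks_fasta = str(paths["peaks_fasta"])
        config.tss = str(paths["tss"])
        config.expression = str(paths["expression"])
        config.samplesheet = str(paths["samplesheet"])
        config.motifs = str(paths["motifs"])
        stage("simulate", n_genes=scen.n_genes, n_targets=scen.n_targets,
              n_partners=len(scen.planted_partners))
    for name in ("peaks_bed", "peaks_fasta", "tss", "expression", "samplesheet", "motifs"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(
                f"input {name!r} missing ({p!r}); provide it or pass --simulate"
            )

    # ---- load inputs ------------------------------------------------------
    peaks = fio.read_bed(config.peaks_bed)
    kept = filter_peaks(peaks, config.min_posterior)
    seqs = fio.read_fasta(config.peaks_fasta)
    tss = fio.read_tss(config.tss)
    expr = fio.read_expression(config.expression, config.samplesheet)
    pwms = fio.read_pwm(config.motifs, dialect="meme")
    by_id = {p.motif_id: p for p in pwms}
    if config.primary_motif_id not in by_id:
        raise KeyError(f"primary motif {config.primary_motif_id!r} not in {config.motifs}")
    primary = by_id[config.primary_motif_id]
    secondaries = [p for p in pwms if p.motif_id != config.primary_motif_id]
    stage("load", n_peaks=len(peaks), n_peaks_kept=len(kept), n_sequences=len(seqs),
          n_genes=len(expr.genes), n_motifs=len(pwms))

    # ---- peak -> gene assignment -----------------------------------------
    assignments = assign_peaks(kept, tss, window_bp=config.window_bp)
    adf = assignments_to_frame(assignments)
    adf.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    stage("annotate", n_assigned_peaks=len(assignments),
          n_assigned_genes=int(adf["gene_id"].nunique()) if len(adf) else 0)

    # ---- spacing enrichment ----------------------------------------------
    kept_seqs = {p.name: seqs[p.name] for p in kept if p.name in seqs}
    scan = spacing_enrichment(
        kept_seqs, primary, secondaries, margin=config.margin,
        alpha=config.spacing_alpha, seed=config.seed,
    )
    sdf = pd.DataFrame([dataclasses.asdict(r) for r in scan.results])
    sdf.to_csv(outdir / "spacing.tsv", sep="\t", index=False)
    sig_partners = sorted({r.secondary_id for r in scan.significant(config.spacing_alpha)})
    stage("spacing", n_seqs=scan.n_seqs, n_dropped=scan.n_dropped,
          significant_partners=sig_partners)

    # ---- target sets from promoter binding -------------------------------
    tf_to_peaks = {}
    for pid in sig_partners:
        tf_to_peaks[pid] = [
            p for p in kept
            if p.name in kept_seqs
            and contains_motif(kept_seqs[p.name], by_id[pid], config.presence_fraction)
            and contains_motif(kept_seqs[p.name], primary, config.presence_fraction)
        ]
    tf_to_peaks["__primary__"] = [
        p for p in kept
        if p.name in kept_seqs
        and contains_motif(kept_seqs[p.name], primary, config.presence_fraction)
    ]
    binding = promoter_binding(tf_to_peaks, tss, half_width=config.promoter_half_width)
    target_sets = []
    for pid in sig_partners:
        members = binding.bound_genes(pid) & set(expr.genes)
        if members:
            target_sets.append(fio.GeneSet(pid, f"promoter targets of {pid}", frozenset(members)))
    fio.write_gmt(target_sets, outdir / "target_sets.gmt")
    stage("target_sets", sets={s.set_id: len(s.genes) for s in target_sets})

    # ---- cooperativity (expression support for each partner) -------------
    coop_rows = []
    for s in target_sets:
        res = coop_test(binding, expr, "__primary__", s.set_id,
                        top_fraction=config.top_fraction, condition=config.condition)
        coop_rows.append({"partner": s.set_id, "p_value": res.p_value,
                          "n_both": res.n_both, "x_observed": res.x_observed,
                          "top_k": res.top_k, "degenerate": res.degenerate})
    pd.DataFrame(coop_rows).to_csv(outdir / "cooperativity.tsv", sep="\t", index=False)
    stage("cooperativity", n_tested=len(coop_rows))

    # ---- GP target ranking ------------------------------------------------
    scores = rank_genes(expr, config.tf_gene, condition=config.condition)
    score_df = pd.DataFrame(
        [{"gene_id": s.gene_id, "ll_alt": s.ll_alt, "ll_null": s.ll_null, "score": s.score}
         for s in scores]
    )
    score_df.to_csv(outdir / "target_scores.tsv", sep="\t", index=False)
    stage("rank", n_scored=len(scores))

    # ---- GSEA --------------------------------------------------------------
    metric = {s.gene_id: s.score for s in scores}
    if target_sets:
        gsea = gsea_preranked(metric, target_sets, n_perm=config.gsea_nperm,
                              seed=config.seed, weight_p=config.gsea_weight)
    else:
        gsea = []
    gdf = pd.DataFrame([dataclasses.asdict(r) for r in gsea],
                       columns=["set_id", "es", "nes", "p_nominal", "fwer", "n_members"])
    gdf.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
    stage("gsea", passing_fwer=[r.set_id for r in gsea if r.fwer < config.gsea_fwer])

    # ---- differential expression -------------------------------------------
    times = [t for t in expr.select(condition=config.condition).times if t != config.basal_time]
    de_frames = []
    de_direction: dict[str, str] = {}
    de_counts = {}
    for t in times:
        res = sam_test(expr, config.condition, time_b=t, time_a=config.basal_time,
                       n_perm=config.de_nperm, fdr_cut=config.de_fdr, seed=config.seed)
        for r in res:
            if r.direction != "ns":
                # annotate with the earliest significant direction
                de_direction.setdefault(r.gene_id, r.direction)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in res])
        frame.insert(0, "time_h", t)
        de_frames.append(frame)
        de_counts[f"t{t:g}"] = {
            "up": int((frame["direction"] == "up").sum()),
            "down": int((frame["direction"] == "down").sum()),
        }
    pd.concat(de_frames).to_csv(outdir / "de.tsv", sep="\t", index=False)
    stage("de", **de_counts)

    # ---- over-representation ----------------------------------------------
    universe = set(expr.genes)
    overrep = []
    for t, frame in zip(times, de_frames):
        for direction in ("up", "down"):
            de_genes = set(frame.loc[frame["direction"] == direction, "gene_id"])
            if not de_genes:
                continue
            for s in target_sets:
                r = fisher_overrep(s, de_genes, universe, direction=direction)
                overrep.append(r)
    odf = pd.DataFrame(
        [dataclasses.asdict(r) for r in overrep],
        columns=["set_id", "direction", "k_overlap", "n_set", "n_de", "n_universe",
                 "odds_ratio", "p"],
    )
    odf.to_csv(outdir / "overrep.tsv", sep="\t", index=False)
    stage("overrep", n_tests=len(overrep),
          n_significant=int((odf["p"] < config.fisher_alpha).sum()) if len(odf) else 0)

    # ---- network ------------------------------------------------------------
    network = assemble(
        scan.results, gsea, overrep, target_sets,
        de_direction=de_direction, primary_tf=config.tf_gene,
        alpha=config.spacing_alpha, fwer_cut=config.gsea_fwer,
        fisher_cut=config.fisher_alpha,
    )
    network.write(outdir / "network.tsv")
    stage("network", n_partners=network.n_partners, n_targets=network.n_targets,
          n_edges=len(network.edges))

    report["elapsed_s"] = round(time.time() - t_start, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config_used.yaml")
    return report
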