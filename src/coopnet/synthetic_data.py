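"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the study design the pipeline targets: ChIP-seq
peak sequences carrying a primary AP-1 motif (TRE ``TGA[C/G]TCA`` or CRE
``TGACGTCA``) with optional partner motifs planted at fixed spacings; a
two-condition, 0/2/4/8 h, 4-replicate expression time course in which
target genes respond to a smooth TF activity pulse through a linear ODE
(the second condition carries a 20-fold attenuated TF); and a synthetic
chromosome layout in which promoter binding (+/-500 bp) and +/-20 kb
peak-to-gene assignment are both exercised.  Every planted feature is
recorded in a truth table so downstream recovery can be scored without
reference to the generator's internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    ExpressionMatrix,
    GeneSet,
    Peak,
    Pwm,
    TssRecord,
    write_bed,
    write_fasta,
    write_gmt,
    write_meme,
    write_tss,
)
from .motif_scan import reverse_complement
from .motif_spacing import QUADRANTS
from .peak_annotation import BindingMatrix

__all__ = [
    "TRE",
    "CRE",
    "PARTNER_LIBRARY",
    "DECOY_LIBRARY",
    "PlantedPartner",
    "ScenarioConfig",
    "tf_pulse",
    "ode_response",
    "make_peak_sequences",
    "simulate_expression",
    "simulate_coop_dataset",
    "make_tss_and_binding",
    "generate_scenario",
]

BASES = "ACGT"

TRE = Pwm.from_consensus("TRE", "AP1_TRE", "TGASTCA")
CRE = Pwm.from_consensus("CRE", "AP1_CRE", "TGACGTCA")

# candidate partner motifs (distinct, non-AP1 consensus strings)
PARTNER_LIBRARY = {
    "PTN1": Pwm.from_consensus("PTN1", "partner1", "GGGGATTTCC"),
    "PTN2": Pwm.from_consensus("PTN2", "partner2", "TTGCGCAAT"),
    "PTN3": Pwm.from_consensus("PTN3", "partner3", "CAGGTGTCA"),
    "PTN4": Pwm.from_consensus("PTN4", "partner4", "GATAAGGAG"),
    "PTN5": Pwm.from_consensus("PTN5", "partner5", "AACCGGTTA"),
}
DECOY_LIBRARY = {
    "DCY1": Pwm.from_consensus("DCY1", "decoy1", "CCCTTAAGG"),
    "DCY2": Pwm.from_consensus("DCY2", "decoy2", "TGTACACTG"),
    "DCY3": Pwm.from_consensus("DCY3", "decoy3", "GGAACCTTG"),
}


@dataclass(frozen=True)
class PlantedPartner:
    pwm: Pwm
    gap: int = 10
    quadrant: str = "same-strand-right"
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")


@dataclass
class ScenarioConfig:
    """Defaults emulate the study design: 0/2/4/8 h, 4 replicates, two
    conditions with a 20-fold attenuated TF in the second."""

    seed: int = 0
    n_peaks: int = 300
    peak_len: int = 200
    primary_motif: str = "TRE"
    planted_partners: list[PlantedPartner] = field(default_factory=list)
    n_genes: int = 600
    n_targets: int = 120
    time_points: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    replicates: int = 4
    noise_sd: float = 0.25
    conditions: tuple[str, str] = ("WKY", "congenic")
    tf_attenuation: float = 20.0
    tf_gene: str = "JunD"
    margin: int = 50
    # ODE parameter ranges for target genes
    decay_range: tuple[float, float] = (0.3, 1.5)
    sensitivity_range: tuple[float, float] = (0.5, 2.0)
    baseline_range: tuple[float, float] = (4.0, 8.0)
    coop_block_sizes: tuple[int, ...] = ()
    coop_block_corr: float = 0.7

    @property
    def primary_pwm(self) -> Pwm:
        if self.primary_motif == "TRE":
            return TRE
        if self.primary_motif == "CRE":
            return CRE
        raise ValueError(f"primary_motif must be TRE or CRE, got {self.primary_motif!r}")

    def __post_init__(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")


def _sample_site(pwm: Pwm, rng: np.random.Generator, mode: str = "consensus") -> str:
    """Sample a site from the PWM.

    ``consensus`` restricts each position to its consensus base(s)
    (probability >= 0.1, covering degenerate positions like TRE's S);
    ``full`` samples from the raw base probabilities, occasionally
    producing off-consensus bases.
    """
    out = []
    for row in pwm.probs:
        if mode == "consensus":
            p = np.where(row >= 0.1, row, 0.0)
        else:
            p = row
        out.append(BASES[rng.choice(4, p=p / p.sum())])
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _plant(seq: list[str], offset: int, site: str) -> None:
    seq[offset : offset + len(site)] = list(site)


def make_peak_sequences(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Peak sequences with a planted primary site and optional partners.

    Every sequence carries one primary-motif instance sampled from the
    PWM; each planted partner lands at its configured (gap, quadrant) in
    a Bernoulli(``fraction``) subset of sequences.  The returned truth
    table records every planted site.
    """
    rng = rng or np.random.default_rng(config.seed)
    primary = config.primary_pwm
    L1 = len(primary)
    margin = config.margin
    max_l2 = max((len(p.pwm) for p in config.planted_partners), default=0)
    for p in config.planted_partners:
        if p.gap + len(p.pwm) > margin:
            raise ValueError(
                f"gap {p.gap} + motif length {len(p.pwm)} exceeds margin {margin}"
            )
    if config.peak_len < L1 + 2 * margin + 2:
        raise ValueError("peak_len too short for primary motif plus margins")

    seqs: dict[str, str] = {}
    rows = []
    for i in range(config.n_peaks):
        name = f"peak_{i:04d}"
        chars = [BASES[b] for b in _random_seq(config.peak_len, rng)]
        # primary offset leaves full margins inside the sequence
        p_off = int(rng.integers(margin, config.peak_len - margin - L1 + 1))
        _plant(chars, p_off, _sample_site(primary, rng))
        rows.append({"seq_id": name, "element": primary.motif_id, "offset": p_off,
                     "strand": "+", "gap": -1, "quadrant": ""})
        for partner in config.planted_partners:
            if rng.random() >= partner.fraction:
                continue
            site = _sample_site(partner.pwm, rng)
            L2 = len(site)
            if partner.quadrant.endswith("right"):
                off = p_off + L1 + partner.gap
            else:
                off = p_off - partner.gap - L2
            strand = "+" if partner.quadrant.startswith("same") else "-"
            _plant(chars, off, site if strand == "+" else reverse_complement(site))
            rows.append({"seq_id": name, "element": partner.pwm.motif_id, "offset": off,
                         "strand": strand, "gap": partner.gap, "quadrant": partner.quadrant})
        seq = "".join(chars)
        # half the sequences are stored primary-minus to exercise orientation
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        seqs[name] = seq
    return seqs, pd.DataFrame(rows)


def tf_pulse(t: np.ndarray, amplitude: float = 2.0, rise_h: float = 2.0) -> np.ndarray:
    """Smooth TF activity pulse: rises by ``rise_h`` hours, decays by 8 h."""
    t = np.asarray(t, float)
    return amplitude * (t / rise_h) * np.exp(1.0 - t / rise_h)


def ode_response(
    t_obs: Sequence[float],
    B: float,
    S: float,
    D: float,
    x0: float,
    force: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    force_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free solution of dx/dt = B + S f - D x by trapezoidal integration."""
    if D <= 0:
        raise ValueError("decay rate D must be positive")
    if grid is None:
        grid = np.linspace(0.0, max(t_obs), 801)
    if force is None:
        force = tf_pulse(grid)
    force = force_scale * np.asarray(force, float)
    out = []
    for t in t_obs:
        m = grid <= t
        if m.sum() < 2:
            integ = 0.0
        else:
            integ = np.trapezoid(np.exp(-D * (t - grid[m])) * force[m], grid[m])
        out.append(B / D + (x0 - B / D) * np.exp(-D * t) + S * integ)
    return np.array(out)


def simulate_expression(
    config: ScenarioConfig,
    target_genes: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-condition time-course expression matrix plus per-gene truth.

    The TF gene tracks the activity pulse; target genes respond through
    the ODE; remaining genes sit at their basal level.  The second
    condition scales the TF force (and the TF gene's own pulse) by
    ``1 / tf_attenuation``.  Optional cooperative blocks of non-target
    genes share a latent profile to elevate within-block correlation.
    """
    rng = rng or np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    gene_ids = list(gene_ids)
    if config.tf_gene not in gene_ids:
        gene_ids = [config.tf_gene] + gene_ids
    if target_genes is None:
        pool = [g for g in gene_ids if g != config.tf_gene]
        target_genes = pool[: config.n_targets]
    target_set = set(target_genes)

    t_obs = np.array(config.time_points, float)
    grid = np.linspace(0.0, float(t_obs.max()), 801)
    force = tf_pulse(grid)

    samples = []
    for cond in config.conditions:
        for t in config.time_points:
            for r in range(1, config.replicates + 1):
                samples.append({"sample": f"{cond}_t{t:g}_r{r}",
                                "condition": cond, "time_h": t, "replicate": r})
    sheet = pd.DataFrame(samples).set_index("sample")
    n_samp = len(sheet)

    truth_rows = []
    values = np.empty((len(gene_ids), n_samp))
    cond_scale = {config.conditions[0]: 1.0, config.conditions[1]: 1.0 / config.tf_attenuation}

    # cooperative blocks claim non-target, non-TF genes from the end
    free = [g for g in gene_ids if g != config.tf_gene and g not in target_set]
    blocks: list[list[str]] = []
    cursor = len(free)
    for size in config.coop_block_sizes:
        blocks.append(free[cursor - size : cursor])
        cursor -= size
    block_of = {g: bi for bi, blk in enumerate(blocks) for g in blk}
    # latent block profiles, standardised so the within-block correlation
    # lam^2 / (lam^2 + sd^2) hits its nominal value exactly
    block_profiles = {}
    for bi in range(len(blocks)):
        z = np.cumsum(rng.normal(0, 1.0, len(config.time_points)))
        block_profiles[bi] = (z - z.mean()) / z.std()

    for gi, g in enumerate(gene_ids):
        row = np.empty(n_samp)
        if g == config.tf_gene:
            base = float(rng.uniform(*config.baseline_range))
            kind, B, S, D = "tf", np.nan, np.nan, np.nan
            for si, (sname, meta) in enumerate(sheet.iterrows()):
                mu = base + cond_scale[meta["condition"]] * tf_pulse(np.array([meta["time_h"]]))[0]
                row[si] = mu + rng.normal(0, config.noise_sd)
        elif g in target_set:
            D = float(rng.uniform(*config.decay_range))
            S = float(rng.uniform(*config.sensitivity_range))
            base = float(rng.uniform(*config.baseline_range))
            B = base * D
            kind = "target"
            per_cond = {
                cond: ode_response(t_obs, B, S, D, base, force=force, grid=grid,
                                   force_scale=scale)
                for cond, scale in cond_scale.items()
            }
            t_index = {t: i for i, t in enumerate(t_obs)}
            for si, (sname, meta) in enumerate(sheet.iterrows()):
                mu = per_cond[meta["condition"]][t_index[meta["time_h"]]]
                row[si] = mu + rng.normal(0, config.noise_sd)
        else:
            base = float(rng.uniform(*config.baseline_range))
            kind, B, S, D = "background", np.nan, np.nan, np.nan
            lam = 0.0
            if g in block_of:
                kind = "coop_block"
                rho = config.coop_block_corr
                lam = np.sqrt(rho / (1 - rho)) * config.noise_sd
            t_index = {t: i for i, t in enumerate(t_obs)}
            for si, (sname, meta) in enumerate(sheet.iterrows()):
                mu = base
                if lam:
                    mu += lam * block_profiles[block_of[g]][t_index[meta["time_h"]]]
                row[si] = mu + rng.normal(0, config.noise_sd)
        values[gi] = row
        truth_rows.append({"gene_id": g, "kind": kind, "B": B, "S": S, "D": D,
                           "block": block_of.get(g, -1)})

    data = pd.DataFrame(values, index=gene_ids, columns=sheet.index)
    return ExpressionMatrix(data, sheet), pd.DataFrame(truth_rows)


def simulate_coop_dataset(
    n_both: int = 100,
    n_a_only: int = 100,
    n_b_only: int = 100,
    n_samples: int = 16,
    r_both: float = 0.7,
    r_single: float = 0.1,
    seed: int = 0,
) -> tuple[BindingMatrix, ExpressionMatrix]:
    """Expression + binding fixture for the cooperativity test.

    Genes bound by both TFs share a latent factor giving expected
    pairwise correlation ``r_both``; each single-TF class shares its own
    factor at ``r_single``.  Setting ``r_both == r_single`` gives an
    exchangeable null.
    """
    rng = np.random.default_rng(seed)

    def block(n_genes: int, rho: float, prefix: str) -> tuple[list[str], np.ndarray]:
        z = rng.normal(size=n_samples)
        lam = np.sqrt(max(rho, 0.0))
        eps = rng.normal(size=(n_genes, n_samples))
        vals = lam * z[None, :] + np.sqrt(1 - lam**2) * eps
        return [f"{prefix}{i:03d}" for i in range(n_genes)], vals

    gb, vb = block(n_both, r_both, "both_")
    ga, va = block(n_a_only, r_single, "aonly_")
    gc, vc = block(n_b_only, r_single, "bonly_")
    genes = gb + ga + gc
    values = np.vstack([vb, va, vc])
    sheet = pd.DataFrame({
        "sample": [f"s{i:02d}" for i in range(n_samples)],
        "condition": "WKY",
        "time_h": [float(i) for i in range(n_samples)],
        "replicate": 1,
    }).set_index("sample")
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sheet.index), sheet)
    ind = pd.DataFrame(0, index=genes, columns=["TF_A", "TF_B"], dtype=int)
    ind.loc[gb, ["TF_A", "TF_B"]] = 1
    ind.loc[ga, "TF_A"] = 1
    ind.loc[gc, "TF_B"] = 1
    return BindingMatrix(ind), expr


def make_tss_and_binding(
    config: ScenarioConfig,
    target_to_partner: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[TssRecord], list[Peak], BindingMatrix, pd.DataFrame]:
    """Synthetic chromosome layout: TSS table, peaks and truth binding.

    Target genes get a promoter peak (midpoint within +/-300 bp of the
    TSS); some background genes get distal peaks inside the +/-20 kb
    assignment window; a few peaks land just outside it or carry a low
    posterior, exercising both boundaries.
    """
    rng = rng or np.random.default_rng(config.seed)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    spacing = 100_000
    tss = [TssRecord(g, "chr1", "+" if i % 2 == 0 else "-", 50_000 + i * spacing)
           for i, g in enumerate(gene_ids)]
    tss_by_gene = {r.gene_id: r for r in tss}
    target_to_partner = target_to_partner or {}

    peaks: list[Peak] = []
    rows = []
    half = config.peak_len // 2
    idx = 0

    def add_peak(center: int, gene: str, role: str, posterior: float) -> Peak:
        nonlocal idx
        p = Peak("chr1", center - half, center + config.peak_len - half,
                 f"peak_{idx:04d}", posterior)
        idx += 1
        peaks.append(p)
        rows.append({"peak": p.name, "gene_id": gene, "role": role,
                     "posterior": posterior, "distance": abs(p.midpoint - tss_by_gene[gene].tss)
                     if gene else -1})
        return p

    for gene, partner in target_to_partner.items():
        r = tss_by_gene[gene]
        offset = int(rng.integers(-300, 301))
        add_peak(r.tss + offset, gene, f"promoter:{partner}", float(rng.uniform(0.91, 1.0)))

    # distal peaks near background genes (inside the 20 kb window, outside promoters)
    background = [g for g in gene_ids if g not in target_to_partner]
    n_distal = max(0, config.n_peaks - len(target_to_partner) - 6)
    for g in rng.choice(background, size=n_distal, replace=True):
        r = tss_by_gene[g]
        sign = 1 if rng.random() < 0.5 else -1
        dist = int(rng.integers(1_000, 15_000))
        add_peak(r.tss + sign * dist, g, "distal", float(rng.uniform(0.91, 1.0)))
    # boundary cases
    r0 = tss_by_gene[background[0]]
    add_peak(r0.tss + 20_000, background[0], "window-edge", 0.95)
    add_peak(r0.tss + 20_001 + (config.peak_len % 2), background[0], "outside-window", 0.95)
    # low-posterior peaks that the 0.9 filter removes
    for g in background[1:5]:
        r = tss_by_gene[g]
        add_peak(r.tss + 2_000, g, "low-posterior", 0.5)

    truth = pd.DataFrame(rows)
    ind = pd.DataFrame(0, index=gene_ids,
                       columns=sorted({p for p in target_to_partner.values()}) or ["none"],
                       dtype=int)
    for gene, partner in target_to_partner.items():
        ind.loc[gene, partner] = 1
    return tss, peaks, BindingMatrix(ind), truth


def generate_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete coordinated scenario to ``outdir``.

    Partner-containing promoter peaks drive target genes: for each
    planted partner, a slice of the target genes receives a promoter peak
    whose sequence carries the primary motif plus that partner's motif at
    its configured spacing, and the same genes respond to the TF pulse in
    the expression matrix.  Files written: peaks.bed, peaks.fasta,
    tss.tsv, expression.tsv, samplesheet.tsv, motifs.meme (primary +
    partners + decoys), truth_*.tsv, truth_sets.gmt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    partners = config.planted_partners
    if not partners:
        raise ValueError("generate_scenario needs at least one planted partner")

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    targets = gene_ids[: config.n_targets]
    per = int(np.ceil(config.n_targets / len(partners)))
    target_to_partner = {
        g: partners[min(i // per, len(partners) - 1)].pwm.motif_id
        for i, g in enumerate(targets)
    }

    tss, peaks, truth_binding, truth_peaks = make_tss_and_binding(
        config, target_to_partner, rng
    )

    # sequences: promoter peaks get primary + their partner at its spacing;
    # everything else primary only
    partner_by_id = {p.pwm.motif_id: p for p in partners}
    primary = config.primary_pwm
    L1 = len(primary)
    seq_rows = []
    seqs: dict[str, str] = {}
    role_by_peak = dict(zip(truth_peaks["peak"], truth_peaks["role"]))
    for peak in peaks:
        chars = [BASES[b] for b in _random_seq(config.peak_len, rng)]
        p_off = int(rng.integers(config.margin, config.peak_len - config.margin - L1 + 1))
        _plant(chars, p_off, _sample_site(primary, rng))
        role = role_by_peak[peak.name]
        if role.startswith("promoter:"):
            planted = partner_by_id[role.split(":", 1)[1]]
            site = _sample_site(planted.pwm, rng)
            if planted.quadrant.endswith("right"):
                off = p_off + L1 + planted.gap
            else:
                off = p_off - planted.gap - len(site)
            strand = "+" if planted.quadrant.startswith("same") else "-"
            _plant(chars, off, site if strand == "+" else reverse_complement(site))
            seq_rows.append({"seq_id": peak.name, "element": planted.pwm.motif_id,
                             "offset": off, "strand": strand, "gap": planted.gap,
                             "quadrant": planted.quadrant})
        seq = "".join(chars)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        seqs[peak.name] = seq

    expr, truth_expr = simulate_expression(
        config, target_genes=targets, gene_ids=gene_ids, rng=rng
    )

    truth_sets = [
        GeneSet(pid, f"planted targets of {pid}",
                frozenset(g for g, p in target_to_partner.items() if p == pid))
        for pid in sorted({p for p in target_to_partner.values()})
    ]

    paths = {
        "peaks_bed": outdir / "peaks.bed",
        "peaks_fasta": outdir / "peaks.fasta",
        "tss": outdir / "tss.tsv",
        "expression": outdir / "expression.tsv",
        "samplesheet": outdir / "samplesheet.tsv",
        "motifs": outdir / "motifs.meme",
        "truth_peaks": outdir / "truth_peaks.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
        "truth_sets": outdir / "truth_sets.gmt",
    }
    write_bed(peaks, paths["peaks_bed"])
    write_fasta(seqs, paths["peaks_fasta"])
    write_tss(tss, paths["tss"])
    expr.to_tsv(paths["expression"], paths["samplesheet"])
    write_meme(
        [primary] + [p.pwm for p in partners] + list(DECOY_LIBRARY.values()),
        paths["motifs"],
    )
    truth_peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
    pd.DataFrame(seq_rows).to_csv(paths["truth_sites"], sep="\t", index=False)
    truth_expr.to_csv(paths["truth_expression"], sep="\t", index=False)
    write_gmt(truth_sets, paths["truth_sets"])
    return paths
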