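"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention, which is also the only genomic interval format read
here).  Parsers validate eagerly and raise :class:`FormatError` with the
offending line number so that malformed inputs fail at the boundary, not
three stages later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "FormatError",
    "Peak",
    "TssRecord",
    "Pwm",
    "ExpressionMatrix",
    "GeneSet",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_tss",
    "read_pwm",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_network",
]

BASES = "ACGT"


class FormatError(ValueError):
    """A file failed validation while being read or written."""


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: genomic interval plus posterior probability.

    ``start``/``end`` are 0-based half-open.  ``posterior`` is the peak
    caller's posterior probability of a true binding event; pre-filtered
    inputs without a score column default to 1.0 so they pass the
    downstream posterior filter unchanged.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    posterior: float = 1.0
    read_count: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak {self.name or self.chrom}: start {self.start} >= end {self.end}"
            )
        if not (0.0 <= self.posterior <= 1.0):
            raise FormatError(
                f"peak {self.name or self.chrom}: posterior {self.posterior} outside [0, 1]"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site of one gene (0-based position)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise FormatError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix as base probabilities (columns A, C, G, T).

    ``probs`` rows each sum to 1 after pseudocount renormalisation.
    """

    motif_id: str
    name: str
    probs: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise FormatError(f"{self.motif_id}: probs must be L x 4")
        if probs.shape[0] < 4:
            raise FormatError(f"{self.motif_id}: motif length {probs.shape[0]} < 4")
        if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise FormatError(f"{self.motif_id}: rows are not probability vectors")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls, motif_id: str, name: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "Pwm":
        """Column-sum normalise a count matrix, then add ``pseudocount`` to
        each probability and renormalise rows."""
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise FormatError(f"{motif_id}: row of all zeros in count matrix")
        probs = counts / sums + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, name=name, probs=probs, pseudocount=pseudocount)

    @classmethod
    def from_consensus(
        cls, motif_id: str, name: str, consensus: str, strength: float = 0.97
    ) -> "Pwm":
        """Build a PWM from an IUPAC-ish consensus string.

        Supported degenerate codes: S (C/G), W (A/T), R (A/G), Y (C/T),
        N (any).  ``strength`` is the total probability mass on the
        consensus base(s) at each position.
        """
        codes = {
            "A": "A", "C": "C", "G": "G", "T": "T",
            "S": "CG", "W": "AT", "R": "AG", "Y": "CT", "N": "ACGT",
        }
        rows = []
        for ch in consensus.upper():
            allowed = codes.get(ch)
            if allowed is None:
                raise FormatError(f"{motif_id}: unsupported consensus symbol {ch!r}")
            row = np.full(4, (1.0 - strength) / (4 - len(allowed)) if len(allowed) < 4 else 0.25)
            for b in allowed:
                row[BASES.index(b)] = strength / len(allowed)
            rows.append(row / row.sum())
        return cls(motif_id=motif_id, name=name, probs=np.array(rows))


@dataclass(frozen=True)
class GeneSet:
    """Named collection of gene identifiers (GMT record)."""

    set_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.set_id} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


class ExpressionMatrix:
    """Genes x samples expression values (log2 scale) with sample metadata.

    ``data`` is a DataFrame indexed by gene id with one column per sample
    label; ``samples`` is a DataFrame indexed by sample label with columns
    ``condition``, ``time_h``, ``replicate``.
    """

    def __init__(self, data: pd.DataFrame, samples: pd.DataFrame):
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        missing = [c for c in data.columns if c not in samples.index]
        if missing:
            raise FormatError(f"samples missing from samplesheet: {missing}")
        for col in ("condition", "time_h", "replicate"):
            if col not in samples.columns:
                raise FormatError(f"samplesheet lacks column {col!r}")
        vals = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        samples = samples.loc[list(data.columns)]
        order = samples.sort_values(["condition", "time_h", "replicate"]).index
        self.data = data[order].copy()
        self.samples = samples.loc[order].copy()

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.samples["time_h"].unique())

    def select(self, condition: str | None = None, time_h: float | None = None) -> "ExpressionMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if time_h is not None:
            mask &= self.samples["time_h"] == time_h
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise FormatError(f"no samples for condition={condition!r}, time_h={time_h!r}")
        return ExpressionMatrix(self.data[cols], self.samples.loc[cols])

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def to_tsv(self, matrix_path: str | Path, samplesheet_path: str | Path) -> None:
        self.data.to_csv(matrix_path, sep="\t", index_label="gene_id")
        out = self.samples.reset_index(names="sample")
        out.to_csv(samplesheet_path, sep="\t", index=False)

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.genes)} genes x {self.data.shape[1]} samples, "
            f"conditions={self.conditions}, times={self.times})"
        )


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[Peak]:
    """Read BED 3-5 columns into peaks.

    Column 4 is the peak name, column 5 (if present) the posterior
    probability.  Missing posteriors default to 1.0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            posterior = 1.0
            if len(fields) > 4:
                try:
                    posterior = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                peaks.append(Peak(chrom, start, end, name, posterior))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.posterior:g}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase sequence mapping."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSS annotation

def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a tab-separated TSS table: gene_id, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    return [
        TssRecord(r.gene_id, r.chrom, r.strand, int(r.tss)) for r in df.itertuples()
    ]


def write_tss(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n")


# ---------------------------------------------------------------------------
# PWM (TRANSFAC counts / MEME minimal)

def read_pwm(path: str | Path, dialect: str = "transfac", pseudocount: float = 0.01) -> list[Pwm]:
    """Read motifs from a TRANSFAC matrix file or MEME minimal motif file.

    TRANSFAC count matrices are converted to probabilities by column-sum
    normalisation followed by pseudocount renormalisation; MEME minimal
    files already carry probabilities, which are pseudocount-renormalised
    the same way.
    """
    if dialect not in {"transfac", "meme"}:
        raise ValueError(f"unknown PWM dialect {dialect!r} (expected 'transfac' or 'meme')")
    fmt = "transfac" if dialect == "transfac" else "minimal"
    with open(path) as fh:
        try:
            records = list(bio_motifs.parse(fh, fmt))
        except Exception as exc:  # Biopython raises bare Exception subclasses
            raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    pwms: list[Pwm] = []
    for rec in records:
        motif_id = (
            getattr(rec, "matrix_id", None)
            or (rec.get("AC") if hasattr(rec, "get") else None)
            or (rec.get("ID") if hasattr(rec, "get") else None)
            or rec.name
            or f"motif_{len(pwms) + 1}"
        )
        name = rec.name or motif_id
        counts = np.array([[rec.counts[b][i] for b in BASES] for i in range(rec.length)])
        pwms.append(Pwm.from_counts(str(motif_id), str(name), counts, pseudocount=pseudocount))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_meme(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.name}\n")
            # large nsites: MEME readers that reconstruct counts as
            # round(p * nsites) then keep ~3 decimals of the probabilities
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 1000 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression matrix + samplesheet

def read_expression(matrix_path: str | Path, samplesheet_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV and its samplesheet.

    The samplesheet must have columns sample, condition, time_h, replicate
    and cover every column of the matrix header.
    """
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    for col in data.columns:
        try:
            data[col] = pd.to_numeric(data[col], errors="raise")
        except (ValueError, TypeError):
            bad = data[pd.to_numeric(data[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{matrix_path}: non-numeric value for gene {bad!r} in sample {col!r}"
            ) from None
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    required = {"sample", "condition", "time_h", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"{samplesheet_path}: needs columns {sorted(required)}")
    sheet = sheet.set_index("sample")
    return ExpressionMatrix(data, sheet)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            set_id, description, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {set_id}; deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id, description, frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Network edge list

NETWORK_COLUMNS = ["source", "target", "edge_type", "fwer", "fisher_p", "direction"]


def write_network(edges: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write a typed edge list as TSV.

    Each edge is a mapping with keys source, target, edge_type
    ('dimer-partner' or 'complex-target') and optional evidence fields
    fwer, fisher_p, direction.  Duplicate (source, target, edge_type)
    triples are written once (first occurrence wins).
    """
    seen: set[tuple] = set()
    rows = []
    for e in edges:
        key = (e["source"], e["target"], e["edge_type"])
        if key in seen:
            continue
        seen.add(key)
        rows.append({c: e.get(c, "") for c in NETWORK_COLUMNS})
    df = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
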