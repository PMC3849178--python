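"""Log-odds PWM scanning of peak sequences.

Scores are log2 odds (bits) of the motif model against a background base
composition.  ``N`` bases contribute 0 bits (neutral under log-odds).
Both strands are always scanned; reverse-strand hits are reported at the
offset of the site in the forward sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import BASES, Pwm

__all__ = ["MotifHit", "log_odds", "best_hit", "hits_above", "max_score", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# index 4 encodes N
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: sequence id, 0-based offset, strand, score in bits."""

    seq_id: str
    motif_id: str
    offset: int
    strand: str
    score: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def log_odds(pwm: Pwm, background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    """L x 4 matrix of log2(p/background) scores."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return np.log2(pwm.probs / bg)


def max_score(pwm: Pwm, background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Maximum achievable log-odds score (per-row maxima summed)."""
    return float(log_odds(pwm, background).max(axis=1).sum())


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains unsupported symbol {exc.args[0]!r}") from exc


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of every length-L window given a log-odds matrix with an
    extra all-zero column for N."""
    L = lom.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    lom5 = np.hstack([lom, np.zeros((L, 1))])
    # windows[i, j] = codes[i + j]
    idx = np.arange(n)[:, None] + np.arange(L)[None, :]
    return lom5[np.arange(L)[None, :], codes[idx]].sum(axis=1)


def scan(
    sequence: str,
    pwm: Pwm,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seq_id: str = "",
) -> list[MotifHit]:
    """All window scores on both strands, unsorted by score.

    A reverse-strand hit at offset ``o`` means positions ``[o, o+L)`` of
    the forward sequence match the reverse complement of the motif.
    """
    seq = sequence.upper()
    lom = log_odds(pwm, background)
    codes = _encode(seq)
    L = len(pwm)
    fwd = _window_scores(codes, lom)
    # reverse strand: score the forward sequence with the reverse-complemented PWM
    lom_rc = lom[::-1, ::-1]
    rev = _window_scores(codes, lom_rc)
    hits = [
        MotifHit(seq_id, pwm.motif_id, int(o), "+", float(s)) for o, s in enumerate(fwd)
    ] + [
        MotifHit(seq_id, pwm.motif_id, int(o), "-", float(s)) for o, s in enumerate(rev)
    ]
    return hits


def best_hit(
    sequence: str,
    pwm: Pwm,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seq_id: str = "",
) -> MotifHit | None:
    """Maximal-score hit over both strands, or None for a too-short sequence.

    Ties are broken by smaller offset, then + strand.
    """
    hits = scan(sequence, pwm, background, seq_id)
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, h.offset, h.strand))


def hits_above(
    sequence: str,
    pwm: Pwm,
    min_score: float,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seq_id: str = "",
) -> list[MotifHit]:
    """All hits with score >= min_score, sorted by offset then strand."""
    hits = [h for h in scan(sequence, pwm, background, seq_id) if h.score >= min_score]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def contains_motif(
    sequence: str,
    pwm: Pwm,
    fraction_of_max: float = 0.7,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> bool:
    """Presence call: does the sequence contain a site scoring at least
    ``fraction_of_max`` of the PWM's maximum achievable log-odds?

    The fraction-of-max rule is database-dialect independent; 0.7 is the
    default presence threshold throughout the pipeline.
    """
    bh = best_hit(sequence, pwm, background)
    return bh is not None and bh.score >= fraction_of_max * max_score(pwm, background)
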