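"""PWM scanning of promoter sequences on both strands.

Every length-m window of a promoter is scored against the PWM by summing one
log-odds weight per position.  Minus-strand hits score the reverse
complement of the window; their ``start`` is still the 0-based offset of the
window's leftmost base in promoter coordinates, so deduplication and
reporting share one coordinate frame.  Windows containing N are skipped.

The relative score min-max normalises the raw score into [0, 1]:
``rel = (score - min_score) / (max_score - min_score)``; it reaches 1
exactly on the consensus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motif_io import BASE_INDEX, PWM
from .promoters import PromoterSequence

__all__ = ["Hit", "score_window", "scan_promoter", "scan_scores", "hits_to_frame", "encode"]

# A=0 C=1 G=2 T=3, N=4; complement of code c is 3-c for c<4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N (case-insensitive) as 0..3, anything else as 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Hit:
    """One scored binding-site candidate for a (TF, gene) pair."""

    matrix_id: str
    tf_name: str
    gene_id: str
    start: int
    strand: str
    score: float
    rel_score: float
    pvalue: float | None = None


def score_window(pwm: PWM, window: str) -> float:
    """Score one length-m A/C/G/T window: sum of per-position weights, in bits."""
    if len(window) != pwm.m:
        raise ValidationError(
            f"window length {len(window)} != motif length {pwm.m} for {pwm.matrix_id}"
        )
    codes = encode(window)
    if np.any(codes > 3):
        raise ValidationError(f"ambiguous base in window {window!r}")
    return float(pwm.weights[codes, np.arange(pwm.m)].sum())


def scan_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised scan of one sequence.

    Returns ``(starts, fwd, rev)``: window start offsets of the N-free
    windows and their scores on the forward strand and on the reverse
    complement.  Empty arrays when the sequence is shorter than the motif.
    """
    m = pwm.m
    n = len(seq)
    nwin = n - m + 1
    if nwin <= 0:
        empty = np.empty(0)
        return np.empty(0, dtype=np.int64), empty, empty
    codes = encode(seq)
    valid = codes <= 3
    # a window is N-free iff all m of its positions are valid
    ok = np.ones(nwin, dtype=bool)
    fwd = np.zeros(nwin)
    rev = np.zeros(nwin)
    safe = np.where(valid, codes, 0)
    w = pwm.weights
    for j in range(m):
        col = safe[j : j + nwin]
        ok &= valid[j : j + nwin]
        fwd += w[:, j][col]
        # reverse-complement window read 5'->3': position j of the rc window
        # is the complement (3 - code) of sequence position (start + m-1-j)
        rev += w[:, j][3 - safe[m - 1 - j : m - 1 - j + nwin]]
    starts = np.nonzero(ok)[0]
    return starts, fwd[ok], rev[ok]


def _rel(pwm: PWM, scores: np.ndarray) -> np.ndarray:
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        return np.ones_like(scores)
    return (scores - pwm.min_score) / span


def scan_promoter(
    pwm: PWM,
    prom: PromoterSequence,
    strands: str = "both",
    min_rel_score: float | None = None,
) -> list[Hit]:
    """Emit one :class:`Hit` per N-free window per scanned strand.

    ``strands`` is ``"both"`` (default) or ``"forward"``.  Promoters shorter
    than the motif yield an empty list.  ``min_rel_score``, when given,
    keeps only windows whose relative score reaches it (the reference
    scanning ecosystem's equivalent floor defaults to 0.8); ``None`` emits
    every window.
    """
    if strands not in ("both", "forward"):
        raise ValidationError(f"strands must be 'both' or 'forward', got {strands!r}")
    if min_rel_score is not None and not (0 <= min_rel_score <= 1):
        raise ValidationError(f"min_rel_score must be in [0, 1], got {min_rel_score}")
    starts, fwd, rev = scan_scores(pwm, prom.seq)
    hits: list[Hit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        if strand == "-" and strands == "forward":
            continue
        rels = _rel(pwm, scores)
        for s, sc, rl in zip(starts, scores, rels):
            if min_rel_score is not None and rl < min_rel_score:
                continue
            hits.append(
                Hit(
                    matrix_id=pwm.matrix_id,
                    tf_name=pwm.tf_name,
                    gene_id=prom.gene_id,
                    start=int(s),
                    strand=strand,
                    score=float(sc),
                    rel_score=float(rl),
                )
            )
    return hits


def scan_all(
    pwms: Sequence[PWM],
    promoters: Sequence[PromoterSequence],
    strands: str = "both",
    min_rel_score: float | None = None,
) -> list[Hit]:
    """Scan every promoter with every PWM; deterministic order."""
    hits: list[Hit] = []
    for pwm in pwms:
        for prom in promoters:
            hits.extend(scan_promoter(pwm, prom, strands, min_rel_score))
    return hits


HIT_COLUMNS = ["matrix_id", "tf_name", "gene_id", "start", "strand", "score", "rel_score", "pvalue"]


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    """Hits as a DataFrame with the CSV column order."""
    return pd.DataFrame(
        [(h.matrix_id, h.tf_name, h.gene_id, h.start, h.strand, h.score, h.rel_score, h.pvalue)
         for h in hits],
        columns=HIT_COLUMNS,
    )
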