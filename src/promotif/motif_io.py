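"""JASPAR PFM parsing/serialisation and log-odds PWM construction.

A position frequency matrix (PFM) holds the observed base counts at each
position of a transcription-factor binding motif.  For scanning, the PFM is
converted to a position weight matrix (PWM) of log2-odds scores against an
i.i.d. background model:

    p[b, j] = (count[b, j] + pseudocount * bg[b]) / (N_j + pseudocount)
    w[b, j] = log2(p[b, j] / bg[b])

where ``N_j`` is the column count sum.  A window's binding score is the sum
of one weight per position, in bits.  The pseudocount regularises zero
counts; the default of 0.8 follows common practice in the motif-analysis
ecosystem so that real JASPAR matrices score comparably across tools.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import MotifFormatError, ValidationError

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BASE_INDEX",
    "Background",
    "PFM",
    "PWM",
    "parse_jaspar",
    "write_jaspar",
    "pfm_to_pwm",
]


@dataclass(frozen=True)
class Background:
    """i.i.d. base probabilities over A, C, G, T.

    Used both for the log-odds transform and as the null model in exact
    score p-values.
    """

    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.probs) != 4:
            raise ValidationError("background must have exactly 4 probabilities (A,C,G,T)")
        if any(p <= 0 for p in self.probs):
            raise ValidationError("background probabilities must all be > 0")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"background probabilities must sum to 1 (got {sum(self.probs)!r})"
            )

    @classmethod
    def uniform(cls) -> "Background":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "Background":
        """Estimate background from observed A/C/G/T frequencies (N ignored)."""
        counts = np.zeros(4, dtype=float)
        for seq in seqs:
            for b, i in BASE_INDEX.items():
                counts[i] += seq.upper().count(b)
        total = counts.sum()
        if total == 0:
            raise ValidationError("cannot estimate background: no A/C/G/T bases found")
        if np.any(counts == 0):
            # keep all probabilities strictly positive
            counts += 1.0
            total = counts.sum()
        return cls(tuple(counts / total))  # type: ignore[arg-type]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass
class PFM:
    """Position frequency matrix: 4 x m non-negative base counts (rows A,C,G,T)."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError(
                f"{self.matrix_id}: counts must be a 4 x m matrix, got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise ValidationError(f"{self.matrix_id}: motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValidationError(f"{self.matrix_id}: negative count in PFM")
        if not np.any(self.counts.sum(axis=0) > 0):
            raise ValidationError(f"{self.matrix_id}: all columns have zero count sum")

    @property
    def m(self) -> int:
        """Motif length in positions."""
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Per-column argmax base; ties broken by alphabet order A<C<G<T."""
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))


@dataclass
class PWM:
    """Log2-odds weight matrix with its background, pseudocount and score range."""

    matrix_id: str
    tf_name: str
    weights: np.ndarray
    background: Background
    pseudocount: float
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValidationError(f"{self.matrix_id}: weights must be 4 x m")
        self.min_score = float(self.weights.min(axis=0).sum())
        self.max_score = float(self.weights.max(axis=0).sum())

    @property
    def m(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> str:
        """The window spelling the per-column maximum weight (score = max_score)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.weights, axis=0))


def _iter_lines(source: str | TextIO | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_jaspar(source: str | TextIO | Iterable[str]) -> list[PFM]:
    """Parse JASPAR-format PFM text into a list of :class:`PFM`.

    Accepts the 2016+ dialect — a header line ``>ID NAME`` followed by four
    base rows — in both the bracketed (``A [ 1 2 3 ]``) and the bare
    (``A 1 2 3``) row forms.  Base rows are identified by their leading
    letter, not their order.  Non-integer counts are accepted (JASPAR
    contains scaled matrices).
    """
    records: list[PFM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        parts = header[1:].split(None, 1)
        matrix_id = parts[0] if parts else ""
        tf_name = parts[1].strip() if len(parts) > 1 else ""
        missing = [b for b in ALPHABET if b not in rows]
        if missing:
            raise MotifFormatError(
                f"matrix {matrix_id or '<unnamed>'}: missing base row(s) {','.join(missing)}"
            )
        lengths = {len(rows[b]) for b in ALPHABET}
        if len(lengths) != 1:
            raise MotifFormatError(f"matrix {matrix_id}: unequal row lengths {sorted(lengths)}")
        counts = np.array([rows[b] for b in ALPHABET], dtype=float)
        if np.any(counts < 0):
            raise ValidationError(f"matrix {matrix_id}: negative count")
        records.append(PFM(matrix_id=matrix_id, tf_name=tf_name, counts=counts))
        header, rows = None, {}

    for raw in _iter_lines(source):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line
            continue
        letter = line[0].upper()
        if letter not in BASE_INDEX:
            raise MotifFormatError(f"unrecognised line in PFM file: {line[:40]!r}")
        if header is None:
            raise MotifFormatError(f"base row before any '>' header: {line[:40]!r}")
        if letter in rows:
            raise MotifFormatError(f"duplicate {letter} row in matrix {header[1:].split()[0]}")
        body = line[1:].replace("[", " ").replace("]", " ")
        try:
            rows[letter] = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise MotifFormatError(f"non-numeric count in row {line[:40]!r}") from exc
        if not rows[letter]:
            raise MotifFormatError(f"empty {letter} row in matrix {header[1:].split()[0]}")
    flush()
    return records


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def jaspar_text(pfms: Sequence[PFM]) -> str:
    """Serialise PFMs in the canonical bracketed JASPAR dialect."""
    out: list[str] = []
    for pfm in pfms:
        out.append(f">{pfm.matrix_id} {pfm.tf_name}".rstrip())
        for b in ALPHABET:
            vals = " ".join(_format_count(v) for v in pfm.counts[BASE_INDEX[b]])
            out.append(f"{b} [ {vals} ]")
    return "\n".join(out) + ("\n" if out else "")


def write_jaspar(pfms: Sequence[PFM], dest: str | TextIO) -> None:
    text = jaspar_text(pfms)
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)


def pfm_to_pwm(
    pfm: PFM,
    background: Background | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Convert a PFM to a log2-odds PWM against ``background``.

    With ``pseudocount == 0`` every count in a used column must be strictly
    positive (log of zero is undefined).
    """
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    bg = (background or Background.uniform()).as_array()
    counts = pfm.counts
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValidationError(f"{pfm.matrix_id}: zero column sum")
    if pseudocount == 0 and np.any(counts == 0):
        raise ValidationError(
            f"{pfm.matrix_id}: zero count with zero pseudocount (log of zero)"
        )
    p = (counts + pseudocount * bg[:, None]) / (col_sums + pseudocount)
    weights = np.log2(p / bg[:, None])
    return PWM(
        matrix_id=pfm.matrix_id,
        tf_name=pfm.tf_name,
        weights=weights,
        background=Background(tuple(bg)),  # type: ignore[arg-type]
        pseudocount=float(pseudocount),
    )
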