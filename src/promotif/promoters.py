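"""Strand-aware extraction of upstream promoter regions.

The promoter of a gene is the region strictly upstream of its transcription
start site (TSS) on the gene's own strand — by default 800 bp.  The TSS base
itself is excluded.  All coordinates are 0-based half-open on the forward
strand of the source contig; minus-strand promoters are reverse-complemented
so that every returned sequence reads 5'->3' on the gene's strand.

Regions truncated by a contig boundary are returned shorter and flagged
``clipped``.  Lower-case bases are uppercased and IUPAC ambiguity codes
other than N are mapped to N, so downstream scanning only ever sees
A/C/G/T/N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TSSRecord",
    "PromoterSequence",
    "read_tss",
    "extract_promoter",
    "extract_promoters",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# anything that is not A/C/G/T/N after uppercasing becomes N
_SANITIZE = {ord(c): "N" for c in "RYSWKMBDHVU"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize(seq: str) -> str:
    s = seq.upper().translate(_SANITIZE)
    if any(c not in "ACGTN" for c in set(s)):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValidationError(f"sequence contains non-nucleotide characters: {bad}")
    return s


@dataclass(frozen=True)
class TSSRecord:
    """One gene's transcription start site (0-based position of the TSS base)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class PromoterSequence:
    """One gene's upstream region with provenance coordinates.

    ``start``/``end`` are the source interval in forward-strand 0-based
    half-open coordinates; ``seq`` reads 5'->3' on the gene's strand.
    """

    gene_id: str
    seq: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool

    def __len__(self) -> int:
        return len(self.seq)


_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-", "–": "-"}


def _norm_strand(tok: str, context: str) -> str:
    try:
        return _STRAND_ALIASES[tok]
    except KeyError:
        raise ValidationError(f"{context}: unknown strand symbol {tok!r}") from None


def _dedupe(records: list[TSSRecord]) -> list[TSSRecord]:
    seen: dict[str, TSSRecord] = {}
    for rec in records:
        if rec.gene_id in seen:
            logger.warning("duplicate gene_id %s in TSS file: keeping first occurrence", rec.gene_id)
            continue
        seen[rec.gene_id] = rec
    return list(seen.values())


def read_tss(path: str, format: str = "auto") -> list[TSSRecord]:
    """Read TSS annotation from BED6 or a 4-column TSV (gene_id, chrom, tss, strand).

    BED6 intervals are 0-based half-open; the TSS is chromStart for ``+``
    genes and chromEnd - 1 for ``-`` genes.  Duplicate gene_ids keep the
    first occurrence with a logged warning.
    """
    if format not in ("auto", "bed6", "tsv"):
        raise ValidationError(f"unknown TSS format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    if not lines:
        raise ValidationError(f"TSS file {path} is empty")

    if format == "auto":
        ncol = len(lines[0].split("\t")) if "\t" in lines[0] else len(lines[0].split())
        format = "bed6" if ncol >= 6 else "tsv"

    records: list[TSSRecord] = []
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t") if "\t" in line else line.split()
        ctx = f"{path}:{i}"
        if format == "bed6":
            if len(fields) < 6:
                raise ValidationError(f"{ctx}: BED6 line has {len(fields)} fields")
            chrom, start_s, end_s, name, _score, strand_tok = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(f"{ctx}: malformed coordinates {start_s!r}/{end_s!r}") from None
            if start < 0 or end <= start:
                raise ValidationError(f"{ctx}: invalid interval [{start},{end})")
            strand = _norm_strand(strand_tok, ctx)
            tss = start if strand == "+" else end - 1
            records.append(TSSRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
        else:
            if i == 1 and len(fields) >= 3 and not fields[2].lstrip("-").isdigit():
                continue  # header row
            if len(fields) < 4:
                raise ValidationError(f"{ctx}: TSV line needs 4 columns (gene_id, chrom, tss, strand)")
            gene_id, chrom, tss_s, strand_tok = fields[:4]
            try:
                tss = int(tss_s)
            except ValueError:
                raise ValidationError(f"{ctx}: malformed TSS coordinate {tss_s!r}") from None
            records.append(
                TSSRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=_norm_strand(strand_tok, ctx))
            )
    if not records:
        raise ValidationError(f"TSS file {path} contains no records")
    return _dedupe(records)


def _contig_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a pyfaidx Fasta or a plain mapping of strings."""
    segment = genome[chrom][start:end]
    seq = getattr(segment, "seq", segment)
    return str(seq)


def extract_promoter(genome, rec: TSSRecord, upstream: int = 800) -> PromoterSequence:
    """Extract the region of ``upstream`` bp strictly upstream of the TSS.

    For a ``+`` gene this is the forward-strand interval
    ``[max(0, tss - L), tss)``; for a ``-`` gene it is
    ``[tss + 1, min(contig_len, tss + 1 + L))`` reverse-complemented.
    """
    if upstream < 1:
        raise ValidationError(f"upstream length must be >= 1, got {upstream}")
    try:
        clen = _contig_len(genome, rec.chrom)
    except KeyError:
        raise KeyError(f"chromosome {rec.chrom!r} not found in genome") from None
    if rec.tss >= clen:
        raise ValidationError(
            f"{rec.gene_id}: tss {rec.tss} beyond end of contig {rec.chrom} (length {clen})"
        )
    if rec.strand == "+":
        start, end = max(0, rec.tss - upstream), rec.tss
        seq = _sanitize(_fetch(genome, rec.chrom, start, end))
    else:
        start, end = rec.tss + 1, min(clen, rec.tss + 1 + upstream)
        seq = reverse_complement(_sanitize(_fetch(genome, rec.chrom, start, end)))
    return PromoterSequence(
        gene_id=rec.gene_id,
        seq=seq,
        chrom=rec.chrom,
        start=start,
        end=end,
        strand=rec.strand,
        clipped=len(seq) < upstream,
    )


def extract_promoters(genome, records: Sequence[TSSRecord], upstream: int = 800) -> list[PromoterSequence]:
    return [extract_promoter(genome, rec, upstream) for rec in records]


def write_promoters_fasta(promoters: Iterable[PromoterSequence], dest: str | TextIO) -> None:
    """Write promoters as FASTA with header ``gene_id|chrom:start-end(strand)``."""

    def _write(fh: TextIO) -> None:
        for p in promoters:
            fh.write(f">{p.gene_id}|{p.chrom}:{p.start}-{p.end}({p.strand})\n{p.seq}\n")

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            _write(fh)
    else:
        _write(dest)


def read_promoters_fasta(path: str) -> list[PromoterSequence]:
    """Read promoters written by :func:`write_promoters_fasta`."""
    promoters: list[PromoterSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = _sanitize("".join(chunks))
        gene_id, _, loc = header.partition("|")
        chrom, start, end, strand = "", 0, len(seq), "+"
        if loc:
            chrom, _, rest = loc.partition(":")
            span, _, st = rest.partition("(")
            a, _, b = span.partition("-")
            if a.isdigit() and b.isdigit():
                start, end = int(a), int(b)
            strand = st.rstrip(")") or "+"
        promoters.append(
            PromoterSequence(gene_id=gene_id, seq=seq, chrom=chrom, start=start, end=end,
                             strand=strand, clipped=False)
        )
        header, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
            else:
                chunks.append(line)
    flush()
    if not promoters:
        raise ValidationError(f"no sequences in FASTA {path}")
    return promoters
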