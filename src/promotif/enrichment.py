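"""Top-quantile hit filtering, TF-gene deduplication and enrichment ranking.

The screening keeps only the strongest-scoring site candidates: all hits
from all TFs and promoters are pooled, ranked by binding score, and those
reaching the empirical top-q quantile (default top 1%) are retained.  A TF
may hit the same promoter many times; multiple hits for one TF-gene
combination are collapsed to the single best.  Each TF's enrichment ratio
is then the number of distinct genes of interest it hits, divided by the
total number of genes of interest — e.g. unique hits in 8 of 10 genes give
a ratio of 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motif_io import PWM
from .scanner import Hit

__all__ = [
    "EnrichmentRow",
    "quantile_threshold",
    "filter_top_quantile",
    "dedup_hits",
    "enrichment_table",
    "enrichment_to_frame",
]


@dataclass
class EnrichmentRow:
    """Per-TF unique-gene-hit count, enrichment ratio and target genes."""

    matrix_id: str
    tf_name: str
    unique_gene_hits: int
    n_genes: int
    ratio: float
    target_genes: list[str]


def quantile_threshold(scores: np.ndarray, q: float = 0.01) -> float:
    """Score cutoff of the top-q fraction: the nearest-rank-above empirical
    (1-q)-quantile, so that with n distinct scores exactly floor(q*n) (and
    never fewer than one) reach it, and ties at the cutoff saturate."""
    if not (0 < q < 1):
        raise ValidationError(f"quantile fraction must be in (0, 1), got {q}")
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("quantile filter: empty score list")
    return float(np.quantile(scores, 1.0 - q, method="higher"))


def filter_top_quantile(
    hits: Sequence[Hit], q: float = 0.01, metric: str = "raw"
) -> list[Hit]:
    """Retain hits whose score reaches the pooled top-q empirical quantile.

    ``metric`` selects the ranking score: ``"raw"`` (bits, the default) or
    ``"relative"`` (min-max normalised).  Ties at the threshold are all
    retained; at least the maximum-scoring hit always survives.
    """
    if metric not in ("raw", "relative"):
        raise ValidationError(f"metric must be 'raw' or 'relative', got {metric!r}")
    if not hits:
        raise ValidationError("quantile filter: no hits to filter")
    values = np.array([h.score if metric == "raw" else h.rel_score for h in hits])
    thr = quantile_threshold(values, q)
    return [h for h, v in zip(hits, values) if v >= thr]


def _dedup_key(h: Hit) -> tuple:
    # best score first; ties -> smallest start, then forward strand
    return (-h.score, h.start, 0 if h.strand == "+" else 1)


def dedup_hits(hits: Sequence[Hit]) -> list[Hit]:
    """Keep exactly one hit per (matrix_id, gene_id): the highest-scoring,
    ties broken by smallest start then forward strand.  Output order is
    deterministic (sorted by matrix_id, gene_id) regardless of input order."""
    best: dict[tuple[str, str], Hit] = {}
    for h in hits:
        key = (h.matrix_id, h.gene_id)
        cur = best.get(key)
        if cur is None or _dedup_key(h) < _dedup_key(cur):
            best[key] = h
    return [best[k] for k in sorted(best)]


def enrichment_table(
    unique_hits: Sequence[Hit],
    gene_list: Sequence[str],
    pwms: Sequence[PWM],
) -> list[EnrichmentRow]:
    """One row per PWM (zero-hit PWMs included), sorted by ratio descending,
    ties by tf_name then matrix_id ascending.

    ``unique_hits`` must already be deduplicated; every hit must reference a
    gene present in ``gene_list``.
    """
    if not gene_list:
        raise ValidationError("enrichment: gene list is empty")
    genes = list(dict.fromkeys(gene_list))
    gene_set = set(genes)
    n_genes = len(genes)

    per_tf: dict[str, set[str]] = {pwm.matrix_id: set() for pwm in pwms}
    names = {pwm.matrix_id: pwm.tf_name for pwm in pwms}
    for h in unique_hits:
        if h.gene_id not in gene_set:
            raise ValidationError(
                f"enrichment: hit gene {h.gene_id!r} not in the gene list"
            )
        per_tf.setdefault(h.matrix_id, set()).add(h.gene_id)
        names.setdefault(h.matrix_id, h.tf_name)

    rows = [
        EnrichmentRow(
            matrix_id=mid,
            tf_name=names[mid],
            unique_gene_hits=len(hit_genes),
            n_genes=n_genes,
            ratio=len(hit_genes) / n_genes,
            target_genes=sorted(hit_genes, key=genes.index),
        )
        for mid, hit_genes in per_tf.items()
    ]
    rows.sort(key=lambda r: (-r.ratio, r.tf_name, r.matrix_id))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.matrix_id, r.tf_name, r.unique_gene_hits, r.n_genes, r.ratio,
             ";".join(r.target_genes))
            for r in rows
        ],
        columns=["matrix_id", "tf_name", "unique_gene_hits", "n_genes", "ratio", "target_genes"],
    )
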