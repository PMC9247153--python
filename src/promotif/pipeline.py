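"""End-to-end orchestration: gene list -> promoters -> scan -> filter -> rank.

A run takes a genome FASTA, a TSS annotation, a JASPAR PFM file and a gene
list (given directly, or derived from a differential-expression table with
|logFC| > 0.585 and adjusted p < 0.05), and produces the two result tables
of the screening: the retained hits with their exact p-values
(``hits.csv``) and the per-TF enrichment ranking (``enrichment.csv``),
plus a JSON metadata file recording versions, parameters and input
checksums so a run can be reproduced bit-exactly.

p-values are computed only for hits surviving the top-quantile filter;
having been selected from the extreme upper tail they are always small,
but they are stored for inspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .enrichment import (dedup_hits, enrichment_table, enrichment_to_frame,
                         quantile_threshold)
from .errors import ValidationError
from .motif_io import Background, parse_jaspar, pfm_to_pwm
from .promoters import extract_promoters, read_tss
from .pvalue import score_distribution
from .scanner import Hit, hits_to_frame, scan_scores

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "filter_de_genes", "read_gene_list", "run"]

HITS_SCHEMA = "# promotif hits v1: matrix_id,tf_name,gene_id,start,strand,score,rel_score,pvalue"
ENRICH_SCHEMA = ("# promotif enrichment v1: matrix_id,tf_name,unique_gene_hits,"
                 "n_genes,ratio,target_genes")


@dataclass
class RunConfig:
    """Paths and parameters of one screening run.

    Defaults pin the published analysis settings: 800 bp upstream windows,
    an 80% relative-score scan floor (the reference scanner's default),
    the top 1% of pooled binding scores retained, pseudocount 0.8,
    p-value grid 1e-4 bits, both strands scanned, and the DE thresholds
    |logFC| > 0.585 with adjusted p < 0.05.  Set ``min_rel_score`` to 0
    for the fully inclusive scan (every window enters the ranking).
    """

    genome: str = ""
    tss: str = ""
    pfm: str = ""
    genes: str = ""            # comma-separated gene list file
    de_table: str = ""         # alternative: DE results table (CSV/TSV)
    outdir: str = "."
    upstream: int = 800
    quantile: float = 0.01
    min_rel_score: float = 0.8
    pseudocount: float = 0.8
    background: str | list[float] = "uniform"   # "uniform", "promoters", or 4 probs
    epsilon: float = 1e-4
    strands: str = "both"
    metric: str = "raw"
    lfc_threshold: float = 0.585
    padj_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides take precedence (CLI > file)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("genome", "tss", "pfm"):
            p = getattr(self, name)
            if not p:
                raise ValidationError(f"config: {name} path is required")
            if not os.path.exists(p):
                raise ValidationError(f"config: {name} file not found: {p}")
        if not self.genes and not self.de_table:
            raise ValidationError("config: either a gene list or a DE table is required")
        for name, p in (("genes", self.genes), ("de_table", self.de_table)):
            if p and not os.path.exists(p):
                raise ValidationError(f"config: {name} file not found: {p}")
        if self.upstream < 1:
            raise ValidationError("config: upstream must be >= 1")
        if not (0 < self.quantile < 1):
            raise ValidationError("config: quantile must be in (0, 1)")
        if not (0 <= self.min_rel_score <= 1):
            raise ValidationError("config: min_rel_score must be in [0, 1]")
        if self.pseudocount < 0:
            raise ValidationError("config: pseudocount must be >= 0")
        if self.epsilon <= 0:
            raise ValidationError("config: epsilon must be > 0")
        if self.strands not in ("both", "forward"):
            raise ValidationError("config: strands must be 'both' or 'forward'")
        if self.metric not in ("raw", "relative"):
            raise ValidationError("config: metric must be 'raw' or 'relative'")


@dataclass
class RunReport:
    """Stage counts and output paths of a completed run."""

    n_genes: int
    n_promoters: int
    n_pwms: int
    n_raw_hits: int
    n_retained: int
    n_unique_pairs: int
    threshold: float
    hits_csv: str
    enrichment_csv: str
    metadata_json: str
    top_rows: list = field(default_factory=list)


def filter_de_genes(table, lfc_threshold: float = 0.585, padj_threshold: float = 0.05) -> list[str]:
    """Genes with |logFC| strictly above and adjusted p strictly below threshold.

    ``table`` is a DataFrame or a CSV/TSV path with columns gene_id, logFC
    and an adjusted-p column (padj / adj.P.Val / FDR accepted).  Input order
    is preserved; duplicate gene ids are dropped with a warning.
    """
    import pandas as pd

    if isinstance(table, (str, os.PathLike)):
        table = pd.read_csv(table, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in table.columns}
    gene_col = next((cols[c] for c in ("gene_id", "gene", "symbol") if c in cols), None)
    lfc_col = next((cols[c] for c in ("logfc", "log2foldchange", "lfc") if c in cols), None)
    padj_col = next((cols[c] for c in ("padj", "adj.p.val", "fdr", "qvalue", "adjusted_pvalue")
                     if c in cols), None)
    missing = [n for n, c in (("gene_id", gene_col), ("logFC", lfc_col), ("padj", padj_col))
               if c is None]
    if missing:
        raise ValidationError(f"DE table: missing column(s) {missing}; have {list(table.columns)}")
    genes: list[str] = []
    seen: set[str] = set()
    for idx, row in enumerate(table.itertuples(index=False), start=1):
        rec = dict(zip(table.columns, row))
        try:
            lfc = float(rec[lfc_col])
            padj = float(rec[padj_col])
        except (TypeError, ValueError):
            raise ValidationError(f"DE table row {idx}: non-numeric logFC/padj") from None
        if not (0 <= padj <= 1):
            raise ValidationError(f"DE table row {idx}: padj {padj} outside [0, 1]")
        if abs(lfc) > lfc_threshold and padj < padj_threshold:
            g = str(rec[gene_col])
            if g in seen:
                logger.warning("DE table: duplicate gene %s dropped", g)
                continue
            seen.add(g)
            genes.append(g)
    return genes


def read_gene_list(path: str) -> list[str]:
    """Comma- and/or newline-separated gene identifiers, trimmed and
    deduplicated preserving order."""
    with open(path) as fh:
        raw = fh.read()
    genes: list[str] = []
    seen: set[str] = set()
    for tok in raw.replace("\n", ",").split(","):
        g = tok.strip()
        if not g:
            continue
        if g in seen:
            logger.warning("gene list: duplicate identifier %s kept once", g)
            continue
        seen.add(g)
        genes.append(g)
    if not genes:
        raise ValidationError(f"gene list {path} is empty after parsing")
    return genes


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_background(config: RunConfig, promoters) -> Background:
    bg = config.background
    if bg == "uniform" or bg is None:
        return Background.uniform()
    if bg == "promoters":
        return Background.from_sequences(p.seq for p in promoters)
    if isinstance(bg, (list, tuple)) and len(bg) == 4:
        return Background(tuple(float(x) for x in bg))
    raise ValidationError(f"config: unrecognised background {bg!r}")


def run(config: RunConfig) -> RunReport:
    """Execute the full screening and write hits.csv, enrichment.csv and
    run_metadata.json into ``config.outdir``.

    Outputs are byte-identical for identical inputs, config and seed
    (timestamps live only in the metadata file, outside the CSVs).
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)

    # --- gene list
    if config.genes:
        gene_list = read_gene_list(config.genes)
    else:
        gene_list = filter_de_genes(config.de_table, config.lfc_threshold, config.padj_threshold)
    if not gene_list:
        raise ValidationError("no genes of interest after filtering")
    logger.info("stage genes: %d genes of interest", len(gene_list))

    # --- promoters
    tss_records = {r.gene_id: r for r in read_tss(config.tss)}
    missing = [g for g in gene_list if g not in tss_records]
    if missing:
        logger.warning("no TSS for %d gene(s): %s — skipped; the enrichment "
                       "denominator keeps the full gene list", len(missing), ",".join(missing))
    selected = [tss_records[g] for g in gene_list if g in tss_records]
    if not selected:
        raise ValidationError("none of the genes of interest have a TSS record")
    import pyfaidx

    genome = pyfaidx.Fasta(config.genome)
    promoters = extract_promoters(genome, selected, config.upstream)
    logger.info("stage promoters: %d promoters extracted (%d clipped)",
                len(promoters), sum(p.clipped for p in promoters))

    # --- motifs
    with open(config.pfm) as fh:
        pfms = parse_jaspar(fh)
    if not pfms:
        raise ValidationError(f"no PFM records in {config.pfm}")
    background = _resolve_background(config, promoters)
    pwms = [pfm_to_pwm(p, background, config.pseudocount) for p in pfms]
    logger.info("stage motifs: %d PWMs (pseudocount %g)", len(pwms), config.pseudocount)

    # --- scan: collect score arrays first, materialise only retained hits.
    # the relative-score floor (reference-scanner default 80%) is applied
    # before pooling; the top-quantile threshold is taken over the pool
    scans = []  # (pwm, promoter, starts, strand, scores, rel_scores)
    n_raw = 0
    for pwm in pwms:
        span = pwm.max_score - pwm.min_score
        for prom in promoters:
            starts, fwd, rev = scan_scores(pwm, prom.seq)
            for strand, scores in (("+", fwd), ("-", rev)):
                if strand == "-" and config.strands == "forward":
                    continue
                n_raw += scores.size
                rels = (scores - pwm.min_score) / span if span > 0 else np.ones_like(scores)
                keep = rels >= config.min_rel_score
                if np.any(keep):
                    scans.append((pwm, prom, starts[keep], strand, scores[keep], rels[keep]))
    if n_raw == 0:
        raise ValidationError("scan produced no hits (promoters shorter than every motif?)")
    pool_metric = np.concatenate(
        [(rels if config.metric == "relative" else scores)
         for _pwm, _prom, _starts, _strand, scores, rels in scans]
    ) if scans else np.empty(0)
    logger.info("stage scan: %d raw hits, %d at rel_score >= %g",
                n_raw, pool_metric.size, config.min_rel_score)
    if pool_metric.size == 0:
        raise ValidationError("no hits pass the relative-score floor; lower min_rel_score")
    thr = quantile_threshold(pool_metric, config.quantile)

    retained: list[Hit] = []
    dists = {pwm.matrix_id: None for pwm in pwms}
    for pwm, prom, starts, strand, scores, rels in scans:
        keep = (rels if config.metric == "relative" else scores) >= thr
        if not np.any(keep):
            continue
        if dists[pwm.matrix_id] is None:
            dists[pwm.matrix_id] = score_distribution(pwm, background, config.epsilon)
        dist = dists[pwm.matrix_id]
        for s, sc, rl in zip(starts[keep], scores[keep], rels[keep]):
            retained.append(Hit(matrix_id=pwm.matrix_id, tf_name=pwm.tf_name,
                                gene_id=prom.gene_id, start=int(s), strand=strand,
                                score=float(sc), rel_score=float(rl),
                                pvalue=dist.survival(float(sc))))
    logger.info("stage filter: %d hits at or above the top-%g%% threshold (%.4f %s)",
                len(retained), 100 * config.quantile, thr, config.metric)

    unique = dedup_hits(retained)
    logger.info("stage dedup: %d unique TF-gene pairs", len(unique))
    rows = enrichment_table(unique, gene_list, pwms)

    # --- outputs
    hits_csv = os.path.join(config.outdir, "hits.csv")
    enr_csv = os.path.join(config.outdir, "enrichment.csv")
    meta_json = os.path.join(config.outdir, "run_metadata.json")

    hits_df = hits_to_frame(sorted(retained, key=lambda h: (h.matrix_id, h.gene_id,
                                                            h.start, h.strand)))
    with open(hits_csv, "w") as fh:
        fh.write(HITS_SCHEMA + "\n")
        hits_df.to_csv(fh, index=False)
    with open(enr_csv, "w") as fh:
        fh.write(ENRICH_SCHEMA + "\n")
        enrichment_to_frame(rows).to_csv(fh, index=False)

    import datetime

    meta = {
        "tool": "promotif",
        "version": __version__,
        "platform": platform.platform(),
        "python": platform.python_version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        "input_checksums": {name: _sha256(p) for name, p in
                            (("genome", config.genome), ("tss", config.tss),
                             ("pfm", config.pfm), ("genes", config.genes),
                             ("de_table", config.de_table)) if p},
        "stage_counts": {"genes": len(gene_list), "promoters": len(promoters),
                         "pwms": len(pwms), "raw_hits": n_raw,
                         "retained_hits": len(retained), "unique_pairs": len(unique)},
        "score_threshold": thr,
    }
    with open(meta_json, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunReport(n_genes=len(gene_list), n_promoters=len(promoters), n_pwms=len(pwms),
                     n_raw_hits=n_raw, n_retained=len(retained), n_unique_pairs=len(unique),
                     threshold=float(thr), hits_csv=hits_csv, enrichment_csv=enr_csv,
                     metadata_json=meta_json, top_rows=rows[:10])
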