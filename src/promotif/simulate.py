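"""Synthetic promoters with motif instances planted at known positions.

The generator builds i.i.d.-background promoter sequences, plants one motif
instance per selected promoter at a uniform random position and strand, and
records the ground truth, so the whole screening pipeline can be exercised
end to end with a known answer.  Decoy PFMs — column-wise permutations of
the planted matrix that preserve base composition and information content
while destroying the positional signal — provide the ranking null.

Fixtures are written as plain-text files (promoter FASTA, a synthetic
genome with each promoter embedded upstream of a known TSS, a TSS table,
a JASPAR PFM file including decoys, a truth CSV and a JSON metadata file),
and re-reading them reproduces the structures exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motif_io import ALPHABET, Background, PFM, write_jaspar
from .promoters import PromoterSequence, reverse_complement

__all__ = [
    "PlantedTruth",
    "random_promoters",
    "plant_motifs",
    "decoy_pfms",
    "default_planted_pfm",
    "write_fixture",
    "read_truth",
]


def default_planted_pfm(consensus: str = "TGACGTCATGCA", depth: int = 100,
                        dominance: float = 0.85, matrix_id: str = "PLANT001",
                        tf_name: str = "planted") -> PFM:
    """An information-rich synthetic motif for planting experiments.

    Each column gives ``dominance`` of ``depth`` counts to the consensus
    base and splits the rest evenly — roughly 1.3 bits of information per
    position, comparable to a well-defined JASPAR core motif.
    """
    counts = np.zeros((4, len(consensus)))
    major = dominance * depth
    minor = (depth - major) / 3.0
    for j, b in enumerate(consensus):
        counts[:, j] = minor
        counts[ALPHABET.index(b), j] = major
    return PFM(matrix_id=matrix_id, tf_name=tf_name, counts=counts)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted motif instance.

    ``position`` is the 0-based offset of the instance in the promoter;
    ``planted_seq`` is the instance read on the motif strand (for a ``-``
    plant the promoter carries its reverse complement).
    """

    gene_id: str
    matrix_id: str
    position: int
    strand: str
    planted_seq: str


def random_promoters(
    n: int,
    length: int = 800,
    background: Background | None = None,
    seed: int = 0,
) -> list[PromoterSequence]:
    """``n`` i.i.d.-background promoters of the given length.

    Deterministic for a fixed seed; gene ids are ``g0001``, ``g0002``, ...
    Each promoter is given synthetic provenance: its own contig named after
    the gene, interval ``[0, length)`` on the plus strand.
    """
    if n < 1 or length < 1:
        raise ValidationError(f"need n >= 1 and length >= 1, got n={n}, length={length}")
    bg = (background or Background.uniform()).as_array()
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    return [
        PromoterSequence(
            gene_id=f"g{i + 1:04d}",
            seq="".join(letters[rng.choice(4, size=length, p=bg)]),
            chrom=f"chr_g{i + 1:04d}",
            start=0,
            end=length,
            strand="+",
            clipped=False,
        )
        for i in range(n)
    ]


def _sample_instance(pfm: PFM, mode: str, rng: np.random.Generator) -> str:
    if mode == "consensus":
        return pfm.consensus()
    probs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)
    return "".join(ALPHABET[rng.choice(4, p=probs[:, j])] for j in range(pfm.m))


def plant_motifs(
    promoters: list[PromoterSequence],
    pfm: PFM,
    fraction: float,
    mode: str = "consensus",
    seed: int = 0,
) -> tuple[list[PromoterSequence], list[PlantedTruth]]:
    """Plant one motif instance into ``round(fraction * n)`` promoters.

    The receiving promoters, the position and the strand are drawn
    uniformly at random.  ``mode="consensus"`` plants the per-column argmax
    string; ``mode="sample"`` draws each base from the column frequencies.
    All other promoter positions are untouched; inputs are not modified.
    """
    if not (0 <= fraction <= 1):
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    if mode not in ("consensus", "sample"):
        raise ValidationError(f"mode must be 'consensus' or 'sample', got {mode!r}")
    m = pfm.m
    if promoters and len(promoters[0].seq) < m:
        raise ValidationError("promoters shorter than the motif cannot receive a plant")
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(promoters)))
    chosen = sorted(rng.choice(len(promoters), size=n_plant, replace=False))
    out = [
        PromoterSequence(**{**p.__dict__}) for p in promoters
    ]
    truths: list[PlantedTruth] = []
    for i in chosen:
        p = out[i]
        pos = int(rng.integers(0, len(p.seq) - m + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        inst = _sample_instance(pfm, mode, rng)
        embedded = inst if strand == "+" else reverse_complement(inst)
        p.seq = p.seq[:pos] + embedded + p.seq[pos + m :]
        truths.append(
            PlantedTruth(gene_id=p.gene_id, matrix_id=pfm.matrix_id, position=pos,
                         strand=strand, planted_seq=inst)
        )
    return out, truths


def decoy_pfms(pfm: PFM, k: int, seed: int = 0) -> list[PFM]:
    """``k`` decoys: the counts of each column independently permuted across
    bases, and the column order shuffled.  Base composition and per-column
    information content are preserved; the positional signal is destroyed."""
    if k < 0:
        raise ValidationError(f"decoy count must be >= 0, got {k}")
    rng = np.random.default_rng(seed)
    decoys: list[PFM] = []
    for d in range(k):
        counts = pfm.counts.copy()
        for j in range(pfm.m):
            counts[:, j] = counts[rng.permutation(4), j]
        counts = counts[:, rng.permutation(pfm.m)]
        decoys.append(
            PFM(matrix_id=f"DECOY{d + 1:03d}", tf_name=f"decoy{d + 1:03d}", counts=counts)
        )
    return decoys


# layout of a written fixture directory
FIXTURE_FILES = {
    "genome": "genome.fa",
    "promoters": "promoters.fa",
    "tss": "tss.tsv",
    "pfms": "motifs.jaspar",
    "truth": "truth.csv",
    "meta": "fixture.json",
}

_TSS_PAD = 10  # bases separating the promoter from the contig edge / TSS side


def write_fixture(
    promoters: list[PromoterSequence],
    truths: list[PlantedTruth],
    pfms: list[PFM],
    outdir: str,
    seed: int | None = None,
    params: dict | None = None,
) -> dict[str, str]:
    """Write a complete pipeline fixture; returns the path of each file.

    Each promoter is embedded in its own synthetic contig with a known TSS.
    Genes alternate strands: even-indexed genes sit on ``+`` (contig =
    promoter + downstream pad, TSS at position L), odd-indexed genes on
    ``-`` (contig = pad + reverse complement of the promoter, TSS at the
    pad's last base), so extraction re-derives the exact promoter strings
    on both strands.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in FIXTURE_FILES.items()}
    rng = np.random.default_rng(0 if seed is None else seed)
    letters = np.array(list(ALPHABET))

    genome_lines: list[str] = []
    tss_lines = ["gene_id\tchrom\ttss\tstrand"]
    prom_lines: list[str] = []
    for i, p in enumerate(promoters):
        pad = "".join(letters[rng.integers(0, 4, size=_TSS_PAD)])
        chrom = f"chr_{p.gene_id}"
        if i % 2 == 0:
            contig = p.seq + pad
            tss, strand = len(p.seq), "+"
            start, end = 0, len(p.seq)
        else:
            contig = pad + reverse_complement(p.seq)
            tss, strand = _TSS_PAD - 1, "-"
            start, end = _TSS_PAD, _TSS_PAD + len(p.seq)
        genome_lines.append(f">{chrom}\n{contig}")
        tss_lines.append(f"{p.gene_id}\t{chrom}\t{tss}\t{strand}")
        prom_lines.append(f">{p.gene_id}|{chrom}:{start}-{end}({strand})\n{p.seq}")

    with open(paths["genome"], "w") as fh:
        fh.write("\n".join(genome_lines) + "\n")
    with open(paths["tss"], "w") as fh:
        fh.write("\n".join(tss_lines) + "\n")
    with open(paths["promoters"], "w") as fh:
        fh.write("\n".join(prom_lines) + "\n")
    write_jaspar(pfms, paths["pfms"])
    pd.DataFrame([asdict(t) for t in truths],
                 columns=["gene_id", "matrix_id", "position", "strand", "planted_seq"]
                 ).to_csv(paths["truth"], index=False)
    with open(paths["meta"], "w") as fh:
        json.dump({"seed": seed, "n_promoters": len(promoters),
                   "promoter_length": len(promoters[0].seq) if promoters else 0,
                   "n_pfms": len(pfms), "params": params or {}}, fh, indent=2)
        fh.write("\n")
    return paths


def read_truth(path: str) -> list[PlantedTruth]:
    df = pd.read_csv(path)
    return [
        PlantedTruth(gene_id=str(r.gene_id), matrix_id=str(r.matrix_id),
                     position=int(r.position), strand=str(r.strand),
                     planted_seq=str(r.planted_seq))
        for r in df.itertuples()
    ]
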