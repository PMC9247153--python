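# Methods

## Model and procedure

The screening treats promoter sequences as draws from an i.i.d. nucleotide
background and asks which motifs occur in them more strongly than that
background explains. The pipeline is:

1. **Promoter extraction.** For each gene, the `L` bp strictly upstream of
   its TSS on its own strand (default `L = 800`). Coordinates are 0-based
   half-open throughout; for a `+` gene the interval is `[tss−L, tss)`, for
   a `−` gene `[tss+1, tss+1+L)` reverse-complemented. The TSS base itself
   is excluded — "upstream" means upstream. Regions truncated by a contig
   edge are kept and flagged `clipped`; promoters shorter than a motif
   simply yield no windows. Lower-case bases are uppercased and non-ACGTN
   IUPAC codes become N; windows containing N are skipped rather than
   penalised, which avoids inventing an ambiguity score.

2. **Scoring.** PFM counts become log2-odds weights with a pseudocount
   (`p = (c + κ·π_b)/(N + κ)`, `w = log2(p/π_b)`, default `κ = 0.8`).
   Window scores are column sums in bits; minus-strand hits score the
   reverse complement of the window but are reported at the window's
   leftmost promoter coordinate, so both strands share one coordinate
   frame. Scanning is vectorised (integer-encoded sequence, one weight-row
   gather per motif position) and exactly equals the naive per-position
   loop, which the tests keep as an independent oracle.

3. **Selection.** Windows below a relative-score floor (default 0.80) are
   dropped; all remaining hits from all TFs, genes and strands are pooled
   and the top fraction `q` (default 0.01) by raw score retained. The
   threshold is the nearest-rank-above empirical `(1−q)`-quantile
   (`numpy.quantile(..., method="higher")`): with `n` distinct scores
   exactly `⌊qn⌋` (never fewer than one) reach it, ties at the threshold
   are all kept, and retention is reproducible across platforms because no
   interpolation is involved. Ranking by raw score is the default; relative
   score is selectable (`metric="relative"`) since raw scores are not
   scale-comparable across motif lengths.

4. **p-values.** Each retained hit gets the exact tail probability
   `P(S ≥ s)` of its score under the background, from the full distribution
   of `S = Σ_j W_j` computed by convolving the four-point per-position laws
   on an ε-grid (default `ε = 1e-4` bits). Weights are rounded **up** to
   the grid and the query score **down**, so the discretised score of every
   window dominates its true score and the reported p-value never
   underestimates the true one; the over-estimate is bounded by the
   probability mass of windows within `(m+1)·ε` below the query — in
   practice at most one enumeration word's mass, as the tests verify
   against exhaustive `4^m` enumeration. p-values are computed only after
   the quantile filter (they are diagnostics of already-selected extreme
   scores, and are always small); the inverse lookup `pvalue_to_score`
   returns the smallest grid score meeting a target α and flags α below the
   consensus-window probability as unattainable. The same single-strand
   null is used for minus-strand hits; no multiplicity correction is
   applied across positions, strands or TF×gene tests — the method defines
   a descriptive ratio, not a hypothesis test.

5. **Enrichment.** One hit per (matrix, gene) survives deduplication — the
   highest score, ties broken by smaller start then forward strand — and
   each TF's enrichment ratio is unique-gene-hits divided by the total
   number of genes of interest. Rows are sorted by ratio descending, ties
   by TF name then matrix id, so output CSVs are byte-stable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `upstream` (L) | 800 bp | promoter length upstream of the TSS |
| `quantile` (q) | 0.01 | pooled top-score fraction retained |
| `min_rel_score` | 0.80 | scan floor on the min-max normalised score |
| `pseudocount` (κ) | 0.8 | PFM regulariser in the log-odds transform |
| `background` | uniform | i.i.d. base probabilities; `"promoters"` estimates them from the extracted set |
| `epsilon` (ε) | 1e-4 bits | p-value DP grid; one-sided error ≤ mass within `(m+1)ε` of the query |
| `strands` | both | promoter elements are orientation-ambiguous |
| `lfc_threshold`, `padj_threshold` | 0.585, 0.05 | DE gene selection, strict inequalities |

The relative-score floor deserves a note. A pooled top-1% rank filter alone
cannot separate a true motif from decoys that share its score distribution:
every matrix then retains ~1% of its own windows, roughly 16 per
promoter, and every ratio saturates at 1. The floor restores the intended
geometry — only near-consensus windows enter the ranking, so the threshold
lands on genuinely motif-like scores — and 0.80 is the long-standing
default of the scanning ecosystem this workflow comes from. Setting
`min_rel_score = 0` gives the fully inclusive scan if wanted.

Pseudocount, background and log base are conventions rather than derived
quantities; the defaults (κ = 0.8, uniform background, log2) follow the
de-facto standard of the motif-analysis ecosystem so that real JASPAR
matrices score comparably across tools, and all three are configurable.

## Synthetic data

`promotif.simulate` builds promoters as i.i.d. draws from the background,
plants one motif instance per selected promoter (uniform random position
and strand; consensus string or per-column sampled), and emits decoy PFMs
whose columns have their counts permuted across bases and their order
shuffled — preserving base composition and per-column information content
while destroying any match to the planted sites, which makes them a fair
ranking null. Fixtures are written as plain text (genome FASTA with each
promoter embedded on alternating strands of its own contig, TSS TSV,
JASPAR motif file, truth CSV, JSON metadata) and round-trip exactly.

The headline check plants a 12-bp, ~1.3-bit-per-position consensus motif in
8 of 10 promoters of 800 bp with 20 decoys, mirroring an
8-of-10-genes-of-interest geometry at desk scale: the planted TF must top
the enrichment table with ratio ≥ 0.8 in ≥95% of 50 seeded replicates. The
generator emulates none of the structure of real promoters — no CpG
islands, repeats, positional bias toward the TSS, or co-occurring motifs —
so passing it demonstrates that the machinery (extraction arithmetic,
strand handling, pooled ranking, deduplication, ratio computation) is
correct, not that the method's biological discrimination on real genomes
has any particular sensitivity or false-positive rate.

## Numerical choices and degenerate inputs

- Deterministic tie-breaks everywhere (quantile ties retained; dedup ties
  by position then strand; enrichment ties by name) so reruns are
  byte-identical; run metadata records versions, parameters and input
  checksums sufficient to reproduce a run exactly.
- Grid rounding uses a 1e-9 slop so weights or queries already on the
  ε-grid are not pushed a bin by float noise; `pvalue_to_score(1.0)`
  returns `min_score` exactly rather than the grid-rounded minimum.
- A PWM with zero score span (all columns uniform) gives every window
  relative score 1 rather than 0/0.
- Duplicate gene ids keep the first occurrence with a warning; genes of
  interest without a TSS record are skipped with a warning but remain in
  the enrichment denominator (the ratio divides by the full gene list).
- Zero counts with zero pseudocount are rejected rather than yielding
  −inf weights.

## Problem sizes

The default verification runs use 10 × 800 bp promoters × 21 matrices
(≈3.3×10⁵ windows per replicate, 50 replicates), exhaustive enumeration up
to `4^8` words for the p-value oracle, and 1,000 random (PWM, window) pairs
for the scanner oracle — chosen so the full suite and the acceptance script
each complete in a few seconds on one core while still exercising every
code path at the published parameter settings.

## Known limitations

- i.i.d. background only: no Markov backgrounds, dinucleotide-preserving
  shuffles, or genomic background gene sets; the enrichment ratio is
  descriptive and is not accompanied by a hypergeometric-style test.
- One TSS per gene, supplied by the caller; no transcript-isoform
  selection, and no overlap merging of adjacent hits.
- Motif catalogues and genomes are local files; nothing is fetched from
  remote services, so results depend on the catalogue release the user
  provides.
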