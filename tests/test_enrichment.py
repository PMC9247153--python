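"""Top-quantile retention, TF-gene deduplication and enrichment ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif import (Hit, ValidationError, dedup_hits, enrichment_table,
                      filter_top_quantile, pfm_to_pwm, quantile_threshold)
from promotif.enrichment import enrichment_to_frame
from promotif.motif_io import PFM


def make_hit(matrix="M1", tf="TF1", gene="gA", start=0, strand="+", score=1.0, rel=0.5):
    return Hit(matrix_id=matrix, tf_name=tf, gene_id=gene, start=start,
               strand=strand, score=score, rel_score=rel)


def make_pwm(matrix_id="M1", tf_name="TF1"):
    return pfm_to_pwm(PFM(matrix_id, tf_name, np.array([[4, 1], [2, 3], [1, 5], [1, 1]], float)))


class TestFilterTopQuantile:
    def test_exactly_ten_of_thousand_distinct(self, rng):
        scores = rng.permutation(np.arange(1000, dtype=float))
        hits = [make_hit(score=s) for s in scores]
        kept = filter_top_quantile(hits, q=0.01)
        assert sorted(h.score for h in kept) == list(np.arange(990.0, 1000.0))
        assert len(kept) == 10

    def test_all_equal_scores_tie_saturation(self):
        hits = [make_hit(score=5.0) for _ in range(100)]
        assert len(filter_top_quantile(hits, q=0.01)) == 100

    def test_small_input_keeps_at_least_the_maximum(self):
        hits = [make_hit(score=float(i)) for i in range(50)]
        kept = filter_top_quantile(hits, q=0.01)
        assert len(kept) >= 1 and max(h.score for h in kept) == 49.0

    def test_relative_metric_ranks_by_rel_score(self):
        hits = [make_hit(score=10.0, rel=0.1), make_hit(score=1.0, rel=0.9)]
        kept = filter_top_quantile(hits, q=0.4, metric="relative")
        assert [h.rel_score for h in kept] == [0.9]

    def test_empty_input_and_bad_parameters_rejected(self):
        with pytest.raises(ValidationError, match="quantile"):
            filter_top_quantile([], q=0.01)
        with pytest.raises(ValidationError):
            filter_top_quantile([make_hit()], q=0.0)
        with pytest.raises(ValidationError):
            filter_top_quantile([make_hit()], q=0.01, metric="bogus")

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=300),
           st.floats(min_value=0.005, max_value=0.5))
    def test_retained_fraction_bounded_by_tie_mass(self, raw, q):
        """Retention lies in [q, q + tie mass at the threshold] (up to the
        one-hit floor on tiny inputs)."""
        hits = [make_hit(score=float(s)) for s in raw]
        kept = filter_top_quantile(hits, q=q)
        thr = quantile_threshold(np.array([h.score for h in hits]), q)
        n = len(hits)
        ties = sum(1 for h in hits if h.score == thr)
        strictly_above = sum(1 for h in hits if h.score > thr)
        assert len(kept) == strictly_above + ties
        assert len(kept) >= max(1, int(np.floor(q * n)))
        assert strictly_above <= q * n  # never over-retains beyond the quantile


class TestDedupHits:
    def test_keeps_highest_score_per_tf_gene(self):
        hits = [make_hit(score=5.0, start=3), make_hit(score=7.0, start=9),
                make_hit(score=6.0, start=1)]
        (kept,) = dedup_hits(hits)
        assert kept.score == 7.0 and kept.start == 9

    def test_ties_broken_by_start_then_forward_strand(self):
        hits = [make_hit(score=5.0, start=4, strand="-"),
                make_hit(score=5.0, start=4, strand="+"),
                make_hit(score=5.0, start=2, strand="-")]
        (kept,) = dedup_hits(hits)
        assert (kept.start, kept.strand) == (2, "-")

    def test_already_unique_is_idempotent(self):
        hits = [make_hit(gene="gA", score=1.0), make_hit(gene="gB", score=2.0)]
        assert dedup_hits(hits) == dedup_hits(dedup_hits(hits))
        assert len(dedup_hits(hits)) == 2

    @settings(deadline=None, max_examples=20)
    @given(st.permutations(list(range(12))))
    def test_invariant_under_input_permutation(self, order):
        base = [make_hit(gene=f"g{i % 4}", matrix=f"M{i % 3}", start=i, score=float(i % 5))
                for i in range(12)]
        shuffled = [base[i] for i in order]
        assert dedup_hits(shuffled) == dedup_hits(base)


class TestEnrichmentTable:
    GENES = [f"g{i}" for i in range(10)]

    def test_eight_of_ten_genes_gives_ratio_point_eight(self):
        hits = [make_hit(gene=f"g{i}", score=9.0) for i in range(8)]
        (row,) = enrichment_table(hits, self.GENES, [make_pwm()])
        assert row.ratio == 0.8
        assert row.unique_gene_hits == 8 and row.n_genes == 10
        assert row.target_genes == [f"g{i}" for i in range(8)]

    def test_zero_hit_pwm_gets_zero_ratio_row(self):
        rows = enrichment_table([], self.GENES, [make_pwm(), make_pwm("M2", "TF2")])
        assert [r.ratio for r in rows] == [0.0, 0.0]
        assert all(r.target_genes == [] for r in rows)

    def test_hit_in_every_gene_gives_ratio_one(self):
        hits = [make_hit(gene=g, score=1.0) for g in self.GENES]
        (row,) = enrichment_table(hits, self.GENES, [make_pwm()])
        assert row.ratio == 1.0

    def test_sorted_by_ratio_then_name(self):
        pwms = [make_pwm("M1", "ZZZ"), make_pwm("M2", "AAA"), make_pwm("M3", "MMM")]
        hits = ([make_hit(matrix="M1", tf="ZZZ", gene=g) for g in self.GENES[:4]]
                + [make_hit(matrix="M2", tf="AAA", gene=g) for g in self.GENES[:4]]
                + [make_hit(matrix="M3", tf="MMM", gene=g) for g in self.GENES[:9]])
        rows = enrichment_table(hits, self.GENES, pwms)
        assert [(r.tf_name, r.ratio) for r in rows] == [("MMM", 0.9), ("AAA", 0.4), ("ZZZ", 0.4)]

    def test_unknown_gene_rejected_and_empty_list_rejected(self):
        with pytest.raises(ValidationError, match="not in the gene list"):
            enrichment_table([make_hit(gene="mystery")], self.GENES, [make_pwm()])
        with pytest.raises(ValidationError, match="empty"):
            enrichment_table([], [], [make_pwm()])

    def test_unique_hit_counts_sum_to_deduplicated_hits(self):
        hits = [make_hit(matrix=f"M{i % 3}", gene=f"g{i % 5}", score=float(i)) for i in range(30)]
        unique = dedup_hits(hits)
        pwms = [make_pwm(f"M{i}", f"TF{i}") for i in range(3)]
        rows = enrichment_table(unique, self.GENES, pwms)
        assert sum(r.unique_gene_hits for r in rows) == len(unique)

    def test_decoy_pwm_does_not_change_existing_rows(self):
        """Adding a zero-hit PWM (threshold held fixed) leaves ratios intact."""
        hits = [make_hit(gene=g) for g in self.GENES[:8]]
        before = enrichment_table(hits, self.GENES, [make_pwm()])
        after = enrichment_table(hits, self.GENES, [make_pwm(), make_pwm("DEC", "decoy")])
        assert before[0].ratio == after[0].ratio == 0.8
        assert {r.matrix_id: r.unique_gene_hits for r in after}["DEC"] == 0

    def test_frame_export_schema(self):
        rows = enrichment_table([make_hit(gene="g0")], self.GENES, [make_pwm()])
        df = enrichment_to_frame(rows)
        assert list(df.columns) == ["matrix_id", "tf_name", "unique_gene_hits",
                                    "n_genes", "ratio", "target_genes"]
        assert df.loc[0, "ratio"] == 0.1
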