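"""Synthetic promoter generation, motif planting and fixture round-trips."""

import json

import numpy as np
import pytest

from promotif import (Background, ValidationError, parse_jaspar, pfm_to_pwm,
                      plant_motifs, random_promoters, scan_promoter)
from promotif.promoters import read_promoters_fasta, reverse_complement
from promotif.simulate import (decoy_pfms, default_planted_pfm, read_truth,
                               write_fixture)


class TestRandomPromoters:
    def test_same_seed_reproduces_sequences(self):
        a = random_promoters(5, 100, seed=42)
        b = random_promoters(5, 100, seed=42)
        assert [p.seq for p in a] == [p.seq for p in b]
        assert [p.gene_id for p in a] == ["g0001", "g0002", "g0003", "g0004", "g0005"]

    def test_different_seed_differs(self):
        assert random_promoters(3, 80, seed=1)[0].seq != random_promoters(3, 80, seed=2)[0].seq

    def test_base_frequencies_near_uniform(self):
        # 200 x 800 = 160,000 draws; binomial 99.9% CI half-width ~0.0036
        proms = random_promoters(200, 800, seed=3)
        pooled = "".join(p.seq for p in proms)
        for b in "ACGT":
            assert pooled.count(b) / len(pooled) == pytest.approx(0.25, abs=0.01)

    def test_skewed_background_respected(self):
        bg = Background((0.4, 0.1, 0.1, 0.4))
        pooled = "".join(p.seq for p in random_promoters(100, 500, background=bg, seed=4))
        assert pooled.count("A") / len(pooled) == pytest.approx(0.4, abs=0.02)
        assert pooled.count("C") / len(pooled) == pytest.approx(0.1, abs=0.02)

    def test_degenerate_single_letter_promoter(self):
        (p,) = random_promoters(1, 1, seed=5)
        assert len(p.seq) == 1 and p.seq in "ACGT"

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            random_promoters(0, 10)
        with pytest.raises(ValidationError):
            random_promoters(2, 0)


class TestPlantMotifs:
    def test_fraction_zero_leaves_promoters_untouched(self):
        proms = random_promoters(6, 50, seed=6)
        planted, truths = plant_motifs(proms, default_planted_pfm(), 0.0, seed=7)
        assert truths == []
        assert [p.seq for p in planted] == [p.seq for p in proms]

    def test_eight_of_ten_truth_records(self):
        proms = random_promoters(10, 100, seed=8)
        _, truths = plant_motifs(proms, default_planted_pfm(), 0.8, seed=9)
        assert len(truths) == 8
        assert len({t.gene_id for t in truths}) == 8

    def test_planted_window_is_at_recorded_position(self):
        pfm = default_planted_pfm()
        proms = random_promoters(10, 200, seed=10)
        planted, truths = plant_motifs(proms, pfm, 1.0, mode="consensus", seed=11)
        by_gene = {p.gene_id: p for p in planted}
        for t in truths:
            window = by_gene[t.gene_id].seq[t.position : t.position + pfm.m]
            expected = t.planted_seq if t.strand == "+" else reverse_complement(t.planted_seq)
            assert window == expected
            assert t.planted_seq == pfm.consensus()

    def test_consensus_plant_rescans_at_rel_score_one(self):
        pfm = default_planted_pfm()
        pwm = pfm_to_pwm(pfm)
        proms = random_promoters(5, 120, seed=12)
        planted, truths = plant_motifs(proms, pfm, 1.0, mode="consensus", seed=13)
        by_gene = {p.gene_id: p for p in planted}
        for t in truths:
            hits = {(h.start, h.strand): h for h in scan_promoter(pwm, by_gene[t.gene_id])}
            assert hits[(t.position, t.strand)].rel_score == pytest.approx(1.0)

    def test_sample_mode_draws_from_column_frequencies(self):
        pfm = default_planted_pfm(dominance=0.99)
        proms = random_promoters(40, 60, seed=14)
        _, truths = plant_motifs(proms, pfm, 1.0, mode="sample", seed=15)
        matches = sum(t.planted_seq == pfm.consensus() for t in truths)
        assert matches >= 30  # 0.99^12 ~ 0.89 per plant

    def test_original_promoters_not_mutated(self):
        proms = random_promoters(4, 60, seed=16)
        before = [p.seq for p in proms]
        plant_motifs(proms, default_planted_pfm(), 1.0, seed=17)
        assert [p.seq for p in proms] == before

    def test_invalid_fraction_and_mode_rejected(self):
        proms = random_promoters(2, 60, seed=18)
        with pytest.raises(ValidationError):
            plant_motifs(proms, default_planted_pfm(), 1.5)
        with pytest.raises(ValidationError):
            plant_motifs(proms, default_planted_pfm(), 0.5, mode="bogus")


class TestDecoys:
    def test_count_and_preserved_column_multisets(self):
        pfm = default_planted_pfm()
        decoys = decoy_pfms(pfm, 5, seed=19)
        assert len(decoys) == 5
        ref = sorted(map(tuple, sorted(pfm.counts.T.tolist())))
        for d in decoys:
            assert d.m == pfm.m
            # multiset of column count-multisets is preserved
            got = sorted(map(tuple, sorted(np.sort(d.counts, axis=0).T.tolist())))
            want = sorted(map(tuple, sorted(np.sort(pfm.counts, axis=0).T.tolist())))
            assert got == want
        assert ref  # planted matrix untouched

    def test_decoys_score_planted_consensus_below_max(self):
        pfm = default_planted_pfm()
        consensus = pfm.consensus()
        for d in decoy_pfms(pfm, 10, seed=20):
            pwm = pfm_to_pwm(d)
            from promotif import score_window

            assert score_window(pwm, consensus) < pwm.max_score - 1.0


class TestWriteFixture:
    def test_round_trip_reproduces_structures(self, planted_fixture):
        paths, _genes, planted_id = planted_fixture
        proms = read_promoters_fasta(paths["promoters"])
        assert len(proms) == 10 and all(len(p.seq) == 800 for p in proms)
        with open(paths["pfms"]) as fh:
            pfms = parse_jaspar(fh)
        assert len(pfms) == 21  # planted + 20 decoys
        assert pfms[0].matrix_id == planted_id
        truths = read_truth(paths["truth"])
        assert len(truths) == 8
        meta = json.load(open(paths["meta"]))
        assert meta["seed"] == 7 and meta["n_promoters"] == 10

    def test_embedded_contigs_reextract_exact_promoters(self, planted_fixture):
        """Extraction from the synthetic genome + TSS table re-derives the
        planted promoter strings on both strands."""
        from promotif import extract_promoters, read_tss

        paths, _genes, _pid = planted_fixture
        genome = {}
        with open(paths["genome"]) as fh:
            name = None
            for line in fh:
                if line.startswith(">"):
                    name = line[1:].strip()
                    genome[name] = ""
                else:
                    genome[name] += line.strip()
        records = read_tss(paths["tss"])
        extracted = extract_promoters(genome, records, 800)
        originals = {p.gene_id: p.seq for p in read_promoters_fasta(paths["promoters"])}
        strands = set()
        for p in extracted:
            assert p.seq == originals[p.gene_id]
            strands.add(p.strand)
        assert strands == {"+", "-"}  # fixture exercises both orientations
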