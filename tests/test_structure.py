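"""Quadripartite partitioning, GC accounting, junctions, cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastsurvey.errors import InvertedRepeatTieError, NoInvertedRepeatError, UndefinedGCError
from plastsurvey.model import CircularGenome, revcomp
from plastsurvey.published import class_table, region_table
from plastsurvey.structure import (
    brute_force_longest_ir,
    class_stats,
    detect_inverted_repeats,
    find_longest_inverted_repeat,
    gc_content,
    region_stats,
    report_junctions,
    summarize_cohort,
)

from .conftest import make_genome, planted_ir_genome, random_dna


class TestInvertedRepeatDetection:
    def test_planted_ir_recovered_exactly(self):
        genome, truth = planted_ir_genome(seed=1, n=1000, ir_len=200)
        p = detect_inverted_repeats(genome, min_ir=100)
        assert p.ir_length == 200
        assert p.lengths() == {"lsc": truth["lsc"], "ssc": truth["ssc"], "ir": 200, "full": 1000}
        assert p.ira[0] % 1000 == truth["ira_start"]
        assert p.irb[0] % 1000 == truth["irb_start"]

    def test_ira_is_reverse_complement_of_irb(self):
        genome, _ = planted_ir_genome(seed=2)
        p = detect_inverted_repeats(genome, min_ir=100)
        assert genome.fetch(*p.ira) == revcomp(genome.fetch(*p.irb))

    @pytest.mark.parametrize("offset", [1, 137, 999])
    def test_rotation_invariance(self, offset):
        genome, _ = planted_ir_genome(seed=3)
        p0 = detect_inverted_repeats(genome, min_ir=100)
        p1 = detect_inverted_repeats(genome.rotated(offset), min_ir=100)
        assert p0.lengths() == p1.lengths()

    def test_reverse_complement_invariance(self):
        genome, _ = planted_ir_genome(seed=4)
        flipped = CircularGenome(id="rc", seq=revcomp(genome.seq))
        p0 = detect_inverted_repeats(genome, min_ir=100)
        p1 = detect_inverted_repeats(flipped, min_ir=100)
        assert p0.lengths() == p1.lengths()

    def test_no_ir_in_random_sequence(self):
        rng = np.random.default_rng(5)
        genome = CircularGenome(id="rand", seq=random_dna(rng, 5000))
        with pytest.raises(NoInvertedRepeatError):
            detect_inverted_repeats(genome, min_ir=1000)

    def test_two_equal_maximal_repeats_raise_tie_error(self):
        rng = np.random.default_rng(6)
        a, b = random_dna(rng, 150), random_dna(rng, 150)
        filler = [random_dna(rng, 400) for _ in range(4)]
        seq = list(filler[0] + a + filler[1] + b + filler[2] + revcomp(a) + filler[3] + revcomp(b))
        n, L = len(seq), 150
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i, j in [(400, 1500), (950, 2050)]:  # copy starts of the two pairs
            if seq[i - 1] == comp[seq[(j + L) % n]]:
                seq[i - 1] = next(c for c in "ACGT" if c != comp[seq[(j + L) % n]])
            if seq[i + L] == comp[seq[j - 1]]:
                seq[j - 1] = next(c for c in "ACGT" if comp[c] != seq[i + L])
        with pytest.raises(InvertedRepeatTieError) as exc:
            detect_inverted_repeats(CircularGenome(id="tie", seq="".join(seq)), min_ir=100)
        assert len(exc.value.candidates) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quadratic_brute_force(self, seed):
        """Hashed search equals an O(n^2) all-pairs scan on small circles."""
        genome, _ = planted_ir_genome(seed=seed, n=420, ir_len=60)
        L_fast, pairs_fast = find_longest_inverted_repeat(genome.seq, min_ir=20)
        L_slow, pairs_slow = brute_force_longest_ir(genome.seq, min_ir=20)
        assert L_fast == L_slow
        assert pairs_fast == pairs_slow


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("AATT", 0.0)])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguity_excluded_from_both_counts(self):
        assert gc_content("GCNNRY") == 1.0

    def test_all_ambiguous_is_undefined(self):
        with pytest.raises(UndefinedGCError):
            gc_content("NNNN")

    @given(st.text(alphabet="ACGTN-", min_size=4, max_size=60).filter(lambda s: set(s) & set("ACGT")))
    def test_reverse_complement_invariance(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))


class TestRegionAndClassStats:
    def test_region_lengths_tile_the_circle(self, cohort6):
        for g in cohort6.genomes:
            p = detect_inverted_repeats(g, min_ir=1000)
            L = region_stats(g, p).lengths
            assert L["lsc"] + L["ssc"] + 2 * L["ir"] == L["full"]

    def test_planted_class_lengths(self):
        g = make_genome(
            "ACGT" * 150,  # 600 bp
            [("gA", "CDS", [(0, 300, 1)]), ("tA", "tRNA", [(400, 470, 1)])],
        )
        cs = class_stats(g)
        assert cs.lengths["protein_coding"] == 300
        assert cs.lengths["tRNA"] == 70
        assert cs.lengths["intergenic"] == 600 - 300 - 70
        assert sum(cs.lengths.values()) == 600

    def test_overlap_precedence_cds_beats_intron(self):
        g = make_genome(
            "ACGT" * 100,
            [("gA", "CDS", [(0, 200, 1)]), ("gA intron", "intron", [(50, 150, 1)])],
        )
        cs = class_stats(g)
        assert cs.lengths["protein_coding"] == 200
        assert cs.lengths["intron"] == 0

    def test_simulated_class_lengths_match_architecture(self, cohort6):
        arch = cohort6.architecture
        exp = {"protein_coding": 0, "tRNA": 0, "rRNA": 0, "intron": 0}
        for region, mult in ((arch.lsc, 1), (arch.ir, 2), (arch.ssc, 1)):
            for u in region:
                key = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}.get(u.ftype)
                if key:
                    exp[key] += mult * sum(u.exon_lengths)
                    exp["intron"] += mult * sum(u.intron_lengths)
        for g in cohort6.genomes:
            cs = class_stats(g)
            for key, val in exp.items():
                assert cs.lengths[key] == val
            assert cs.counts == arch.gene_counts()


class TestJunctions:
    def test_gene_straddling_boundary_is_reported(self):
        genome, truth = planted_ir_genome(seed=8, n=1000, ir_len=200)
        straddler = (truth["ira_start"] - 20, truth["ira_start"] + 20, 1)
        g = make_genome(genome.seq, [("bridge", "gene", [straddler])])
        p = detect_inverted_repeats(g, min_ir=100)
        lsc_ira = next(j for j in report_junctions(g, p) if j.junction == "LSC-IRa")
        assert lsc_ira.within == ("bridge",)

    def test_boundary_in_spacer_reports_flanks(self):
        genome, truth = planted_ir_genome(seed=9, n=1000, ir_len=200)
        a = truth["ira_start"]
        g = make_genome(
            genome.seq,
            [("left", "gene", [(a - 60, a - 10, 1)]), ("right", "gene", [(a + 10, a + 60, 1)])],
        )
        p = detect_inverted_repeats(g, min_ir=100)
        lsc_ira = next(j for j in report_junctions(g, p) if j.junction == "LSC-IRa")
        assert lsc_ira.within == ()
        assert lsc_ira.flanking == ("left", "right")

    def test_default_architecture_junction_genes(self, cohort6):
        g = cohort6.genomes[0]
        p = detect_inverted_repeats(g, min_ir=1000)
        by_name = {j.junction: j for j in report_junctions(g, p)}
        assert by_name["LSC-IRa"].within == ("rpl2",)  # first IR gene starts at the boundary
        assert by_name["IRb-LSC"].within == ("trnH",)


class TestCohortSummary:
    def test_published_region_dispersion(self):
        """LSC varies most across the cohort, then IR, then SSC."""
        summary = summarize_cohort(region_table())
        assert round(summary.loc["mean", "full_bp"]) == 155806
        assert round(summary.loc["sd", "lsc_bp"]) == 616
        assert round(summary.loc["sd", "ir_bp"]) == 250
        assert round(summary.loc["sd", "ssc_bp"]) == 126

    def test_published_intergenic_dispersion(self):
        summary = summarize_cohort(class_table())
        assert round(summary.loc["sd", "intergenic_bp"]) == 617

    def test_identical_rows_have_zero_sd(self):
        table = region_table().iloc[[0, 0]]
        summary = summarize_cohort(table)
        assert (summary.loc["sd"] == 0).all()

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(region_table().iloc[[0]])
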