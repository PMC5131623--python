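"""Site counts, K80 distances, codon recoding, masking, scheme assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastsurvey.alnstats import (
    ambiguate_rls_codons,
    count_parsimony_informative,
    count_variable_sites,
    k80_distance,
    mask_poorly_aligned,
    summarize_alignment,
    translate_cds,
)
from plastsurvey.errors import AlignmentError, FrameError, SaturationError
from plastsurvey.model import MarkerAlignment


def brute_force_site_counts(rows: list[str]) -> tuple[int, int]:
    """Per-column Python oracle for variable and parsimony-informative sites."""
    n_var = n_pis = 0
    for col in zip(*rows):
        tally: dict[str, int] = {}
        for ch in col:
            if ch in "ACGT":
                tally[ch] = tally.get(ch, 0) + 1
        if len(tally) >= 2:
            n_var += 1
            if sum(1 for c in tally.values() if c >= 2) >= 2:
                n_pis += 1
    return n_var, n_pis


def random_alignment(rng: np.random.Generator, n=8, width=200, alphabet="ACGT-N") -> MarkerAlignment:
    rows = [
        "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=width))
        for _ in range(n)
    ]
    return MarkerAlignment("rand", [f"t{i}" for i in range(n)], rows)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "rows,n_var",
        [
            (["ACGT", "ACGT", "ACGT", "ACGT"], 0),
            (["ACGT", "ACGA", "ACGT", "ACGT"], 1),
            (["ACGT", "ACG-", "ACGN", "ACGT"], 0),  # gaps/N are not states
        ],
    )
    def test_variable_site_examples(self, rows, n_var):
        aln = MarkerAlignment("m", list("abcd"), rows)
        assert count_variable_sites(aln) == n_var

    def test_pis_needs_two_bases_twice(self):
        aln = MarkerAlignment("m", list("abcd"), ["AA", "AA", "CA", "CC"])
        # col 0: A,A,C,C informative; col 1: A,A,A,C not
        assert count_parsimony_informative(aln) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_brute_force_oracle(self, seed):
        aln = random_alignment(np.random.default_rng(seed))
        v, p = brute_force_site_counts(aln.rows)
        assert count_variable_sites(aln) == v
        assert count_parsimony_informative(aln) == p

    @pytest.mark.parametrize("seed", range(5))
    def test_removing_a_taxon_never_increases_variable_sites(self, seed):
        aln = random_alignment(np.random.default_rng(100 + seed), n=6)
        v_full = count_variable_sites(aln)
        sub = MarkerAlignment("m", aln.labels[:-1], aln.rows[:-1])
        assert count_variable_sites(sub) <= v_full


class TestK80:
    def test_identical_sequences_have_zero_distance(self):
        assert k80_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_known_proportions(self):
        """P=0.10 (transitions), Q=0.05 -> d = 0.1702 to 4 decimals."""
        x = "A" * 100
        y = "G" * 10 + "C" * 5 + "A" * 85  # 10 transitions, 5 transversions
        d = k80_distance(x, y)
        expected = -0.5 * math.log((1 - 2 * 0.10 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert d == pytest.approx(expected)
        assert round(d, 4) == 0.1702

    def test_saturation_raises(self):
        x = "A" * 10
        y = "G" * 10  # P = 0.5, Q = 0
        with pytest.raises(SaturationError):
            k80_distance(x, y)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        # columns with - or N in either row are excluded before counting
        assert k80_distance("ACGT-A", "ACGTNA") == 0.0
        d_clean = k80_distance("AAAAAAAAAA", "GAAAAAAAAA")
        d_gappy = k80_distance("AAAAAAAAAA--", "GAAAAAAAAANN")
        assert d_gappy == pytest.approx(d_clean)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, 500)
        y = x.copy()
        hit = rng.random(500) < 0.15
        y[hit] = rng.integers(0, 4, int(hit.sum()))
        sx = "".join("ACGT"[i] for i in x)
        sy = "".join("ACGT"[i] for i in y)
        assert k80_distance(sx, sy) == pytest.approx(k80_distance(sy, sx))

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(AlignmentError):
            k80_distance("----", "ACGT")


class TestSummary:
    def test_all_identical_alignment(self):
        aln = MarkerAlignment("m", list("abcd"), ["ACGT"] * 4)
        s = summarize_alignment(aln)
        assert s.n_variable == 0 and s.n_pis == 0 and s.mean_k80 == 0.0

    def test_pis_never_exceeds_variable(self):
        for seed in range(5):
            aln = random_alignment(np.random.default_rng(seed), n=6, width=300)
            s = summarize_alignment(aln)
            assert s.n_pis <= s.n_variable <= s.aligned_length

    def test_ungapped_length_statistics(self):
        aln = MarkerAlignment("m", list("abcd"), ["ACGT--", "ACGTAC", "AC--AC", "ACGTA-"])
        s = summarize_alignment(aln)
        assert (s.min_seq_length, s.max_seq_length) == (4, 6)
        assert s.mean_seq_length == pytest.approx((4 + 6 + 4 + 5) / 4)


class TestAmbiguation:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            ("ATG", "ATG"),  # Met untouched
            ("CTT", "YTN"), ("TTA", "YTN"), ("TTG", "YTN"),  # Leu family
            ("AGA", "MGN"), ("CGC", "MGN"),  # Arg family
            ("TCA", "TCN"), ("AGT", "AGY"),  # two Ser families stay distinct
            ("A-G", "A-G"), ("ANG", "ANG"),  # gaps/ambiguity untouched
        ],
    )
    def test_codon_recoding_table(self, codon, expected):
        aln = MarkerAlignment("m", ["a"], [codon], "cds")
        assert ambiguate_rls_codons(aln).rows[0] == expected

    def test_frame_error(self):
        with pytest.raises(FrameError):
            ambiguate_rls_codons(MarkerAlignment("m", ["a"], ["ACGTA"], "cds"))

    @given(st.lists(st.sampled_from(["ATG", "CTT", "AGA", "TCA", "AGT", "GGG", "TAA", "N--"]),
                    min_size=1, max_size=12))
    def test_idempotence(self, codons):
        row = "".join(codons)
        aln = MarkerAlignment("m", ["a"], [row], "cds")
        once = ambiguate_rls_codons(aln)
        twice = ambiguate_rls_codons(once)
        assert once.rows == twice.rows
        assert once.width == aln.width


class TestTranslation:
    def test_plastid_code_with_terminal_stop_dropped(self):
        aln = MarkerAlignment("m", ["a"], ["ATGGCTTAA"], "cds")
        assert translate_cds(aln).rows[0] == "MA"

    def test_gap_and_ambiguous_codons(self):
        aln = MarkerAlignment("m", ["a", "b"], ["---ATGANG", "ATGATGAAG"], "cds")
        prot = translate_cds(aln)
        assert prot.rows[0] == "-MX"
        assert prot.rows[1] == "MMK"

    def test_internal_stop_becomes_x(self, caplog):
        aln = MarkerAlignment("m", ["a"], ["ATGTAAGCT"], "cds")
        assert translate_cds(aln).rows[0] == "MXA"


class TestMask:
    def test_gap_free_alignment_unchanged(self):
        aln = MarkerAlignment("m", list("abcd"), ["ACGTACGT"] * 4)
        assert mask_poorly_aligned(aln).rows == aln.rows

    def test_planted_gap_block_removed(self):
        rng = np.random.default_rng(1)
        clean = random_alignment(rng, n=6, width=200, alphabet="ACGT")
        rows = [r[:100] + "-" * 50 + r[100:150] for r in clean.rows]
        aln = MarkerAlignment("m", clean.labels, rows)
        masked = mask_poorly_aligned(aln, window=5, max_gap_frac=0.5)
        # the 50 gap columns go, plus the clean edge columns caught in
        # windows that are majority-gap (2 on each side at window=5)
        assert masked.width == aln.width - 54
        assert all("-" not in r for r in masked.rows)

    @pytest.mark.parametrize("seed", range(3))
    def test_output_never_longer_than_input(self, seed):
        aln = random_alignment(np.random.default_rng(seed), n=5, width=120)
        assert mask_poorly_aligned(aln).width <= aln.width


class TestSchemes:
    @pytest.fixture(scope="class")
    def schemes(self, cohort6):
        from plastsurvey.pipeline import build_scheme_set

        return build_scheme_set(cohort6.genomes, min_ir=1000)

    def test_full_is_filtered_ncs_plus_cds(self, schemes):
        assert (
            schemes.schemes["full"].width
            == schemes.schemes["ncs_filtered"].width + schemes.schemes["cds"].width
        )

    def test_ambiguated_scheme_equals_recoding_the_cds_scheme(self, schemes):
        recoded = ambiguate_rls_codons(schemes.schemes["cds"])
        assert recoded.rows == schemes.schemes["cds_ambiguated"].rows

    def test_partition_map_has_one_entry_per_gene(self, schemes, cohort6):
        arch = cohort6.architecture
        n_genes = sum(
            1 for region in (arch.lsc, arch.ir, arch.ssc) for u in region if u.ftype == "CDS"
        )
        assert len(schemes.partitions["cds"]) == n_genes
        spans = sorted((s, e) for _, s, e in schemes.partitions["cds"])
        assert spans[0][0] == 0 and spans[-1][1] == schemes.schemes["cds"].width
        assert all(e0 == s1 for (_, e0), (s1, _) in zip(spans, spans[1:]))
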