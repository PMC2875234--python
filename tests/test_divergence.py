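import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintdiv.divergence import (
    EmptyAlignmentError,
    count_gaps,
    jukes_cantor,
    nei_gojobori,
    percent_identity,
    silent_cpg_mutability,
    snp_density,
)
from imprintdiv.codonmodel import CODONS
from imprintdiv.io import SnpRecord, ValidationError

from oracles import ng_differences, ng_pair_counts, ng_sites


class TestPercentIdentity:
    def test_full_identity(self, make_protein_alignment):
        assert percent_identity(make_protein_alignment("MA", "MA")) == 100.0

    def test_gap_counts_as_mismatch(self, make_protein_alignment):
        assert percent_identity(make_protein_alignment("MA", "M-")) == 50.0

    def test_ungapped_denominator_option(self, make_protein_alignment):
        pa = make_protein_alignment("MAV", "M-V")
        assert percent_identity(pa, "ungapped_columns") == 100.0
        assert percent_identity(pa) == pytest.approx(200.0 / 3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        cols=st.lists(
            st.tuples(st.sampled_from("ACDEF-"), st.sampled_from("ACDEF-")).filter(
                lambda t: t != ("-", "-")
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_direct_recount_and_symmetry(self, cols):
        from imprintdiv.align import ProteinAlignment

        def make_protein_alignment(x, y):
            return ProteinAlignment("g", "human", "mouse", (x, y))

        a = "".join(c[0] for c in cols)
        b = "".join(c[1] for c in cols)
        pa = make_protein_alignment(a, b)
        expected = 100.0 * sum(x == y and x != "-" for x, y in cols) / len(cols)
        assert percent_identity(pa) == pytest.approx(expected)
        assert percent_identity(make_protein_alignment(b, a)) == pytest.approx(expected)


class TestCountGaps:
    @pytest.mark.parametrize(
        "a,b,events",
        [("MAAV", "M--V", 1), ("MAVA", "MAVA", 0), ("MAVA", "M-V-", 2), ("M-VA", "MA-A", 2)],
    )
    def test_indel_events(self, a, b, events, make_protein_alignment):
        assert count_gaps(make_protein_alignment(a, b)) == events

    def test_column_mode(self, make_protein_alignment):
        assert count_gaps(make_protein_alignment("MAAV", "M--V"), mode="columns") == 2


class TestNeiGojobori:
    def test_identical_sequences(self, make_codon_alignment):
        res = nei_gojobori(make_codon_alignment("ATGGAATTT", "ATGGAATTT"))
        assert res.Ka == 0 and res.Ks == 0 and res.ka_ks is None
        assert res.S + res.N == pytest.approx(9.0, abs=1e-9)

    def test_single_synonymous_difference(self, make_codon_alignment):
        res = nei_gojobori(make_codon_alignment("ATGGAATTT", "ATGGAGTTT"))
        assert res.Nd == 0 and res.Sd == 1
        assert res.Ka == 0
        # at only 3 codons the single synonymous change saturates the
        # correction (pS = Sd/S > 3/4); counts still match the oracle
        S, N, Sd, Nd = ng_pair_counts(["ATG", "GAA", "TTT"], ["ATG", "GAG", "TTT"])
        assert (res.S, res.N, res.Sd, res.Nd) == (
            pytest.approx(S), pytest.approx(N), Sd, Nd
        )
        assert res.saturated and res.Ks is None

    def test_single_synonymous_difference_magnitude(self, make_codon_alignment):
        """With enough synonymous sites the GAA->GAG change gives Ka = 0 and
        a positive Ks equal to the oracle's corrected pS."""
        a = "ATGGAATTT" * 4
        b = "ATGGAGTTT" + "ATGGAATTT" * 3
        res = nei_gojobori(make_codon_alignment(a, b))
        assert res.Nd == 0 and res.Sd == 1 and res.Ka == 0
        codons = lambda s: [s[i : i + 3] for i in range(0, len(s), 3)]
        S, N, Sd, Nd = ng_pair_counts(codons(a), codons(b))
        assert res.Ks == pytest.approx(jukes_cantor(Sd / S))
        assert res.Ks > 0

    def test_gap_and_n_codons_skipped(self, make_codon_alignment):
        res = nei_gojobori(make_codon_alignment("ATGGAA---TTN", "ATGGAGAAATTT"))
        assert res.n_codons == 2  # gap column and N column excluded

    def test_empty_alignment_error(self, make_codon_alignment):
        with pytest.raises(EmptyAlignmentError):
            nei_gojobori(make_codon_alignment("---", "ATG"))

    def test_row_swap_invariance(self, make_codon_alignment, rng):
        codons = [CODONS[i] for i in rng.integers(0, 61, 30)]
        other = [CODONS[i] for i in rng.integers(0, 61, 30)]
        a, b = "".join(codons), "".join(other)
        r1 = nei_gojobori(make_codon_alignment(a, b))
        r2 = nei_gojobori(make_codon_alignment(b, a))
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_exhaustive_61x61_pair_scan(self, make_codon_alignment):
        """(S, N, Sd, Nd) match the brute-force pathway/site oracle exactly
        on every ordered pair of sense codons."""
        from imprintdiv.divergence import _pathway_differences, _syn_sites

        for c1 in CODONS:
            s_impl = _syn_sites(c1)
            s_oracle, n_oracle = ng_sites(c1)
            assert s_impl == pytest.approx(s_oracle, abs=1e-12)
        for c1, c2 in itertools.product(CODONS, repeat=2):
            sd, nd = _pathway_differences(c1, c2)
            sd_o, nd_o = ng_differences(c1, c2)
            assert sd == pytest.approx(sd_o, abs=1e-12), (c1, c2)
            assert nd == pytest.approx(nd_o, abs=1e-12), (c1, c2)

    def test_correction_monotone_below_saturation(self):
        ps = np.linspace(0, 0.74, 50)
        ds = [jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))
        assert jukes_cantor(0.75) is None

    def test_saturation_flagged(self, make_codon_alignment):
        # Hamming-maximal codons at every position drive pN above 3/4
        ca = make_codon_alignment("AAA" * 20, "CCC" * 20)
        res = nei_gojobori(ca)
        assert res.saturated and res.Ka is None


class TestSilentCpG:
    def test_silent_tpg_mismatch(self, make_codon_alignment):
        res = silent_cpg_mutability(make_codon_alignment("TTCGGG", "TTTGGG"))
        assert (res.n_cpg_cpg, res.n_cpg_tpg) == (0, 1)
        assert res.mutability_index == 1.0

    def test_conserved_cpg(self, make_codon_alignment):
        res = silent_cpg_mutability(make_codon_alignment("TTCGGG", "TTCGGG"))
        assert (res.n_cpg_cpg, res.n_cpg_tpg) == (1, 0)
        assert res.mutability_index == 0.0

    def test_gap_adjacent_contexts_skipped(self, make_codon_alignment):
        # in the standard code a third-position C<->T exchange is always
        # synonymous, so the discounting cases are gapped/ambiguous contexts
        res = silent_cpg_mutability(make_codon_alignment("TTC---GGG", "TTTNNNGGG"))
        assert (res.n_cpg_cpg, res.n_cpg_tpg) == (0, 0)  # gap-adjacent skipped

    def test_undefined_when_no_contexts(self, make_codon_alignment):
        res = silent_cpg_mutability(make_codon_alignment("AAAAAA", "AAAAAA"))
        assert res.mutability_index is None and res.ratio_tpg_to_cpg is None

    def test_direct_recount_on_constructed_alignment(self, make_codon_alignment, rng):
        """Counts equal a position-by-position recount on random 10-codon
        alignments built from C/T third-position variants."""
        for _ in range(20):
            idx = rng.integers(0, 61, 10)
            rows = []
            for flip in (False, True):
                codons = []
                for k, i in enumerate(idx):
                    c = CODONS[i]
                    if flip and c[2] in "CT" and rng.random() < 0.5:
                        c = c[:2] + ("T" if c[2] == "C" else "C")
                        if c not in CODONS:
                            c = CODONS[i]
                    codons.append(c)
                rows.append("".join(codons))
            ca = make_codon_alignment(*rows)
            res = silent_cpg_mutability(ca)
            # independent recount
            a, b = rows
            exp_cpg = exp_tpg = 0
            for i in range(0, len(a) - 3, 3):
                da = a[i + 2] + a[i + 3]
                db = b[i + 2] + b[i + 3]
                if da == "CG" and db == "CG":
                    exp_cpg += 1
                elif {da, db} == {"CG", "TG"}:
                    cpg_codon = a[i : i + 3] if da == "CG" else b[i : i + 3]
                    c_var, t_var = cpg_codon[:2] + "C", cpg_codon[:2] + "T"
                    if c_var in CODONS and t_var in CODONS:
                        from Bio.Seq import Seq

                        if str(Seq(c_var).translate()) == str(Seq(t_var).translate()):
                            exp_tpg += 1
            assert (res.n_cpg_cpg, res.n_cpg_tpg) == (exp_cpg, exp_tpg)


class TestSnpDensity:
    @pytest.mark.parametrize("length,count,expected", [(1000, 2, 2.0), (500, 3, 6.0)])
    def test_examples(self, length, count, expected):
        assert snp_density(SnpRecord("g", length, count)) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            SnpRecord("g", 0, 1)
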