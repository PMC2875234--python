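import numpy as np
import pytest

from imprintdiv.align import MultiCodonAlignment
from imprintdiv.branch import (
    BRANCHES,
    CodonBranchModel,
    CodonModelParams,
    DataError,
    QuartetTree,
    codon_log_likelihood,
    fit_branch_models,
    lrt,
    lrt_critical_value,
    saturation_filter,
)
from imprintdiv.codonmodel import CODONS, uniform_frequencies

from oracles import exhaustive_quartet_loglik

QUARTET = ("human", "mouse", "rat", "cow")


def _aln(codon_rows: dict[str, str]) -> MultiCodonAlignment:
    return MultiCodonAlignment("g", QUARTET, tuple(codon_rows[sp] for sp in QUARTET))


def _uniform_params(kappa=2.0, w_bg=0.3, w_fg=0.3):
    return CodonModelParams(kappa, w_bg, w_fg, uniform_frequencies())


class TestSaturationFilter:
    @pytest.mark.parametrize(
        "ks,expected",
        [(0.0, "drop_zero"), (2.6, "drop_saturated"), (0.5, "keep"), (2.5, "keep")],
    )
    def test_rule(self, ks, expected):
        assert saturation_filter(ks) == expected


class TestQuartetTree:
    def test_newick_round_trip(self):
        tree = QuartetTree({"human": 0.3, "mouse": 0.1, "rat": 0.12, "cow": 0.4,
                            "ancestor": 0.2})
        assert QuartetTree.from_newick(tree.to_newick()) == tree

    def test_foreground_mark_required(self):
        with pytest.raises(ValueError, match="#1"):
            QuartetTree.from_newick("(human:0.1,(mouse:0.1,rat:0.1):0.1,cow:0.1);")

    def test_wrong_tips_rejected(self):
        with pytest.raises(ValueError):
            QuartetTree.from_newick("(human:0.1,(mouse:0.1,dog:0.1)#1:0.1,cow:0.1);")

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            QuartetTree({"human": -0.1, "mouse": 0.1, "rat": 0.1, "cow": 0.1,
                         "ancestor": 0.1})


class TestLogLikelihood:
    def test_zero_lengths_identical_column(self):
        """With all branch lengths zero and one shared codon, the likelihood
        is just that codon's equilibrium frequency."""
        aln = _aln({sp: "ATG" for sp in QUARTET})
        tree = QuartetTree({b: 0.0 for b in BRANCHES})
        lnl = codon_log_likelihood(aln, tree, _uniform_params())
        assert lnl == pytest.approx(np.log(1.0 / 61), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_state_oracle(self, seed):
        """Pruning equals explicit summation over all 61x61 internal-state
        pairs on small alignments."""
        rng = np.random.default_rng(seed)
        ncol = int(rng.integers(1, 6))
        cols = rng.integers(0, 61, size=(ncol, 4))
        aln = _aln({
            sp: "".join(CODONS[c] for c in cols[:, i]) for i, sp in enumerate(QUARTET)
        })
        bl = {b: float(t) for b, t in zip(BRANCHES, rng.uniform(0.01, 0.8, 5))}
        kappa = float(rng.uniform(1, 5))
        w_bg, w_fg = float(rng.uniform(0.05, 2)), float(rng.uniform(0.05, 2))
        tree = QuartetTree(bl)
        params = CodonModelParams(kappa, w_bg, w_fg, uniform_frequencies())
        lnl = codon_log_likelihood(aln, tree, params)
        oracle = exhaustive_quartet_loglik(
            [tuple(c) for c in cols], bl, kappa, w_bg, w_fg, uniform_frequencies()
        )
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_mouse_rat_relabel_symmetry(self, quartet_alignment):
        aln, _ = quartet_alignment
        rows = dict(zip(aln.species, aln.rows))
        swapped = _aln({**rows, "mouse": rows["rat"], "rat": rows["mouse"]})
        tree = QuartetTree({"human": 0.3, "mouse": 0.1, "rat": 0.1, "cow": 0.4,
                            "ancestor": 0.2})
        params = _uniform_params(w_fg=0.8)
        assert codon_log_likelihood(_aln(rows), tree, params) == pytest.approx(
            codon_log_likelihood(swapped, tree, params), abs=1e-9
        )

    def test_stop_codon_rejected(self):
        aln = _aln({**{sp: "ATG" for sp in QUARTET}, "cow": "TAA"})
        tree = QuartetTree()
        with pytest.raises(DataError, match="stop"):
            codon_log_likelihood(aln, tree, _uniform_params())

    def test_gap_columns_excluded(self):
        rows = {sp: "ATGAAA" for sp in QUARTET}
        rows["cow"] = "---AAA"
        gapped = _aln(rows)
        plain = _aln({sp: "AAA" for sp in QUARTET})
        tree = QuartetTree()
        params = _uniform_params()
        assert codon_log_likelihood(gapped, tree, params) == pytest.approx(
            codon_log_likelihood(plain, tree, params)
        )


class TestFit:
    def test_minimum_codons_enforced(self):
        aln = _aln({sp: "ATGAAA" for sp in QUARTET})
        with pytest.raises(DataError, match="usable codons"):
            CodonBranchModel(aln)

    def test_nesting_and_lrt(self, quartet_alignment):
        aln, truth = quartet_alignment
        one, two, res = fit_branch_models(aln, n_starts=1)
        assert two.lnL >= one.lnL - 1e-4  # nested models
        assert res.statistic >= 0
        assert one.converged and two.converged
        # omega in a sane neighbourhood of the generating value at 60 codons
        assert 0.01 < one.params.omega_background < 1.0

    def test_results_summary_and_rates(self, quartet_alignment):
        aln, _ = quartet_alignment
        one = CodonBranchModel(aln).fit("one_ratio", n_starts=1)
        text = one.summary()
        assert "one-ratio" in text and "kappa" in text and "#1" in text
        ka, ks = one.ka_per_branch, one.ks_per_branch
        for b in BRANCHES:
            assert ka[b] >= 0 and ks[b] >= 0
            # the flow decomposition makes per-branch Ka/Ks equal the
            # branch's omega exactly
            if ks[b] > 0:
                assert ka[b] / ks[b] == pytest.approx(
                    one.params.omega_background, rel=1e-9
                )

    def test_unknown_model_rejected(self, quartet_alignment):
        aln, _ = quartet_alignment
        with pytest.raises(ValueError):
            CodonBranchModel(aln).fit("three_ratios")


class TestLrt:
    def _results(self, lnl, model, w_bg=0.2, w_fg=0.5):
        from imprintdiv.branch import BranchModelResults

        return BranchModelResults(
            model=model, lnL=lnl,
            params=CodonModelParams(2.0, w_bg, w_fg, uniform_frequencies()),
            tree=QuartetTree(), converged=True, n_codons=100,
        )

    def test_significant_at_threshold(self):
        res = lrt(self._results(-1000.0, "one_ratio"), self._results(-998.0, "two_ratios"))
        assert res.statistic == pytest.approx(4.0) and res.significant
        assert res.direction == "elevated"

    def test_not_significant(self):
        res = lrt(self._results(-1000.0, "one_ratio"), self._results(-999.5, "two_ratios"))
        assert res.statistic == pytest.approx(1.0) and not res.significant

    def test_numerical_negative_clipped(self):
        res = lrt(
            self._results(-1000.0, "one_ratio"),
            self._results(-1000.0 - 1e-6, "two_ratios"),
        )
        assert res.statistic == 0.0 and not res.significant

    def test_reduced_direction(self):
        res = lrt(
            self._results(-1000.0, "one_ratio"),
            self._results(-990.0, "two_ratios", w_bg=0.5, w_fg=0.1),
        )
        assert res.direction == "reduced"

    def test_model_order_enforced(self):
        with pytest.raises(ValueError):
            lrt(self._results(-1.0, "two_ratios"), self._results(-1.0, "one_ratio"))


def test_boundary_mixture_critical_value():
    """The 5% critical value of the 1/2 delta_0 + 1/2 chi2_1 mixture is the
    decision threshold 2.71."""
    assert round(lrt_critical_value(0.05), 2) == 2.71
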