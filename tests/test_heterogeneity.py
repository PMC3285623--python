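"""Homogeneity and symmetry tests, deviation statistics and recoding."""

import numpy as np
import pandas as pd
import pytest

import mitocomp as mc
from mitocomp.alignment import MultipleAlignment, AA_STATES
from mitocomp.heterogeneity import (
    BinPartition,
    bowker_from_divergence,
    max_taxon_chi2,
)

from _oracles import set_partitions_into_k


class TestChi2Homogeneity:
    def test_proportional_rows_give_zero(self):
        cm = pd.DataFrame([[10, 20, 30], [20, 40, 60]], columns=list("ABC"))
        res = mc.chi2_homogeneity(cm)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        cm = pd.DataFrame([[10, 0], [0, 10]], columns=list("AB"))
        res = mc.chi2_homogeneity(cm)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_forty_nine_taxa_df(self):
        rng = np.random.default_rng(0)
        cm = pd.DataFrame(rng.integers(50, 150, (49, 4)), columns=list("ACGT"))
        assert mc.chi2_homogeneity(cm).df == 144

    def test_zero_pooled_state_dropped_with_warning(self):
        cm = pd.DataFrame([[5, 5, 0], [5, 5, 0]], columns=list("ABC"))
        with pytest.warns(UserWarning, match="dropped"):
            res = mc.chi2_homogeneity(cm)
        assert res.df == 1

    def test_permutation_and_scaling_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.integers(10, 60, (6, 4))
        cm = pd.DataFrame(m, columns=list("ACGT"))
        base = mc.chi2_homogeneity(cm).statistic
        perm = mc.chi2_homogeneity(cm.iloc[::-1, ::-1]).statistic
        assert perm == pytest.approx(base)
        scaled = mc.chi2_homogeneity(cm * 3).statistic
        assert scaled == pytest.approx(3 * base)


class TestMatchedPairsSymmetry:
    def test_symmetric_divergence_scores_zero(self):
        res = mc.matched_pairs_symmetry("AACCGT", "CCAAGT")
        # N_AC = 2 = N_CA: perfectly symmetric
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_single_pair(self):
        """N_AB=5, N_BA=1 -> S = 16/6, df 1, p about 0.102."""
        n = np.zeros((4, 4), dtype=int)
        np.fill_diagonal(n, 10)
        n[0, 1], n[1, 0] = 5, 1
        res = bowker_from_divergence(n)
        assert res.statistic == pytest.approx(16 / 6)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.102, abs=0.001)

    def test_swap_invariance(self):
        a, b = "ACGTACGGGA", "TTGTACGCCA"
        r1 = mc.matched_pairs_symmetry(a, b)
        r2 = mc.matched_pairs_symmetry(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.df == r2.df

    def test_no_offdiagonal_pairs_degenerate(self):
        res = mc.matched_pairs_symmetry("AAAA", "AAAA")
        assert res.degenerate and res.p_value == 1.0

    def test_gap_columns_skipped(self):
        r1 = mc.matched_pairs_symmetry("ACG-", "ACGT")
        r2 = mc.matched_pairs_symmetry("ACG", "ACG")
        assert r1.statistic == r2.statistic


class TestPairwiseSummary:
    def test_identical_rows_zero_fraction(self):
        al = MultipleAlignment.from_rows({"a": "ACGT" * 5, "b": "ACGT" * 5,
                                          "c": "ACGT" * 5})
        frac, table = mc.pairwise_symmetry_summary(al)
        assert frac == 0.0
        assert len(table) == 3

    def test_one_asymmetric_pair_of_three(self):
        sym = "ACGT" * 25
        asym = "C" * 50 + sym[50:]
        al = MultipleAlignment.from_rows({"a": sym, "b": sym, "c": asym})
        frac, table = mc.pairwise_symmetry_summary(al, alpha=0.05)
        assert frac == pytest.approx(2 / 3)  # both a-c and b-c are asymmetric

    def test_codon_position_restriction(self):
        al = MultipleAlignment.from_rows({"a": "ACGACG", "b": "ACGACG"})
        frac, table = mc.pairwise_symmetry_summary(al, positions=(1, 2))
        assert len(table) == 1


class TestDeviationStatistics:
    def test_homogeneous_alignment_scores_zero(self):
        al = MultipleAlignment.from_rows({"a": "ACGT" * 5, "b": "ACGT" * 5})
        assert mc.taxon_deviation(al).max() == pytest.approx(0.0)
        assert mc.global_deviation(al) == pytest.approx(0.0)

    def test_two_state_hand_sum(self):
        """Global (0.5, 0.5) vs taxon (0.7, 0.3): deviation 0.4."""
        al = MultipleAlignment.from_rows(
            {"t1": "0" * 70 + "1" * 30, "t2": "0" * 30 + "1" * 70},
            alphabet="RECODED-2")
        d = mc.taxon_deviation(al)
        assert d["t1"] == pytest.approx(0.4)
        assert mc.global_deviation(al) == pytest.approx(0.4)

    def test_triangle_bound(self):
        rng = np.random.default_rng(5)
        rows = {f"t{i}": "".join(rng.choice(list(AA_STATES), 100))
                for i in range(6)}
        al = MultipleAlignment.from_rows(rows, alphabet="AA20")
        assert (mc.taxon_deviation(al) <= 2.0).all()

    def test_monotone_in_shift_magnitude(self):
        """The planted taxon's deviation grows with its composition shift."""
        base = np.full(20, 0.05)
        devs = []
        for tv in (0.0, 0.1, 0.2, 0.3):
            shifted = base.copy()
            shifted[0] += tv
            shifted[1:] -= tv / 19
            cfg = mc.SimulationConfig(
                "((a:2.0,b:0.1):0.05,(c:0.1,d:0.1):0.05);",
                AA_STATES, tuple(base), 4000, seed=17,
                shifts=[mc.CompositionShift("a", 0.0, tuple(shifted))])
            al, _ = mc.simulate_alignment(cfg)
            devs.append(mc.taxon_deviation(al)["a"])
        assert devs == sorted(devs)


class TestPosteriorPredictive:
    @staticmethod
    def _source(newick, freqs, n_sites, seed0):
        def src(i):
            cfg = mc.SimulationConfig(newick, AA_STATES, freqs, n_sites,
                                      seed=seed0 + i)
            return mc.simulate_alignment(cfg)[0]
        return src

    def test_self_consistent_null(self):
        newick = "((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);"
        freqs = tuple(np.full(20, 0.05))
        obs, _ = mc.simulate_alignment(
            mc.SimulationConfig(newick, AA_STATES, freqs, 800, seed=1))
        rep = mc.posterior_predictive(
            obs, self._source(newick, freqs, 800, 1000), n_reps=60)
        assert abs(rep.global_z) < 4
        assert rep.n_deviating <= 2

    def test_planted_taxon_flagged(self):
        newick = "((a:1.0,b:1.0):0.2,(c:1.0,d:1.0):0.2);"
        base = np.full(20, 0.05)
        shifted = base.copy()
        shifted[0] += 0.25
        shifted[1:] -= 0.25 / 19
        obs, _ = mc.simulate_alignment(
            mc.SimulationConfig(newick, AA_STATES, tuple(base), 1500, seed=2,
                                shifts=[mc.CompositionShift("a", 0.0, tuple(shifted))]))
        rep = mc.posterior_predictive(
            obs, self._source(newick, tuple(base), 1500, 5000), n_reps=60)
        assert bool(rep.per_taxon.loc["a", "deviating"])
        assert rep.per_taxon.loc["a", "z_score"] > 3

    def test_too_few_replicates_refused(self):
        al = MultipleAlignment.from_rows({"a": "ACDE", "b": "ACDF"},
                                         alphabet="AA20")
        with pytest.raises(ValueError, match="n_reps"):
            mc.posterior_predictive(al, lambda i: al, n_reps=5)

    def test_degenerate_replicates_flagged(self):
        al = MultipleAlignment.from_rows({"a": "ACDE" * 5, "b": "ACDF" * 5},
                                         alphabet="AA20")
        rep = mc.posterior_predictive(al, lambda i: al, n_reps=25)
        assert rep.per_taxon["degenerate"].all()
        assert not rep.per_taxon["deviating"].any()


class TestRecoding:
    def test_dayhoff_group_example(self):
        al = MultipleAlignment.from_rows({"x": "ACDE"}, alphabet="AA20")
        out = mc.recode(al, BinPartition(mc.DAYHOFF_GROUPS))
        sym = out.meta["recoding"]
        assert out.row("x") == sym["AGPST"] + sym["C"] + sym["DENQ"] + sym["DENQ"]

    def test_identity_partition_preserves_structure(self):
        al = MultipleAlignment.from_rows({"x": "ACD-E", "y": "AC-DE"},
                                         alphabet="AA20")
        part = BinPartition(tuple(sorted(AA_STATES)))
        out = mc.recode(al, part)
        assert out.n_columns == al.n_columns
        # bijective renaming: equal residues stay equal, gaps stay gaps
        assert out.matrix[0, 3] == "-"
        assert out.matrix[0, 0] == out.matrix[1, 0]

    def test_residue_count_conserved(self):
        rng = np.random.default_rng(6)
        rows = {f"t{i}": "".join(rng.choice(list(AA_STATES + "-"), 200))
                for i in range(4)}
        al = MultipleAlignment.from_rows(rows, alphabet="AA20")
        out = mc.recode(al, BinPartition(mc.DAYHOFF_GROUPS))
        before = mc.count_matrix(al).sum(axis=1)
        after = mc.count_matrix(out).sum(axis=1)
        assert (before.to_numpy() == after.to_numpy()).all()

    def test_uncovered_residue_rejected(self):
        al = MultipleAlignment.from_rows({"x": "ACDE"}, alphabet="AA20")
        with pytest.raises(ValueError, match="cover"):
            mc.recode(al, BinPartition(("AC", "DE")))


class TestMinmaxBins:
    @staticmethod
    def _toy_alignment(n_states=5, n_taxa=6, n_cols=150, seed=8):
        rng = np.random.default_rng(seed)
        states = "0123456789"[:n_states]
        rows = {}
        for i in range(n_taxa):
            w = rng.dirichlet(np.ones(n_states) * 3)
            rows[f"t{i}"] = "".join(rng.choice(list(states), n_cols, p=w))
        return MultipleAlignment.from_rows(rows, alphabet=f"RECODED-{n_states}")

    def test_identity_partition_at_full_k(self):
        al = self._toy_alignment()
        part = mc.find_minmax_bins(al, 5)
        assert part.canonical() == ("0", "1", "2", "3", "4")

    @pytest.mark.parametrize("n_states, k", [(4, 2), (5, 2), (5, 3), (6, 3)])
    def test_heuristic_equals_exhaustive_optimum(self, n_states, k):
        al = self._toy_alignment(n_states=n_states, seed=n_states * 10 + k)
        counts = mc.count_matrix(al)
        states = list(counts.columns)
        best = min(
            max_taxon_chi2(counts, groups)[0]
            for groups in set_partitions_into_k(states, k)
        )
        part = mc.find_minmax_bins(al, k, seed=0, restarts=30)
        stat, _ = max_taxon_chi2(counts, part.canonical())
        assert stat == pytest.approx(best, rel=1e-9)

    def test_binned_statistic_bounded_by_search_objective(self):
        al = self._toy_alignment(n_states=6, seed=42)
        counts = mc.count_matrix(al)
        part = mc.find_minmax_bins(al, 3, seed=1, restarts=30)
        stat, _ = max_taxon_chi2(counts, part.canonical())
        worse = tuple(sorted(["012", "34", "5"]))
        assert stat <= max_taxon_chi2(counts, worse)[0] + 1e-9

    def test_k_out_of_range(self):
        al = self._toy_alignment()
        with pytest.raises(ValueError):
            mc.find_minmax_bins(al, 1)
        with pytest.raises(ValueError):
            mc.find_minmax_bins(al, 6)

    def test_partition_serialization_roundtrip(self):
        part = BinPartition(mc.MINMAX9_GROUPS)
        assert BinPartition.parse(part.serialize()).canonical() == part.canonical()


class TestSelectBinCount:
    def test_homogeneous_data_keeps_maximum_bins(self):
        rng = np.random.default_rng(12)
        rows = {f"t{i}": "".join(rng.choice(list("01234"), 300)) for i in range(5)}
        al = MultipleAlignment.from_rows(rows, alphabet="RECODED-5")
        k, _ = mc.select_bin_count(al, k_max=5, seed=0, restarts=10)
        assert k == 5

    def test_alpha_one_returns_single_bin_with_warning(self):
        rng = np.random.default_rng(13)
        rows = {f"t{i}": "".join(rng.choice(list("0123"), 100)) for i in range(4)}
        al = MultipleAlignment.from_rows(rows, alphabet="RECODED-4")
        with pytest.warns(UserWarning, match="single bin"):
            k, _ = mc.select_bin_count(al, k_max=4, alpha=1.0, restarts=5)
        assert k == 1
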