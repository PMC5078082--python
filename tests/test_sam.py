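import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egwaskit.sam import (
    NONE,
    PermutationNull,
    choose_s0,
    sam_analyze,
    sam_permutation_calls,
    sam_statistics,
    ttest_bh_calls,
    tune_delta,
)

from conftest import build_experiment


class TestSamStatistics:
    def test_hand_evaluated_formula(self):
        # case {2,4} vs control {1,1}: r=2, s=sqrt(0.5*(2+0))=1, d=2
        exp = build_experiment([[2, 4, 1, 1], [3.0, 3.2, 3.1, 2.9]], n_cases=2)
        stats = sam_statistics(exp, s0=0.0)
        assert stats.loc["g1", "r"] == pytest.approx(2.0)
        assert stats.loc["g1", "s"] == pytest.approx(1.0)
        assert stats.loc["g1", "d"] == pytest.approx(2.0)

    def test_equal_means_give_zero_d(self):
        exp = build_experiment([[5, 7, 4, 8], [1, 2, 3, 4]], n_cases=2)
        for s0 in (0.0, 0.5, 3.0):
            assert sam_statistics(exp, s0).loc["g1", "d"] == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 100.0])
    def test_scale_invariance_at_zero_s0(self, c):
        base = np.array([[2.0, 4.0, 1.0, 1.5], [1, 2, 3, 4.0]])
        d0 = sam_statistics(build_experiment(base, 2), 0.0)["d"]
        scaled = base.copy()
        scaled[0] *= c
        d1 = sam_statistics(build_experiment(scaled, 2), 0.0)["d"]
        assert d1["g1"] == pytest.approx(d0["g1"])

    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        base = np.array([[2.0, 4.0, 1.0, 1.5], [1, 2, 3, 4.0]])
        d0 = sam_statistics(build_experiment(base, 2), 0.3)["d"]
        shifted = base.copy()
        shifted[0] += shift
        d1 = sam_statistics(build_experiment(shifted, 2), 0.3)["d"]
        assert d1["g1"] == pytest.approx(d0["g1"], rel=1e-9, abs=1e-9)

    def test_zero_denominator_rejected(self):
        exp = build_experiment([[2, 4, 1, 1], [3, 3, 3, 3.0]], n_cases=2)
        with pytest.raises(ValueError, match="s \\+ s0"):
            sam_statistics(exp, 0.0)


class TestChooseS0:
    def test_degenerate_equal_spread_returns_common_value(self):
        rng = np.random.default_rng(0)
        s = np.full(300, 0.37)
        assert choose_s0(rng.normal(size=300), s) == pytest.approx(0.37)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        s = np.abs(rng.normal(0.3, 0.2, 500)) + 0.01
        r = rng.normal(0, s + 0.05)
        perm = rng.permutation(500)
        assert choose_s0(r, s) == choose_s0(r[perm], s[perm])

    def test_variance_dependent_inflation_yields_positive_s0(self):
        # r has spread (s + tau) so raw d = r/s blows up at small s; an
        # independent brute-force CV scan over the same candidate grid is
        # the oracle
        rng = np.random.default_rng(2)
        s = np.abs(rng.normal(0.2, 0.15, 2000)) + 0.005
        r = rng.normal(0, s + 0.1)
        chosen = choose_s0(r, s)
        assert chosen > 0

        def oracle(r, s):
            best_cv, best = np.inf, None
            bins = pd.qcut(s, 100, duplicates="drop")
            for cand in np.percentile(s, np.arange(0, 101, 5)):
                d = pd.Series(r / (s + cand))
                mads = d.groupby(bins, observed=True).apply(
                    lambda g: np.median(np.abs(g - np.median(g)))
                )
                cv = mads.std(ddof=1) / mads.mean()
                if cv < best_cv:
                    best_cv, best = cv, cand
            return best

        assert chosen == pytest.approx(oracle(r, s))


class TestPermutationCalls:
    def test_huge_delta_calls_nothing(self, strong_experiment):
        exp, _ = strong_experiment
        calls, fdr = sam_permutation_calls(exp, s0=0.1, B=60, delta=1e6, seed=0)
        assert len(calls.called) == 0
        assert fdr == 0.0

    def test_call_sets_nested_in_delta(self, strong_experiment):
        exp, _ = strong_experiment
        null = PermutationNull(exp, s0=0.1, B=60, seed=0)
        previous = None
        for delta in [0.2, 0.5, 1.0, 2.0]:
            calls, _ = sam_permutation_calls(exp, 0.1, 60, delta, null=null)
            if previous is not None:
                assert calls.called <= previous
            previous = calls.called

    def test_bitwise_reproducible(self, small_compendium):
        exp = small_compendium[0][0]
        a = sam_analyze(exp, B=64, seed=42)
        b = sam_analyze(exp, B=64, seed=42)
        pd.testing.assert_frame_equal(a.calls.table, b.calls.table)
        assert a.s0 == b.s0 and a.delta == b.delta and a.fdr == b.fdr

    def test_full_enumeration_fallback_for_tiny_designs(self):
        rng = np.random.default_rng(3)
        exp = build_experiment(rng.normal(size=(50, 6)), n_cases=3)
        null = PermutationNull(exp, s0=0.1, B=60, seed=0)
        assert null.B == 20  # C(6,3) distinct assignments


class TestTuneDelta:
    def test_vacuous_target_gives_zero_delta(self, strong_experiment):
        exp, _ = strong_experiment
        assert tune_delta(exp, s0=0.1, B=60, fdr_target=1.0, seed=0) == 0.0

    def test_tightening_target_never_enlarges_call_set(self, strong_experiment):
        exp, _ = strong_experiment
        null = PermutationNull(exp, s0=0.1, B=60, seed=0)
        sizes = []
        for target in [0.01, 0.05, 0.25, 1.0]:
            delta = tune_delta(exp, 0.1, 60, target, null=null)
            calls, _ = sam_permutation_calls(exp, 0.1, 60, delta, null=null)
            sizes.append(len(calls.called))
        assert sizes == sorted(sizes)

    def test_strong_planted_signal_mostly_recovered(self, strong_experiment):
        exp, truth = strong_experiment
        result = sam_analyze(exp, fdr_target=0.05, B=100, seed=5)
        active = truth.active_genes("E01") & set(exp.genes)
        recovered = active & result.calls.called
        assert len(recovered) >= 0.9 * len(active)
        # calls agree with the q-values at the tuned threshold
        table = result.calls.table
        assert (table.loc[table["call"] != NONE, "q"] <= result.fdr + 1e-12).all()


def test_welch_bh_engine_agrees_with_sam_on_strong_signal(strong_experiment):
    exp, _ = strong_experiment
    sam_called = sam_analyze(exp, fdr_target=0.05, B=100, seed=5).calls.called
    tt_called = ttest_bh_calls(exp, fdr_target=0.05).called
    jaccard = len(sam_called & tt_called) / len(sam_called | tt_called)
    assert jaccard >= 0.8
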