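import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from egwaskit.egwas import (
    DEFAULT_THRESHOLD,
    UPPER,
    EgwasResult,
    fisher_gene_p,
    manhattan_table,
    run_egwas,
    vote_count,
)
from egwaskit.evaluation import fisher_two_sided_oracle, random_vote_tables
from egwaskit.sam import DECallSet


def make_call_set(experiment_id, calls):
    table = pd.DataFrame(
        {"d": 0.0, "call": pd.Series(calls), "q": 1.0},
    )
    return DECallSet(experiment_id, table)


UNIVERSE = ["gA", "gB", "gC", "gD"]


@pytest.fixture
def three_experiments():
    # gA: called everywhere; gB: absent from E2, called once elsewhere;
    # gC: measured everywhere, never called; gD: only measured in E3
    return [
        make_call_set("E1", {"gA": "up", "gB": "down", "gC": "none"}),
        make_call_set("E2", {"gA": "up", "gC": "none"}),
        make_call_set("E3", {"gA": "down", "gB": "none", "gC": "none", "gD": "none"}),
    ]


class TestVoteCount:
    def test_hand_tallied_counts(self, three_experiments):
        votes = vote_count(three_experiments, UNIVERSE)
        tab = votes.table
        assert tab.loc["gA"].tolist()[:3] == [3, 0, 3]  # saturated vote
        assert tab.loc["gB"].tolist()[:3] == [1, 1, 2]  # coverage exclusion
        assert tab.loc["gC"].tolist()[:3] == [0, 3, 3]
        assert tab.loc["gD"].tolist()[:3] == [0, 1, 1]
        assert votes.totals == (4, 5)
        # conservation: n_pos + n_neg = number of measuring experiments
        assert (tab["n_pos"] + tab["n_neg"] == tab["n_measured"]).all()
        # direction is retained but does not affect n_pos
        assert tab.loc["gA", "n_up"] == 2 and tab.loc["gA", "n_down"] == 1

    def test_duplicate_experiment_ids_rejected(self, three_experiments):
        with pytest.raises(ValueError, match="duplicate experiment ids"):
            vote_count(three_experiments[:1] * 2, UNIVERSE)

    def test_calls_outside_universe_rejected(self, three_experiments):
        with pytest.raises(ValueError, match="outside the universe"):
            vote_count(three_experiments, ["gA", "gB", "gC"])


class TestFisherGeneP:
    def test_degenerate_margin_gives_one(self):
        assert fisher_gene_p(0, 13, 0, 399987) == 1.0

    def test_example_table_matches_enumeration_oracle(self):
        p = fisher_gene_p(10, 3, 500, 9500)
        assert p == pytest.approx(fisher_two_sided_oracle(10, 3, 500, 9500), rel=1e-10)

    def test_more_extreme_table_has_smaller_p(self):
        assert fisher_gene_p(5, 8, 2998, 37002) < fisher_gene_p(3, 10, 3000, 37000)

    def test_seeded_grid_matches_oracle_and_scipy(self):
        for a, b, c, d in random_vote_tables(150, seed=5, max_background=10000):
            p = fisher_gene_p(a, b, c, d)
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-10)
            assert p == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-7, abs=1e-300
            )

    def test_upper_tail_monotone_in_n_pos(self):
        # with margins fixed, over-calling beyond expectation shrinks the
        # upper-tail p strictly
        ps = [fisher_gene_p(a, 13 - a, 400 - a, 4600 - (13 - a), UPPER)
              for a in range(3, 13)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_gene_p(-1, 3, 5, 5)
        with pytest.raises(ValueError):
            fisher_gene_p(0, 0, 5, 5)


class TestRunEgwas:
    def test_global_null_all_p_one(self, three_experiments):
        null_sets = [
            make_call_set(cs.experiment_id,
                          {g: "none" for g in cs.table.index})
            for cs in three_experiments
        ]
        result = run_egwas(vote_count(null_sets, UNIVERSE))
        assert (result.table["p"] == 1.0).all()
        assert result.significant == []

    def test_default_threshold_constant(self, three_experiments):
        result = run_egwas(vote_count(three_experiments, UNIVERSE))
        assert result.threshold == DEFAULT_THRESHOLD == 1.0e-5

    def test_ranks_are_a_permutation_with_tie_rules(self, three_experiments):
        result = run_egwas(vote_count(three_experiments, UNIVERSE))
        tab = result.table
        assert sorted(tab["rank"]) == list(range(1, len(tab) + 1))
        assert (tab["p"].diff().dropna() >= 0).all()
        # equal p: higher n_pos first, then lexicographic id
        for (_, a), (_, b) in zip(tab.iterrows(), tab.iloc[1:].iterrows()):
            if a["p"] == b["p"]:
                assert (a["n_pos"], a.name) >= (b["n_pos"], a.name) or a.name < b.name

    def test_unmeasured_genes_reported_separately(self, three_experiments):
        result = run_egwas(vote_count(three_experiments, UNIVERSE + ["gE"]))
        assert result.unmeasured == ["gE"]
        assert "gE" not in result.table.index

    def test_bonferroni_exact_flag(self, three_experiments):
        result = run_egwas(vote_count(three_experiments, UNIVERSE),
                           bonferroni_exact=True)
        assert result.threshold == pytest.approx(0.05 / len(result.table))


class TestManhattan:
    @staticmethod
    def result_with_p(pvals):
        table = pd.DataFrame({
            "n_pos": 1, "n_neg": 1,
            "p": pd.Series(pvals),
        })
        table["rank"] = table["p"].rank(method="first").astype(int)
        table["significant"] = table["p"] < DEFAULT_THRESHOLD
        return EgwasResult(table, threshold=DEFAULT_THRESHOLD)

    def test_log_identity_and_reference_line(self):
        result = self.result_with_p({"gA": 1.0, "gB": 0.01})
        positions = pd.DataFrame(
            {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr2"], "start": [0, 5]}
        )
        table, ref = manhattan_table(result, positions)
        assert table.loc["gA", "neg_log10_p"] == 0.0
        assert ref == pytest.approx(5.0)

    def test_high_precision_log_of_reported_candidate_p(self):
        # -log10(6.83e-6) evaluated with arbitrary-precision arithmetic
        import mpmath

        mpmath.mp.dps = 40
        expected = float(-mpmath.log(mpmath.mpf("6.83e-6")) / mpmath.log(10))
        result = self.result_with_p({"gA": 6.83e-6, "gB": 0.5})
        positions = pd.DataFrame(
            {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"], "start": [0, 1]}
        )
        table, _ = manhattan_table(result, positions)
        assert table.loc["gA", "neg_log10_p"] == pytest.approx(expected, rel=1e-12)

    def test_genes_without_positions_dropped_sorted_output(self):
        result = self.result_with_p({"gA": 0.5, "gB": 0.1, "gC": 0.2})
        positions = pd.DataFrame(
            {"gene_id": ["gB", "gA"], "chrom": ["chr2", "chr1"], "start": [7, 3]}
        )
        table, _ = manhattan_table(result, positions)
        assert list(table.index) == ["gA", "gB"]  # chrom order, gC dropped
        with pytest.raises(ValueError, match="no scored gene"):
            manhattan_table(result, positions.iloc[:0])
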