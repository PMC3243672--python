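"""Self-correlation, Δ_AB, member ranking and adherence."""

import numpy as np
import pandas as pd
import pytest

from coevonet.alignment import Alignment
from coevonet.analytics import (
    ScoreLookup,
    adherence,
    delta_ab,
    delta_matrix,
    rank_members,
    self_correlation_matrix,
)


def make_score_table(pairs):
    """Build a score DataFrame from {(a, b): (score_ab, score_ba)}."""
    rows = []
    for (a, b), (sab, sba) in pairs.items():
        rows.append(
            {
                "label_a": a, "label_b": b,
                "score_ab": sab, "score_ba": sba,
                "mean_score": 0.5 * (sab + sba),
            }
        )
    return pd.DataFrame(rows)


class TestSelfCorrelation:
    def test_perfect_co_occurrence(self):
        rows = ["AD"] * 5 + ["CE"] * 5
        aln = Alignment([f"s{i}" for i in range(10)], rows)
        sc = self_correlation_matrix(aln, [("A1", 1, "A"), ("D2", 2, "D")])
        assert sc.overall_freq == [50.0, 50.0]
        assert sc.conditional_freq[0, 1] == pytest.approx(100.0)
        assert sc.conditional_freq[1, 0] == pytest.approx(100.0)

    def test_independent_members_conditional_near_overall(self):
        rng = np.random.default_rng(0)
        n = 4000
        col1 = rng.choice(["A", "C"], size=n)
        col2 = rng.choice(["D", "E"], size=n)
        aln = Alignment(
            [f"s{i}" for i in range(n)],
            [a + b for a, b in zip(col1, col2)],
        )
        sc = self_correlation_matrix(aln, [("A1", 1, "A"), ("D2", 2, "D")])
        assert sc.conditional_freq[0, 1] == pytest.approx(
            sc.overall_freq[0], abs=3.0
        )

    def test_matches_direct_contingency_count(self, planted_fixture):
        aln, _ = planted_fixture
        members = [("H5", 5, "H"), ("D6", 6, "D"), ("W7", 7, "W")]
        sc = self_correlation_matrix(aln, members)
        # brute-force count for one entry: % of D6 carriers that carry H5
        carriers = [r for r in aln.rows if r[5] == "D"]
        both = sum(1 for r in carriers if r[4] == "H")
        assert sc.conditional_freq[0, 1] == pytest.approx(
            100.0 * both / len(carriers)
        )

    def test_absent_member_errors(self):
        aln = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(ValueError, match="absent"):
            self_correlation_matrix(aln, [("W1", 1, "W"), ("C2", 2, "C")])

    def test_members_on_same_column_rejected(self):
        aln = Alignment(["a", "b"], ["AC", "CC"])
        with pytest.raises(ValueError, match="distinct columns"):
            self_correlation_matrix(aln, [("A1", 1, "A"), ("C1", 1, "C")])


class TestDeltaAB:
    def test_singleton_diagonal_is_zero(self):
        table = make_score_table({("a", "b"): (5.0, 5.0)})
        assert delta_ab(table, ["a"], ["a"]) == 0.0

    def test_constant_cross_table(self):
        table = make_score_table(
            {
                ("a1", "b1"): (-30.0, -30.0),
                ("a1", "b2"): (-30.0, -30.0),
                ("a2", "b1"): (-30.0, -30.0),
                ("a2", "b2"): (-30.0, -30.0),
            }
        )
        assert delta_ab(table, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(-30.0)

    def test_direction_resolved_asymmetry(self):
        table = make_score_table({("a1", "b1"): (-10.0, -20.0)})
        assert delta_ab(table, ["a1"], ["b1"]) == pytest.approx(-10.0)
        assert delta_ab(table, ["b1"], ["a1"]) == pytest.approx(-20.0)
        sym = delta_ab(table, ["a1"], ["b1"], direction_resolved=False)
        assert sym == pytest.approx(-15.0)

    def test_diagonal_averages_unordered_pairs(self):
        table = make_score_table(
            {("a", "b"): (10.0, 10.0), ("a", "c"): (20.0, 20.0),
             ("b", "c"): (30.0, 30.0)}
        )
        assert delta_ab(table, ["a", "b", "c"], ["a", "b", "c"]) == pytest.approx(20.0)

    def test_planted_relationships(self, planted_fixture):
        from conftest import (
            PLANTED_EXCLUSIVE_A,
            PLANTED_EXCLUSIVE_B,
            PLANTED_INDEPENDENT,
        )
        from coevonet.scoring import score_table

        aln, _ = planted_fixture
        _, table = score_table(aln, 0.3)
        lookup = ScoreLookup(table)
        excl = delta_ab(lookup, sorted(PLANTED_EXCLUSIVE_A), sorted(PLANTED_EXCLUSIVE_B))
        indep = delta_ab(lookup, sorted(PLANTED_EXCLUSIVE_A), sorted(PLANTED_INDEPENDENT))
        within = delta_ab(lookup, sorted(PLANTED_EXCLUSIVE_A), sorted(PLANTED_EXCLUSIVE_A))
        assert excl < -20
        assert abs(indep) < 5
        assert within > 20

    def test_delta_matrix_shape_and_diagonal(self):
        table = make_score_table({("a", "b"): (10.0, 10.0)})
        dm = delta_matrix(table, [["a", "b"], ["c"]])
        assert dm.shape == (2, 2)
        assert dm.loc["1", "1"] == pytest.approx(10.0)
        assert dm.loc["2", "2"] == 0.0


def brute_force_ranking(scores, members):
    """Independent elimination loop using sums (order-equivalent to means)."""
    remaining = sorted(members)
    order = []
    while len(remaining) > 2:
        sums = {
            m: sum(scores.get(frozenset((m, o)), 0.0) for o in remaining if o != m)
            for m in remaining
        }
        worst = min(remaining, key=lambda m: (sums[m], m))
        order.append(worst)
        remaining.remove(worst)
    return order, tuple(remaining)


class TestRankMembers:
    def test_forced_elimination_order(self):
        table = make_score_table(
            {("A", "B"): (50.0, 50.0), ("A", "C"): (10.0, 10.0),
             ("B", "C"): (10.0, 10.0)}
        )
        ranking = rank_members(table, ["A", "B", "C"])
        assert [lab for lab, _ in ranking.elimination_order] == ["C"]
        assert ranking.elimination_order[0][1] == pytest.approx(10.0)
        assert ranking.final_pair == ("A", "B", pytest.approx(50.0))

    def test_all_negative_member_eliminated_first(self):
        # one member anti-correlated with every other: first out, with a
        # negative reported mean
        pairs = {}
        members = ["H40", "M1", "M2", "M3", "M4"]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a == "H40" or b == "H40":
                    pairs[(a, b)] = (-20.0, -19.8)
                else:
                    pairs[(a, b)] = (90.0, 90.0)
        ranking = rank_members(make_score_table(pairs), members)
        first, first_mean = ranking.elimination_order[0]
        assert first == "H40" and first_mean < 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        members = [f"m{i}" for i in range(k)]
        pairs, scores = {}, {}
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                s = float(rng.normal(20, 40))
                pairs[(a, b)] = (s, s)
                scores[frozenset((a, b))] = s
        ranking = rank_members(make_score_table(pairs), members)
        order, final = brute_force_ranking(scores, members)
        assert [lab for lab, _ in ranking.elimination_order] == order
        assert tuple(sorted(ranking.final_pair[:2])) == tuple(sorted(final))

    def test_order_invariant_to_member_input_order(self):
        pairs = {("a", "b"): (5.0, 5.0), ("a", "c"): (9.0, 9.0),
                 ("b", "c"): (7.0, 7.0)}
        t = make_score_table(pairs)
        r1 = rank_members(t, ["a", "b", "c"])
        r2 = rank_members(t, ["c", "a", "b"])
        assert r1 == r2

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            rank_members(make_score_table({}), ["x"])


class TestAdherence:
    members = [("A1", 1, "A"), ("C2", 2, "C"), ("D3", 3, "D")]
    weights = {("A1", "C2"): 10.0, ("A1", "D3"): 20.0, ("C2", "D3"): 30.0}

    def test_full_and_empty(self):
        assert adherence("ACD", self.members, self.weights) == 1.0
        assert adherence("GGG", self.members, self.weights) == 0.0

    def test_partial_weighting(self):
        # carries A1 and C2 only: one pair of weight 10 out of 60
        assert adherence("ACG", self.members, self.weights) == pytest.approx(10 / 60)

    def test_monotone_in_added_residues(self):
        low = adherence("ACG", self.members, self.weights)
        high = adherence("ACD", self.members, self.weights)
        assert high >= low

    def test_zero_weight_community_errors(self):
        with pytest.raises(ValueError, match="zero positive"):
            adherence("ACD", self.members, {})

    def test_negative_weights_ignored(self):
        w = dict(self.weights)
        w[("A1", "C2")] = -10.0
        val = adherence("ACG", self.members, w)
        assert val == 0.0  # only pair present has non-positive weight
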