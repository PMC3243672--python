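"""Binomial-tail scores: exact-value oracles, signs, and eligibility."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevonet.alignment import Alignment
from coevonet.scoring import (
    ResidueNode,
    binomial_tail_log10,
    directional_score,
    eligible_nodes,
    min_perturbation_fraction,
    node_label,
    reference_numbering,
    score_all_pairs,
    score_table,
)


def exact_tail_log10(n: int, s: int, p: Fraction, tail: str) -> float:
    """Arbitrary-precision oracle: exact rational tail, then log10."""
    ks = range(s, n + 1) if tail == "upper" else range(0, s + 1)
    total = sum(
        Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k) for k in ks
    )
    if total == 1:
        return 0.0
    if total > Fraction(1, 2):
        return -math.log1p(float(total - 1)) / math.log(10)
    return -(math.log10(total.numerator) - math.log10(total.denominator))


class TestBinomialTail:
    def test_whole_distribution_tails_are_zero(self):
        assert binomial_tail_log10(10, 0, 0.5, "upper") == 0.0
        assert binomial_tail_log10(10, 10, 0.5, "lower") == 0.0

    def test_closed_form_all_successes(self):
        # P(X >= 10 | n=10, p=1/2) = 2^-10
        assert binomial_tail_log10(10, 10, 0.5, "upper") == pytest.approx(
            10 * math.log10(2), rel=1e-12
        )

    def test_six_term_tail_matches_rational_sum(self):
        expected = exact_tail_log10(30, 25, Fraction(1, 2), "upper")
        assert binomial_tail_log10(30, 25, 0.5, "upper") == pytest.approx(
            expected, rel=1e-12
        )

    def test_far_below_float_underflow(self):
        # p = 0.3^800 ~ 1e-418 is unrepresentable as a float, but the
        # log-space path must report the score
        got = binomial_tail_log10(800, 800, 0.3, "upper")
        assert got == pytest.approx(-800 * math.log10(0.3), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_tail_log10(10, 11, 0.5)
        with pytest.raises(ValueError):
            binomial_tail_log10(10, 5, 0.0)
        with pytest.raises(ValueError):
            binomial_tail_log10(10, 5, 1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 60),
        s_frac=st.floats(0, 1),
        p_thousandths=st.integers(1, 999),
        tail=st.sampled_from(["upper", "lower"]),
    )
    def test_matches_exact_rational_oracle(self, n, s_frac, p_thousandths, tail):
        s = int(round(s_frac * n))
        p = Fraction(p_thousandths, 1000)
        expected = exact_tail_log10(n, s, p, tail)
        got = binomial_tail_log10(n, s, float(p), tail)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 60),
        s_frac=st.floats(0, 1),
        p_thousandths=st.integers(1, 999),
    )
    def test_upper_and_lower_tails_are_complementary(self, n, s_frac, p_thousandths):
        s = max(1, int(round(s_frac * n)))
        p = p_thousandths / 1000
        upper = binomial_tail_log10(n, s, p, "upper")
        lower = binomial_tail_log10(n, s - 1, p, "lower")
        assert 10.0**-upper + 10.0**-lower == pytest.approx(1.0, abs=1e-9)


def _node(column, count, N):
    return ResidueNode(column=column, residue="A", count=count, frequency=count / N)


class TestDirectionalScore:
    def test_joint_at_expectation_is_near_zero(self):
        a = _node(1, 30, 100)
        b = ResidueNode(column=2, residue="C", count=50, frequency=0.5)
        ds = directional_score(100, a, b, 15)
        assert 0 <= ds.signed_log_p < 1

    def test_full_co_occurrence_positive(self):
        a = _node(1, 30, 100)
        b = ResidueNode(column=2, residue="C", count=50, frequency=0.5)
        ds = directional_score(100, a, b, 30)
        assert ds.signed_log_p == pytest.approx(30 * math.log10(2), rel=1e-12)
        assert ds.conditional_frequency == 1.0

    def test_zero_co_occurrence_negative(self):
        a = _node(1, 30, 100)
        b = ResidueNode(column=2, residue="C", count=50, frequency=0.5)
        ds = directional_score(100, a, b, 0)
        assert ds.signed_log_p == pytest.approx(-30 * math.log10(2), rel=1e-12)

    def test_invariant_target_rejected(self):
        a = _node(1, 30, 100)
        b = ResidueNode(column=2, residue="C", count=100, frequency=1.0)
        with pytest.raises(ValueError):
            directional_score(100, a, b, 30)


class TestScoreAllPairs:
    def test_covarying_columns(self, covarying_alignment):
        edges = score_all_pairs(covarying_alignment, 0.3)
        assert len(edges) == 4  # {A3,C3} x {D7,E7}
        by_labels = {(e.label_a, e.label_b): e for e in edges}
        expected = 20 * math.log10(2)
        for (la, lb), e in by_labels.items():
            assert e.score_ab == pytest.approx(e.score_ba, rel=1e-9)
            matched = (la[0], lb[0]) in {("A", "D"), ("C", "E")}
            sign = 1 if matched else -1
            assert e.mean_score == pytest.approx(sign * expected, rel=1e-9)

    def test_iid_uniform_columns_score_below_background_bound(self):
        rng = np.random.default_rng(2718)
        mat = rng.choice(list("ACD"), size=(200, 30))
        aln = Alignment(
            [f"s{i}" for i in range(200)], ["".join(r) for r in mat]
        )
        _, table = score_table(aln, 0.2)
        assert len(table) > 0
        assert table["mean_score"].abs().max() < 5

    def test_node_below_min_fraction_absent(self):
        rows = ["AD"] * 2 + ["CD"] * 8
        aln = Alignment([f"s{i}" for i in range(10)], rows)
        nodes = eligible_nodes(aln, 0.3)
        assert ("A", 1) not in {(n.residue, n.column) for n in nodes}

    def test_row_permutation_invariance(self, covarying_alignment):
        aln = covarying_alignment
        perm = np.random.default_rng(0).permutation(aln.N)
        shuffled = Alignment(
            [aln.sequence_ids[i] for i in perm], [aln.rows[i] for i in perm]
        )
        _, t1 = score_table(aln, 0.3)
        _, t2 = score_table(shuffled, 0.3)
        key = ["col_a", "res_a", "col_b", "res_b"]
        t1 = t1.sort_values(key).reset_index(drop=True)
        t2 = t2.sort_values(key).reset_index(drop=True)
        assert np.allclose(t1["mean_score"], t2["mean_score"])

    def test_gapped_sequences_excluded_from_trials(self):
        # sequences gapped at column 2 are not observations for pairs
        # targeting that column
        rows = ["AD", "AD", "AD", "A-", "CE", "CE", "CE", "C-"]
        aln = Alignment([f"s{i}" for i in range(8)], rows)
        _, table = score_table(aln, 0.2)
        row = table[(table.col_a == 1) & (table.res_a == "A")]
        ad = row[(row.col_b == 2) & (row.res_b == "D")].iloc[0]
        assert ad.joint_ab == 3


class TestMinPerturbationFraction:
    def test_sod_scale_is_attainable(self):
        assert min_perturbation_fraction(675) <= 0.3

    def test_too_few_sequences_errors(self):
        with pytest.raises(ValueError, match="more sequences"):
            min_perturbation_fraction(20)

    def test_monotone_in_alignment_size(self):
        prev = 1.0
        for N in (150, 300, 600, 1200, 2400):
            f = min_perturbation_fraction(N)
            assert f <= prev
            prev = f


class TestLabels:
    def test_reference_numbering_skips_gaps(self):
        aln = Alignment(["ref", "x"], ["A-CD", "AGCD"])
        refmap = reference_numbering(aln, "ref")
        assert refmap == {1: 1, 3: 2, 4: 3}

    def test_node_label_styles(self):
        nd = ResidueNode(column=3, residue="G", count=5, frequency=0.5)
        assert node_label(nd) == "G3"
        assert node_label(nd, {3: 71}) == "G71"
        assert node_label(nd, {2: 1}) == "GX(3)"
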