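"""Cohen's kappa, contingency tables, distribution tables, and the rDR post hoc."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drconcord import (
    ContingencyTable,
    build_contingency,
    cohen_kappa,
    distribution_table,
    kappa_vs_final,
    pairwise_kappa_summary,
    rdr_analysis,
)

tables = st.lists(
    st.lists(st.integers(0, 12), min_size=4, max_size=4), min_size=4, max_size=4
)


def _table(counts):
    return ContingencyTable(np.asarray(counts))


class TestBuildContingency:
    def test_diagonal_counts(self):
        t = build_contingency([0, 1], [0, 1], k=5)
        assert t.counts[0, 0] == 1 and t.counts[1, 1] == 1 and t.n == 2
        assert t.k == 5  # scale-fixed, zero rows retained

    def test_full_cross(self):
        t = build_contingency([0, 0, 1, 1], [0, 1, 0, 1], k=2)
        assert (t.counts == 1).all()

    def test_degenerate_constant(self):
        t = build_contingency([0, 0, 0], [0, 0, 0], k=5)
        assert t.counts[0, 0] == 3 and t.counts.sum() == 3

    def test_errors(self):
        with pytest.raises(ValueError):
            build_contingency([0, 1], [0], k=5)
        with pytest.raises(ValueError):
            build_contingency([0, 5], [0, 1], k=5)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(build_contingency([0, 1, 2, 1], [0, 1, 2, 1], k=5)) == 1.0

    def test_chance_level(self):
        assert cohen_kappa(_table([[1, 1], [1, 1]])) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # p_o = 11/16, p_e = 85/256 -> kappa = 91/171
        assert cohen_kappa(_table([[4, 1, 0], [2, 3, 1], [0, 1, 4]])) == pytest.approx(91 / 171)

    def test_both_raters_constant_and_equal(self):
        assert cohen_kappa(build_contingency([0, 0], [0, 0], k=5)) == 1.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cohen_kappa(ContingencyTable(np.zeros((3, 3), int)))

    @given(tables)
    def test_range_symmetry_and_transpose(self, counts):
        t = _table(counts)
        if t.n == 0:
            return
        for w in ("none", "linear", "quadratic"):
            k = cohen_kappa(t, w)
            assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9
            assert cohen_kappa(t.transpose(), w) == pytest.approx(k)

    @given(tables, st.permutations(list(range(4))))
    def test_relabeling_invariance_unweighted(self, counts, perm):
        t = _table(counts)
        if t.n == 0:
            return
        relabeled = ContingencyTable(t.counts[np.ix_(perm, perm)])
        assert cohen_kappa(relabeled) == pytest.approx(cohen_kappa(t))

    def test_all_weightings_agree_on_diagonal_tables(self):
        t = _table(np.diag([3, 0, 5, 2]))
        assert (
            cohen_kappa(t, "none")
            == cohen_kappa(t, "linear")
            == cohen_kappa(t, "quadratic")
            == 1.0
        )

    def test_cross_check_against_sklearn(self):
        """Agreement with an independent implementation on 100 random tables."""
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 8, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            a, b = [], []
            for i, j in itertools.product(range(k), repeat=2):
                a += [i] * counts[i, j]
                b += [j] * counts[i, j]
            for ours, theirs in (
                ("none", None),
                ("linear", "linear"),
                ("quadratic", "quadratic"),
            ):
                ref = sklearn.cohen_kappa_score(
                    a, b, labels=list(range(k)), weights=theirs
                )
                if np.isnan(ref):  # sklearn returns NaN for zero expected disagreement
                    continue
                assert cohen_kappa(ContingencyTable(counts), ours) == pytest.approx(
                    ref, abs=1e-10
                )


class TestKappaReports:
    def test_identical_raters_give_unit_kappas(self):
        ratings = {"g1": [0, 1, 2], "g2": [0, 1, 2], "g3": [0, 1, 2]}
        assert set(kappa_vs_final(ratings, [0, 1, 2]).values()) == {1.0}
        pairwise, means = pairwise_kappa_summary(ratings)
        assert set(pairwise.values()) == {1.0} and set(means.values()) == {1.0}

    def test_two_graders_mean_equals_single_pairwise(self):
        ratings = {"a": [0, 1, 2, 2], "b": [0, 1, 1, 2]}
        pairwise, means = pairwise_kappa_summary(ratings)
        assert means["a"] == means["b"] == pairwise[("a", "b")]

    def test_single_grader_rejected(self):
        with pytest.raises(ValueError):
            pairwise_kappa_summary({"a": [0, 1]})


class TestDistributionTable:
    def test_reference_patient_distribution(self):
        grades = [0] * 245 + [1] * 54 + [2] * 29 + [3] * 7
        dist = distribution_table(grades, k=4)
        assert dist.percentages == {0: 73.13, 1: 16.12, 2: 8.66, 3: 2.09}
        assert dist.count_at_or_above(2) == 36
        assert dist.share_at_or_above(1) == 26.87
        assert dist.share_at_or_above(1, ndigits=0) == 27

    def test_single_grade(self):
        dist = distribution_table([0], k=5)
        assert dist.percentages[0] == 100.0 and dist.total == 1
        assert dist.counts[4] == 0  # zero-count levels retained

    def test_uniform(self):
        dist = distribution_table([0, 1, 2, 3], k=4)
        assert set(dist.percentages.values()) == {25.0}


def _rdr_one_patient(triple, ai):
    summary = rdr_analysis({("p", "OD"): triple}, {"p": ai})
    return summary


class TestRdrAnalysis:
    def test_all_agree_everywhere(self):
        s = rdr_analysis(
            {("p", "OD"): (0, 0, 0), ("p", "OS"): (2, 2, 2)}, {"p": 2}
        )
        assert s.eye_full_agreement == 2 and s.eye_majority == 0
        assert s.patient_full_agreement == 1
        assert s.full_agreement_ai_disagreements == 0

    def test_ai_against_majority_worked_example(self):
        # humans (0, 0, 2): majority non-referable; AI (2) is referable -> against
        s = _rdr_one_patient((0, 0, 2), ai=2)
        assert s.patient_majority == 1
        assert s.majority_ai_against_majority == 1
        assert s.majority_ai_with_majority == 0

    def test_brute_force_over_all_binary_patterns(self):
        """Walk all 2^3 x 2 referable patterns against a literal re-derivation."""
        for bits in itertools.product((0, 2), repeat=3):
            for ai in (0, 2):
                s = _rdr_one_patient(bits, ai)
                n_ref = sum(b == 2 for b in bits)
                ai_ref = ai == 2
                if n_ref in (0, 3):
                    assert s.patient_full_agreement == 1
                    expect_dis = int(ai_ref != (n_ref == 3))
                    assert s.full_agreement_ai_disagreements == expect_dis
                    assert s.ai_referable_disagreements == int(expect_dis and ai_ref)
                    assert s.ai_nonreferable_disagreements == int(expect_dis and not ai_ref)
                else:
                    majority = n_ref == 2
                    assert s.patient_majority == 1
                    assert s.majority_ai_with_majority == int(ai_ref == majority)
                    assert s.majority_ai_against_majority == int(ai_ref != majority)

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4)),
            min_size=1,
            max_size=8,
        ),
        st.integers(0, 3),
    )
    def test_patient_counts_partition(self, triples, ai):
        eyes = {("p", "OD") if i == 0 else (f"q{i}", "OD"): t for i, t in enumerate(triples)}
        ais = {pid: ai for pid, _ in eyes}
        s = rdr_analysis(eyes, ais)
        assert s.patient_full_agreement + s.patient_majority == s.n_patients
        assert s.eye_full_agreement + s.eye_majority == s.n_eyes
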