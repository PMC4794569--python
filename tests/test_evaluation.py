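"""Statistics tests: worked examples on the bundled reader-concordance
fixtures, algebraic identities on random matrices, and exact McNemar
enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

import hep2cad as h
from hep2cad.evaluation import ConfusionMatrix, excluded_classes


@pytest.fixture(scope="module")
def senior_cm():
    return h.load_senior_concordance()


count_matrices = st.integers(2, 5).flatmap(
    lambda k: st.lists(
        st.lists(st.integers(0, 30), min_size=k, max_size=k),
        min_size=k,
        max_size=k,
    )
)


class TestConfusionMatrix:
    def test_identical_lists_are_diagonal(self):
        labels = ["a", "b", "a", "c"] * 3
        cm = h.confusion_matrix(labels, labels, ["a", "b", "c"])
        assert cm.n == 12
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_empty_inputs(self):
        cm = h.confusion_matrix([], [], ["a", "b"])
        assert cm.n == 0 and cm.counts.sum() == 0

    def test_matches_brute_force_tally(self, rng):
        classes = ["x", "y", "z"]
        ref = rng.choice(classes, 60)
        pred = rng.choice(classes, 60)
        cm = h.confusion_matrix(ref, pred, classes)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                expected = sum(1 for r, p in zip(ref, pred) if r == a and p == b)
                assert cm.counts[i, j] == expected

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="bogus"):
            h.confusion_matrix(["a", "bogus"], ["a", "a"], ["a"])


class TestSeniorConcordanceFixture:
    def test_margins_reproduce_published_totals(self, senior_cm):
        assert senior_cm.n == 589
        assert senior_cm.row_totals().tolist() == [141, 134, 122, 114, 39, 31, 8]
        assert senior_cm.col_totals().tolist() == [172, 142, 94, 99, 44, 31, 7]

    def test_observed_agreement_rounds_to_71_percent(self, senior_cm):
        agreement = h.accuracy(senior_cm)
        assert agreement == pytest.approx(419 / 589)
        assert round(100 * agreement) == 71

    def test_kappa_rounds_to_0_64(self, senior_cm):
        assert round(h.cohens_kappa(senior_cm), 2) == 0.64

    def test_centromere_perfect_concordance(self, senior_cm):
        # with reader 1 as the reference axis (columns)
        transposed = ConfusionMatrix(senior_cm.classes, senior_cm.counts.T)
        assert h.ccr(transposed, "centromere") == 1.0

    def test_readers_not_independent(self, senior_cm):
        assert h.chi_square_independence(senior_cm).p_value < 0.05


class TestCcrAccuracyMac:
    def test_zero_diagonal_gives_zero_ccr(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[0, 5], [1, 4]]))
        assert h.ccr(cm, "a") == 0.0

    def test_empty_class_ccr_is_error(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[0, 0], [1, 4]]))
        with pytest.raises(ValueError, match="no reference"):
            h.ccr(cm, "a")

    def test_perfect_agreement_accuracy_one(self):
        cm = ConfusionMatrix(("a", "b"), np.diag([7, 3]))
        assert h.accuracy(cm) == 1.0

    def test_published_cad_diagonals_give_mac_79_4(self):
        rates = list(h.cad_diagonal_rates().values())
        assert rates == [81.1, 54.8, 80.8, 86.7, 89.7, 83.3]
        assert round(h.mean_class_accuracy(rates), 1) == 79.4

    def test_mac_equals_accuracy_for_equal_class_sizes(self, rng):
        counts = rng.integers(0, 10, size=(3, 3))
        np.fill_diagonal(counts, 10)
        row = counts.sum(axis=1)
        # rescale rows to equal totals by construction: use a doubly-padded
        # diagonal so each row sums to the same value
        n = row.max()
        for i in range(3):
            counts[i, i] += n - row[i]
        cm = ConfusionMatrix(("a", "b", "c"), counts)
        assert h.mean_class_accuracy(cm) == pytest.approx(h.accuracy(cm))

    def test_mac_excludes_and_reports_empty_classes(self):
        cm = ConfusionMatrix(("a", "b", "c"), np.array([[4, 0, 0], [0, 6, 0], [0, 0, 0]]))
        assert h.mean_class_accuracy(cm) == 1.0
        assert excluded_classes(cm) == ["c"]

    @given(count_matrices)
    @settings(max_examples=60, deadline=None)
    def test_accuracy_is_trace_over_n(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        k = counts.shape[0]
        cm = ConfusionMatrix(tuple(f"c{i}" for i in range(k)), counts)
        assert h.accuracy(cm) == pytest.approx(np.trace(counts) / counts.sum())

    @given(count_matrices, st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_mac_invariant_to_reordering_and_scaling(self, counts, perm_seed):
        counts = np.array(counts) + np.eye(len(counts), dtype=int)  # N_k > 0
        k = counts.shape[0]
        classes = tuple(f"c{i}" for i in range(k))
        mac = h.mean_class_accuracy(ConfusionMatrix(classes, counts))
        perm = np.random.default_rng(perm_seed).permutation(k)
        permuted = counts[np.ix_(perm, perm)]
        assert h.mean_class_accuracy(
            ConfusionMatrix(tuple(classes[i] for i in perm), permuted)
        ) == pytest.approx(mac)
        assert h.mean_class_accuracy(
            ConfusionMatrix(classes, counts * 10)
        ) == pytest.approx(mac)


class TestCohensKappa:
    def test_perfect_agreement(self):
        cm = ConfusionMatrix(("a", "b"), np.diag([5, 5]))
        assert h.cohens_kappa(cm) == 1.0

    def test_chance_level_agreement_is_zero(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[25, 25], [25, 25]]))
        assert h.cohens_kappa(cm) == pytest.approx(0.0)

    @given(count_matrices)
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_perfect_iff_diagonal(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        k = counts.shape[0]
        cm = ConfusionMatrix(tuple(f"c{i}" for i in range(k)), counts)
        kappa = h.cohens_kappa(cm)
        assert -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12
        off_diagonal = counts.sum() - np.trace(counts)
        if kappa == 1.0:
            assert off_diagonal == 0

    def test_matches_sklearn_on_random_labels(self, rng):
        a = rng.choice(["x", "y", "z"], 200)
        b = rng.choice(["x", "y", "z"], 200)
        cm = h.confusion_matrix(a, b, ["x", "y", "z"])
        assert h.cohens_kappa(cm) == pytest.approx(cohen_kappa_score(a, b))


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        assert h.mcnemar_test(5, 5).p_value == pytest.approx(1.0)

    def test_exact_binomial_example(self):
        res = h.mcnemar_test(1, 9)
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(22 / 1024)

    def test_no_discordance_convention(self):
        assert h.mcnemar_test(0, 0).p_value == 1.0

    def test_corrected_mode_statistic(self):
        res = h.mcnemar_test(30, 10, mode="corrected")
        assert res.statistic == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)
        assert res.p_value == pytest.approx(sps.chi2.sf(res.statistic, 1))

    def test_exact_matches_full_binomial_enumeration(self):
        """For every (b, c) with b + c <= 20, the exact two-sided p-value
        equals the enumerated binomial(n, 1/2) tail mass of outcomes no
        more likely than the observed one."""
        for n in range(1, 21):
            pmf = [sps.binom.pmf(i, n, 0.5) for i in range(n + 1)]
            for b in range(n + 1):
                expected = sum(p for p in pmf if p <= pmf[b] + 1e-12)
                got = h.mcnemar_test(b, n - b, mode="exact").p_value
                assert got == pytest.approx(min(expected, 1.0), rel=1e-9), (b, n - b)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            h.mcnemar_test(-1, 3)


class TestChiSquare:
    def test_perfect_independence(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[10, 10], [10, 10]]))
        res = h.chi_square_independence(cm)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[20, 0], [0, 20]]))
        res = h.chi_square_independence(cm)
        assert res.statistic == pytest.approx(40.0)
        assert res.df == 1

    def test_empty_rows_dropped_and_reported(self):
        counts = np.array([[10, 2, 0], [3, 12, 0], [0, 0, 0]])
        cm = ConfusionMatrix(("a", "b", "c"), counts)
        res = h.chi_square_independence(cm)
        assert res.dropped_rows == ("c",) and res.dropped_cols == ("c",)
        assert res.df == 1

    def test_single_class_after_dropping_is_error(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[5, 0], [3, 0]]))
        with pytest.raises(ValueError, match="at least 2"):
            h.chi_square_independence(cm)


class TestAgreementReport:
    def test_identical_lists(self):
        labels = ["a", "b"] * 10
        rep = h.agreement_report(labels, labels, ["a", "b"])
        assert rep.observed_agreement == 1.0
        assert rep.kappa == 1.0

    def test_disjoint_labelings_zero_agreement(self):
        a = ["a"] * 10 + ["b"] * 10
        b = ["b"] * 10 + ["a"] * 10
        rep = h.agreement_report(a, b, ["a", "b"])
        assert rep.observed_agreement == 0.0

    def test_reconstructed_fixture_matches_direct_statistics(self, senior_cm):
        labels_a, labels_b = [], []
        for i, ca in enumerate(senior_cm.classes):
            for j, cb in enumerate(senior_cm.classes):
                labels_a += [ca] * senior_cm.counts[i, j]
                labels_b += [cb] * senior_cm.counts[i, j]
        rep = h.agreement_report(labels_a, labels_b, senior_cm.classes)
        assert rep.n == 589
        assert round(100 * rep.observed_agreement) == 71
        assert round(rep.kappa, 2) == 0.64
        assert "kappa" in rep.to_text()


class TestReaderWithCad:
    def test_never_policy_is_identity(self):
        reader = ["a", "b", "a"]
        res = h.reader_with_cad(reader, ["b", "b", "b"], ["a", "b", "b"], policy="never")
        assert res.assisted_labels == reader
        assert res.after == res.before

    def test_always_policy_equals_cad_metrics(self):
        cad = ["b", "b", "a", "a"]
        gold = ["b", "a", "a", "a"]
        res = h.reader_with_cad(["a", "a", "b", "b"], cad, gold, policy="always")
        assert res.assisted_labels == cad
        cm = h.confusion_matrix(gold, cad, ["a", "b"])
        assert res.after["accuracy"] == pytest.approx(h.accuracy(cm))

    def test_confident_cad_improves_weak_reader(self, rng):
        """A 60%-accurate reader assisted by an 85%-accurate CAD under the
        confidence-gated policy cannot get worse, on a 500-well simulation."""
        classes = [p.value for p in h.PATTERNS]
        gold = rng.choice(classes, 500)
        reader = [g if rng.random() < 0.60 else rng.choice(classes) for g in gold]
        cad = [g if rng.random() < 0.85 else rng.choice(classes) for g in gold]
        res = h.reader_with_cad(reader, cad, gold, policy="confidence",
                                cad_confidences=[0.9] * 500)
        assert res.after["accuracy"] >= res.before["accuracy"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            h.reader_with_cad(["a"], ["a", "b"], ["a", "b"])
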