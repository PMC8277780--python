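"""Ordinal core: expected-value scores, QWK metric/loss, auxiliary metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordmil.ordinal import (
    ContractViolation,
    OrdinalLabelSpace,
    accuracy,
    confusion_matrix,
    crc3,
    expected_value_score,
    lesion_sensitivity,
    qwk,
    qwk_loss,
    qwk_loss_grad,
    soft_confusion,
)


def pair_counting_qwk(truth, pred, k):
    """Brute-force oracle: observed disagreement over rating pairs, expected
    disagreement over the full cartesian product of truth x prediction labels."""
    n = len(truth)
    w = lambda i, j: (i - j) ** 2 / (k - 1) ** 2
    observed = sum(w(t, p) for t, p in zip(truth, pred)) / n
    expected = sum(w(t, p) for t in truth for p in pred) / n**2
    return 1.0 - observed / expected


def counts_to_ratings(c):
    truth, pred = [], []
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            truth += [i] * int(c[i, j])
            pred += [j] * int(c[i, j])
    return truth, pred


class TestExpectedValueScore:
    space = crc3()

    @pytest.mark.parametrize(
        "p, expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 2.0), ((0.2, 0.3, 0.5), 1.3), ((0, 1, 0), 1.0)],
    )
    def test_direct_evaluation(self, p, expected):
        assert expected_value_score(p, self.space) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractViolation):
            expected_value_score((0.5, 0.5), self.space)

    def test_off_simplex_rejected(self):
        with pytest.raises(ContractViolation):
            expected_value_score((0.5, 0.2, 0.2), self.space)

    @given(
        p=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        src=st.integers(0, 2),
        dst=st.integers(0, 2),
        frac=st.floats(0.1, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_severity_mass(self, p, src, dst, frac):
        """Moving mass from class i to class j > i strictly increases the score."""
        p = np.array(p) / np.sum(p)
        if src >= dst:
            return
        moved = p.copy()
        delta = frac * p[src]
        moved[src] -= delta
        moved[dst] += delta
        if delta < 1e-9:
            return
        assert expected_value_score(moved, self.space) > expected_value_score(p, self.space)

    def test_custom_class_values(self):
        space = OrdinalLabelSpace(("a", "b", "c"), values=(0.0, 1.0, 4.0))
        assert expected_value_score((0.5, 0.0, 0.5), space) == pytest.approx(2.0)


class TestQwkMetric:
    def test_perfect_agreement(self):
        assert qwk(np.diag([5.0, 5.0, 5.0])) == pytest.approx(1.0)

    def test_two_class_hand_computation(self):
        # observed weighted disagreement 5, expected from marginals 5 -> kappa 0
        assert qwk(np.array([[5.0, 0.0], [5.0, 0.0]])) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.integers(2, 5)
            c = rng.integers(0, 6, size=(k, k)).astype(float)
            truth, pred = counts_to_ratings(c)
            if not truth or len(set(truth)) < 2 or len(set(pred)) < 2:
                continue
            assert qwk(c) == pytest.approx(pair_counting_qwk(truth, pred, k), abs=1e-12)

    def test_matches_sklearn_cohen_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            truth = rng.integers(0, 3, size=40)
            pred = rng.integers(0, 3, size=40)
            c = confusion_matrix(truth, pred, 3)
            assert qwk(c) == pytest.approx(
                cohen_kappa_score(truth, pred, labels=[0, 1, 2], weights="quadratic"),
                abs=1e-10,
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0.1, 5.0, size=(3, 3))
        assert qwk(4.2 * c) == pytest.approx(qwk(c), abs=1e-12)

    def test_quadratic_weight_monotonicity(self):
        """Moving off-diagonal mass farther from the diagonal lowers kappa."""
        near = np.diag([10.0, 10.0, 10.0])
        near[0, 1] = 4.0
        far = np.diag([10.0, 10.0, 10.0])
        far[0, 2] = 4.0
        assert qwk(far) < qwk(near)

    def test_single_cell_diagonal_is_perfect(self):
        c = np.zeros((3, 3))
        c[1, 1] = 8.0
        assert qwk(c) == 1.0

    def test_single_cell_off_diagonal_is_chance(self):
        # all mass at (0, 2): observed equals expected disagreement, kappa 0
        c = np.zeros((3, 3))
        c[0, 2] = 8.0
        assert qwk(c) == pytest.approx(0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ContractViolation):
            qwk(np.zeros((3, 3)))


class TestQwkLoss:
    def test_one_hot_correct_predictions_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2, 1, 0]]
        assert qwk_loss(probs, [0, 1, 2, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_label_independent_predictions_chance_loss(self):
        """Identical predictions across a label-balanced batch give kappa_soft = 0."""
        probs = np.tile([0.2, 0.5, 0.3], (6, 1))
        assert qwk_loss(probs, [0, 0, 1, 1, 2, 2]) == pytest.approx(1.0, abs=1e-12)

    def test_bridge_to_hard_metric(self):
        """On one-hot predictions the loss equals 1 - qwk of the hard confusion."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            truth = rng.integers(0, 3, size=32)
            pred = rng.integers(0, 3, size=32)
            if len(set(truth)) < 2:
                continue
            probs = np.eye(3)[pred]
            hard = confusion_matrix(truth, pred, 3)
            assert qwk_loss(probs, truth) == pytest.approx(1.0 - qwk(hard), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ContractViolation):
            qwk_loss(np.zeros((0, 3)), [])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(3), size=12)
        labels = rng.integers(0, 3, size=12)
        grad = qwk_loss_grad(probs, labels)
        eps = 1e-7
        # the analytic gradient is exact along simplex-preserving (sum-zero)
        # directions, which is all a softmax layer can produce
        for s in range(12):
            v = rng.normal(size=3)
            v -= v.mean()
            bumped = probs.copy()
            bumped[s] += eps * v
            fd = (_raw_loss(bumped, labels) - _raw_loss(probs, labels)) / eps
            assert float(grad[s] @ v) == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_true_class_gradient_nonpositive(self):
        """More mass on the correct class never increases the loss."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            probs = rng.dirichlet(np.ones(3), size=16)
            labels = rng.integers(0, 3, size=16)
            grad = qwk_loss_grad(probs, labels)
            assert np.all(grad[np.arange(16), labels] <= 1e-10)

    def test_log_variant_zero_at_perfect(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert qwk_loss(probs, [0, 1, 2], variant="log") == pytest.approx(0.0, abs=1e-6)


def _raw_loss(probs, labels):
    """Loss as an unconstrained function of the probability table (oracle for grads)."""
    k = probs.shape[1]
    s = np.zeros((k, k))
    np.add.at(s, np.asarray(labels), probs)
    w = np.add.outer(np.arange(k), -np.arange(k)) ** 2 / (k - 1) ** 2
    n = s.sum()
    return (w * s).sum() / ((s.sum(axis=1) @ w @ s.sum(axis=0)) / n)


class TestSoftConfusion:
    def test_accumulates_probability_mass(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        s = soft_confusion(probs, [0, 0, 2], 3)
        np.testing.assert_allclose(s[0], [0.8, 1.0, 0.2])
        np.testing.assert_allclose(s[1], 0.0)
        np.testing.assert_allclose(s[2], [0.2, 0.2, 0.6])

    def test_one_hot_equals_hard_confusion(self):
        truth = [0, 1, 2, 2, 1]
        pred = [0, 2, 2, 1, 1]
        np.testing.assert_array_equal(
            soft_confusion(np.eye(3)[pred], truth, 3), confusion_matrix(truth, pred, 3)
        )


class TestAuxiliaryMetrics:
    space = crc3()

    @pytest.mark.parametrize(
        "truth, pred, expected",
        [((1, 2, 1), (2, 1, 1), 1.0), ((1, 2, 0), (0, 2, 0), 0.5), ((1, 2), (0, 0), 0.0)],
    )
    def test_lesion_sensitivity(self, truth, pred, expected):
        assert lesion_sensitivity(truth, pred, self.space) == pytest.approx(expected)

    def test_lesion_sensitivity_undefined_without_lesions(self):
        with pytest.raises(ContractViolation):
            lesion_sensitivity([0, 0], [1, 0], self.space)

    def test_accuracy(self):
        assert accuracy([0, 1, 2, 1], [0, 2, 2, 1]) == pytest.approx(0.75)


class TestLabelSpace:
    def test_crc_instance(self):
        space = crc3()
        assert space.n_classes == 3
        assert space.values == (0.0, 1.0, 2.0)
        assert space.index_of("high-grade") == 2

    def test_too_few_classes_rejected(self):
        with pytest.raises(ContractViolation):
            OrdinalLabelSpace(("only",))

    def test_non_increasing_values_rejected(self):
        with pytest.raises(ContractViolation):
            OrdinalLabelSpace(("a", "b", "c"), values=(0.0, 2.0, 1.0))
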