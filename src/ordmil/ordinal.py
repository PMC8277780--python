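"""Ordinal label spaces, expected-value tile scoring, and the quadratic
weighted kappa (QWK) in both its metric and differentiable-loss forms.

The diagnostic classes of a grading problem are ordered by severity
(e.g. non-neoplastic < low-grade lesion < high-grade lesion), so a
confusion between distant grades is clinically worse than one between
neighbours.  Two quantities encode that order here:

* the *expected-value score* of a probability vector,
  ``sum_i x_i * p_i``, used to rank tiles by predicted severity, and
* the *quadratic weighted kappa*, chance-corrected agreement with
  penalty ``(i - j)^2 / (K - 1)^2`` for predicting class ``j`` on a
  true class ``i``; ``kappa = 1`` is perfect agreement, ``0`` chance.

The training loss is ``1 - kappa`` evaluated on a *soft* confusion
matrix that accumulates predicted probability mass instead of hard
counts, which makes it differentiable and reduces exactly to the
metric when predictions are one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OrdinalLabelSpace",
    "ContractViolation",
    "expected_value_score",
    "quadratic_weights",
    "confusion_matrix",
    "soft_confusion",
    "qwk",
    "qwk_loss",
    "qwk_loss_grad",
    "accuracy",
    "lesion_sensitivity",
    "METRICS",
]

#: Denominator guard for degenerate confusion matrices (all mass in one cell).
QWK_EPS = 1e-9


class ContractViolation(ValueError):
    """An operation was called with inputs outside its contract."""


@dataclass(frozen=True)
class OrdinalLabelSpace:
    """The K ordered diagnostic classes and their numeric values.

    Parameters
    ----------
    names
        Class names ordered from least to most severe.
    values
        Numeric value ``x_i`` of each class, strictly increasing.
        Defaults to ``0 .. K-1``; non-uniform severity spacings are
        allowed by passing explicit values.
    """

    names: tuple[str, ...]
    values: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ContractViolation("an ordinal label space needs K >= 2 classes")
        if self.values is None:
            object.__setattr__(self, "values", tuple(float(i) for i in range(len(self.names))))
        values = tuple(float(v) for v in self.values)
        if len(values) != len(self.names):
            raise ContractViolation("values must match the number of class names")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ContractViolation("class values must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_classes


def crc3() -> OrdinalLabelSpace:
    """The three-grade colorectal space: non-neoplastic < low-grade < high-grade."""
    return OrdinalLabelSpace(("non-neoplastic", "low-grade", "high-grade"))


def _check_simplex(p: np.ndarray, k: int, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != k:
        raise ContractViolation(f"probability vector has length {p.shape[-1]}, expected {k}")
    if np.any(p < -atol) or np.any(np.abs(p.sum(axis=-1) - 1.0) > atol):
        raise ContractViolation("probabilities must lie on the simplex")
    return p


def expected_value_score(p: Sequence[float], space: OrdinalLabelSpace) -> float:
    """Expected severity ``sum_i x_i * p_i`` of a class-probability vector.

    Lies in ``[x_0, x_{K-1}]``; moving mass to a more severe class
    strictly increases it, which is what makes it a tile-ranking rule.
    """
    p = _check_simplex(np.asarray(p, dtype=float), space.n_classes)
    return float(np.dot(p, np.asarray(space.values)))


def quadratic_weights(k: int) -> np.ndarray:
    """Disagreement weights ``w_ij = (i - j)^2 / (K - 1)^2``."""
    idx = np.arange(k, dtype=float)
    return (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def confusion_matrix(truth: Sequence[int], pred: Sequence[int], k: int) -> np.ndarray:
    """Hard K x K confusion matrix ``C[i, j]`` = count of true i predicted j."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ContractViolation("truth and pred must be equal-length 1-D sequences")
    if truth.size == 0:
        raise ContractViolation("empty label sequences")
    if np.any((truth < 0) | (truth >= k)) or np.any((pred < 0) | (pred >= k)):
        raise ContractViolation(f"labels must lie in [0, {k})")
    c = np.zeros((k, k))
    np.add.at(c, (truth, pred), 1.0)
    return c


def soft_confusion(probs: np.ndarray, labels: Sequence[int], k: int) -> np.ndarray:
    """Soft confusion ``S[i, j]`` = summed probability mass ``p_j`` over samples of true class i."""
    probs = _check_simplex(np.atleast_2d(np.asarray(probs, dtype=float)), k)
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0] or labels.size == 0:
        raise ContractViolation("batch of probabilities and labels must be non-empty and aligned")
    if np.any((labels < 0) | (labels >= k)):
        raise ContractViolation(f"labels must lie in [0, {k})")
    s = np.zeros((k, k))
    np.add.at(s, labels, probs)
    return s


def qwk(c: np.ndarray, eps: float = QWK_EPS) -> float:
    """Quadratic weighted kappa of a (hard or soft) confusion matrix.

    ``kappa = 1 - sum(w * C) / sum(w * E)`` with ``E_ij = row_i col_j / n``
    the chance-agreement matrix from the marginals.  Equals 1 iff C is
    diagonal.  A matrix with all mass in a single cell has zero expected
    disagreement; it is treated as perfect agreement when diagonal and
    rejected otherwise.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
        raise ContractViolation("confusion matrix must be square with K >= 2")
    if np.any(c < 0):
        raise ContractViolation("confusion matrix entries must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ContractViolation("confusion matrix must contain at least one observation")
    w = quadratic_weights(c.shape[0])
    observed = float((w * c).sum())
    expected = float(w @ c.sum(axis=1) @ c.sum(axis=0)) / n
    if expected < eps:
        if observed < eps:
            return 1.0
        raise ContractViolation("zero expected disagreement with non-diagonal observations")
    return 1.0 - observed / expected


def qwk_loss(
    probs: np.ndarray,
    labels: Sequence[int],
    k: int | None = None,
    variant: str = "linear",
    eps: float = QWK_EPS,
) -> float:
    """Differentiable QWK training loss on a batch of predictions.

    Builds the soft confusion matrix of the batch and returns
    ``1 - kappa_soft`` (``variant="linear"``, range [0, 2]) or
    ``-log((1 + kappa_soft)/2 + eps)`` (``variant="log"``).  On one-hot
    predictions the linear form equals ``1 - qwk`` of the hard
    confusion matrix of the same batch.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if k is None:
        k = probs.shape[1]
    s = soft_confusion(probs, labels, k)
    kappa = qwk(s, eps=eps)
    if variant == "linear":
        return 1.0 - kappa
    if variant == "log":
        return float(-np.log((1.0 + kappa) / 2.0 + eps))
    raise ContractViolation(f"unknown qwk_loss variant {variant!r}")


def qwk_loss_grad(
    probs: np.ndarray, labels: Sequence[int], k: int | None = None, variant: str = "linear"
) -> np.ndarray:
    """Analytic gradient of :func:`qwk_loss` w.r.t. each probability.

    With fixed true labels the row marginals of the soft confusion are
    constants, so the loss is a ratio of two affine functions of the
    probabilities; the quotient rule gives the gradient in closed form.

    The gradient is returned in the simplex gauge: the batch mass ``n``
    is treated as constant, which is exact along simplex-preserving
    directions.  Per-sample constant offsets are annihilated by the
    softmax Jacobian, so this is the correct quantity to backpropagate.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if k is None:
        k = probs.shape[1]
    s = soft_confusion(probs, labels, k)
    w = quadratic_weights(k)
    n = s.sum()
    num = float((w * s).sum())
    row = s.sum(axis=1)  # fixed counts per true class
    a = w.T @ row  # a_j = sum_i w_ij row_i
    den = float(a @ s.sum(axis=0)) / n
    den = max(den, QWK_EPS)
    # d(num)/dp_j for a sample with true class y is w[y, j]; d(den)/dp_j = a_j / n
    grad = (w[labels] * den - num * (a[None, :] / n)) / den**2
    if variant == "log":
        kappa = 1.0 - num / den
        grad *= 1.0 / (2.0 * ((1.0 + kappa) / 2.0 + QWK_EPS))
    return grad


def cross_entropy_loss(probs: np.ndarray, labels: Sequence[int], eps: float = 1e-12) -> float:
    """Mean negative log-likelihood; the order-blind baseline loss."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def accuracy(truth: Sequence[int], pred: Sequence[int]) -> float:
    """Fraction of exactly correct predictions."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0 or truth.shape != pred.shape:
        raise ContractViolation("truth and pred must be equal-length non-empty sequences")
    return float(np.mean(truth == pred))


def lesion_sensitivity(
    truth: Sequence[int], pred: Sequence[int], space: OrdinalLabelSpace | None = None
) -> float:
    """Fraction of truly lesional slides (class > 0) predicted as lesional.

    Undefined when no lesional slide is present in the truth; that case
    raises :class:`ContractViolation` rather than returning a number.
    """
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.size == 0 or truth.shape != pred.shape:
        raise ContractViolation("truth and pred must be equal-length non-empty sequences")
    lesional = truth > 0
    if not lesional.any():
        raise ContractViolation("lesion sensitivity is undefined without lesional slides")
    return float(np.mean(pred[lesional] > 0))


def qwk_from_labels(truth: Sequence[int], pred: Sequence[int], k: int) -> float:
    return qwk(confusion_matrix(truth, pred, k))


#: Metric registry keyed by name; each takes (truth, pred, space).
METRICS = {
    "qwk": lambda t, p, space: qwk_from_labels(t, p, space.n_classes),
    "accuracy": lambda t, p, space: accuracy(t, p),
    "lesion_sensitivity": lambda t, p, space: lesion_sensitivity(t, p, space),
}
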