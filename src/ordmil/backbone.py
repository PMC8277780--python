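"""Tile classification backbones.

A backbone maps a fixed-size RGB tile to class probabilities on the
simplex.  The contract is deliberately small — featurise, predict, take
a gradient step — so the MIL engine does not care what sits behind it.

The provided :class:`TextureBackbone` is a compact, CPU-fast model:
a fixed bank of texture statistics (channel means and spreads, edge
density, dark-object fraction, saturation) feeding a one-hidden-layer
softmax network trained with Adam.  Gradients are computed analytically,
including the batch-level quadratic-weighted-kappa loss whose gradient
w.r.t. the probabilities comes from :func:`ordmil.ordinal.qwk_loss_grad`.
On blob-density textures these statistics are sufficient; the class is
also the reference implementation of the contract for anyone plugging
in a heavier convolutional model.

Features are normalised with fixed constants (means/scales chosen for
stained-tissue imagery and recorded on the instance), not batch
statistics, so evaluation-mode predictions are a pure function of the
parameter state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import sobel

from .ordinal import (
    ContractViolation,
    OrdinalLabelSpace,
    cross_entropy_loss,
    qwk_loss,
    qwk_loss_grad,
)

__all__ = ["Backbone", "TextureBackbone", "extract_texture_features", "N_FEATURES"]

N_FEATURES = 10

#: Fixed per-feature normalisation constants (offset, scale); all features are
#: constructed to live roughly in [0, 1] so the identity-ish constants below
#: keep activations well-scaled without data-dependent statistics.
FEATURE_OFFSET = np.full(N_FEATURES, 0.5)
FEATURE_SCALE = np.full(N_FEATURES, 0.25)


def extract_texture_features(image: np.ndarray) -> np.ndarray:
    """Texture statistics of one RGB tile, each scaled to roughly [0, 1].

    The set targets stained-tissue imagery: per-channel means (stain
    colour), grey-level spread (texture contrast), Sobel edge density
    (object boundaries), dark-pixel fractions at two cut-offs (nuclear
    area), and mean saturation (stain presence).
    """
    img = np.asarray(image, dtype=float) / 255.0
    if img.ndim != 3 or img.shape[2] != 3:
        raise ContractViolation("tile image must be H x W x 3")
    grey = rgb2gray(img)
    edges = sobel(grey)
    sat = rgb2hsv(img)[..., 1]
    return np.array(
        [
            img[..., 0].mean(),
            img[..., 1].mean(),
            img[..., 2].mean(),
            grey.std() * 4.0,
            edges.mean() * 8.0,
            float((grey < 0.45).mean()),
            float((grey < 0.60).mean()),
            sat.mean() * 2.0,
            sat.std() * 4.0,
            grey.mean(),
        ]
    )


class Backbone:
    """Contract: trainable map from an RGB tile to class probabilities."""

    space: OrdinalLabelSpace

    def featurize(self, image: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        feats = np.stack([self.featurize(im) for im in images])
        return self.predict_proba_features(feats)

    def train_batch(self, feats: np.ndarray, labels: np.ndarray, loss: str, lr: float, **kw) -> float:
        raise NotImplementedError

    def state_dict(self) -> dict:
        raise NotImplementedError

    def load_state_dict(self, state: dict) -> None:
        raise NotImplementedError


@dataclass
class _AdamState:
    m: dict
    v: dict
    t: int = 0


class TextureBackbone(Backbone):
    """Texture features + one-hidden-layer softmax network (Adam-trained).

    Parameters
    ----------
    space
        Ordinal label space; the output dimension is ``space.n_classes``.
    hidden
        Width of the tanh hidden layer.
    seed
        Seed for the parameter initialisation.
    """

    def __init__(self, space: OrdinalLabelSpace, hidden: int = 16, seed: int = 0):
        self.space = space
        self.hidden = hidden
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = space.n_classes
        self.params = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(N_FEATURES), (N_FEATURES, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, k)),
            "b2": np.zeros(k),
        }
        self._adam = _AdamState(
            m={n: np.zeros_like(p) for n, p in self.params.items()},
            v={n: np.zeros_like(p) for n, p in self.params.items()},
        )

    # -- inference ---------------------------------------------------------

    def featurize(self, image: np.ndarray) -> np.ndarray:
        return (extract_texture_features(image) - FEATURE_OFFSET) / FEATURE_SCALE

    #: Logit bound: keeps the softmax away from exact saturation, where the
    #: QWK loss has a flat constant-prediction plateau with vanishing gradient.
    LOGIT_CLAMP = 10.0

    def _forward(self, feats: np.ndarray):
        z1 = feats @ self.params["W1"] + self.params["b1"]
        h = np.tanh(z1)
        z2 = h @ self.params["W2"] + self.params["b2"]
        z2 = np.clip(z2, -self.LOGIT_CLAMP, self.LOGIT_CLAMP)
        z2 = z2 - z2.max(axis=1, keepdims=True)
        e = np.exp(z2)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, h

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.atleast_2d(feats))
        return probs

    # -- training ----------------------------------------------------------

    def train_batch(
        self,
        feats: np.ndarray,
        labels: np.ndarray,
        loss: str = "qwk",
        lr: float = 1e-4,
        ce_weight: float = 0.5,
        variant: str = "linear",
    ) -> float:
        """One Adam step on a batch; returns the batch loss before the step.

        With ``loss="qwk"`` the objective is the batch soft-kappa loss
        plus ``ce_weight`` times the cross-entropy.  The stabiliser
        matters: kappa is invariant-to-scale and rewards extreme
        prediction marginals, so on its own it admits local optima that
        drop interior classes entirely; a small likelihood term anchors
        each sample to its own label without changing the ordinal
        weighting that dominates the objective.  ``ce_weight=0``
        restores the pure kappa loss.
        """
        feats = np.atleast_2d(feats)
        labels = np.asarray(labels, dtype=int)
        if feats.shape[0] != labels.shape[0] or feats.shape[0] == 0:
            raise ContractViolation("batch features and labels must be non-empty and aligned")
        probs, h = self._forward(feats)
        b, k = probs.shape
        if loss == "qwk":
            value = qwk_loss(probs, labels, k, variant=variant)
            dprobs = qwk_loss_grad(probs, labels, k, variant=variant)
            # softmax Jacobian: dz = p * (g - <g, p>)
            dz2 = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
            if ce_weight > 0:
                value += ce_weight * cross_entropy_loss(probs, labels)
                dce = probs.copy()
                dce[np.arange(b), labels] -= 1.0
                dz2 += ce_weight * dce / b
        elif loss == "cross_entropy":
            value = cross_entropy_loss(probs, labels)
            dz2 = probs.copy()
            dz2[np.arange(b), labels] -= 1.0
            dz2 /= b
        else:
            raise ContractViolation(f"unknown loss {loss!r}")
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite {loss} loss on batch of {b}")
        grads = {
            "W2": h.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dh = dz2 @ self.params["W2"].T
        dz1 = dh * (1.0 - h**2)
        grads["W1"] = feats.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        self._adam_step(grads, lr)
        return float(value)

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        st = self._adam
        st.t += 1
        for name, g in grads.items():
            st.m[name] = beta1 * st.m[name] + (1 - beta1) * g
            st.v[name] = beta2 * st.v[name] + (1 - beta2) * g**2
            mhat = st.m[name] / (1 - beta1**st.t)
            vhat = st.v[name] / (1 - beta2**st.t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "params": copy.deepcopy(self.params),
            "adam": copy.deepcopy({"m": self._adam.m, "v": self._adam.v, "t": self._adam.t}),
            "hidden": self.hidden,
            "seed": self.seed,
            "class_names": list(self.space.names),
        }

    def load_state_dict(self, state: dict) -> None:
        if list(state["class_names"]) != list(self.space.names):
            raise ContractViolation("checkpoint label space does not match the backbone's")
        self.params = copy.deepcopy(state["params"])
        adam = state["adam"]
        self._adam = _AdamState(
            m=copy.deepcopy(adam["m"]), v=copy.deepcopy(adam["v"]), t=adam["t"]
        )

    def clone(self) -> "TextureBackbone":
        twin = TextureBackbone(self.space, hidden=self.hidden, seed=self.seed)
        twin.load_state_dict(self.state_dict())
        return twin


class StubBackbone(Backbone):
    """Deterministic test double: a fixed function of each tile, no training.

    ``rule`` maps an image to a probability vector; by default every
    tile receives the uniform distribution.
    """

    def __init__(self, space: OrdinalLabelSpace, rule=None):
        self.space = space
        k = space.n_classes
        self.rule = rule or (lambda image: np.full(k, 1.0 / k))

    def featurize(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, dtype=float)

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        raise NotImplementedError("stub backbones predict from images directly")

    def predict_proba(self, images) -> np.ndarray:
        return np.stack([np.asarray(self.rule(im), dtype=float) for im in images])

    def train_batch(self, feats, labels, loss="qwk", lr=1e-4, **kw) -> float:
        return 0.0

    def state_dict(self) -> dict:
        return {"class_names": list(self.space.names)}

    def load_state_dict(self, state: dict) -> None:
        pass
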