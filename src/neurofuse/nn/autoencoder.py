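"""Stacked denoising autoencoder with tied weights.

Each layer encodes ``y = sigmoid(W x + b)`` and decodes through the
transposed encoder weights, ``x_hat = sigmoid(W^T y + b')`` — the decoder
weight matrix is tied to the encoder at all times. Layers are pretrained
greedily and unsupervised: the layer's input is corrupted by masking each
entry to zero with probability ``corruption_p``, and the reconstruction of
the *uncorrupted* input is scored by the summed Bernoulli cross-entropy

    L(x, x_hat) = - sum_k [ x_k log x_hat_k + (1 - x_k) log(1 - x_hat_k) ]

averaged over the batch, plus an L2 weight penalty. The next layer trains
on the previous layer's clean codes. Fine-tuning appends a softmax head and
backpropagates label cross-entropy through the whole stack with dropout
(rate ``corruption_p``) active on every layer input during training only.
The intermediate representation of a patient is the top hidden layer's
activation with the softmax head removed and no corruption applied.

Inputs must lie in [0, 1]: the Bernoulli reconstruction likelihood is only
proper on the unit interval, so upstream [1, 2]-coded clinical features and
1/2/3 genotype levels are affinely rescaled before reaching this module
(see ``ehr.to_unit_interval`` / ``snp.to_unit_interval``).

Optimization is Adam with a batch size of 3 by default; everything is
deterministic given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from ._optim import Adam

_EPS = 1e-12


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def bernoulli_cross_entropy(x, x_hat) -> float:
    """Summed-over-dimensions, averaged-over-rows reconstruction loss."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.clip(np.atleast_2d(np.asarray(x_hat, dtype=float)), _EPS, 1 - _EPS)
    per_row = -np.sum(x * np.log(x_hat) + (1 - x) * np.log(1 - x_hat), axis=1)
    return float(per_row.mean())


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_unit_interval(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2D (samples x features) array")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError(
            "autoencoder inputs must lie in [0, 1]; rescale first "
            "(ehr.to_unit_interval / snp.to_unit_interval)"
        )
    return X


class StackedDenoisingAutoencoder(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Greedy layer-wise pretrained denoising autoencoder with softmax head.

    Parameters
    ----------
    layer_sizes : tuple of int, default (200, 100, 50)
        Hidden widths; the last entry is the intermediate-feature width.
    corruption_p : float, default 0.6
        Masking probability during pretraining and dropout rate during
        fine-tuning.
    l2_pretrain, l2_finetune : float
        L2 weight-decay coefficients for the two phases.
    pretrain_epochs, finetune_epochs : int
        Maximum passes over the data per phase (per layer for pretraining).
    """

    def __init__(self, layer_sizes=(200, 100, 50), corruption_p=0.6,
                 l2_pretrain=0.03, l2_finetune=0.03,
                 pretrain_epochs=25, finetune_epochs=25,
                 batch_size=3, learning_rate=1e-3, random_state=0):
        self.layer_sizes = layer_sizes
        self.corruption_p = corruption_p
        self.l2_pretrain = l2_pretrain
        self.l2_finetune = l2_finetune
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _init_layer(self, rng, d_in, d_out):
        limit = np.sqrt(6.0 / (d_in + d_out))
        return {
            "W": rng.uniform(-limit, limit, size=(d_out, d_in)),
            "b": np.zeros(d_out),
            "b_prime": np.zeros(d_in),
        }

    # -- forward pieces ----------------------------------------------------

    def _encode_layer(self, layer, x):
        return _sigmoid(x @ layer["W"].T + layer["b"])

    def _decode_layer(self, layer, y):
        return _sigmoid(y @ layer["W"] + layer["b_prime"])

    def encode(self, X) -> np.ndarray:
        """Compose the encoder stack: sigmoid(W x + b) through every layer."""
        self._require("layers_")
        h = _check_unit_interval(X)
        for layer in self.layers_:
            if h.shape[1] != layer["W"].shape[1]:
                raise ValueError(
                    f"input width {h.shape[1]} does not match layer width "
                    f"{layer['W'].shape[1]}"
                )
            h = self._encode_layer(layer, h)
        return h

    def reconstruct(self, X, layer: int = 0) -> np.ndarray:
        """Encode up to ``layer`` (inclusive) and decode that single layer."""
        self._require("layers_")
        h = _check_unit_interval(X)
        for l in self.layers_[:layer]:
            h = self._encode_layer(l, h)
        lay = self.layers_[layer]
        return self._decode_layer(lay, self._encode_layer(lay, h))

    # -- unsupervised pretraining -----------------------------------------

    def pretrain(self, X):
        """Greedy layer-wise denoising pretraining; returns self."""
        X = _check_unit_interval(X)
        if len(X) < 1:
            raise ValueError("need at least one training sample")
        rng = np.random.default_rng(self.random_state)
        self.layers_ = []
        self.pretrain_curves_ = []
        h = X
        for width in self.layer_sizes:
            layer = self._init_layer(rng, h.shape[1], width)
            curve = self._train_layer(layer, h, rng)
            self.layers_.append(layer)
            self.pretrain_curves_.append(curve)
            h = self._encode_layer(layer, h)  # clean codes feed the next layer
        return self

    def _train_layer(self, layer, H, rng):
        n = len(H)
        opt = Adam([layer["W"], layer["b"], layer["b_prime"]], lr=self.learning_rate)
        curve = [self._layer_loss(layer, H)]
        for _ in range(self.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                xb = H[order[start:start + self.batch_size]]
                corrupted = xb * (rng.random(xb.shape) >= self.corruption_p)
                y = self._encode_layer(layer, corrupted)
                x_hat = np.clip(self._decode_layer(layer, y), _EPS, 1 - _EPS)
                m = len(xb)
                delta2 = (x_hat - xb) / m                      # dL/dz_decode
                dy = delta2 @ layer["W"].T
                delta1 = dy * y * (1.0 - y)                    # dL/dz_encode
                gW = (y.T @ delta2) + (delta1.T @ corrupted) + 2 * self.l2_pretrain * layer["W"]
                gb = delta1.sum(axis=0)
                gbp = delta2.sum(axis=0)
                opt.step([gW, gb, gbp])
            curve.append(self._layer_loss(layer, H))
        return curve

    def _layer_loss(self, layer, H) -> float:
        x_hat = self._decode_layer(layer, self._encode_layer(layer, H))
        return bernoulli_cross_entropy(H, x_hat)

    # -- supervised fine-tuning -------------------------------------------

    def finetune(self, X, y):
        """Append a softmax head and backpropagate through the stack."""
        self._require("layers_")
        X = _check_unit_interval(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("fine-tuning needs at least two classes")
        n_classes = len(self.classes_)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, 1])
        )
        d_top = self.layer_sizes[-1]
        limit = np.sqrt(6.0 / (d_top + n_classes))
        self.softmax_W_ = rng.uniform(-limit, limit, size=(n_classes, d_top))
        self.softmax_b_ = np.zeros(n_classes)

        params = []
        for layer in self.layers_:
            params += [layer["W"], layer["b"]]
        params += [self.softmax_W_, self.softmax_b_]
        opt = Adam(params, lr=self.learning_rate)

        n = len(X)
        p = self.corruption_p
        self.finetune_curve_ = []
        for _ in range(self.finetune_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                m = len(xb)
                # forward with inverted dropout on each hidden activation
                # (the raw input is left intact during fine-tuning; masking
                # noise belongs to the unsupervised pretraining phase)
                acts, masks = [], []
                h = xb
                for li, layer in enumerate(self.layers_):
                    if li == 0:
                        mask = np.ones_like(h)
                    else:
                        mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    masks.append(mask)
                    acts.append(h * mask)
                    h = self._encode_layer(layer, acts[-1])
                    acts.append(h)  # post-activation
                top_mask = (rng.random(h.shape) >= p) / (1.0 - p)
                hd = h * top_mask
                probs = _softmax(hd @ self.softmax_W_.T + self.softmax_b_)
                delta = probs.copy()
                delta[np.arange(m), yb] -= 1.0
                delta /= m

                grads = [None] * len(params)
                grads[-2] = delta.T @ hd + 2 * self.l2_finetune * self.softmax_W_
                grads[-1] = delta.sum(axis=0)
                dh = (delta @ self.softmax_W_) * top_mask
                for li in range(len(self.layers_) - 1, -1, -1):
                    layer = self.layers_[li]
                    h_out = acts[2 * li + 1]
                    h_in = acts[2 * li]
                    dz = dh * h_out * (1.0 - h_out)
                    grads[2 * li] = dz.T @ h_in + 2 * self.l2_finetune * layer["W"]
                    grads[2 * li + 1] = dz.sum(axis=0)
                    if li > 0:
                        dh = (dz @ layer["W"]) * masks[li]
                opt.step(grads)
            self.finetune_curve_.append(self._supervised_loss(X, y_idx))
        return self

    def _supervised_loss(self, X, y_idx) -> float:
        probs = np.clip(self.predict_proba_from_unit(X), _EPS, 1.0)
        return float(-np.mean(np.log(probs[np.arange(len(X)), y_idx])))

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y):
        """Pretrain unsupervised, then fine-tune with the softmax head."""
        self.pretrain(X)
        self.finetune(X, y)
        return self

    def transform(self, X) -> np.ndarray:
        """Intermediate features: top hidden activations, no corruption."""
        return self.encode(X)

    def predict_proba_from_unit(self, X) -> np.ndarray:
        h = self.encode(X)
        return _softmax(h @ self.softmax_W_.T + self.softmax_b_)

    def predict_proba(self, X) -> np.ndarray:
        self._require("softmax_W_")
        return self.predict_proba_from_unit(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def _require(self, attr):
        if not hasattr(self, attr):
            raise RuntimeError(
                f"model is missing {attr!r}; call pretrain/fit first"
            )
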