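"""Multi-region 3D convolutional network for brain-region crops.

Architecture (per patient): each region crop passes through a 3D
convolutional module whose kernels and batch-norm parameters are shared
across all regions, then a region-specific first-level fully connected
layer; the per-region outputs are concatenated and passed through a
second-level fully connected layer and a softmax head trained with
negative log-likelihood.

Per region the default module is: valid 3D convolution (10 kernels of
5x5x5, stride 1) -> max-pool 3x3x3 (stride 3, floor) -> ReLU -> volumetric
batch normalization -> flatten -> fc1 (ReLU) -> dropout. The concatenated
fc1 outputs feed fc2 (ReLU) -> dropout -> softmax. With the default
22x23x18 crop the conv output is 18x19x14 and pooling gives 6x6x4 per
kernel (1440 flattened). A config switch (``layer_order="conventional"``)
reorders the module to conv -> BN -> ReLU -> pool.

The model's intermediate features are the concatenated first-level fully
connected outputs (dropout off): ``n_regions * fc1_width`` wide, 5 x 20 =
100 by default.

Everything is numpy: convolution via im2col, max-pool with recorded argmax
for the backward pass, standard batch-norm backprop, Adam updates, early
stopping on a held-out validation split. Deterministic given
``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from numpy.lib.stride_tricks import sliding_window_view

from ._optim import Adam

_BN_EPS = 1e-5
_DTYPE = np.float64


def conv_output_shape(crop_shape, kernel_shape) -> tuple:
    """Valid convolution, stride 1: out = in - kernel + 1 per axis."""
    out = tuple(c - k + 1 for c, k in zip(crop_shape, kernel_shape))
    if any(d <= 0 for d in out):
        raise ValueError(f"kernel {kernel_shape} does not fit crop {crop_shape}")
    return out


def pool_output_shape(map_shape, pool_shape) -> tuple:
    """Non-overlapping pooling with floor division."""
    out = tuple(m // p for m, p in zip(map_shape, pool_shape))
    if any(d <= 0 for d in out):
        raise ValueError(f"pool {pool_shape} does not fit feature map {map_shape}")
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class RegionCNNClassifier(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Shared-weight per-region 3D CNN with a two-level fully connected head.

    ``fit`` expects ``X`` of shape (n_patients, n_regions, d0, d1, d2) and
    class labels ``y``; ``transform`` returns the concatenated first-level
    fully connected features.
    """

    def __init__(self, n_kernels=10, kernel_shape=(5, 5, 5), pool_shape=(3, 3, 3),
                 fc1_width=20, fc2_width=20, dropout_p=0.5, batch_size=5,
                 learning_rate=1e-3, max_epochs=30, patience=10,
                 val_fraction=0.2, layer_order="methods", random_state=0):
        self.n_kernels = n_kernels
        self.kernel_shape = kernel_shape
        self.pool_shape = pool_shape
        self.fc1_width = fc1_width
        self.fc2_width = fc2_width
        self.dropout_p = dropout_p
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.layer_order = layer_order
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def _init_params(self, rng, n_regions, crop_shape, n_classes):
        if self.layer_order not in ("methods", "conventional"):
            raise ValueError("layer_order must be 'methods' or 'conventional'")
        kshape = tuple(self.kernel_shape)
        kv = int(np.prod(kshape))
        self.conv_shape_ = conv_output_shape(crop_shape, kshape)
        self.pool_shape_out_ = pool_output_shape(self.conv_shape_, self.pool_shape)
        self.flat_width_ = self.n_kernels * int(np.prod(self.pool_shape_out_))
        self.crop_shape_ = tuple(crop_shape)
        self.n_regions_ = n_regions

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)

        self.params_ = {
            "conv_W": glorot((self.n_kernels, kv), kv, self.n_kernels),
            "conv_b": np.zeros(self.n_kernels, dtype=_DTYPE),
            "bn_gamma": np.ones(self.n_kernels, dtype=_DTYPE),
            "bn_beta": np.zeros(self.n_kernels, dtype=_DTYPE),
            "fc1_W": glorot((n_regions, self.fc1_width, self.flat_width_),
                            self.flat_width_, self.fc1_width),
            "fc1_b": np.zeros((n_regions, self.fc1_width), dtype=_DTYPE),
            "fc2_W": glorot((self.fc2_width, n_regions * self.fc1_width),
                            n_regions * self.fc1_width, self.fc2_width),
            "fc2_b": np.zeros(self.fc2_width, dtype=_DTYPE),
            "out_W": glorot((n_classes, self.fc2_width), self.fc2_width, n_classes),
            "out_b": np.zeros(n_classes, dtype=_DTYPE),
        }
        self.bn_running_mean_ = np.zeros(self.n_kernels, dtype=_DTYPE)
        self.bn_running_var_ = np.ones(self.n_kernels, dtype=_DTYPE)

    # -- layer forward/backward pieces ------------------------------------

    def _conv_forward(self, vols):
        """vols: (m, d0, d1, d2) -> maps (m, K, c0, c1, c2) plus im2col cache."""
        kshape = tuple(self.kernel_shape)
        win = sliding_window_view(vols, kshape, axis=(1, 2, 3))
        m = vols.shape[0]
        cols = win.reshape(m, int(np.prod(self.conv_shape_)), int(np.prod(kshape)))
        out = cols @ self.params_["conv_W"].T + self.params_["conv_b"]
        maps = out.transpose(0, 2, 1).reshape((m, self.n_kernels) + self.conv_shape_)
        return maps, cols

    def _conv_backward(self, dmaps, cols):
        m = dmaps.shape[0]
        dout = dmaps.reshape(m, self.n_kernels, -1).transpose(0, 2, 1)
        dW = np.einsum("mpk,mpv->kv", dout, cols)
        db = dout.sum(axis=(0, 1))
        return dW, db

    def _pool_forward(self, maps):
        p0, p1, p2 = self.pool_shape
        o0, o1, o2 = self.pool_shape_out_
        m, k = maps.shape[:2]
        trimmed = maps[:, :, : o0 * p0, : o1 * p1, : o2 * p2]
        windows = trimmed.reshape(m, k, o0, p0, o1, p1, o2, p2)
        windows = windows.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            m, k, o0, o1, o2, p0 * p1 * p2
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        return out, idx

    def _pool_backward(self, dout, idx):
        p0, p1, p2 = self.pool_shape
        o0, o1, o2 = self.pool_shape_out_
        m, k = dout.shape[:2]
        dwin = np.zeros((m, k, o0, o1, o2, p0 * p1 * p2), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(m, k, o0, o1, o2, p0, p1, p2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        ).reshape(m, k, o0 * p0, o1 * p1, o2 * p2)
        dmaps = np.zeros((m, k) + self.conv_shape_, dtype=dout.dtype)
        dmaps[:, :, : o0 * p0, : o1 * p1, : o2 * p2] = dwin
        return dmaps

    def _bn_forward(self, x, training):
        axes = (0, 2, 3, 4)
        gamma = self.params_["bn_gamma"][None, :, None, None, None]
        beta = self.params_["bn_beta"][None, :, None, None, None]
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.bn_running_mean_ = 0.9 * self.bn_running_mean_ + 0.1 * mean
            self.bn_running_var_ = 0.9 * self.bn_running_var_ + 0.1 * var
        else:
            mean, var = self.bn_running_mean_, self.bn_running_var_
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        return x_hat * gamma + beta, (x_hat, inv)

    def _bn_backward(self, dout, cache):
        x_hat, inv = cache
        axes = (0, 2, 3, 4)
        dgamma = (dout * x_hat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        gamma = self.params_["bn_gamma"][None, :, None, None, None]
        dxhat = dout * gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - x_hat * (dxhat * x_hat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None, None]
        return dx, dgamma, dbeta

    # -- full network ------------------------------------------------------

    def _forward(self, X, training, rng=None):
        """X: (n, R, d0, d1, d2). Returns probs plus caches for backward."""
        n, R = X.shape[:2]
        vols = X.reshape((n * R,) + X.shape[2:]).astype(_DTYPE)
        maps, cols = self._conv_forward(vols)

        if self.layer_order == "methods":
            pooled, pool_idx = self._pool_forward(maps)
            relu_in = pooled
            relu_out = np.maximum(relu_in, 0.0)
            bn_out, bn_cache = self._bn_forward(relu_out, training)
            flat_src = bn_out
        else:  # conventional: conv -> BN -> ReLU -> pool
            bn_out, bn_cache = self._bn_forward(maps, training)
            relu_in = bn_out
            relu_out = np.maximum(relu_in, 0.0)
            pooled, pool_idx = self._pool_forward(relu_out)
            flat_src = pooled

        flat = flat_src.reshape(n, R, self.flat_width_)
        z1 = np.einsum("nrf,rhf->nrh", flat, self.params_["fc1_W"]) + self.params_["fc1_b"]
        h1 = np.maximum(z1, 0.0)
        if training:
            m1 = (rng.random(h1.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
        else:
            m1 = np.ones_like(h1)
        h1d = h1 * m1
        concat = h1d.reshape(n, R * self.fc1_width)
        z2 = concat @ self.params_["fc2_W"].T + self.params_["fc2_b"]
        h2 = np.maximum(z2, 0.0)
        if training:
            m2 = (rng.random(h2.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
        else:
            m2 = np.ones_like(h2)
        h2d = h2 * m2
        probs = _softmax(h2d @ self.params_["out_W"].T + self.params_["out_b"])
        cache = dict(cols=cols, pool_idx=pool_idx, relu_in=relu_in,
                     bn_cache=bn_cache, flat=flat, z1=z1, m1=m1, h1d=h1d,
                     concat=concat, z2=z2, m2=m2, h2d=h2d, n=n, R=R)
        return probs, cache

    def _backward(self, probs, y_idx, cache):
        p = self.params_
        n, R = cache["n"], cache["R"]
        delta = probs.copy()
        delta[np.arange(n), y_idx] -= 1.0
        delta /= n

        g = {}
        g["out_W"] = delta.T @ cache["h2d"]
        g["out_b"] = delta.sum(axis=0)
        dh2 = (delta @ p["out_W"]) * cache["m2"]
        dz2 = dh2 * (cache["z2"] > 0)
        g["fc2_W"] = dz2.T @ cache["concat"]
        g["fc2_b"] = dz2.sum(axis=0)
        dconcat = (dz2 @ p["fc2_W"]).reshape(n, R, self.fc1_width)
        dh1 = dconcat * cache["m1"]
        dz1 = dh1 * (cache["z1"] > 0)
        g["fc1_W"] = np.einsum("nrh,nrf->rhf", dz1, cache["flat"])
        g["fc1_b"] = dz1.sum(axis=0)
        dflat = np.einsum("nrh,rhf->nrf", dz1, p["fc1_W"]).reshape(
            n * R, self.n_kernels, *self.pool_shape_out_
        )

        if self.layer_order == "methods":
            dbn, g["bn_gamma"], g["bn_beta"] = self._bn_backward(dflat, cache["bn_cache"])
            drelu = dbn * (cache["relu_in"] > 0)
            dmaps = self._pool_backward(drelu, cache["pool_idx"])
        else:
            dpool = self._pool_backward(dflat, cache["pool_idx"])
            drelu = dpool * (cache["relu_in"] > 0)
            dmaps, g["bn_gamma"], g["bn_beta"] = self._bn_backward(drelu, cache["bn_cache"])

        g["conv_W"], g["conv_b"] = self._conv_backward(dmaps, cache["cols"])
        return g

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=_DTYPE)
        y = np.asarray(y)
        if X.ndim != 5:
            raise ValueError(
                "expected X of shape (n_patients, n_regions, d0, d1, d2), "
                f"got {X.shape}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if len(X) < self.batch_size:
            raise ValueError(
                f"need at least one batch ({self.batch_size} samples), got {len(X)}"
            )
        rng = np.random.default_rng(self.random_state)
        self._init_params(rng, X.shape[1], X.shape[2:], len(self.classes_))

        # stratified validation split for early stopping
        val_mask = np.zeros(len(X), dtype=bool)
        for c in range(len(self.classes_)):
            members = np.flatnonzero(y_idx == c)
            rng.shuffle(members)
            n_val = max(1, int(round(self.val_fraction * len(members))))
            val_mask[members[:n_val]] = True
        Xtr, ytr = X[~val_mask], y_idx[~val_mask]
        Xval, yval = X[val_mask], y_idx[val_mask]

        order_keys = sorted(self.params_)
        opt = Adam([self.params_[k] for k in order_keys], lr=self.learning_rate)
        best = (-np.inf, None, None, None)
        patience_left = self.patience
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                probs, cache = self._forward(Xtr[idx], training=True, rng=rng)
                grads = self._backward(probs, ytr[idx], cache)
                opt.step([grads[k] for k in order_keys])
            val_acc = float(np.mean(self._predict_idx(Xval) == yval))
            self.history_.append({"epoch": epoch, "val_accuracy": val_acc})
            if val_acc > best[0]:
                best = (val_acc,
                        {k: v.copy() for k, v in self.params_.items()},
                        self.bn_running_mean_.copy(), self.bn_running_var_.copy())
                patience_left = self.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best[1] is not None:
            self.params_ = best[1]
            self.bn_running_mean_, self.bn_running_var_ = best[2], best[3]
        self.validation_accuracy_ = best[0]
        return self

    # -- inference ---------------------------------------------------------

    def _predict_idx(self, X):
        probs, _ = self._forward(np.asarray(X, dtype=_DTYPE), training=False)
        return np.argmax(probs, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        self._require()
        probs, _ = self._forward(np.asarray(X, dtype=_DTYPE), training=False)
        return probs

    def predict(self, X) -> np.ndarray:
        self._require()
        return self.classes_[self._predict_idx(X)]

    def transform(self, X) -> np.ndarray:
        """Intermediate features: concatenated fc1 outputs, dropout off."""
        self._require()
        X = np.asarray(X, dtype=_DTYPE)
        n, R = X.shape[:2]
        _, cache = self._forward(X, training=False)
        h1 = np.maximum(cache["z1"], 0.0)
        return h1.reshape(n, R * self.fc1_width)

    def _require(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
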