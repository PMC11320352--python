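"""A small, dependency-free convolutional network trained with Adam.

This is the ``tiny`` backbone of the classifier ensemble: two 3x3 conv
blocks followed by a dense 2-class softmax head, implemented directly on
numpy with im2col convolutions and manual backpropagation.  It trains in
seconds on a CPU, is deterministic under a fixed seed, and exposes the
gradients of class logits with respect to the last conv activations,
which is what Grad-CAM needs.

Input images are expected in [0, 1]; they are average-pooled from
224 x 224 down to ``pooled_size`` (default 28) and centered before the
first convolution — at that scale the planted cohort signal (a smooth
color shift over face regions) is fully preserved while training stays
fast.  The head is dense over the 14 x 14 x C2 feature map rather than
globally pooled: spatially localized class evidence then reaches the
logits at full strength, which matters at the small sample sizes this
backbone is built for.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W), zero-padded by 1 -> (B, C*9, H*W) patches for 3x3 conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * 9, H * W)


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B, C, H, Wd = x.shape
    F = W.shape[0]
    cols = _im2col(x)
    out = (W.reshape(F, -1) @ cols).reshape(B, F, H, Wd)
    return out + b[None, :, None, None], cols


def _conv3x3_backward(dy: np.ndarray, cols: np.ndarray, x_shape, W: np.ndarray):
    B, C, H, Wd = x_shape
    F = W.shape[0]
    dyf = dy.reshape(B, F, H * Wd)
    dW = np.einsum("bkp,bfp->fk", cols, dyf).reshape(W.shape)
    db = dyf.sum(axis=(0, 2))
    # grad wrt input of a stride-1 'same' 3x3 conv == 'same' conv of dy with
    # channel-swapped, 180-degree-flipped kernels
    Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = _conv3x3(dy, Wt, np.zeros(C))
    return dx, dW, db


class TinyConvNet:
    """conv(3x3) -> ReLU -> maxpool2 -> conv(3x3) -> ReLU -> flatten -> dense(2)."""

    def __init__(
        self,
        in_channels: int = 3,
        conv_channels: tuple[int, int] = (8, 16),
        pooled_size: int = 28,
        n_classes: int = 2,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.pooled_size = pooled_size
        c1, c2 = conv_channels
        h2 = pooled_size // 2
        self._feat_shape = (c2, h2, h2)
        rng = np.random.default_rng(seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W1": he(in_channels * 9, (c1, in_channels, 3, 3)),
            "b1": np.zeros(c1),
            "W2": he(c1 * 9, (c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "Wf": he(c2 * h2 * h2, (c2 * h2 * h2, n_classes)),
            "bf": np.zeros(n_classes),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- data plumbing ------------------------------------------------------

    def pool_input(self, X: np.ndarray) -> np.ndarray:
        """(B,C,H,W) -> (B,C,p,p) by average pooling; identity if already p."""
        B, C, H, W = X.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        p = self.pooled_size
        if (H, W) == (p, p):
            return X.astype(np.float64, copy=False)
        if H % p or W % p:
            raise ValueError(f"input size {H}x{W} not divisible by pooled size {p}")
        return X.reshape(B, C, p, H // p, p, W // p).mean(axis=(3, 5))

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray):
        P = self.params
        x = x - 0.5  # center [0,1] inputs
        z1, cols1 = _conv3x3(x, P["W1"], P["b1"])
        a1 = np.maximum(z1, 0.0)
        B, C1, H, W = a1.shape
        a1r = a1.reshape(B, C1, H // 2, 2, W // 2, 2)
        pooled = a1r.max(axis=(3, 5))
        z2, cols2 = _conv3x3(pooled, P["W2"], P["b2"])
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(B, -1)
        logits = flat @ P["Wf"] + P["bf"]
        cache = (x, cols1, z1, a1r, pooled, cols2, z2, a2, flat)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache):
        P = self.params
        x, cols1, z1, a1r, pooled, cols2, z2, a2, flat = cache
        B = len(flat)
        grads = {"Wf": flat.T @ dlogits, "bf": dlogits.sum(axis=0)}
        da2 = (dlogits @ P["Wf"].T).reshape(a2.shape)
        dz2 = np.where(z2 > 0, da2, 0.0)
        dpooled, grads["W2"], grads["b2"] = _conv3x3_backward(dz2, cols2, pooled.shape, P["W2"])
        # maxpool backward: route gradient to the argmax within each 2x2 block
        up = np.repeat(np.repeat(pooled, 2, axis=2), 2, axis=3)
        a1 = a1r.reshape(B, a1r.shape[1], up.shape[2], up.shape[3])
        dup = np.repeat(np.repeat(dpooled, 2, axis=2), 2, axis=3)
        da1 = np.where(a1 == up, dup, 0.0)
        dz1 = np.where(z1 > 0, da1, 0.0)
        _, grads["W1"], grads["b1"] = _conv3x3_backward(dz1, cols1, x.shape, P["W1"])
        return grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 5,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        seed: int = 0,
    ) -> list[float]:
        """Minimize softmax cross-entropy; returns the per-epoch mean loss."""
        Xp = self.pool_input(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        n = len(Xp)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                ix = order[start : start + batch_size]
                xb, yb = Xp[ix], y[ix]
                logits, cache = self._forward(xb)
                logits = logits - logits.max(axis=1, keepdims=True)
                expl = np.exp(logits)
                probs = expl / expl.sum(axis=1, keepdims=True)
                losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))))
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._backward(dlogits, cache)
                self._adam_step(grads, learning_rate)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        Xp = self.pool_input(np.asarray(X, dtype=np.float64))
        out = []
        for start in range(0, len(Xp), batch_size):
            logits, _ = self._forward(Xp[start : start + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            out.append(expl / expl.sum(axis=1, keepdims=True))
        return np.vstack(out)

    def gradcam(self, X: np.ndarray, class_index: int = 1) -> np.ndarray:
        """Gradient-weighted class activation maps at the last conv layer.

        Returns (B, h, w) nonnegative maps at conv resolution; the caller
        upsamples to image size.  The gradient target is the class score
        after softmax — for this two-class head that is the logit contrast
        (class minus rival) up to a positive per-sample factor, so the map
        reflects the full discriminative evidence.  Channel weights are
        the spatial means of the gradient; negative evidence is rectified
        away.
        """
        Xp = self.pool_input(np.asarray(X, dtype=np.float64))
        _, cache = self._forward(Xp)
        z2, a2 = cache[6], cache[7]
        B = len(a2)
        Wf = self.params["Wf"]
        if Wf.shape[1] == 2:
            w_col = (Wf[:, class_index] - Wf[:, 1 - class_index]).reshape(self._feat_shape)
        else:
            w_col = Wf[:, class_index].reshape(self._feat_shape)
        da2 = np.where(z2 > 0, 1.0, 0.0) * w_col[None]
        alpha = da2.mean(axis=(2, 3))  # (B, C2)
        cam = np.einsum("bc,bchw->bhw", alpha, a2)
        return np.maximum(cam, 0.0)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = dict(in_channels=self.in_channels, pooled_size=self.pooled_size)
        np.savez(path, _meta=np.array(list(meta.items()), dtype=object), **self.params)

    @classmethod
    def load(cls, path: str) -> "TinyConvNet":
        data = np.load(path, allow_pickle=True)
        meta = dict(data["_meta"])
        net = cls(
            in_channels=int(meta["in_channels"]),
            conv_channels=(data["W1"].shape[0], data["W2"].shape[0]),
            pooled_size=int(meta["pooled_size"]),
            n_classes=data["bf"].shape[0],
        )
        for k in net.params:
            net.params[k] = data[k]
        return net
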