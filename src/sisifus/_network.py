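"""Minimal convolutional patch regressor (pure numpy).

Maps a p×p×2 normalised intensity patch to a scalar central-pixel lifetime.
Architecture: three 3×3 valid convolutions (channels 16 → 32 → 64) with
ReLU, then three fully connected layers (128 → 32 → 1), linear output.
Trained with Adam on mean absolute error.  Convolutions run as im2col +
matmul; gradients are written out by hand so the whole regressor stays
dependency-free and bit-deterministic for a fixed seed in single-threaded
mode.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

CONV_CHANNELS = (16, 32, 64)
FC_WIDTHS = (128, 32)
KERNEL = 3


def _im2col(x: np.ndarray, k: int = KERNEL) -> np.ndarray:
    """(B, H, W, C) -> (B, Ho, Wo, k*k*C) patches for a valid convolution."""
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (B, Ho, Wo, k, k, C)
    B, Ho, Wo = v.shape[:3]
    return np.ascontiguousarray(v).reshape(B, Ho, Wo, k * k * x.shape[3])


def _col2im(dcols: np.ndarray, x_shape: Tuple[int, ...], k: int = KERNEL) -> np.ndarray:
    """Adjoint of _im2col: scatter-add column gradients back onto the input."""
    B, H, W, C = x_shape
    Ho, Wo = H - k + 1, W - k + 1
    d = dcols.reshape(B, Ho, Wo, k, k, C)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dx[:, di : di + Ho, dj : dj + Wo, :] += d[:, :, :, di, dj, :]
    return dx


class PatchRegressor:
    """3-conv + 3-FC network from patches (B, p, p, 2) to lifetimes (B,)."""

    def __init__(self, patch: int = 13, in_channels: int = 2, seed: int = 0) -> None:
        self.patch = patch
        rng = np.random.default_rng(seed)
        self.params: Dict[str, np.ndarray] = {}
        c_in = in_channels
        side = patch
        for li, c_out in enumerate(CONV_CHANNELS):
            fan_in = KERNEL * KERNEL * c_in
            self.params[f"Wc{li}"] = (
                rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"bc{li}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
            side -= KERNEL - 1
        flat = side * side * c_in
        widths = [flat, *FC_WIDTHS, 1]
        for li in range(3):
            fan_in = widths[li]
            self.params[f"Wf{li}"] = (
                rng.standard_normal((fan_in, widths[li + 1])) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"bf{li}"] = np.zeros(widths[li + 1], dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        # regression targets are standardised internally so the output layer
        # does not spend epochs learning the label offset and scale
        self._label_mu = 0.0
        self._label_sd = 1.0
        self.history: Dict[str, List[float]] = {"train_mae": [], "val_mae": []}

    # ----- forward / backward -------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        acts = {"a0": x.astype(np.float32, copy=False)}
        a = acts["a0"]
        for li in range(3):
            cols = _im2col(a)
            z = cols @ self.params[f"Wc{li}"] + self.params[f"bc{li}"]
            a = np.maximum(z, 0.0)
            if cache:
                acts[f"cols{li}"] = cols
                acts[f"z{li}"] = z
                acts[f"a{li + 1}"] = a
        B = a.shape[0]
        f = a.reshape(B, -1)
        if cache:
            acts["flat"] = f
        for li in range(3):
            z = f @ self.params[f"Wf{li}"] + self.params[f"bf{li}"]
            f = np.maximum(z, 0.0) if li < 2 else z
            if cache:
                acts[f"fz{li}"] = z
                acts[f"fa{li}"] = f
        pred = f[:, 0]
        return (pred, acts) if cache else pred

    def _backward(self, acts: dict, dpred: np.ndarray) -> Dict[str, np.ndarray]:
        grads: Dict[str, np.ndarray] = {}
        g = dpred[:, None].astype(np.float32)
        for li in (2, 1, 0):
            inp = acts["flat"] if li == 0 else acts[f"fa{li - 1}"]
            grads[f"Wf{li}"] = inp.T @ g
            grads[f"bf{li}"] = g.sum(axis=0)
            g = g @ self.params[f"Wf{li}"].T
            if li > 0:
                g = g * (acts[f"fz{li - 1}"] > 0)
        g = g.reshape(acts["a3"].shape)
        for li in (2, 1, 0):
            g = g * (acts[f"z{li}"] > 0)
            cols = acts[f"cols{li}"]
            B, Ho, Wo, kk = cols.shape
            c_out = g.shape[-1]
            grads[f"Wc{li}"] = cols.reshape(-1, kk).T @ g.reshape(-1, c_out)
            grads[f"bc{li}"] = g.reshape(-1, c_out).sum(axis=0)
            dcols = (g @ self.params[f"Wc{li}"].T).reshape(B, Ho, Wo, kk)
            g = _col2im(dcols, acts[f"a{li}"].shape if li > 0 else acts["a0"].shape)
        return grads

    def _adam_step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # ----- public API ----------------------------------------------------
    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int = 150,
        batch: int = 100,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> Dict[str, List[float]]:
        """Train with Adam on mean absolute error; records per-epoch history."""
        rng = np.random.default_rng(seed)
        X_train = X_train.astype(np.float32, copy=False)
        self._label_mu = float(np.mean(y_train))
        self._label_sd = float(np.std(y_train)) or 1.0
        y_train = ((y_train - self._label_mu) / self._label_sd).astype(np.float32)
        K = X_train.shape[0]
        for _ in range(epochs):
            perm = rng.permutation(K)
            epoch_abs = 0.0
            for s in range(0, K, batch):
                idx = perm[s : s + batch]
                xb, yb = X_train[idx], y_train[idx]
                pred, acts = self._forward(xb, cache=True)
                err = pred - yb
                epoch_abs += float(np.abs(err).sum())
                dpred = np.sign(err) / err.size
                grads = self._backward(acts, dpred)
                self._adam_step(grads, lr)
            train_mae = epoch_abs / K * self._label_sd
            val_mae = float(np.mean(np.abs(self.predict(X_val) - y_val)))
            if not (np.isfinite(train_mae) and np.isfinite(val_mae)):
                raise FloatingPointError(f"training diverged (seed {seed})")
            self.history["train_mae"].append(train_mae)
            self.history["val_mae"].append(val_mae)
        return self.history

    def predict(self, X: np.ndarray, chunk: int = 2048) -> np.ndarray:
        X = X.astype(np.float32, copy=False)
        out = np.empty(X.shape[0], dtype=np.float64)
        for s in range(0, X.shape[0], chunk):
            out[s : s + chunk] = self._forward(X[s : s + chunk])
        return out * self._label_sd + self._label_mu

    @property
    def final_val_mae(self) -> float:
        if not self.history["val_mae"]:
            raise RuntimeError("network has not been trained")
        return self.history["val_mae"][-1]
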