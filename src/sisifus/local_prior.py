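"""Local prior: per-window intensity-to-lifetime regression.

Within a small neighbourhood of a sample, fluorophore concentration varies
slowly, so lifetime is often a simple function of intensity locally even
when no global relation exists.  For every low-resolution sample ``(i, j)``
a w×w window of (intensity, lifetime) pairs — intensity read at the
corresponding high-resolution sample positions — is fitted with a scalar
function f, and f is evaluated at every high-resolution intensity pixel of
the λ×λ block anchored at ``(i, j)``:

    tau_hat[λi+x, λj+y] = f_ij(I[λi+x, λj+y]),   0 <= x, y < λ.

Sliding the window one sample at a time tiles the high-resolution grid
exactly once.  Windows are clamped (shifted) at the borders so edge blocks
still see w² samples.  Duplicate intensities are averaged before fitting;
evaluation outside the sampled intensity range clamps to the nearest
sampled lifetime, which keeps predictions inside the window's lifetime
range and stops noise amplification at extreme intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, Tuple

import numpy as np

from .core import IntensityImage, LifetimeImage, SamplingSpec
from .priors import PriorImage

__all__ = ["LocalPriorConfig", "fit_window_function", "build_local_prior"]

FUNCTION_KINDS = ("linear_interp", "nearest", "cubic_spline", "rbf_gp")


@dataclass
class LocalPriorConfig:
    """Window size (in low-res samples, odd, 3..9) and local function family."""

    window: int = 5
    function_kind: str = "linear_interp"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or not (3 <= self.window <= 9):
            raise ValueError("window must be odd and within [3, 9]")
        if self.function_kind not in FUNCTION_KINDS:
            raise ValueError(f"unknown function kind {self.function_kind!r}")


def _dedupe(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sort by intensity and average lifetimes at duplicate intensities."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    xu, inv = np.unique(x, return_inverse=True)
    ysum = np.bincount(inv, weights=y)
    cnt = np.bincount(inv)
    return xu, ysum / cnt


def fit_window_function(
    pairs: Iterable[Tuple[float, float]] | Sequence[Tuple[float, float]],
    kind: str = "linear_interp",
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit a scalar intensity→lifetime map from (intensity, lifetime) pairs.

    Interpolates the (deduplicated) pairs and clamps outside the sampled
    intensity range.  With all intensities identical the constant map at
    the mean lifetime is returned (degenerate-window fallback).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one (intensity, lifetime) pair")
    x, y = _dedupe(arr[:, 0], arr[:, 1])

    if x.size == 1:
        c = float(y[0]) if x.size == 1 else float(np.mean(y))
        return lambda q: np.full_like(np.asarray(q, dtype=float), c)

    if kind == "linear_interp":
        return lambda q: np.interp(np.asarray(q, dtype=float), x, y)
    if kind == "nearest":
        # ties resolved toward the lower intensity
        edges = 0.5 * (x[:-1] + x[1:])

        def f_nearest(q: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(edges, np.asarray(q, dtype=float), side="left")
            return y[idx]

        return f_nearest
    if kind == "cubic_spline":
        from scipy.interpolate import CubicSpline

        if x.size < 4:
            return lambda q: np.interp(np.asarray(q, dtype=float), x, y)
        cs = CubicSpline(x, y)
        lo, hi = x[0], x[-1]
        return lambda q: cs(np.clip(np.asarray(q, dtype=float), lo, hi))
    if kind == "rbf_gp":
        from scipy.interpolate import RBFInterpolator

        rbf = RBFInterpolator(x[:, None], y, kernel="thin_plate_spline", smoothing=1e-10)
        lo, hi = x[0], x[-1]
        return lambda q: rbf(np.clip(np.asarray(q, dtype=float), lo, hi).reshape(-1, 1)).reshape(
            np.asarray(q).shape
        )
    raise ValueError(f"unknown function kind {kind!r}")


def build_local_prior(
    tau_lr: LifetimeImage,
    intensity_hr: IntensityImage,
    spec: SamplingSpec,
    cfg: LocalPriorConfig | None = None,
) -> PriorImage:
    """Slide a w×w sample window across the grid and predict each λ×λ block."""
    cfg = cfg or LocalPriorConfig()
    m, n = tau_lr.shape
    M, N = intensity_hr.shape
    if spec.lr_shape((M, N)) != (m, n):
        raise ValueError("intensity and lifetime shapes inconsistent with sampling spec")

    lam = spec.factor
    I = intensity_hr.values
    sample_I = I[spec.offset[0] :: lam, spec.offset[1] :: lam]

    w = cfg.window
    h = w // 2
    values = np.zeros((M, N))
    valid = np.zeros((M, N), dtype=bool)

    for i in range(m):
        r0 = int(np.clip(i - h, 0, max(m - w, 0)))
        r1 = min(r0 + w, m)
        for j in range(n):
            c0 = int(np.clip(j - h, 0, max(n - w, 0)))
            c1 = min(c0 + w, n)
            vmask = tau_lr.valid[r0:r1, c0:c1]
            block = np.s_[lam * i : lam * (i + 1), lam * j : lam * (j + 1)]
            if not vmask.any():
                continue  # block stays invalid
            xs = sample_I[r0:r1, c0:c1][vmask].ravel()
            ys = tau_lr.tau[r0:r1, c0:c1][vmask].ravel()
            f = fit_window_function(np.column_stack([xs, ys]), cfg.function_kind)
            values[block] = f(I[block])
            valid[block] = True

    return PriorImage(values=values, valid=valid)
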