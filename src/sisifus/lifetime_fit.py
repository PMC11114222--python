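"""Per-pixel fluorescence lifetime estimation from arrival-time histograms.

Each pixel of a time-resolved datacube holds a photon arrival-time
histogram.  Under mono-exponential kinetics the expected histogram is

    h_k = a * exp(-t_k / tau) + b,      t_k = k * bin_width,

optionally convolved with the instrument response function (IRF).  The
lifetime ``tau`` is recovered by nonlinear least squares with an analytic
initial guess: the background from the histogram tail, then a log-linear
regression on the background-subtracted decay.  Without an IRF, bins
before the histogram peak are excluded (they carry rise, not decay).

Residuals are scaled by the model's Poisson standard deviation (Pearson
weighting): unweighted least squares on photon-counting data lets the
bounded background term absorb tail counts and biases tau low by several
percent at ~10³ photons, while model-based weighting keeps the bias well
below 1% at 10⁴ photons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import FLIMDataCube, IntensityImage, LifetimeImage

__all__ = ["DecayFitResult", "EmptySignalError", "fit_monoexponential", "fit_image"]

TAU_MIN = 0.01  # ns
TAU_MAX = 100.0  # ns


class EmptySignalError(ValueError):
    """Histogram carries no photons."""


@dataclass
class DecayFitResult:
    tau: float  # ns
    amplitude: float  # photons/bin
    background: float  # photons/bin
    residual_norm: float
    ok: bool = True  # False when no decaying component was found


def _model(params: np.ndarray, t: np.ndarray, irf: Optional[np.ndarray]) -> np.ndarray:
    tau, a, b = params
    decay = np.exp(-t / tau)
    if irf is not None:
        decay = np.convolve(decay, irf)[: t.size]
    return a * decay + b


def _initial_guess(h: np.ndarray, t: np.ndarray) -> Tuple[float, float, float]:
    n = h.size
    b0 = float(np.mean(h[-max(2, n // 10) :]))
    sig = h - b0
    peak = int(np.argmax(h))
    # log-linear regression over the decaying, above-background stretch
    idx = np.arange(peak, n)
    pos = sig[idx] > max(1e-12, 0.05 * max(sig.max(), 1e-12))
    idx = idx[pos]
    if idx.size >= 2:
        slope, _ = np.polyfit(t[idx], np.log(sig[idx]), 1)
        tau0 = -1.0 / slope if slope < 0 else 0.5 * (t[-1] - t[0])
    else:
        tau0 = 0.5 * (t[-1] - t[0])
    tau0 = float(np.clip(tau0, TAU_MIN, TAU_MAX))
    a0 = float(max(h[peak] - b0, 1e-9))
    return tau0, a0, max(b0, 0.0)


def fit_monoexponential(
    histogram: np.ndarray,
    bin_width: float,
    irf: Optional[np.ndarray] = None,
) -> DecayFitResult:
    """Fit ``a*exp(-t/tau) + b`` (IRF-convolved when given) to one histogram.

    Raises
    ------
    EmptySignalError
        If the histogram sums to zero.
    ValueError
        On non-finite entries.
    """
    h = np.asarray(histogram, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("histogram contains non-finite entries")
    if h.size < 4:
        raise ValueError("need at least 4 time bins")
    if h.sum() <= 0:
        raise EmptySignalError("histogram contains no photons")

    t = np.arange(h.size) * float(bin_width)
    if irf is None:
        # exclude the rising edge: fit from the peak bin onward
        peak = int(np.argmax(h))
        h_fit, t_fit = h[peak:], t[peak:] - t[peak]
    else:
        h_fit, t_fit = h, t

    tau0, a0, b0 = _initial_guess(h_fit, t_fit)

    def residuals(p: np.ndarray) -> np.ndarray:
        mu = _model(p, t_fit, irf)
        return (mu - h_fit) / np.sqrt(np.maximum(mu, 0.25))

    sol = least_squares(
        residuals,
        x0=[tau0, a0, b0],
        bounds=([TAU_MIN, 0.0, 0.0], [TAU_MAX, np.inf, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    tau, a, b = sol.x
    rnorm = float(np.linalg.norm(sol.fun))
    # a decay is "found" only if the exponential component carries signal
    ok = a > 1e-6 * max(b, 1.0) and TAU_MIN < tau < TAU_MAX
    return DecayFitResult(
        tau=float(tau), amplitude=float(a), background=float(b),
        residual_norm=rnorm, ok=bool(ok),
    )


def fit_image(
    cube: FLIMDataCube,
    min_counts: float = 50.0,
) -> Tuple[LifetimeImage, IntensityImage]:
    """Fit every pixel of a datacube; pixels below ``min_counts`` photons
    (or with failed fits) are marked invalid.

    Returns the lifetime image and the time-integrated intensity image.
    """
    m, n, _ = cube.shape
    tau = np.zeros((m, n))
    valid = np.zeros((m, n), dtype=bool)
    intensity = cube.intensity().astype(float)
    for i in range(m):
        for j in range(n):
            if intensity[i, j] < min_counts:
                continue
            try:
                res = fit_monoexponential(cube.counts[i, j], cube.bin_width, cube.irf)
            except (EmptySignalError, ValueError):
                continue
            if res.ok:
                tau[i, j] = res.tau
                valid[i, j] = True
    return LifetimeImage(tau=tau, valid=valid), IntensityImage(values=intensity)
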