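"""Domain containers and the sparse-sampling (decimation) forward model.

A low-resolution FLIM sensor samples the high-resolution lifetime field
``tau_hr`` on a regular grid with integer pitch ``factor`` (the upsampling
factor λ): ``tau_lr = A tau_hr``.  ``A`` is pure point decimation — one
high-resolution pixel per λ×λ block, at a configurable in-block offset —
and its adjoint embeds a low-resolution image back into an otherwise-zero
high-resolution canvas.  Both operators are needed by the inverse-retrieval
solver, whose gradient involves ``A^T (A x - tau_lr)``.

Conventions: 0-based row-major indices; low-res sample ``(i, j)`` maps to
high-res pixel ``(λ·i + offset[0], λ·j + offset[1])``; default offset is
``(0, 0)`` (top-left of each block).  Shapes that are not divisible by λ are
rejected rather than cropped so geometry errors surface early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "FLIMDataCube",
    "LifetimeImage",
    "IntensityImage",
    "SamplingSpec",
    "DimensionError",
    "ConfigError",
    "decimate",
    "embed_adjoint",
]

SUPPORTED_FACTORS = (1, 2, 4, 8, 16)


class DimensionError(ValueError):
    """Array shapes inconsistent with the sampling geometry."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class FLIMDataCube:
    """Time-resolved photon-count histogram cube ``counts[m, n, t]``.

    Parameters
    ----------
    counts
        Non-negative photon counts, one arrival-time histogram per
        low-resolution pixel.
    bin_width
        Width of one time bin in nanoseconds.
    irf
        Optional instrument response function, length ``t``, normalised to
        unit sum.
    """

    counts: np.ndarray
    bin_width: float
    irf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise DimensionError("counts must be a 3-D [m, n, t] array")
        if self.counts.shape[2] < 4:
            raise DimensionError("need at least 4 time bins")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not self.bin_width > 0:
            raise ConfigError("bin_width must be positive")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)
            if self.irf.shape != (self.counts.shape[2],):
                raise DimensionError("irf length must equal the number of time bins")
            if abs(self.irf.sum() - 1.0) > 1e-9:
                raise ValueError("irf must be normalised to unit sum")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.counts.shape

    def intensity(self) -> np.ndarray:
        """Counts integrated along the time axis."""
        return self.counts.sum(axis=2)


@dataclass
class LifetimeImage:
    """Per-pixel fluorescence lifetime in nanoseconds with a validity mask."""

    tau: np.ndarray
    valid: Optional[np.ndarray] = None
    pixel_pitch: Optional[float] = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 2:
            raise DimensionError("tau must be 2-D")
        if self.valid is None:
            self.valid = np.ones(self.tau.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.tau.shape:
            raise DimensionError("valid mask must match tau shape")
        if np.any(self.tau[self.valid] < 0):
            raise ValueError("lifetimes must be non-negative where valid")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.tau.shape


@dataclass
class IntensityImage:
    """Non-negative fluorescence intensity image (photon counts or camera units)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("intensity must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SamplingSpec:
    """Geometry of the decimation operator A: factor λ and in-block offset."""

    factor: int
    offset: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ConfigError("upsampling factor must be >= 1")
        if self.factor not in SUPPORTED_FACTORS:
            raise ConfigError(
                f"factor {self.factor} unsupported; expected one of {SUPPORTED_FACTORS}"
            )
        r, c = self.offset
        if not (0 <= r < self.factor and 0 <= c < self.factor):
            raise ConfigError("offset components must lie in [0, factor)")

    def lr_shape(self, hr_shape: Tuple[int, int]) -> Tuple[int, int]:
        M, N = hr_shape
        if M % self.factor or N % self.factor:
            raise DimensionError(
                f"high-res shape {hr_shape} not divisible by factor {self.factor}"
            )
        return M // self.factor, N // self.factor

    def sample_rows(self, M: int) -> np.ndarray:
        return np.arange(self.offset[0], M, self.factor)

    def sample_cols(self, N: int) -> np.ndarray:
        return np.arange(self.offset[1], N, self.factor)


def _decimate_array(x: np.ndarray, spec: SamplingSpec) -> np.ndarray:
    M, N = x.shape
    spec.lr_shape((M, N))  # validates divisibility
    return x[spec.offset[0] :: spec.factor, spec.offset[1] :: spec.factor]


def decimate(tau_hr: LifetimeImage, spec: SamplingSpec) -> LifetimeImage:
    """Apply the sparse-sampling operator A: keep one pixel per λ×λ block."""
    tau = _decimate_array(tau_hr.tau, spec)
    valid = _decimate_array(tau_hr.valid, spec)
    return LifetimeImage(tau=tau.copy(), valid=valid.copy(), pixel_pitch=tau_hr.pixel_pitch)


def embed_adjoint(
    tau_lr: LifetimeImage | np.ndarray,
    spec: SamplingSpec,
    out_shape: Tuple[int, int],
) -> np.ndarray:
    """Adjoint A^T: embed a low-res image at the sampled high-res positions.

    Satisfies ``<A x, y> = <x, A^T y>`` for all x, y because A is a
    selection operator.
    """
    lr = tau_lr.tau if isinstance(tau_lr, LifetimeImage) else np.asarray(tau_lr, dtype=float)
    M, N = out_shape
    m, n = spec.lr_shape((M, N))
    if lr.shape != (m, n):
        raise DimensionError(
            f"low-res shape {lr.shape} incompatible with out_shape {out_shape} at factor {spec.factor}"
        )
    out = np.zeros(out_shape, dtype=float)
    out[spec.offset[0] :: spec.factor, spec.offset[1] :: spec.factor] = lr
    return out


def decimate_array(x: np.ndarray, spec: SamplingSpec) -> np.ndarray:
    """Array-level decimation (same geometry as :func:`decimate`)."""
    return _decimate_array(np.asarray(x), spec)
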