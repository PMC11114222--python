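"""Synthetic FLIM phantoms: ground-truth scenes, intensity renders, datacubes.

The generator emulates the physics that makes intensity-guided lifetime
upsampling both possible and non-trivial.  A scene is a piecewise lifetime
map built from morphological classes — Gaussian-profiled disk "vesicles"
(blobs), curvilinear band "membranes" (ridges), and background — each with
its own lifetime.  Expected fluorescence intensity follows the
quantum-yield relation for mono-exponential emitters,

    I  ∝  absorbance · k_r · τ,

where k_r is the radiative rate (per class) and the absorbance field —
concentration × absorptivity × thickness — is an unknown smooth confounder,
so intensity is *not* a global function of lifetime.  The low-resolution
time-resolved measurement is rendered per decimated sample as a
mono-exponential arrival-time histogram normalised to the pixel's expected
photon count, optionally convolved with a Gaussian instrument response,
with Poisson counting noise per bin.

All randomness flows from the seed in the spec; fixed seed ⇒ bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import FLIMDataCube, IntensityImage, LifetimeImage, SamplingSpec, decimate, decimate_array

__all__ = [
    "ClassSpec",
    "AbsorbanceSpec",
    "PhantomSpec",
    "generate_scene",
    "expected_intensity",
    "render_intensity",
    "render_datacube",
    "make_fixture",
    "FIXTURE_NAMES",
]

MORPHOLOGIES = ("blob", "ridge", "background")
ABSORBANCE_KINDS = ("constant", "smooth_field", "correlated")


@dataclass(frozen=True)
class ClassSpec:
    """One morphological class: shape family, lifetime, radiative rate, and
    density (expected object count per 64×64 tile; ignored for background)."""

    morphology: str
    tau_ns: float
    density: float = 1.0
    k_r: float = 1.0

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if not self.tau_ns > 0:
            raise ValueError("class lifetime must be positive")


@dataclass(frozen=True)
class AbsorbanceSpec:
    kind: str = "smooth_field"
    amplitude: float = 0.3
    correlation_length: float = 12.0  # pixels; >= 8 for smooth_field

    def __post_init__(self) -> None:
        if self.kind not in ABSORBANCE_KINDS:
            raise ValueError(f"unknown absorbance kind {self.kind!r}")


def _default_classes() -> List[ClassSpec]:
    # vesicle/membrane composition: a dim, probe-poor background and two
    # bright structure classes of equal expected brightness (k_r * tau),
    # so raw intensity alone cannot separate them — morphology can.
    return [
        ClassSpec("background", tau_ns=3.0, k_r=0.3),
        ClassSpec("ridge", tau_ns=4.0, density=3.0, k_r=1.5),
        ClassSpec("blob", tau_ns=2.0, density=5.0, k_r=3.0),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int] = (96, 96)
    classes: List[ClassSpec] = field(default_factory=_default_classes)
    absorbance: AbsorbanceSpec = AbsorbanceSpec()
    photons_per_pixel: float = 2000.0
    bins: int = 128
    bin_width: float = 0.16  # ns
    irf_width: Optional[float] = None  # ns (Gaussian sigma); None = no IRF
    local_linearity: bool = False
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.photons_per_pixel > 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.bins < 16:
            raise ValueError("need at least 16 time bins")


def _smooth_field(shape, rng, corr_len) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr_len, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _stamp_disk(mask: np.ndarray, cr: float, cc: float, radius: float) -> None:
    M, N = mask.shape
    r0, r1 = max(int(cr - radius) - 1, 0), min(int(cr + radius) + 2, M)
    c0, c1 = max(int(cc - radius) - 1, 0), min(int(cc + radius) + 2, N)
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask[r0:r1, c0:c1] |= (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2


def _blob_mask(shape, rng, count) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for _ in range(count):
        cr = rng.uniform(0, shape[0])
        cc = rng.uniform(0, shape[1])
        radius = rng.uniform(4.0, 9.0)
        _stamp_disk(mask, cr, cc, radius)
    return mask


def _ridge_mask(shape, rng, count) -> np.ndarray:
    """Curvilinear bands: sinusoidally perturbed straight paths, stamped
    with small disks along their length."""
    mask = np.zeros(shape, dtype=bool)
    M, N = shape
    diag = float(np.hypot(M, N))
    for _ in range(count):
        cr, cc = rng.uniform(0, M), rng.uniform(0, N)
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        nrm = np.array([-d[1], d[0]])
        amp = rng.uniform(2.0, 8.0)
        period = rng.uniform(0.3 * diag, diag)
        phase = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(1.5, 3.0)
        for s in np.arange(-diag, diag, 1.0):
            off = amp * np.sin(2 * np.pi * s / period + phase)
            p = np.array([cr, cc]) + s * d + off * nrm
            if -width <= p[0] < M + width and -width <= p[1] < N + width:
                _stamp_disk(mask, p[0], p[1], width)
    return mask


def generate_scene_labeled(
    spec: PhantomSpec,
) -> Tuple[LifetimeImage, np.ndarray, np.ndarray]:
    """Scene plus the class-index map (draw order resolves overlaps: later
    classes win)."""
    rng = np.random.default_rng(spec.seed)
    M, N = spec.shape

    if spec.local_linearity:
        # lifetime is a smooth field and (with constant absorbance and k_r)
        # intensity is exactly proportional to it: tau = a*I + b holds
        # globally, the regime in which the local prior is exact.
        base = _smooth_field(spec.shape, rng, 8.0)
        tau0 = spec.classes[0].tau_ns if spec.classes else 2.5
        tau = tau0 * (1.0 + 0.35 * base)
        tau = np.clip(tau, 0.2 * tau0, None)
        class_map = np.zeros(spec.shape, dtype=int)
        absorbance = np.ones(spec.shape)
        return LifetimeImage(tau=tau), absorbance, class_map

    bg = [k for k, c in enumerate(spec.classes) if c.morphology == "background"]
    tau = np.full(spec.shape, spec.classes[bg[0]].tau_ns if bg else 1.0)
    class_map = np.full(spec.shape, bg[0] if bg else -1, dtype=int)
    tiles = (M * N) / 4096.0
    for k, cls in enumerate(spec.classes):
        if cls.morphology == "background":
            continue
        # blobs are 2-D objects (count scales with area); ridges span the
        # field, so their count scales with the side length to keep the
        # class area fraction independent of image size
        scale = tiles if cls.morphology == "blob" else np.sqrt(tiles)
        count = max(1, int(round(cls.density * scale)))
        mask = (_blob_mask if cls.morphology == "blob" else _ridge_mask)(spec.shape, rng, count)
        tau[mask] = cls.tau_ns
        class_map[mask] = k

    if spec.absorbance.kind == "constant":
        absorbance = np.ones(spec.shape)
    elif spec.absorbance.kind == "smooth_field":
        f = _smooth_field(spec.shape, rng, max(spec.absorbance.correlation_length, 8.0))
        absorbance = np.clip(1.0 + spec.absorbance.amplitude * f, 0.1, None)
    else:  # correlated with the structure map
        f = gaussian_filter((tau - tau.mean()) / max(tau.std(), 1e-9), 4.0, mode="reflect")
        absorbance = np.clip(1.0 + spec.absorbance.amplitude * f, 0.1, None)
    return LifetimeImage(tau=tau), absorbance, class_map


def generate_scene(spec: PhantomSpec) -> Tuple[LifetimeImage, np.ndarray]:
    tau, absorbance, _ = generate_scene_labeled(spec)
    return tau, absorbance


def _kr_map(class_map: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    kr = np.ones(class_map.shape)
    for k, cls in enumerate(spec.classes):
        kr[class_map == k] = cls.k_r
    return kr


def expected_intensity(
    tau_hr: LifetimeImage,
    absorbance: np.ndarray,
    spec: PhantomSpec,
    class_map: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Noise-free expected intensity ∝ absorbance · k_r · τ, scaled so the
    field mean equals photons_per_pixel."""
    kr = _kr_map(class_map, spec) if class_map is not None else np.ones(tau_hr.shape)
    expected = absorbance * kr * tau_hr.tau
    mean = expected.mean()
    if mean <= 0:
        raise ValueError("degenerate scene: zero expected intensity")
    return expected * (spec.photons_per_pixel / mean)


def render_intensity(
    tau_hr: LifetimeImage,
    absorbance: np.ndarray,
    spec: PhantomSpec,
    class_map: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> IntensityImage:
    expected = expected_intensity(tau_hr, absorbance, spec, class_map)
    if not spec.poisson_noise:
        return IntensityImage(values=expected)
    rng = rng or np.random.default_rng(spec.seed + 1)
    return IntensityImage(values=rng.poisson(expected).astype(float))


def gaussian_irf(bins: int, bin_width: float, sigma_ns: float) -> np.ndarray:
    """Discrete Gaussian IRF, centred a few sigma into the record, unit sum."""
    sigma_bins = sigma_ns / bin_width
    center = max(3.0 * sigma_bins, 1.0)
    k = np.arange(bins)
    irf = np.exp(-0.5 * ((k - center) / sigma_bins) ** 2)
    return irf / irf.sum()


def render_datacube(
    tau_hr: LifetimeImage,
    intensity_expected: np.ndarray,
    spec: PhantomSpec,
    sampling: SamplingSpec,
    rng: Optional[np.random.Generator] = None,
) -> FLIMDataCube:
    """Mono-exponential arrival-time histograms at the decimated sample
    positions, normalised so each pixel's expected total photon count equals
    its decimated expected intensity, IRF-convolved when configured, with
    per-bin Poisson noise."""
    tau_lr = decimate_array(tau_hr.tau, sampling)
    n_expected = decimate_array(intensity_expected, sampling)
    t = np.arange(spec.bins) * spec.bin_width
    shape_k = np.exp(-t[None, None, :] / tau_lr[:, :, None])
    irf = None
    if spec.irf_width is not None:
        irf = gaussian_irf(spec.bins, spec.bin_width, spec.irf_width)
        m, n = tau_lr.shape
        conv = np.empty_like(shape_k)
        for i in range(m):
            for j in range(n):
                conv[i, j] = np.convolve(shape_k[i, j], irf)[: spec.bins]
        shape_k = conv
    shape_k /= shape_k.sum(axis=2, keepdims=True)  # photon conservation
    expected_counts = n_expected[:, :, None] * shape_k
    if spec.poisson_noise:
        rng = rng or np.random.default_rng(spec.seed + 2)
        counts = rng.poisson(expected_counts).astype(float)
    else:
        counts = expected_counts
    return FLIMDataCube(counts=counts, bin_width=spec.bin_width, irf=irf)


FIXTURE_NAMES = ("flat", "lp_exact", "step_edge", "two_class_8x")


def make_fixture(name: str, seed: int = 0) -> Dict[str, object]:
    """Deterministic end-to-end test bundles.

    flat          constant 2.5 ns scene, noiseless, λ=4 (pipeline smoke).
    lp_exact      lifetime affine in intensity, noiseless, λ=4 (local-prior
                  exact-recovery regime).
    step_edge     two-level 2/4 ns vertical step, noiseless, λ=4 (TV edge
                  preservation).
    two_class_8x  vesicle blobs at 2 ns and membrane ridges at 4 ns, equally
                  bright, on a dim 3 ns background with a smooth absorbance
                  confounder, Poisson noise, λ=8 (the full-method recovery
                  benchmark).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")

    if name == "flat":
        spec = PhantomSpec(
            shape=(64, 64),
            classes=[ClassSpec("background", tau_ns=2.5)],
            absorbance=AbsorbanceSpec(kind="constant"),
            poisson_noise=False,
            seed=seed,
        )
        sampling = SamplingSpec(factor=4)
    elif name == "lp_exact":
        spec = PhantomSpec(
            shape=(64, 64),
            classes=[ClassSpec("background", tau_ns=2.5)],
            absorbance=AbsorbanceSpec(kind="constant"),
            local_linearity=True,
            poisson_noise=False,
            seed=seed,
        )
        sampling = SamplingSpec(factor=4)
    elif name == "step_edge":
        spec = PhantomSpec(
            shape=(64, 64),
            classes=[ClassSpec("background", tau_ns=2.0)],
            absorbance=AbsorbanceSpec(kind="constant"),
            poisson_noise=False,
            seed=seed,
        )
        sampling = SamplingSpec(factor=4)
    else:  # two_class_8x
        # 24x24 sample grid: comparable sample count to published 8x
        # wide-field fields of view, where the patch regressor has enough
        # structure instances to generalise from
        spec = PhantomSpec(shape=(192, 192), seed=seed)
        sampling = SamplingSpec(factor=8)

    tau_hr, absorbance, class_map = generate_scene_labeled(spec)
    if name == "step_edge":
        tau = tau_hr.tau.copy()
        tau[:, tau.shape[1] // 2 :] = 4.0
        class_map = (np.arange(tau.shape[1])[None, :] >= tau.shape[1] // 2).astype(int)
        class_map = np.broadcast_to(class_map, tau.shape).copy()
        tau_hr = LifetimeImage(tau=tau)

    intensity_exp = expected_intensity(tau_hr, absorbance, spec, class_map)
    rng = np.random.default_rng(seed)
    if spec.poisson_noise:
        intensity_hr = IntensityImage(values=rng.poisson(intensity_exp).astype(float))
    else:
        intensity_hr = IntensityImage(values=intensity_exp)
    cube = render_datacube(tau_hr, intensity_exp, spec, sampling, rng=rng)
    tau_lr = decimate(tau_hr, sampling)
    return {
        "name": name,
        "spec": spec,
        "sampling": sampling,
        "tau_hr_gt": tau_hr,
        "class_map": class_map,
        "absorbance": absorbance,
        "intensity_expected": intensity_exp,
        "intensity_hr": intensity_hr,
        "cube": cube,
        "tau_lr": tau_lr,
    }
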