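"""Image-quality metrics and the method-comparison harness.

PSNR and SSIM follow the standard definitions (SSIM with an 11-pixel
Gaussian window, σ = 1.5, stabilisers K1 = 0.01 / K2 = 0.03) and are
computed through scikit-image.  LPIPS is exposed only as an optional hook
because it needs externally distributed pretrained perceptual weights.
For masked evaluation, PSNR uses the masked MSE and SSIM averages the
local SSIM map over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "ssim_masked", "lpips_distance", "evaluate_methods"]

PSNR_CAP_DB = 200.0  # sentinel for identical images (MSE = 0)


@dataclass
class MetricReport:
    method_label: str
    psnr: float
    ssim: float
    lpips: Optional[float] = None


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float, mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio, 10·log10(data_range² / MSE), in dB.

    Identical images return the capped sentinel instead of infinity.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    if not data_range > 0:
        raise ValueError("data_range must be positive")
    diff = (ref - test) ** 2
    mse = float(diff[mask].mean()) if mask is not None else float(diff.mean())
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float) -> float:
    """Mean structural similarity (Gaussian 11×11 window, σ=1.5)."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    if min(ref.shape) < 11:
        raise ValueError("images must be at least 11 pixels in each dimension")
    s = structural_similarity(
        ref, test, data_range=data_range,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
    )
    return float(np.clip(s, -1.0, 1.0))


def ssim_masked(ref: np.ndarray, test: np.ndarray, data_range: float, mask: np.ndarray) -> float:
    """Mean of the local SSIM map restricted to a validity mask."""
    if not np.any(mask):
        raise ValueError("empty mask")
    _, smap = structural_similarity(
        np.asarray(ref, float), np.asarray(test, float), data_range=data_range,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False, full=True,
    )
    return float(np.clip(smap[mask].mean(), -1.0, 1.0))


def lpips_distance(ref: np.ndarray, test: np.ndarray) -> float:
    """Optional perceptual distance; requires the external `lpips` package
    and its pretrained network weights."""
    try:
        import lpips  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "LPIPS requires the optional 'lpips' extra (pretrained perceptual weights)"
        ) from exc
    net = lpips.LPIPS(net="alex")  # pragma: no cover

    def to_t(a: np.ndarray):  # pragma: no cover
        a = np.asarray(a, dtype=np.float32)
        a = 2.0 * (a - a.min()) / max(a.max() - a.min(), 1e-12) - 1.0
        return torch.from_numpy(np.stack([a] * 3)[None])

    with torch.no_grad():  # pragma: no cover
        return float(net(to_t(ref), to_t(test)).item())


def evaluate_methods(
    tau_gt: np.ndarray,
    estimates: Dict[str, np.ndarray],
    mask: Optional[np.ndarray] = None,
    data_range: Optional[float] = None,
) -> List[MetricReport]:
    """One PSNR/SSIM report per method, on the masked region.

    ``data_range`` defaults to the ground truth's max − min over the mask.
    """
    tau_gt = np.asarray(tau_gt, dtype=float)
    if mask is None:
        mask = np.ones(tau_gt.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty evaluation mask")
    if data_range is None:
        vals = tau_gt[mask]
        data_range = float(vals.max() - vals.min())
        if data_range == 0.0:
            data_range = max(float(vals.max()), 1.0)
    reports = []
    for label, est in estimates.items():
        reports.append(
            MetricReport(
                method_label=label,
                psnr=psnr(tau_gt, est, data_range, mask=mask),
                ssim=ssim_masked(tau_gt, est, data_range, mask),
            )
        )
    return reports


def reports_to_frame(reports: List[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"method": r.method_label, "psnr_db": r.psnr, "ssim": r.ssim, "lpips": r.lpips} for r in reports]
    )
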