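"""Global prior: patch-to-lifetime regression trained on the sample itself.

Biological fields of view repeat morphology (vesicles, membranes, cell
walls ...), and morphologically similar structures tend to share lifetime.
The global prior exploits this: intensity patches centred on the sparse
lifetime samples become a self-supervised training set for a small
convolutional regressor, which then predicts the lifetime of every
unsampled patch centre.

Training patches carry two channels: one min-max normalised per patch
(shape and texture) and one divided by the global intensity maximum
(absolute brightness).  The set is augmented by the 8 symmetries of the
square (dihedral group), and — at high upsampling factors, where the
sample count is the bottleneck — by the 8 immediate spatial neighbours of
each sampled patch labelled with the sampled lifetime (3×3 neighbourhood:
9 positions, hence 72× data in total with both augmentations).  The
network cannot form a full patch within (p−1)/2 pixels of the image edge,
so that border is marked invalid in the output prior.  Several restarts
are trained and the prior of median validation quality is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._network import PatchRegressor
from .core import IntensityImage, LifetimeImage, SamplingSpec
from .priors import PriorImage

__all__ = [
    "GlobalPriorConfig",
    "PatchSet",
    "EmptyTrainingSetError",
    "extract_patches",
    "augment_symmetry",
    "augment_neighbors",
    "normalize_patch",
    "train_gp_network",
    "predict_global_prior",
    "select_median_prior",
    "build_global_prior",
]


class EmptyTrainingSetError(ValueError):
    """No sample admits a full patch."""


@dataclass
class GlobalPriorConfig:
    patch: int = 13
    epochs: int = 150
    batch: int = 100
    learning_rate: float = 1e-3
    loss: str = "mae"
    symmetry_augment: bool = True
    neighbor_augment: Optional[bool] = None  # None = auto: enabled for factor >= 8
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch % 2 == 0:
            raise ValueError("patch size must be odd")
        if self.restarts < 1:
            raise ValueError("need at least one restart")
        if self.loss != "mae":
            raise ValueError("only mean-absolute-error training is supported")

    def neighbor_enabled(self, factor: int) -> bool:
        return self.neighbor_augment if self.neighbor_augment is not None else factor >= 8

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "GlobalPriorConfig":
        """Reduced preset (20 epochs, single restart) for small phantoms."""
        return cls(epochs=20, restarts=1, seed=seed)


@dataclass
class PatchSet:
    """Normalised patches [K, p, p, 2], labels (ns), patch centres, and the
    originating sample centre of each patch (augmented copies and neighbour
    patches keep their origin, so train/validation splits never straddle
    copies of one sample)."""

    patches: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    origins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=float)
        self.centers = np.asarray(self.centers, dtype=int)
        if self.origins is None:
            self.origins = self.centers.copy()
        else:
            self.origins = np.asarray(self.origins, dtype=int)
        if not (len(self.patches) == len(self.labels) == len(self.centers) == len(self.origins)):
            raise ValueError("patch/label/center counts disagree")

    def __len__(self) -> int:
        return len(self.patches)


def normalize_patch(raw: np.ndarray, global_max: float) -> np.ndarray:
    """Two-channel patch normalisation.

    Channel 0: per-patch min-max (flat patches map to all zeros).
    Channel 1: raw / global maximum of the intensity image.
    """
    if not global_max > 0:
        raise ValueError("global_max must be positive")
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    ch0 = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    ch1 = raw / global_max
    return np.stack([ch0, ch1], axis=-1)


def _normalize_stack(raw: np.ndarray, global_max: float) -> np.ndarray:
    """Vectorised normalize_patch over a stack [K, p, p]."""
    lo = raw.min(axis=(1, 2), keepdims=True)
    hi = raw.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    ch0 = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.stack([ch0, raw / global_max], axis=-1).astype(np.float32)


def extract_patches(
    intensity_hr: IntensityImage,
    tau_lr: LifetimeImage,
    spec: SamplingSpec,
    p: int = 13,
) -> PatchSet:
    """One labelled patch per valid sample whose p×p window fits the image."""
    if p % 2 == 0:
        raise ValueError("patch size must be odd")
    I = intensity_hr.values
    M, N = I.shape
    if min(M, N) <= p:
        raise ValueError("image smaller than the patch size")
    m, n = spec.lr_shape((M, N))
    if tau_lr.shape != (m, n):
        raise ValueError("lifetime shape inconsistent with sampling spec")
    h = p // 2
    gmax = float(I.max())
    raws, labels, centers = [], [], []
    for i in range(m):
        cr = spec.factor * i + spec.offset[0]
        if cr - h < 0 or cr + h >= M:
            continue
        for j in range(n):
            cc = spec.factor * j + spec.offset[1]
            if cc - h < 0 or cc + h >= N or not tau_lr.valid[i, j]:
                continue
            raws.append(I[cr - h : cr + h + 1, cc - h : cc + h + 1])
            labels.append(tau_lr.tau[i, j])
            centers.append((cr, cc))
    if not raws:
        raise EmptyTrainingSetError("no sample admits a full patch")
    patches = _normalize_stack(np.asarray(raws), gmax)
    return PatchSet(patches=patches, labels=np.asarray(labels), centers=np.asarray(centers))


def _dihedral_images(stack: np.ndarray) -> List[np.ndarray]:
    """The 8 symmetries of the square applied to [K, p, p, C] patches."""
    out = []
    for k in range(4):
        r = np.rot90(stack, k=k, axes=(1, 2))
        out.append(r)
        out.append(np.flip(r, axis=2))
    return out


def augment_symmetry(ps: PatchSet) -> PatchSet:
    """Replace each patch by its 8 rotated/mirrored images (labels copied)."""
    if len(ps) == 0:
        raise ValueError("empty patch set")
    images = _dihedral_images(ps.patches)
    patches = np.concatenate(images, axis=0)
    rep = len(images)
    return PatchSet(
        patches=patches,
        labels=np.tile(ps.labels, rep),
        centers=np.tile(ps.centers, (rep, 1)),
        origins=np.tile(ps.origins, (rep, 1)),
    )


def augment_neighbors(
    ps: PatchSet,
    intensity_hr: IntensityImage,
    spec: SamplingSpec,
    p: int = 13,
) -> PatchSet:
    """Add the 8 one-pixel-shifted neighbour patches of every sampled patch,
    labelled with the sampled lifetime (blind labelling: lifetime is assumed
    to vary slowly within one intensity-pixel pitch).  Neighbours whose
    window leaves the image are skipped."""
    I = intensity_hr.values
    M, N = I.shape
    h = p // 2
    gmax = float(I.max())
    raws, labels, centers, origins = [], [], [], []
    for patch, label, center, origin in zip(ps.patches, ps.labels, ps.centers, ps.origins):
        raws_here = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                cr, cc = center[0] + dr, center[1] + dc
                if cr - h < 0 or cr + h >= M or cc - h < 0 or cc + h >= N:
                    continue
                raws_here.append(I[cr - h : cr + h + 1, cc - h : cc + h + 1])
                labels.append(label)
                centers.append((cr, cc))
                origins.append(origin)
        raws.extend(raws_here)
    if raws:
        new_patches = _normalize_stack(np.asarray(raws), gmax)
        return PatchSet(
            patches=np.concatenate([ps.patches, new_patches], axis=0),
            labels=np.concatenate([ps.labels, np.asarray(labels)]),
            centers=np.concatenate([ps.centers, np.asarray(centers)], axis=0),
            origins=np.concatenate([ps.origins, np.asarray(origins)], axis=0),
        )
    return ps


def _grouped_split(ps: PatchSet, val_frac: float, rng: np.random.Generator):
    """90/10 split by originating sample centre, never by augmented copy."""
    keys = ps.origins[:, 0].astype(np.int64) * 10_000_000 + ps.origins[:, 1]
    uniq = np.unique(keys)
    perm = rng.permutation(len(uniq))
    n_val = max(1, int(round(val_frac * len(uniq))))
    if n_val >= len(uniq):
        raise ValueError("validation split empty or training split empty")
    val_keys = set(uniq[perm[:n_val]].tolist())
    is_val = np.fromiter((k in val_keys for k in keys), dtype=bool, count=len(keys))
    return ~is_val, is_val


def train_gp_network(ps: PatchSet, cfg: GlobalPriorConfig, seed: Optional[int] = None) -> PatchRegressor:
    """Train one patch regressor on a 90/10 origin-grouped split."""
    if len(ps) == 0:
        raise ValueError("empty patch set")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tr, va = _grouped_split(ps, 0.1, rng)
    net = PatchRegressor(patch=cfg.patch, seed=seed)
    net.fit(
        ps.patches[tr], ps.labels[tr], ps.patches[va], ps.labels[va],
        epochs=cfg.epochs, batch=cfg.batch, lr=cfg.learning_rate, seed=seed,
    )
    return net


def predict_global_prior(
    model: PatchRegressor,
    intensity_hr: IntensityImage,
    p: int = 13,
) -> PriorImage:
    """Evaluate the trained regressor at every interior pixel; the (p−1)/2
    border, where no full patch exists, is marked invalid."""
    I = intensity_hr.values
    M, N = I.shape
    h = p // 2
    windows = np.lib.stride_tricks.sliding_window_view(I, (p, p))  # (M-2h, N-2h, p, p)
    Mo, No = windows.shape[:2]
    raw = np.ascontiguousarray(windows).reshape(-1, p, p)
    X = _normalize_stack(raw, float(I.max()))
    pred = model.predict(X).reshape(Mo, No)
    values = np.zeros((M, N))
    valid = np.zeros((M, N), dtype=bool)
    values[h : M - h, h : N - h] = pred
    valid[h : M - h, h : N - h] = True
    return PriorImage(values=values, valid=valid)


def select_median_prior(
    priors: Sequence[PriorImage],
    val_maes: Sequence[float],
) -> Tuple[PriorImage, int]:
    """Keep the restart of median final validation MAE (ties: first)."""
    if len(priors) != len(val_maes) or not priors:
        raise ValueError("need one validation score per prior")
    if len(priors) < 3:
        warnings.warn("fewer than 3 restarts; returning the best available prior")
        idx = int(np.argmin(val_maes))
        return priors[idx], idx
    order = np.argsort(val_maes, kind="stable")
    med_val = val_maes[order[len(order) // 2]]
    idx = int(next(i for i, v in enumerate(val_maes) if v == med_val))  # ties: first
    return priors[idx], idx


def build_global_prior(
    tau_lr: LifetimeImage,
    intensity_hr: IntensityImage,
    spec: SamplingSpec,
    cfg: Optional[GlobalPriorConfig] = None,
) -> Tuple[PriorImage, List[PatchRegressor]]:
    """Full global-prior pipeline: extract, augment, train restarts, predict,
    and keep the median-quality prior."""
    cfg = cfg or GlobalPriorConfig()
    ps = extract_patches(intensity_hr, tau_lr, spec, cfg.patch)
    if cfg.neighbor_enabled(spec.factor):
        ps = augment_neighbors(ps, intensity_hr, spec, cfg.patch)
    if cfg.symmetry_augment:
        ps = augment_symmetry(ps)
    nets: List[PatchRegressor] = []
    priors: List[PriorImage] = []
    for r in range(cfg.restarts):
        net = train_gp_network(ps, cfg, seed=cfg.seed + r)
        nets.append(net)
        priors.append(predict_global_prior(net, intensity_hr, cfg.patch))
    prior, _ = select_median_prior(priors, [n.final_val_mae for n in nets])
    return prior, nets
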