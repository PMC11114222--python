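"""Four-point perspective co-registration of the intensity camera frame.

When lifetime and intensity come from different sensors, the intensity
image is mapped onto the lifetime sensor's field of view with a planar
homography estimated from four hand-picked point correspondences (direct
linear transform: 8 equations in the 8 unknowns of a 3×3 matrix with its
bottom-right element fixed at 1).  Warping uses inverse mapping with
bilinear resampling; pixels pulled from outside the source are zero and
flagged in a validity mask.

Points and matrices use (row, col) coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["Homography", "SingularGeometryError", "homography_from_points", "warp_perspective"]


class SingularGeometryError(ValueError):
    """Degenerate point configuration (three collinear points)."""


@dataclass(frozen=True)
class Homography:
    """3×3 projective map on homogeneous (row, col, 1) coordinates,
    normalised so matrix[2, 2] = 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise SingularGeometryError("homography is singular")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (K, 2) row/col points through the homography."""
        pts = np.asarray(points, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(matrix=np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """self ∘ other: apply ``other`` first."""
        return Homography(matrix=self.matrix @ other.matrix)


def _collinear(pts: np.ndarray) -> bool:
    for drop in range(4):
        tri = np.delete(pts, drop, axis=0)
        area = 0.5 * abs(
            (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
            - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
        )
        if area < 1e-9:
            return True
    return False


def homography_from_points(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Direct linear transform from 4 positional correspondences
    src[k] → dst[k] (no 3 points collinear)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ValueError("need exactly four (row, col) points on each side")
    if _collinear(src) or _collinear(dst):
        raise SingularGeometryError("three of the four points are collinear")
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for k in range(4):
        r, c = src[k]
        R, C = dst[k]
        A[2 * k] = [r, c, 1, 0, 0, 0, -r * R, -c * R]
        b[2 * k] = R
        A[2 * k + 1] = [0, 0, 0, r, c, 1, -r * C, -c * C]
        b[2 * k + 1] = C
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularGeometryError("degenerate point configuration") from exc
    H = np.append(h, 1.0).reshape(3, 3)
    return Homography(matrix=H)


def warp_perspective(
    image: np.ndarray,
    H: Homography,
    out_shape: Tuple[int, int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Warp so that output[p] = image[H⁻¹ p] (inverse-mapped bilinear).

    Returns (warped, valid) where ``valid`` marks output pixels whose
    source location fell inside the input image.
    """
    image = np.asarray(image, dtype=float)
    Hinv = H.inverse().matrix
    rows, cols = np.meshgrid(np.arange(out_shape[0]), np.arange(out_shape[1]), indexing="ij")
    hom = np.stack([rows, cols, np.ones_like(rows)], axis=0).reshape(3, -1)
    src = Hinv @ hom
    src = src[:2] / src[2]
    r_src = src[0].reshape(out_shape)
    c_src = src[1].reshape(out_shape)
    valid = (
        (r_src >= 0) & (r_src <= image.shape[0] - 1)
        & (c_src >= 0) & (c_src <= image.shape[1] - 1)
    )
    warped = map_coordinates(image, [r_src, c_src], order=1, mode="constant", cval=0.0)
    warped[~valid] = 0.0
    return warped, valid
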