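"""Reading and writing the on-disk formats.

Lifetime and intensity images travel as single-page 32-bit float TIFFs
(lifetime in ns).  Datacubes travel as multi-page TIFFs, one page per time
bin, with a JSON sidecar carrying ``bin_width_ns`` and an optional ``irf``
list.  Validity masks are 8-bit TIFFs (0/1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .core import FLIMDataCube, IntensityImage, LifetimeImage

PathLike = Union[str, Path]


def write_image(path: PathLike, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_array(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path))) > 0


def write_lifetime(path: PathLike, img: LifetimeImage, mask_path: Optional[PathLike] = None) -> None:
    write_image(path, img.tau)
    if mask_path is not None:
        write_mask(mask_path, img.valid)


def read_lifetime(path: PathLike, mask_path: Optional[PathLike] = None) -> LifetimeImage:
    tau = read_array(path)
    valid = read_mask(mask_path) if mask_path is not None else None
    return LifetimeImage(tau=tau, valid=valid)


def write_intensity(path: PathLike, img: IntensityImage) -> None:
    write_image(path, img.values)


def read_intensity(path: PathLike) -> IntensityImage:
    return IntensityImage(values=read_array(path))


def write_cube(tif_path: PathLike, meta_path: PathLike, cube: FLIMDataCube) -> None:
    # pages are time bins: [t, m, n] on disk, [m, n, t] in memory
    pages = np.moveaxis(cube.counts, 2, 0).astype(np.float32)
    tifffile.imwrite(str(tif_path), pages, photometric="minisblack")
    meta = {"bin_width_ns": cube.bin_width}
    if cube.irf is not None:
        meta["irf"] = [float(v) for v in cube.irf]
    Path(meta_path).write_text(json.dumps(meta))


def read_cube(tif_path: PathLike, meta_path: PathLike) -> FLIMDataCube:
    pages = np.asarray(tifffile.imread(str(tif_path)))
    if pages.ndim != 3:
        raise ValueError("datacube TIFF must be multi-page")
    counts = np.moveaxis(pages, 0, 2)
    meta = json.loads(Path(meta_path).read_text())
    irf = np.asarray(meta["irf"], dtype=float) if "irf" in meta else None
    return FLIMDataCube(counts=counts, bin_width=float(meta["bin_width_ns"]), irf=irf)
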