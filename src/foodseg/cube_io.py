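"""Reading, writing and validation of multispectral cubes and binary masks.

A cube is an ``m x n x W`` stack of reflectance images (band axis last), one
image per narrow wavelength band, as produced by multispectral acquisition
systems for food samples.  On disk a cube is a multi-page float TIFF (one page
per band, page order = band order) with an optional JSON sidecar
``<stem>.wavelengths.json`` holding ``{"wavelengths_nm": [...]}``.  Masks are
single-band 8-bit PNG/TIFF images, 0 = excluded, nonzero = included.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger("foodseg")

MaskLabel = ("foreground_stage1", "informative_final", "custom")


class CubeError(ValueError):
    """Raised for invalid cubes, masks, or unreadable files."""


@dataclass
class SpectralCube:
    """An m x n x W reflectance cube with its wavelength axis.

    Parameters
    ----------
    data:
        Floating-point array of shape (m, n, W); band axis last.
    wavelengths:
        W wavelengths in nm, strictly increasing.
    source_id:
        Free-text provenance tag.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        validate_cube(self)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class BinaryMask:
    """A boolean m x n mask; ``empty`` must be set explicitly for all-false masks."""

    data: np.ndarray
    label: str = "custom"
    empty: bool = field(default=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise CubeError(f"mask must be 2-D, got ndim={self.data.ndim}")
        if self.label not in MaskLabel:
            raise CubeError(f"unknown mask label {self.label!r}")
        if not self.data.any() and not self.empty:
            raise CubeError(
                "mask has no true pixel; pass empty=True to build an "
                "explicitly empty mask"
            )

    @property
    def n_true(self) -> int:
        return int(self.data.sum())


def bare_cube(data: np.ndarray, wavelengths, source_id: str = "") -> SpectralCube:
    """Construct a cube that may contain NaN (post-masking); Inf still rejected."""
    cube = SpectralCube.__new__(SpectralCube)
    cube.data = np.asarray(data, dtype=np.float64)
    cube.wavelengths = np.asarray(wavelengths, dtype=np.float64)
    cube.source_id = source_id
    validate_cube(cube, allow_nan=True)
    return cube


def validate_cube(cube: SpectralCube, allow_nan: bool = False) -> None:
    """Check the SpectralCube invariants; raise CubeError on violation."""
    data = cube.data
    if data.ndim != 3:
        raise CubeError(f"cube data must have 3 axes, got {data.ndim}")
    m, n, w = data.shape
    if m < 3 or n < 3:
        raise CubeError(
            f"spatial size {m}x{n} too small; 3x3 neighborhood operations "
            "require m >= 3 and n >= 3"
        )
    if w < 2:
        raise CubeError(f"cube must have W >= 2 bands, got W={w}")
    if cube.wavelengths.shape != (w,):
        raise CubeError(
            f"wavelength count {cube.wavelengths.size} != band count {w}"
        )
    if np.any(np.diff(cube.wavelengths) <= 0):
        raise CubeError("wavelengths must be strictly increasing")
    if allow_nan:
        if np.isinf(data).any():
            raise CubeError("cube contains infinite values")
    elif not np.isfinite(data).all():
        raise CubeError("cube contains non-finite values")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".wavelengths.json")


def read_cube(
    path: str | Path, wavelengths: Sequence[float] | None = None
) -> SpectralCube:
    """Read a multi-page TIFF cube, with wavelengths from the sidecar if present.

    Pages map to bands in page order.  When neither the sidecar nor the
    ``wavelengths`` argument supplies metadata, band indices 0..W-1 are used
    and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise CubeError(f"no such file: {path}")
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        raise CubeError("single-page TIFF: a cube needs W >= 2 bands")
    if pages.ndim != 3:
        raise CubeError(f"expected a stack of 2-D pages, got ndim={pages.ndim}")
    data = np.moveaxis(pages, 0, -1).astype(np.float64)  # band axis last

    if wavelengths is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            wavelengths = meta["wavelengths_nm"]
        else:
            logger.warning(
                "%s: no wavelength metadata; defaulting to band indices", path
            )
            wavelengths = np.arange(data.shape[2], dtype=float)
    if np.isnan(data).any():
        # a previously masked cube; NaN marks excluded pixels
        logger.warning("%s: cube contains NaN (masked) pixels", path)
        return bare_cube(data, wavelengths, source_id=str(path))
    return SpectralCube(data=data, wavelengths=np.asarray(wavelengths, float),
                        source_id=str(path))


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as a multi-page float TIFF plus wavelength sidecar.

    Lossless: ``read_cube(write_cube(c)) == c`` bitwise on data and
    wavelengths.  NaN values (post-masking) are preserved.
    """
    path = Path(path)
    pages = np.moveaxis(cube.data, -1, 0)
    tifffile.imwrite(path, pages.astype(np.float64), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({"wavelengths_nm": list(map(float, cube.wavelengths))})
    )
    return path


def read_mask(path: str | Path, label: str = "custom") -> BinaryMask:
    """Read a single-band 8-bit image as a boolean mask (any nonzero = true)."""
    path = Path(path)
    if not path.exists():
        raise CubeError(f"no such file: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise CubeError(
            f"mask image must be single-band 2-D, got shape {arr.shape}"
        )
    data = arr != 0
    return BinaryMask(data=data, label=label, empty=not data.any())


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as an 8-bit single-band image (0 = excluded, 255 = included)."""
    path = Path(path)
    iio.imwrite(path, (mask.data.astype(np.uint8) * 255))
    return path
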