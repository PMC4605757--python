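"""Two-phase normalization of a reflectance cube.

Phase one rescales every band image independently to [0, 1]
(``(v - min) / (max - min)``), spreading each band over the full dynamic
range.  Phase two applies the Standard Normal Variate (SNV) transform to
every pixel's spectrum, ``(v - mean(v)) / std(v)``, which removes the
multiplicative illumination component (``snv(a*v + b) == snv(v)`` for a > 0).
Segmentation runs on the phase-one output; the SNV representation is kept
for spectral export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cube_io import SpectralCube

logger = logging.getLogger("foodseg")


@dataclass
class PreprocessedCube:
    """Cube after normalization; ``stage`` records which phases ran."""

    data: np.ndarray
    stage: str  # "bandnorm" | "bandnorm+snv"
    source: SpectralCube
    constant_bands: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    constant_pixels: np.ndarray | None = None

    @property
    def wavelengths(self) -> np.ndarray:
        return self.source.wavelengths


def normalize_bands(cube: SpectralCube) -> PreprocessedCube:
    """Min-max rescale each band to [0, 1] independently.

    A constant band cannot be rescaled; it maps to all zeros and is flagged
    in ``constant_bands`` (a warning is logged rather than raising, so dead
    bands do not abort a batch run).
    """
    data = cube.data
    mins = data.min(axis=(0, 1))
    maxs = data.max(axis=(0, 1))
    span = maxs - mins
    constant = span == 0
    if constant.any():
        logger.warning(
            "constant band(s) %s mapped to zeros", np.nonzero(constant)[0].tolist()
        )
    safe_span = np.where(constant, 1.0, span)
    out = (data - mins) / safe_span
    out[:, :, constant] = 0.0
    return PreprocessedCube(
        data=out, stage="bandnorm", source=cube, constant_bands=constant
    )


def snv(pre: PreprocessedCube) -> PreprocessedCube:
    """Standard Normal Variate: center and scale each pixel's spectrum.

    Uses the sample standard deviation (W - 1 denominator).  Constant
    spectra are set to zero and flagged in ``constant_pixels``.
    Requires the band-normalized (phase-one) input.
    """
    if pre.stage != "bandnorm":
        raise ValueError(f"snv expects stage='bandnorm', got {pre.stage!r}")
    data = pre.data
    if data.shape[2] < 2:
        raise ValueError("SNV needs W >= 2 bands")
    mean = data.mean(axis=2, keepdims=True)
    std = data.std(axis=2, ddof=1, keepdims=True)
    # relative tolerance: a flat spectrum's std is roundoff, not signal
    flat = std <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    constant = flat[:, :, 0]
    safe_std = np.where(flat, 1.0, std)
    out = (data - mean) / safe_std
    out[constant, :] = 0.0
    if constant.any():
        logger.warning("%d constant-spectrum pixel(s) set to zero", constant.sum())
    return PreprocessedCube(
        data=out,
        stage="bandnorm+snv",
        source=pre.source,
        constant_bands=pre.constant_bands,
        constant_pixels=constant,
    )
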