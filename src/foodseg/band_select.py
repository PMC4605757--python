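"""Unsupervised spectral band-pair selection via an edge-based contrast measure.

For every pair of band images (i, j) a single grey "difference image"
``I_diff = |b_i - b_j|`` is formed and rescaled to [0, 1].  Each difference
image is scored by the edge-based contrast measure (EBCM): the mean over
pixels of

    c(x, y) = |I(x, y) - e(x, y)| / |I(x, y) + e(x, y)|

where ``e`` is the edge-weighted mean grey level of the pixel's 3x3
neighborhood, with weights given by the Sobel gradient magnitude.  EBCM is
large for images full of edges and small for blurry, piecewise-flat images.
The pair with *minimum* EBCM is selected: the flattest difference image is
the one whose distinct regions separate most cleanly in the histogram,
which is exactly what the downstream mixture-model thresholding needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .cube_io import BinaryMask
from .preprocess import PreprocessedCube

__all__ = [
    "DifferenceImage",
    "EdgeMap",
    "BandPairScore",
    "sobel_magnitude",
    "ebcm",
    "select_band_pair",
    "select_band_pair_masked",
    "write_scores_csv",
]


def write_scores_csv(scores: list["BandPairScore"], path) -> None:
    """Write a ranked score list as CSV with columns pair_i, pair_j, ebcm."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_i", "pair_j", "ebcm"])
        for s in scores:
            writer.writerow([s.pair[0], s.pair[1], repr(s.ebcm)])


@dataclass
class DifferenceImage:
    """Rescaled grey image formed from one band pair; values in [0, 1]."""

    data: np.ndarray
    pair: tuple[int, int]


@dataclass
class EdgeMap:
    """Per-pixel Sobel gradient magnitudes (nonnegative)."""

    data: np.ndarray


@dataclass
class BandPairScore:
    pair: tuple[int, int]
    ebcm: float


def sobel_magnitude(image: np.ndarray) -> EdgeMap:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), reflect padding at borders."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("sobel_magnitude needs a 2-D image of at least 3x3")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    gx = ndimage.sobel(image, axis=1, mode="mirror")
    gy = ndimage.sobel(image, axis=0, mode="mirror")
    return EdgeMap(data=np.hypot(gx, gy))


def ebcm(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Edge-based contrast measure of a grey image with values in [0, 1].

    ``e(x,y)`` is the Sobel-weighted mean grey level over the pixel's 3x3
    neighborhood (reflect padding, the center pixel included).  Conventions
    for the degenerate denominators: a neighborhood with zero total edge
    weight takes ``e = I`` (so c = 0, no local contrast), and pixels with
    ``I + e == 0`` take c = 0 (the limit along I = e).  With ``mask`` the
    average runs only over the masked pixels; the neighborhood operations
    still see the full image.
    """
    image = np.asarray(image, dtype=np.float64)
    g = sobel_magnitude(image).data
    footprint = np.ones((3, 3))
    num = ndimage.correlate(g * image, footprint, mode="mirror")
    den = ndimage.correlate(g, footprint, mode="mirror")
    e = np.where(den > 0, num / np.where(den > 0, den, 1.0), image)
    s = image + e
    c = np.where(s > 0, np.abs(image - e) / np.where(s > 0, s, 1.0), 0.0)
    if mask is not None:
        return float(c[mask].mean())
    return float(c.mean())


def _difference_image(
    band_a: np.ndarray,
    band_b: np.ndarray,
    mask: np.ndarray | None,
    combiner: str,
) -> np.ndarray:
    """Form and [0,1]-rescale the pair image; constant images map to zeros."""
    if combiner == "difference":
        d = np.abs(band_a - band_b)
    elif combiner == "ratio":
        eps = 1e-12
        d = np.minimum(band_a, band_b) / (np.maximum(band_a, band_b) + eps)
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    sel = d[mask] if mask is not None else d
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        return np.zeros_like(d)
    # masked rescale can push out-of-mask pixels outside [0,1]; clip so the
    # neighborhood operations stay on the nominal grey range
    return np.clip((d - lo) / (hi - lo), 0.0, 1.0)


def _select(
    cube: PreprocessedCube,
    mask: np.ndarray | None,
    candidates: Iterable[tuple[int, int]] | None,
    combiner: str,
) -> tuple[list[BandPairScore], DifferenceImage]:
    data = cube.data
    w = data.shape[2]
    if w < 2:
        raise ValueError("band selection needs W >= 2")
    if candidates is None:
        pairs: Sequence[tuple[int, int]] = list(combinations(range(w), 2))
    else:
        pairs = [tuple(sorted(p)) for p in candidates]  # type: ignore[misc]
        if not pairs:
            raise ValueError("empty candidate list")

    scores: list[BandPairScore] = []
    images: dict[tuple[int, int], np.ndarray] = {}
    any_contrast = False
    for i, j in pairs:
        d = _difference_image(data[:, :, i], data[:, :, j], mask, combiner)
        sel = d[mask] if mask is not None else d
        if sel.max() > sel.min():
            any_contrast = True
        images[(i, j)] = d
        scores.append(BandPairScore(pair=(i, j), ebcm=ebcm(d, mask)))
    if not any_contrast:
        raise ValueError("no contrast in cube: every candidate difference is constant")
    scores.sort(key=lambda s: (s.ebcm, s.pair))
    winner = scores[0].pair
    return scores, DifferenceImage(data=images[winner], pair=winner)


def select_band_pair(
    cube: PreprocessedCube,
    candidates: Iterable[tuple[int, int]] | None = None,
    combiner: str = "difference",
) -> tuple[list[BandPairScore], DifferenceImage]:
    """Rank all candidate band pairs by ascending EBCM; return the minimizer.

    Ties break lexicographically on the (i, j) pair, so the ranking is
    deterministic.  Raises when every candidate difference image is constant
    ("no contrast in cube").
    """
    return _select(cube, None, candidates, combiner)


def select_band_pair_masked(
    cube: PreprocessedCube,
    mask: BinaryMask,
    candidates: Iterable[tuple[int, int]] | None = None,
    combiner: str = "difference",
) -> tuple[list[BandPairScore], DifferenceImage]:
    """Like :func:`select_band_pair`, restricted to pixels inside ``mask``.

    The EBCM average and the [0,1]-rescale of each difference image use only
    masked pixels.
    """
    if mask.empty or not mask.data.any():
        raise ValueError("empty mask")
    if mask.data.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    return _select(cube, mask.data, candidates, combiner)
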