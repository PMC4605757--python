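"""Evaluation statistics for comparing two segmentations of the same scenes.

Three families of summaries: informative-area fractions with an ordinary
least-squares regression and Pearson correlation between two methods' area
series; binary colocalization of a mask against a basis ("ground truth")
mask, with the exclusive ("anti-colocalized") areas of each method; and
per-wavelength mean +/- std reflectance over a mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cube_io import BinaryMask, SpectralCube

__all__ = [
    "RegressionReport",
    "ColocReport",
    "BandSummary",
    "area_fraction",
    "regress_areas",
    "colocalize",
    "colocalize_batch",
    "band_summary",
    "dice",
]


@dataclass
class RegressionReport:
    """OLS fit y = a*x + b plus Pearson correlation of the two area series."""

    a: float
    b: float
    r_square: float
    rmse: float
    r: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class ColocReport:
    """Overlap percentages of mask A against a basis mask B (percent of |B|).

    ``coloc_pct + excl_b_pct == 100`` by construction: the basis is
    partitioned into the part A covers and the part only B has.
    ``dice`` is a symmetric convenience score, not part of the basis-relative
    bookkeeping.
    """

    coloc_pct: float    # |A & B| / |B| * 100
    excl_a_pct: float   # |A \ B| / |B| * 100  (A-only area, relative to B)
    excl_b_pct: float   # |B \ A| / |B| * 100
    dice: float

    def as_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class BandSummary:
    wavelengths: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def as_dict(self) -> dict:
        return {
            "wavelengths": self.wavelengths.tolist(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }


def area_fraction(mask: BinaryMask) -> float:
    """Fraction of image pixels the mask includes, in [0, 1]."""
    return float(mask.data.sum()) / mask.data.size


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Symmetric Dice overlap 2|A&B| / (|A| + |B|); 1.0 for two empty masks."""
    a = a.data if isinstance(a, BinaryMask) else np.asarray(a, bool)
    b = b.data if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def regress_areas(x, y) -> RegressionReport:
    """OLS regression y = a*x + b with Pearson r and its two-sided p-value.

    The p-value comes from the exact t distribution with n - 2 degrees of
    freedom.  Raises on fewer than 3 points or zero variance in x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_square = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegressionReport(
        a=float(fit.slope), b=float(fit.intercept), r_square=r_square,
        rmse=rmse, r=float(fit.rvalue), p_value=float(fit.pvalue), n=n,
    )


def colocalize(a: BinaryMask, basis: BinaryMask) -> ColocReport:
    """Binary colocalization of mask ``a`` against the ``basis`` mask.

    All percentages are relative to the basis area, following the convention
    of treating the basis segmentation as ground truth.
    """
    if a.data.shape != basis.data.shape:
        raise ValueError("mask shapes differ")
    nb = basis.data.sum()
    if nb == 0:
        raise ValueError("empty basis mask")
    inter = (a.data & basis.data).sum()
    only_a = (a.data & ~basis.data).sum()
    only_b = (basis.data & ~a.data).sum()
    return ColocReport(
        coloc_pct=100.0 * inter / nb,
        excl_a_pct=100.0 * only_a / nb,
        excl_b_pct=100.0 * only_b / nb,
        dice=dice(a, basis),
    )


def colocalize_batch(pairs: list[tuple[BinaryMask, BinaryMask]]) -> dict:
    """Per-sample colocalization plus mean and standard error across samples.

    Standard error = sample std / sqrt(n).
    """
    reports = [colocalize(a, b) for a, b in pairs]
    out: dict = {"per_sample": [r.as_dict() for r in reports]}
    for key in ("coloc_pct", "excl_a_pct", "excl_b_pct"):
        vals = np.array([getattr(r, key) for r in reports])
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[key] = {"mean": float(vals.mean()), "se": se}
    return out


def band_summary(cube: SpectralCube, mask: BinaryMask) -> BandSummary:
    """Per-band mean and sample std of reflectance over the masked pixels.

    NaN pixels (already excluded by a previous mask application) are ignored.
    """
    if mask.data.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if mask.empty or not mask.data.any():
        raise ValueError("empty mask")
    vals = cube.data[mask.data, :]  # (n_pixels, W)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
        std = np.nanstd(vals, axis=0, ddof=1)
    return BandSummary(wavelengths=cube.wavelengths.copy(), mean=mean, std=std)
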