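"""Seeded synthetic multispectral cubes with ground truth.

The generator emulates the structure a diffuse-illumination multispectral
acquisition of a food sample has, and that the segmentation method assumes:
spectrally distinct regions (dark background, bright dish, sample, and
optionally fat speckles inside the sample), additive Gaussian sensor noise,
and a per-pixel multiplicative illumination gain that is *constant across
bands* — exactly the multiplicative component SNV normalization removes.
Pixel values are

    I(x, y, w) = gain(x, y) * signature_region(w) + eps,   eps ~ N(0, sd^2)

clipped at zero.  Gain is drawn from a normal centered on the midpoint of
``gain_range`` with sigma = width/8, truncated to the interval (illumination
falloff concentrates around its mean between hard physical bounds).

The dish matters: with a single homogeneous surround, per-band min-max
normalization maps both regions onto nearly the same two levels in every
band and no band pair carries contrast, which is not how real scenes (dish
rim, packaging, shadows) behave.  The ground-truth masks partition the
image into sample proper (lean), fat, and surround (background + dish).

The generator does not emulate real texture: regions are spectrally
homogeneous with hard boundaries, there is no optical blur, no specular
highlights and no spatial noise correlation, so passing on phantoms shows
the method recovers the structure it models, not that it survives every
artifact of real meat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cube_io import BinaryMask, SpectralCube

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "preset", "PRESET_NAMES"]

PRESET_NAMES = ("meat", "creme", "olives")

# 18 acquisition wavelengths (nm), 405-970
DEFAULT_WAVELENGTHS = np.array(
    [405, 435, 450, 470, 505, 525, 570, 590, 630,
     645, 660, 700, 780, 850, 870, 890, 910, 970], dtype=float
)

# Reflectance signatures, one value per band (405 -> 970 nm).  Lean meat is
# dark below ~600 nm (myoglobin absorption) and steps up in the red/NIR; fat
# is yellowish-white — dimmer in the blue, bright and flat from the green
# onward; the dish is bright plastic with a mild blue-to-NIR rolloff; the
# background is dark cloth; creme is uniformly bright; olives are dark with
# the vegetation NIR rise.
_SIGNATURES = {
    "background": np.linspace(0.05, 0.07, 18),
    "dish": np.linspace(0.82, 0.70, 18),
    "lean": np.array([0.08, 0.08, 0.09, 0.09, 0.10, 0.11, 0.13, 0.18, 0.32,
                      0.36, 0.40, 0.46, 0.52, 0.55, 0.56, 0.56, 0.57, 0.58]),
    "fat": np.array([0.30, 0.36, 0.40, 0.46, 0.55, 0.62, 0.70, 0.71, 0.72,
                     0.72, 0.73, 0.73, 0.74, 0.75, 0.75, 0.76, 0.76, 0.78]),
    "creme": np.linspace(0.55, 0.75, 18),
    "olive": np.array([0.06, 0.07, 0.08, 0.09, 0.13, 0.15, 0.13, 0.12, 0.10,
                       0.10, 0.11, 0.13, 0.35, 0.42, 0.44, 0.45, 0.46, 0.48]),
}


@dataclass
class PhantomSpec:
    """Geometry, spectra and noise levels of one synthetic scene.

    ``sample_centers``/``sample_radii`` are (row, col) pixel coordinates and
    (row, col) semi-axes of the sample ellipse(s); the dish is a larger
    ellipse underneath; fat speckles are disks of random radius in
    ``fat_radius_range`` scattered inside the sample.  The surround is the
    complement of the sample: dish plus background.
    """

    shape: tuple[int, int, int]
    sample_centers: list[tuple[float, float]]
    sample_radii: list[tuple[float, float]]
    signature_surround: np.ndarray        # background outside the dish
    signature_sample: np.ndarray
    signature_fat: np.ndarray | None
    n_fat_blobs: int
    fat_radius_range: tuple[float, float]
    seed: int
    signature_dish: np.ndarray | None = None
    dish_center: tuple[float, float] | None = None
    dish_radii: tuple[float, float] | None = None
    noise_sd: float = 0.02
    gain_range: tuple[float, float] = (0.8, 1.2)
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        m, n, w = self.shape
        if self.wavelengths is None:
            self.wavelengths = (
                DEFAULT_WAVELENGTHS.copy() if w == 18
                else np.linspace(405.0, 970.0, w)
            )
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("signature_surround", "signature_sample", "signature_fat",
                     "signature_dish"):
            sig = getattr(self, name)
            if sig is None:
                continue
            sig = np.asarray(sig, dtype=float)
            setattr(self, name, sig)
            if sig.shape != (w,):
                raise ValueError(f"{name} has length {sig.size}, cube has W={w}")
            if sig.min() < 0 or sig.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.wavelengths.size != w:
            raise ValueError("wavelength list length must equal W")
        for (cy, cx), (ry, rx) in zip(self.sample_centers, self.sample_radii):
            if cy - ry < 0 or cy + ry >= m or cx - rx < 0 or cx + rx >= n:
                raise ValueError("sample region does not fit inside the image")
        if self.n_fat_blobs > 0 and self.signature_fat is None:
            raise ValueError("fat blobs requested but no fat signature given")
        if (self.signature_dish is None) != (self.dish_radii is None):
            raise ValueError("dish signature and geometry must be given together")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PhantomTruth:
    """A generated cube plus the three ground-truth region masks."""

    cube: SpectralCube
    truth_sample: BinaryMask   # lean / sample proper
    truth_fat: BinaryMask
    truth_surround: BinaryMask  # background + dish
    spec: PhantomSpec


def _ellipse_mask(shape: tuple[int, int], center, radii) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _truncnorm_gain(rng: np.random.Generator, lo: float, hi: float,
                    size: tuple[int, int]) -> np.ndarray:
    mid = 0.5 * (lo + hi)
    sigma = (hi - lo) / 8.0
    if sigma == 0:
        return np.full(size, mid)
    a, b = (lo - mid) / sigma, (hi - mid) / sigma
    return stats.truncnorm.rvs(a, b, loc=mid, scale=sigma, size=size,
                               random_state=rng)


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render the scene described by ``spec``; deterministic per seed."""
    m, n, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    sample = np.zeros((m, n), dtype=bool)
    for center, radii in zip(spec.sample_centers, spec.sample_radii):
        sample |= _ellipse_mask((m, n), center, radii)

    fat = np.zeros((m, n), dtype=bool)
    if spec.n_fat_blobs > 0:
        inside = np.argwhere(sample)
        lo_r, hi_r = spec.fat_radius_range
        for _ in range(spec.n_fat_blobs):
            cy, cx = inside[rng.integers(len(inside))]
            r = rng.uniform(lo_r, hi_r)
            fat |= _ellipse_mask((m, n), (cy, cx), (r, r))
        fat &= sample

    lean = sample & ~fat
    surround = ~sample

    signatures = np.zeros((m, n, w))
    signatures[surround, :] = spec.signature_surround
    if spec.signature_dish is not None:
        center = spec.dish_center or (m / 2, n / 2)
        dish = _ellipse_mask((m, n), center, spec.dish_radii) & surround
        signatures[dish, :] = spec.signature_dish
    signatures[lean, :] = spec.signature_sample
    if spec.signature_fat is not None:
        signatures[fat, :] = spec.signature_fat

    gain = _truncnorm_gain(rng, *spec.gain_range, (m, n))
    data = gain[:, :, None] * signatures
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    cube = SpectralCube(
        data=data, wavelengths=spec.wavelengths,
        source_id=f"phantom(seed={spec.seed})",
    )
    return PhantomTruth(
        cube=cube,
        truth_sample=BinaryMask(lean, label="custom", empty=not lean.any()),
        truth_fat=BinaryMask(fat, label="custom", empty=not fat.any()),
        truth_surround=BinaryMask(surround, label="custom",
                                  empty=not surround.any()),
        spec=spec,
    )


def preset(name: str, shape: tuple[int, int, int] = (256, 256, 18),
           seed: int = 0) -> PhantomSpec:
    """A documented scene archetype.

    ``meat``: a lean ellipse with fat speckles, centered in a bright dish on
    a dark background.  ``creme``: one homogeneous bright sample in the
    dish, no fat class.  ``olives``: several dark ellipses filling the
    center of the dish.
    """
    m, n, w = shape
    r = min(m, n)
    common = dict(
        shape=shape,
        signature_surround=_resample(_SIGNATURES["background"], w),
        signature_dish=_resample(_SIGNATURES["dish"], w),
        dish_center=(m / 2, n / 2),
        dish_radii=(0.46 * r, 0.48 * r),
        seed=seed,
    )
    if name == "meat":
        return PhantomSpec(
            sample_centers=[(m / 2, n / 2)],
            sample_radii=[(0.32 * r, 0.36 * r)],
            signature_sample=_resample(_SIGNATURES["lean"], w),
            signature_fat=_resample(_SIGNATURES["fat"], w),
            n_fat_blobs=12,
            fat_radius_range=(0.015 * r, 0.045 * r),
            **common,
        )
    if name == "creme":
        return PhantomSpec(
            sample_centers=[(m / 2, n / 2)],
            sample_radii=[(0.36 * r, 0.36 * r)],
            signature_sample=_resample(_SIGNATURES["creme"], w),
            signature_fat=None,
            n_fat_blobs=0,
            fat_radius_range=(0.0, 0.0),
            **common,
        )
    if name == "olives":
        offsets = [(-0.2, -0.2), (-0.21, 0.02), (-0.2, 0.22), (0.0, -0.12),
                   (0.02, 0.1), (0.2, -0.2), (0.21, 0.01), (0.2, 0.21)]
        centers = [(m / 2 + dy * r, n / 2 + dx * r) for dy, dx in offsets]
        radii = [(0.1 * r, 0.075 * r)] * len(centers)
        return PhantomSpec(
            sample_centers=centers,
            sample_radii=radii,
            signature_sample=_resample(_SIGNATURES["olive"], w),
            signature_fat=None,
            n_fat_blobs=0,
            fat_radius_range=(0.0, 0.0),
            **common,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def _resample(signature: np.ndarray, w: int) -> np.ndarray:
    """Interpolate an 18-point signature onto W bands (identity for W=18)."""
    if signature.size == w:
        return signature.copy()
    x_old = np.linspace(0, 1, signature.size)
    return np.interp(np.linspace(0, 1, w), x_old, signature)
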