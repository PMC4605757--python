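"""The full segmentation cascade.

Stage order, for one reflectance cube:

1. per-band min-max normalization, then SNV (retained for spectral export);
2. stage 1 — band-pair selection + mixture threshold on the whole image,
   removing the non-informative surround (dish, packaging, background);
3. stage 2 — the same machinery restricted to the stage-1 foreground,
   removing fat / connective tissue inside the sample (skippable for
   homogeneous products such as crème);
4. the final mask (stage1 AND stage2) applied to all bands, excluded pixels
   set to NaN.

Which side of a Bayes threshold is "sample" is not decidable from the
histogram alone (fat can outweigh lean, surround can outweigh sample), so
the default rule takes the side that dominates the central 25%-area window
of the image — food samples are centered in the dish.  The rule is
configurable (above | below | central | larger_component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from skimage import morphology

from .band_select import (
    BandPairScore,
    DifferenceImage,
    select_band_pair,
    select_band_pair_masked,
)
from .cube_io import BinaryMask, SpectralCube, bare_cube
from .mixture import (
    FitConfig,
    ThresholdDecision,
    bayes_threshold,
    fit_em,
    kurtosis_threshold,
    select_model,
)
from .preprocess import PreprocessedCube, normalize_bands, snv

logger = logging.getLogger("foodseg")

_MIN_RESTRICT_PIXELS = 20  # a stage cannot fit a mixture on fewer pixels


@dataclass
class PipelineConfig:
    """Everything the cascade can be steered with; defaults run the paper-style
    two-stage meat workflow."""

    fit: FitConfig = field(default_factory=FitConfig)
    skip_stage2: bool = False
    foreground_rule: str = "central"  # above | below | central | larger_component
    combiner: str = "difference"
    cleanup_min_size: int = 9   # remove connected foreground components smaller than this
    cleanup_max_hole: int = 0   # fill holes smaller than this
    # a 2-component fit only counts as two populations when the mixture is
    # actually bimodal (mean separation in units of the larger component sd;
    # an equal-variance mixture is bimodal only above 2) and both classes
    # cover a nonnegligible share of the analyzed pixels
    min_separation: float = 2.0
    min_class_weight: float = 0.02
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        fit = FitConfig(**raw.pop("fit", {}))
        return cls(fit=fit, **raw)

    def as_dict(self) -> dict:
        return {
            "fit": vars(self.fit).copy(),
            "skip_stage2": self.skip_stage2,
            "foreground_rule": self.foreground_rule,
            "combiner": self.combiner,
            "cleanup_min_size": self.cleanup_min_size,
            "cleanup_max_hole": self.cleanup_max_hole,
            "min_separation": self.min_separation,
            "min_class_weight": self.min_class_weight,
            "seed": self.seed,
        }


@dataclass
class StageResult:
    pair: tuple[int, int]
    ebcm_ranking: list[BandPairScore]
    decision: ThresholdDecision
    mask: BinaryMask
    diff: DifferenceImage


@dataclass
class SegmentationResult:
    stage1: StageResult
    stage2: Optional[StageResult]
    final_mask: BinaryMask
    masked_cube: SpectralCube
    config: dict
    log: list[str] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable stage report (pairs, rankings, thresholds)."""
        def stage_dict(s: StageResult) -> dict:
            return {
                "pair": list(s.pair),
                "ebcm_top10": [
                    {"pair": list(r.pair), "ebcm": r.ebcm}
                    for r in s.ebcm_ranking[:10]
                ],
                "decision": s.decision.as_dict(),
                "mask_pixels": s.mask.n_true,
            }
        return {
            "stage1": stage_dict(self.stage1),
            "stage2": stage_dict(self.stage2) if self.stage2 else None,
            "final_mask_pixels": self.final_mask.n_true,
            "config": self.config,
            "log": self.log,
        }


def _central_window(shape: tuple[int, int]) -> tuple[slice, slice]:
    """The centered window covering 25% of the image area (half side lengths)."""
    m, n = shape
    return (slice(m // 4, m // 4 + m // 2), slice(n // 4, n // 4 + n // 2))


def _foreground_mask(
    diff: np.ndarray,
    decision: ThresholdDecision,
    restrict: np.ndarray | None,
    rule: str,
) -> tuple[np.ndarray, str]:
    """Binarize the difference image; return (mask, resolved side)."""
    above = diff >= decision.threshold
    below = ~above
    if restrict is not None:
        above &= restrict
        below &= restrict

    if decision.method == "kurtosis":
        # the tail-rejection rule already fixes the non-rejected side
        side = decision.foreground_side
    elif rule in ("above", "below"):
        side = rule
    elif rule == "larger_component":
        side = "above" if above.sum() >= below.sum() else "below"
    elif rule == "central":
        win = _central_window(diff.shape)
        side = "above" if above[win].sum() >= below[win].sum() else "below"
    else:
        raise ValueError(f"unknown foreground rule {rule!r}")
    return (above if side == "above" else below), side


def _cleanup(mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    if config.cleanup_min_size > 0:
        mask = morphology.remove_small_objects(mask, max_size=config.cleanup_min_size - 1)
    if config.cleanup_max_hole > 0:
        mask = morphology.remove_small_holes(mask, config.cleanup_max_hole)
    return mask


def segment_stage(
    cube: PreprocessedCube,
    restrict: BinaryMask | None = None,
    config: PipelineConfig | None = None,
    label: str = "custom",
) -> StageResult:
    """One band-selection + thresholding stage.

    Selects the minimum-EBCM band pair (within ``restrict`` when given),
    fits a 1-vs-2 component mixture to the winner's intensity histogram,
    thresholds by the Bayes rule (2 components) or tail rejection (1), and
    resolves the foreground side per the configured rule.
    """
    config = config or PipelineConfig()
    rmask = None
    if restrict is not None:
        if restrict.empty or not restrict.data.any():
            raise ValueError("empty restrict mask")
        if restrict.n_true < _MIN_RESTRICT_PIXELS:
            raise ValueError(
                f"restrict mask has {restrict.n_true} pixels; "
                f"need at least {_MIN_RESTRICT_PIXELS}"
            )
        rmask = restrict.data
        ranking, diff = select_band_pair_masked(cube, restrict, combiner=config.combiner)
    else:
        ranking, diff = select_band_pair(cube, combiner=config.combiner)

    values = diff.data[rmask] if rmask is not None else diff.data.ravel()
    model = select_model(values, config.fit)
    if model.C == 2:
        # MML answers "is the histogram better coded with two Gaussians";
        # segmentation additionally needs the two Gaussians to be two
        # *populations*: a bimodal split into classes of meaningful size.
        # Heavy tails or a speck of stray pixels can win the coding battle
        # without being a class; those cases take the unimodal path.
        sep = abs(model.means[1] - model.means[0]) / np.sqrt(model.variances.max())
        if sep < config.min_separation or model.weights.min() < config.min_class_weight:
            model = fit_em(values, 1, config.fit)
    if model.C == 2:
        decision = bayes_threshold(model)
    else:
        decision = kurtosis_threshold(values, model, config.fit)

    fg, side = _foreground_mask(diff.data, decision, rmask, config.foreground_rule)
    decision = replace(decision, foreground_side=side)
    fg = _cleanup(fg, config)
    mask = BinaryMask(data=fg, label=label, empty=not fg.any())
    return StageResult(
        pair=diff.pair, ebcm_ranking=ranking, decision=decision, mask=mask,
        diff=diff,
    )


def apply_mask(cube: SpectralCube, mask: BinaryMask) -> SpectralCube:
    """Set excluded pixels to NaN in every band; included pixels unchanged."""
    if mask.data.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if mask.empty or not mask.data.any():
        raise ValueError("refusing to apply an empty mask")
    out = cube.data.copy()
    out[~mask.data, :] = np.nan
    return bare_cube(out, cube.wavelengths.copy(), cube.source_id + "|masked")


def run_pipeline(cube: SpectralCube, config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full cascade on a reflectance cube.

    Deterministic for a fixed config.  A stage-2 failure (e.g. the stage-1
    mask leaves too few pixels, or no contrast remains) degrades gracefully
    to ``final_mask = stage1.mask`` with a logged warning.
    """
    config = config or PipelineConfig()
    log: list[str] = []

    bandnorm = normalize_bands(cube)
    snv_cube = snv(bandnorm)  # retained for spectral export downstream
    del snv_cube

    stage1 = segment_stage(bandnorm, None, config, label="foreground_stage1")
    log.append(
        f"stage1: pair={stage1.pair} ebcm={stage1.ebcm_ranking[0].ebcm:.6g} "
        f"method={stage1.decision.method} t={stage1.decision.threshold:.6g} "
        f"side={stage1.decision.foreground_side} pixels={stage1.mask.n_true}"
    )

    stage2: StageResult | None = None
    final = stage1.mask.data
    if not config.skip_stage2:
        try:
            stage2 = segment_stage(bandnorm, stage1.mask, config, label="custom")
            final = stage1.mask.data & stage2.mask.data
            log.append(
                f"stage2: pair={stage2.pair} method={stage2.decision.method} "
                f"t={stage2.decision.threshold:.6g} side={stage2.decision.foreground_side} "
                f"pixels={stage2.mask.n_true}"
            )
        except ValueError as exc:
            logger.warning("stage 2 failed (%s); keeping the stage-1 mask", exc)
            log.append(f"stage2 failed: {exc}")
            stage2 = None
            final = stage1.mask.data
    else:
        log.append("stage2 skipped by config")

    final_mask = BinaryMask(
        data=final, label="informative_final", empty=not final.any()
    )
    masked = apply_mask(cube, final_mask)
    return SegmentationResult(
        stage1=stage1, stage2=stage2, final_mask=final_mask,
        masked_cube=masked, config=config.as_dict(), log=log,
    )
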