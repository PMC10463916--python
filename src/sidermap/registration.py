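"""Serial-section co-registration and count-conserving warping.

Adjacent marker sections (GFAP, CD68) are mapped onto their iron
section: an affine transform (moments-initialized, mean-squares on
Gaussian-smoothed binary cortex masks) followed by a free-form B-spline
deformation.  Registration quality is the Dice overlap of the masks
after warping; sections below the threshold (default 0.90) are flagged
as failures and routed to the exclusion log by the pipeline.

Object count matrices are warped by resampling the rasterized mass with
linear interpolation and then rescaling by a single global factor
total_before / total_after, so the warped section carries exactly the
same number of objects as the source — the count-conservation step of
the emulated workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import SimpleITK as sitk

from .types import CountMatrix, GridSpec, SectionDetections


@dataclass
class TransformPair:
    """Affine + non-rigid transform mapping fixed-frame points into the
    moving section's frame (the resampling convention), with its quality."""

    transform: sitk.Transform
    quality: float  # Dice overlap of masks after warping
    failed: bool
    count_scale: float = 1.0
    resolution_um: float = 0.0

    def to_dict(self) -> dict:
        return {
            "quality": self.quality,
            "failed": bool(self.failed),
            "count_scale": self.count_scale,
        }


def _to_image(arr: np.ndarray, resolution_um: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(arr, dtype=np.float64))
    img.SetSpacing((float(resolution_um), float(resolution_um)))
    return img


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float((a & b).sum()) / float(denom)


def register_masks(
    fixed_mask: np.ndarray,
    moving_mask: np.ndarray,
    resolution_um: float,
    dice_threshold: float = 0.90,
    smooth_sigma_factor: float = 2.0,
    bspline_mesh: tuple[int, int] = (4, 3),
    bspline_iterations: int = 10,
    nonrigid: bool = True,
) -> TransformPair:
    """Estimate the affine + B-spline transform between two cortex masks.

    Both masks are Gaussian-smoothed so the mean-squares objective has a
    usable capture range.  The B-spline stage is kept coarse and
    early-stopped: a binary mask constrains a deformation only at its
    boundary, so an aggressively optimized free-form stage invents
    interior displacement the data cannot support.  Degenerate masks
    (< 10 in-cortex cells) are rejected outright.
    """
    fixed_mask = np.asarray(fixed_mask, bool)
    moving_mask = np.asarray(moving_mask, bool)
    for m, name in ((fixed_mask, "fixed"), (moving_mask, "moving")):
        if m.sum() < 10:
            raise ValueError(f"{name} mask is degenerate (< 10 cells)")
    sigma = smooth_sigma_factor * resolution_um
    fixed = sitk.SmoothingRecursiveGaussian(_to_image(fixed_mask, resolution_um), sigma)
    moving = sitk.SmoothingRecursiveGaussian(_to_image(moving_mask, resolution_um), sigma)

    affine = sitk.CenteredTransformInitializer(
        fixed,
        moving,
        sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=80, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(affine, inPlace=True)
    reg.Execute(fixed, moving)

    final: sitk.Transform = affine
    if nonrigid:
        bspline = sitk.BSplineTransformInitializer(fixed, list(bspline_mesh))
        reg2 = sitk.ImageRegistrationMethod()
        reg2.SetMetricAsMeanSquares()
        reg2.SetInterpolator(sitk.sitkLinear)
        reg2.SetOptimizerAsLBFGSB(
            gradientConvergenceTolerance=1e-7,
            numberOfIterations=bspline_iterations,
        )
        reg2.SetMovingInitialTransform(affine)
        reg2.SetInitialTransform(bspline, inPlace=True)
        reg2.SetShrinkFactorsPerLevel([2])
        reg2.SetSmoothingSigmasPerLevel([1.0])
        reg2.Execute(fixed, moving)
        composite = sitk.CompositeTransform(2)
        composite.AddTransform(affine)
        composite.AddTransform(bspline)
        final = composite

    warped = resample_mask(moving_mask, fixed_mask.shape, final, resolution_um)
    quality = _dice(fixed_mask, warped)
    return TransformPair(final, quality, quality < dice_threshold, 1.0, resolution_um)


def register_sections(
    fixed: SectionDetections,
    moving: SectionDetections,
    dice_threshold: float = 0.90,
    **kwargs,
) -> TransformPair:
    """Register a marker section's cortex mask onto its iron section."""
    if fixed.mask_resolution_um != moving.mask_resolution_um:
        raise ValueError("sections must share a mask resolution")
    return register_masks(
        fixed.cortex_mask,
        moving.cortex_mask,
        fixed.mask_resolution_um,
        dice_threshold=dice_threshold,
        **kwargs,
    )


def resample_mask(
    moving_mask: np.ndarray,
    fixed_shape: tuple[int, int],
    transform: sitk.Transform,
    resolution_um: float,
) -> np.ndarray:
    img = _to_image(np.asarray(moving_mask, float), resolution_um)
    ref = sitk.Image(int(fixed_shape[1]), int(fixed_shape[0]), sitk.sitkFloat64)
    ref.SetSpacing((resolution_um, resolution_um))
    out = sitk.Resample(img, ref, transform, sitk.sitkNearestNeighbor, 0.0)
    return sitk.GetArrayFromImage(out) > 0.5


def warp_counts(
    counts: CountMatrix,
    transform: TransformPair,
    fixed_shape: Optional[tuple[int, int]] = None,
) -> tuple[CountMatrix, float]:
    """Warp a count matrix into the fixed frame, conserving total mass.

    Linear resampling spreads each cell's mass over the target grid; the
    single global factor total_before / total_after then restores the
    exact source total.  Raises if the transform maps all mass off-grid.
    """
    grid = counts.grid
    res = grid.cell_size_um
    if fixed_shape is None:
        fixed_shape = grid.shape
    img = _to_image(counts.values, res)
    ref = sitk.Image(int(fixed_shape[1]), int(fixed_shape[0]), sitk.sitkFloat64)
    ref.SetSpacing((res, res))
    out = sitk.Resample(img, ref, transform.transform, sitk.sitkLinear, 0.0)
    warped = np.clip(sitk.GetArrayFromImage(out), 0.0, None)
    before = counts.total
    after = float(warped.sum())
    if before > 0 and after <= 0:
        raise ValueError("transform maps all object mass off-grid")
    scale = before / after if after > 0 else 1.0
    transform.count_scale = scale
    out_grid = GridSpec(grid.origin_x, grid.origin_y, res, fixed_shape[0], fixed_shape[1])
    return CountMatrix(warped * scale, out_grid), scale
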