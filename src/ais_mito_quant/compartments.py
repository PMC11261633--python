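"""Threshold-masked compartment intensities and the somatodendritic:axonal ratio.

The measurement mirrors the standard ImageJ workflow: the mitochondrial
channel is converted to floating point and thresholded to a single fixed
value, with sub-threshold voxels set to NaN; the mean intensity of a
compartment ROI is then the summed intensity of the remaining voxels
divided by their count ("summed intensity divided by the non-zero area").
The somatodendritic-to-axonal ratio divides the calyx mean by the
dorsal/alpha-lobe mean.

ROIs are 2-D polygons in physical (µm) coordinates applied as a prism to
every z-slice; thresholding removes out-of-structure background so the
prism does not dilute compartment means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from matplotlib.path import Path as _MplPath

from .errors import EmptyROIError, ValidationError
from .io import ImageStack, PolyROI, RectROI

__all__ = [
    "CompartmentMeasurement",
    "threshold_to_missing",
    "roi_mean_intensity",
    "somatodendritic_axonal_ratio",
]


@dataclass
class CompartmentMeasurement:
    """Per-hemisphere compartment means and their ratio."""

    fly_id: str
    hemisphere: str
    genotype: str
    age: str
    calyx_mean: float
    lobe_mean: float
    ratio: float
    nonmissing_area_calyx: int
    nonmissing_area_lobe: int


def threshold_to_missing(stack: ImageStack, t: float, channel: int = 0) -> ImageStack:
    """Set voxels strictly below ``t`` to NaN on the quantified channel.

    Values equal to the threshold survive (strict ``<``); other channels
    are untouched.
    """
    if not np.isfinite(t):
        raise ValidationError("threshold must be finite")
    out = stack.copy()
    if not np.issubdtype(out.voxels.dtype, np.floating):
        out.voxels = out.voxels.astype(np.float64)
    ch = out.voxels[channel]
    ch[ch < t] = np.nan
    return out


def roi_voxel_mask(
    roi: Union[PolyROI, RectROI], shape_yx: Tuple[int, int], voxel_size_yx: Tuple[float, float]
) -> np.ndarray:
    """Boolean (y, x) mask of voxel centres inside the ROI polygon."""
    if isinstance(roi, RectROI):
        roi = roi.as_polygon()
    ny, nx = shape_yx
    dy, dx = voxel_size_yx
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = _MplPath(roi.vertices).contains_points(pts)
    return inside.reshape(ny, nx)


def roi_mean_intensity(
    stack: ImageStack,
    roi: Union[PolyROI, RectROI],
    channel: int = 0,
    roi_name: str = "ROI",
) -> Tuple[float, int]:
    """Mean of non-missing voxels inside the ROI prism, with their count.

    Raises :class:`EmptyROIError` when no voxel inside the ROI survives
    (naming the ROI), and :class:`ValidationError` when the ROI does not
    intersect the image at all.
    """
    mask = roi_voxel_mask(roi, stack.shape_zyx[1:], stack.voxel_size[1:])
    if not mask.any():
        raise ValidationError(f"{roi_name} does not intersect the image")
    vox = stack.voxels[channel][:, mask]
    finite = np.isfinite(vox)
    n = int(finite.sum())
    if n == 0:
        raise EmptyROIError(f"empty {roi_name} after threshold")
    return float(vox[finite].sum() / n), n


def somatodendritic_axonal_ratio(
    stack: ImageStack,
    calyx_roi: Union[PolyROI, RectROI],
    lobe_roi: Union[PolyROI, RectROI],
    threshold: float,
    channel: int = 0,
    fly_id: str = "",
    hemisphere: str = "L",
    genotype: str = "",
    age: str = "",
) -> CompartmentMeasurement:
    """Threshold, measure both compartments, and form calyx / lobe.

    The same threshold is applied to both ROIs (one value per
    experiment); an empty-after-threshold compartment raises an error
    naming the offending ROI.
    """
    masked = threshold_to_missing(stack, threshold, channel=channel)
    calyx_mean, calyx_n = roi_mean_intensity(masked, calyx_roi, channel, roi_name="calyx ROI")
    lobe_mean, lobe_n = roi_mean_intensity(masked, lobe_roi, channel, roi_name="lobe ROI")
    return CompartmentMeasurement(
        fly_id=fly_id,
        hemisphere=hemisphere,
        genotype=genotype,
        age=age,
        calyx_mean=calyx_mean,
        lobe_mean=lobe_mean,
        ratio=calyx_mean / lobe_mean,
        nonmissing_area_calyx=calyx_n,
        nonmissing_area_lobe=lobe_n,
    )
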