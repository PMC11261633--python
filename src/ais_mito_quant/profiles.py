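"""Binned intensity profiles across the AIS and their group aggregation.

The workflow mirrors the published quantification: threshold the
mitochondrial channel, flatten the z-stack by maximum projection, lay a
rectangular ROI across the AIS region (its centre at the approximate AIS
centre), average intensity across the ROI width, bin it along the length
at ~0.41 µm, and normalise each image's trace to its own maximum.  Bin
positions are signed µm with 0 at the ROI centre and the distal direction
negative.  "Intensity histogram" in the original protocol is realised as
this spatial line profile (bins are positions, not intensity levels) —
that is the only reading that produces intensity-versus-position plots.

Resampling into the rotated ROI frame uses bilinear interpolation at 4x
oversampling with normalised-convolution handling of missing (NaN)
pixels: values and validity weights are interpolated separately and a
sample is kept only while at least half its interpolation weight comes
from valid pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError
from .io import ImageStack, RectROI

__all__ = [
    "IntensityProfile",
    "GroupProfile",
    "max_project",
    "extract_profile",
    "normalize_profile",
    "aggregate_group",
]


@dataclass
class IntensityProfile:
    """Binned 1-D intensity trace with signed spatial coordinates."""

    positions: np.ndarray   # bin centres, µm, strictly increasing at bin_width
    values: np.ndarray      # intensity per bin; NaN where no valid pixel
    bin_width: float
    normalized: bool = False
    source_id: Optional[str] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValidationError("positions and values must be equal-length 1-D arrays")
        if self.positions.size >= 2:
            steps = np.diff(self.positions)
            if np.any(steps <= 0) or not np.allclose(steps, self.bin_width, rtol=1e-6):
                raise ValidationError(
                    "positions must increase uniformly at bin_width"
                )
        if self.normalized:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not (
                np.nanmax(finite) <= 1.0 + 1e-9 and np.nanmin(finite) >= -1e-9
            ):
                raise ValidationError("normalized profile values must lie in [0, 1]")


@dataclass
class GroupProfile:
    """Per-bin mean ± SEM of normalised profiles over flies."""

    positions: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    n_per_bin: np.ndarray

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("group profile needs n >= 1")
        if np.any(self.sem[np.isfinite(self.sem)] < 0):
            raise ValidationError("sem must be >= 0")


def max_project(stack: ImageStack, channel: int = 0) -> np.ndarray:
    """Maximum projection over z, ignoring missing voxels.

    A pixel is missing in the projection only when it is missing in every
    slice.
    """
    vox = stack.voxels[channel]
    if vox.shape[0] < 1:
        raise ValidationError("stack must have at least one slice")
    finite_any = np.isfinite(vox).any(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        proj = np.nanmax(vox, axis=0)
    proj = np.where(finite_any, proj, np.nan)
    return proj


def extract_profile(
    image2d: np.ndarray,
    voxel_size_yx: tuple,
    roi: RectROI,
    bin_width: float,
    source_id: Optional[str] = None,
    oversample: int = 4,
) -> IntensityProfile:
    """Resample a projected image into the ROI frame and bin along its length.

    The number of bins is ``round(length / bin_width)``; bin centres span
    the ROI length symmetrically about the ROI centre (position 0), so
    positions run from -L'/2 to +L'/2 where L' = n_bins * bin_width.
    Intensities are averaged across the width axis and within each length
    bin; missing pixels are excluded and a bin with no valid sample is
    missing.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    image2d = np.asarray(image2d, dtype=float)
    dy, dx = float(voxel_size_yx[0]), float(voxel_size_yx[1])
    ny, nx = image2d.shape

    corners = roi.corners()
    if (
        corners[:, 0].min() < 0 or corners[:, 1].min() < 0
        or corners[:, 0].max() > nx * dx or corners[:, 1].max() > ny * dy
    ):
        raise ValidationError("ROI extends outside the image")

    n_bins = int(round(roi.length / bin_width))
    if n_bins < 1:
        raise ValidationError("ROI shorter than one bin")
    centers = (np.arange(n_bins) + 0.5) * bin_width - n_bins * bin_width / 2.0

    step = bin_width / oversample
    offsets = (np.arange(oversample) - (oversample - 1) / 2.0) * step
    s = (centers[:, None] + offsets[None, :]).ravel()           # length samples
    nw = max(1, int(round(roi.width / step)))
    t = (np.arange(nw) + 0.5) * (roi.width / nw) - roi.width / 2.0  # width samples

    u = roi.direction
    v = np.array([-u[1], u[0]])
    cx, cy = roi.center
    X = cx + s[:, None] * u[0] + t[None, :] * v[0]
    Y = cy + s[:, None] * u[1] + t[None, :] * v[1]
    rows = Y / dy - 0.5
    cols = X / dx - 0.5
    coords = np.stack([rows.ravel(), cols.ravel()])

    vals = np.nan_to_num(image2d, nan=0.0)
    weights = np.isfinite(image2d).astype(float)
    sv = map_coordinates(vals, coords, order=1, mode="constant", cval=0.0)
    sw = map_coordinates(weights, coords, order=1, mode="constant", cval=0.0)
    samples = np.where(sw > 0.5, sv / np.maximum(sw, 1e-12), np.nan)
    samples = samples.reshape(len(s), nw).reshape(n_bins, oversample, nw)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(samples, axis=(1, 2))

    return IntensityProfile(
        positions=centers,
        values=values,
        bin_width=bin_width,
        normalized=False,
        source_id=source_id,
    )


def normalize_profile(profile: IntensityProfile) -> IntensityProfile:
    """Divide by the trace maximum so the largest bin equals 1.

    Idempotent; raises when the profile is all-missing or its maximum is
    not positive.
    """
    finite = profile.values[np.isfinite(profile.values)]
    if finite.size == 0:
        raise ValidationError("cannot normalize an all-missing profile")
    m = finite.max()
    if m <= 0:
        raise ValidationError("cannot normalize a profile with non-positive maximum")
    return IntensityProfile(
        positions=profile.positions.copy(),
        values=profile.values / m,
        bin_width=profile.bin_width,
        normalized=True,
        source_id=profile.source_id,
    )


def aggregate_group(profiles: Sequence[IntensityProfile]) -> GroupProfile:
    """Per-bin mean and SEM (sample sd / sqrt(n)) over flies.

    All profiles must share the same position grid.  Bins with a single
    valid value report SEM 0 (with a warning); n per bin counts the
    non-missing values entering each bin.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("need at least one profile")
    pos = profiles[0].positions
    bw = profiles[0].bin_width
    for p in profiles[1:]:
        if p.positions.shape != pos.shape or not np.allclose(p.positions, pos, atol=1e-9):
            raise ValidationError("profiles have mismatched position grids")
    mat = np.vstack([p.values for p in profiles])
    n_per_bin = np.isfinite(mat).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n_per_bin > 1, sd / np.sqrt(np.maximum(n_per_bin, 1)), 0.0)
    sem = np.where(n_per_bin == 0, np.nan, sem)
    if np.any(n_per_bin == 1):
        warnings.warn(
            "some bins have a single valid profile; their SEM is reported as 0",
            UserWarning,
            stacklevel=2,
        )
    return GroupProfile(positions=pos.copy(), mean=mean, sem=sem,
                        n=len(profiles), n_per_bin=n_per_bin)
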