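"""AIS interval location and the chord-enclosed signal-dropout statistic.

The dropout statistic formalises a manual measurement: on the normalised
mitochondrial profile a straight chord is drawn joining the profile
values at the distal and proximal AIS edges, and the area enclosed
between chord and curve — counting only where the curve lies *below* the
chord, i.e. the depression — is the "area of mitochondrial signal
dropout" in µm (area under a unit-normalised intensity times µm).  The
companion quantity is the plain trapezoid integral of the normalised
intensity over the AIS interval.

AIS edges are either supplied (mirroring the original marker-guided
manual calls) or detected automatically from the normalised structural
marker profile as the longest contiguous run of bins falling below a
fraction of the flanking baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import TroughNotFoundError, ValidationError
from .profiles import IntensityProfile

__all__ = [
    "AisInterval",
    "DropoutResult",
    "detect_ais_interval",
    "chord_dropout_area",
    "integrated_ais_intensity",
]


@dataclass
class AisInterval:
    """AIS edges on the signed profile axis (distal < proximal, µm)."""

    distal_edge: float
    proximal_edge: float
    method: str = "manual"          # "manual" | "marker-trough"
    marker_channel_used: bool = False

    def __post_init__(self):
        if not self.distal_edge < self.proximal_edge:
            raise ValidationError("distal_edge must be < proximal_edge")

    @property
    def width(self) -> float:
        return self.proximal_edge - self.distal_edge


@dataclass
class DropoutResult:
    fly_id: str
    genotype: str
    age: str
    dropout_area: float
    integrated_intensity: float
    interval: AisInterval


def _check_interval(profile: IntensityProfile, interval: AisInterval) -> None:
    lo, hi = profile.positions[0], profile.positions[-1]
    if interval.distal_edge < lo - 1e-9 or interval.proximal_edge > hi + 1e-9:
        raise ValidationError(
            f"interval ({interval.distal_edge}, {interval.proximal_edge}) outside "
            f"profile range [{lo}, {hi}]"
        )


def _integration_grid(profile: IntensityProfile, interval: AisInterval):
    """Bin-centre nodes inside the interval plus interpolated endpoints."""
    if not profile.normalized:
        raise ValidationError("profile must be normalized")
    _check_interval(profile, interval)
    finite = np.isfinite(profile.values)
    if finite.sum() < 2:
        raise ValidationError("profile needs at least two valid bins")
    fp, fv = profile.positions[finite], profile.values[finite]
    xd = max(interval.distal_edge, profile.positions[0])
    xp = min(interval.proximal_edge, profile.positions[-1])
    inner = profile.positions[(profile.positions > xd) & (profile.positions < xp)]
    xs = np.concatenate([[xd], inner, [xp]])
    ys = np.interp(xs, fp, fv)   # linear interpolation, NaN bins bridged
    return xs, ys


def chord_dropout_area(profile: IntensityProfile, interval: AisInterval) -> float:
    """Area between the edge-to-edge chord and the profile, below the chord.

    With chord ``c(x)`` joining ``(x_d, y(x_d))`` and ``(x_p, y(x_p))``,
    returns the trapezoid-rule integral of ``max(c(x) - y(x), 0)`` over
    the interval (µm, non-negative).  Segments where the curve rises
    above the chord contribute nothing.
    """
    xs, ys = _integration_grid(profile, interval)
    x0, x1 = xs[0], xs[-1]
    c0, c1 = ys[0], ys[-1]
    diff = np.interp(xs, [x0, x1], [c0, c1]) - ys
    # insert chord/curve crossing points so the positive-part trapezoid is
    # exact for the piecewise-linear trace
    cross = np.flatnonzero(diff[:-1] * diff[1:] < 0)
    if cross.size:
        xc = xs[cross] + diff[cross] * (xs[cross + 1] - xs[cross]) / (
            diff[cross] - diff[cross + 1]
        )
        xs = np.sort(np.concatenate([xs, xc]))
        finite = np.isfinite(profile.values)
        ys = np.interp(xs, profile.positions[finite], profile.values[finite])
        diff = np.interp(xs, [x0, x1], [c0, c1]) - ys
    return float(np.trapezoid(np.maximum(diff, 0.0), xs))


def integrated_ais_intensity(profile: IntensityProfile, interval: AisInterval) -> float:
    """Trapezoid integral of the normalised intensity over the interval (µm)."""
    xs, ys = _integration_grid(profile, interval)
    return float(np.trapezoid(ys, xs))


def detect_ais_interval(
    marker_profile: IntensityProfile,
    trough_fraction: float = 0.6,
    min_run_um: float = 2.0,
) -> AisInterval:
    """Detect the AIS as the longest marker trough.

    The baseline is the median of the flanking 25% of bins at each end of
    the normalised marker profile; the trough is the longest contiguous
    run of bins below ``trough_fraction`` x baseline whose physical length
    is at least ``min_run_um``.  Edges are the outer boundaries of that
    run.  Ties keep the first (most distal) run.  Raises
    :class:`TroughNotFoundError` when no run qualifies, so callers can
    fall back to a manual interval.
    """
    if not marker_profile.normalized:
        raise ValidationError("marker profile must be normalized")
    vals = marker_profile.values
    pos = marker_profile.positions
    bw = marker_profile.bin_width
    n = vals.size
    k = max(1, int(round(0.25 * n)))
    flank = np.concatenate([vals[:k], vals[n - k:]])
    flank = flank[np.isfinite(flank)]
    if flank.size == 0:
        raise TroughNotFoundError("no valid flanking bins to establish a baseline")
    baseline = float(np.median(flank))
    thresh = trough_fraction * baseline

    below = np.isfinite(vals) & (vals < thresh)
    best = None
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            run_len = (j - i + 1) * bw
            if run_len >= min_run_um and (best is None or (j - i) > (best[1] - best[0])):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        raise TroughNotFoundError(
            f"no trough detected below {trough_fraction:.2f} x baseline "
            f"({thresh:.3f}) of at least {min_run_um} µm"
        )
    i, j = best
    return AisInterval(
        distal_edge=float(pos[i] - bw / 2.0),
        proximal_edge=float(pos[j] + bw / 2.0),
        method="marker-trough",
        marker_channel_used=True,
    )
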