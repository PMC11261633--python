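"""Reading and writing image stacks, ROIs, configuration and result tables.

Stacks are multi-channel 3-D voxel grids with a physical voxel size in
micrometres.  On disk they are multi-page TIFF files with ImageJ-style
metadata, stored as 32-bit float (the precision the analysis operates at,
since sub-threshold voxels are encoded as NaN).  ROIs live in physical
space (µm) and are stored one per file as small JSON documents with an
explicit units field; this avoids the ambiguity of binary ROI dialects
while remaining trivially convertible.  Tables are plain CSV with missing
values written as empty fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "ImageStack",
    "RectROI",
    "PolyROI",
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi",
    "write_table",
    "read_table",
]


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Multi-channel 3-D voxel grid.

    Parameters
    ----------
    voxels
        Array of shape ``(channel, z, y, x)``.  2-D input is promoted to a
        single-channel, single-slice stack and 3-D input to a single-channel
        stack.  Values are arbitrary real intensity units; NaN marks voxels
        removed by thresholding.
    voxel_size
        Physical voxel size ``(z, y, x)`` in µm; all components > 0.
    channel_names
        Optional channel labels; defaults to ``ch0, ch1, ...``.
    """

    voxels: np.ndarray
    voxel_size: tuple
    channel_names: Optional[list] = None

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis, np.newaxis]
        elif v.ndim == 3:
            v = v[np.newaxis]
        elif v.ndim != 4:
            raise ValidationError(
                f"stack must be 2-D, 3-D or 4-D, got {v.ndim}-D"
            )
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float64)
        self.voxels = v
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or any(s <= 0 or not math.isfinite(s) for s in vs):
            raise ValidationError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(v.shape[0])]
        if len(self.channel_names) != v.shape[0]:
            raise ValidationError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple:
        return self.voxels.shape[1:]

    @property
    def extent_um(self) -> tuple:
        """Physical extent (z, y, x) of the volume in µm."""
        return tuple(n * s for n, s in zip(self.shape_zyx, self.voxel_size))

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.voxel_size, list(self.channel_names))


@dataclass
class RectROI:
    """Rotatable rectangular ROI in physical (µm) coordinates.

    ``center`` is ``(x, y)`` in the projection plane, ``length`` the long
    axis, ``width`` the short axis and ``angle_deg`` the angle of the long
    axis measured counter-clockwise from the image x-axis.  Positions along
    the long axis are signed: negative toward the end the long-axis vector
    points away from (by convention the distal direction when the ROI is
    placed across an AIS).
    """

    center: tuple
    length: float
    width: float
    angle_deg: float = 0.0
    plane: str = "xy"

    def __post_init__(self):
        self.center = (float(self.center[0]), float(self.center[1]))
        self.length = float(self.length)
        self.width = float(self.width)
        self.angle_deg = float(self.angle_deg)
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("RectROI length and width must be > 0")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector (x, y) along the long axis (toward positive positions)."""
        a = math.radians(self.angle_deg)
        return np.array([math.cos(a), math.sin(a)])

    def corners(self) -> np.ndarray:
        """(4, 2) array of corner (x, y) positions in µm."""
        u = self.direction
        v = np.array([-u[1], u[0]])
        c = np.asarray(self.center)
        hl, hw = self.length / 2.0, self.width / 2.0
        return np.array([
            c - hl * u - hw * v,
            c + hl * u - hw * v,
            c + hl * u + hw * v,
            c - hl * u + hw * v,
        ])

    def as_polygon(self) -> "PolyROI":
        return PolyROI(vertices=self.corners(), plane=self.plane)


@dataclass
class PolyROI:
    """Simple polygon ROI in physical (µm) coordinates, vertices (x, y)."""

    vertices: np.ndarray
    plane: str = "xy"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("polygon needs at least 3 (x, y) vertices")
        poly = _ShapelyPolygon(v)
        if (not poly.is_valid) or poly.area <= 0:
            raise ValidationError("polygon must be simple (non-self-intersecting, non-degenerate)")
        self.vertices = v


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

_DEFAULT_GROUPS = [
    {"name": "WT", "genotype": "WT", "age": "larva",
     "exclusion_depth": 0.8, "exclusion_weight": "uniform"},
    {"name": "KO", "genotype": "KO", "age": "larva",
     "exclusion_depth": 0.0, "exclusion_weight": "uniform"},
]


@dataclass
class AnalysisConfig:
    """All tunable constants of an analysis run.

    The single intensity threshold is applied to the quantified
    (mitochondrial) channel of every image of an experiment, sub-threshold
    voxels becoming NaN.  ``roi_length`` maps age class to the length (µm)
    of the rectangular profile ROI (37 µm for larvae, 47 µm for adults by
    default).  ``ais_interval`` optionally fixes the AIS edges (distal,
    proximal) in signed profile coordinates; with ``boundary_method``
    ``"marker-trough"`` they are instead detected from the structural
    marker channel.
    """

    threshold: float = 15.0
    bin_width: float = 0.41
    roi_length: dict = field(default_factory=lambda: {"larva": 37.0, "adult": 47.0})
    roi_width: Optional[float] = None      # default: 2 x peduncle radius
    ais_interval: Optional[tuple] = None   # (distal, proximal) µm, signed
    boundary_method: str = "manual"        # "manual" | "marker-trough"
    alpha: float = 0.05
    seed: int = 0
    n_per_group: int = 8
    groups: list = field(default_factory=lambda: [dict(g) for g in _DEFAULT_GROUPS])
    geometry: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    puncta: dict = field(default_factory=dict)
    marker: dict = field(default_factory=dict)
    make_plots: bool = False

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.boundary_method not in ("manual", "marker-trough"):
            raise ConfigurationError(f"unknown boundary_method {self.boundary_method!r}")
        if self.ais_interval is not None:
            d, p = self.ais_interval
            if not d < p:
                raise ConfigurationError("ais_interval must satisfy distal < proximal")
            self.ais_interval = (float(d), float(p))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            try:
                d = yaml.safe_load(fh) or {}
            except yaml.YAMLError as e:
                raise FormatError(f"could not parse config {path}: {e}") from e
        if not isinstance(d, dict):
            raise FormatError(f"config {path} must be a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "bin_width": self.bin_width,
            "roi_length": dict(self.roi_length),
            "roi_width": self.roi_width,
            "ais_interval": list(self.ais_interval) if self.ais_interval else None,
            "boundary_method": self.boundary_method,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "groups": [dict(g) for g in self.groups],
            "geometry": dict(self.geometry),
            "acquisition": dict(self.acquisition),
            "puncta": dict(self.puncta),
            "marker": dict(self.marker),
            "make_plots": self.make_plots,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Stack I/O (TIFF)
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an ImageJ-style multi-page 32-bit float TIFF.

    Voxel size is recorded in the resolution tags (x, y) and the ImageJ
    ``spacing`` field (z), unit µm.
    """
    arr = np.moveaxis(stack.voxels.astype(np.float32), 0, 1)  # CZYX -> ZCYX
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
            "Labels": list(stack.channel_names),
        },
    )


def _resolution_from_tags(page, has_unit: bool) -> Optional[tuple]:
    """(dy, dx) from the resolution tags, or None when absent.

    Writers emit a placeholder (1, 1) resolution with ResolutionUnit NONE
    by default, so the tags only count as real metadata when the file
    also declares a unit (TIFF ResolutionUnit inch/cm, or an ImageJ-style
    unit field).
    """
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    resunit = page.tags.get("ResolutionUnit")
    if not has_unit and (resunit is None or int(resunit.value) < 2):
        return None
    if xres[0] == 0 or yres[0] == 0:
        return None
    dx = xres[1] / xres[0]
    dy = yres[1] / yres[0]
    return (dy, dx)


def read_stack(path, voxel_size: Optional[tuple] = None) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    2-D images are promoted to a 1-channel, 1-slice stack.  Voxel size is
    taken from the file metadata; if absent it must be supplied via
    ``voxel_size`` (z, y, x in µm), otherwise a :class:`FormatError` is
    raised.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes.upper()
            ij = tf.imagej_metadata
            res = _resolution_from_tags(tf.pages[0], has_unit=bool(ij and ij.get("unit")))
            labels = None
            if ij and "Labels" in ij:
                labels = list(ij["Labels"])
    except (tifffile.TiffFileError, ValueError, OSError) as e:
        raise FormatError(f"could not read TIFF {path}: {e}") from e

    axes = axes.replace("S", "C")
    if any(ax not in "CZYX" for ax in axes):
        raise FormatError(f"unsupported TIFF axes {axes!r} in {path}")
    for ax in "CZYX":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    arr = np.transpose(arr, [axes.index(ax) for ax in "CZYX"])

    if voxel_size is None:
        spacing = ij.get("spacing") if ij else None
        if res is None:
            raise FormatError(
                f"{path} carries no resolution metadata; supply voxel_size explicitly"
            )
        if spacing is None:
            if arr.shape[1] > 1:
                raise FormatError(
                    f"{path} has multiple slices but no z spacing metadata; "
                    "supply voxel_size explicitly"
                )
            spacing = 1.0
        voxel_size = (float(spacing), res[0], res[1])

    if labels is not None and len(labels) != arr.shape[0]:
        labels = None
    return ImageStack(arr, voxel_size, labels)


# ---------------------------------------------------------------------------
# ROI I/O (JSON text)
# ---------------------------------------------------------------------------


def write_roi(roi: Union[RectROI, PolyROI], path) -> None:
    if isinstance(roi, RectROI):
        doc = {
            "type": "rect",
            "units": "um",
            "center": list(roi.center),
            "length": roi.length,
            "width": roi.width,
            "angle_deg": roi.angle_deg,
            "plane": roi.plane,
        }
    elif isinstance(roi, PolyROI):
        doc = {
            "type": "polygon",
            "units": "um",
            "vertices": [list(v) for v in roi.vertices],
            "plane": roi.plane,
        }
    else:
        raise ValidationError(f"unsupported ROI type {type(roi).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_roi(path) -> Union[RectROI, PolyROI]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(
                f"could not parse ROI file {path}: {e.msg} at line {e.lineno}, column {e.colno}"
            ) from e
    if not isinstance(doc, dict) or "type" not in doc:
        raise FormatError(f"ROI file {path} lacks a 'type' field")
    units = doc.get("units", "um")
    if units != "um":
        raise FormatError(f"ROI file {path}: unsupported units {units!r}")
    kind = doc["type"]
    try:
        if kind == "rect":
            return RectROI(
                center=tuple(doc["center"]),
                length=doc["length"],
                width=doc["width"],
                angle_deg=doc.get("angle_deg", 0.0),
                plane=doc.get("plane", "xy"),
            )
        if kind == "polygon":
            return PolyROI(vertices=np.asarray(doc["vertices"], dtype=float),
                           plane=doc.get("plane", "xy"))
    except KeyError as e:
        raise FormatError(f"ROI file {path} missing field {e}") from e
    raise FormatError(f"ROI file {path}: unknown ROI type {kind!r}")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_table(
    rows: Union[Sequence[dict], pd.DataFrame], path, columns: Optional[Sequence[str]] = None
) -> None:
    """Write rows to CSV with deterministic column order.

    Column order follows the first row (or the DataFrame's columns, or
    ``columns`` for an empty row list, which then yields a header-only
    file); missing values are encoded as empty fields.  Rows whose key
    sets differ raise a :class:`ValidationError`.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            cols = list(rows[0].keys())
            colset = set(cols)
            for i, r in enumerate(rows):
                if set(r.keys()) != colset:
                    raise ValidationError(
                        f"row {i} has columns {sorted(r.keys())}, expected {sorted(colset)}"
                    )
            df = pd.DataFrame(rows, columns=cols)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
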