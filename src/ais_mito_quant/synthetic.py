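"""Synthetic two-channel confocal stacks of a mushroom-body-like neuron.

The simulated scene is a stylised mushroom body: a spherical calyx
(somatodendritic compartment, cell bodies + dendrites), a cylindrical
peduncle (proximal axon bundle) containing the axon initial segment (AIS)
as a sub-interval, and a cylindrical axonal lobe.  Channel 0 carries a
punctate mitochondrial signal: puncta are placed by a Poisson point
process with per-compartment densities, thinned inside the AIS by a
configurable exclusion depth, and rendered as 3-D Gaussian spots whose
width combines the physical punctum size with the point-spread function.
Channel 1 carries a structural marker filling the whole neuron but
attenuated inside the AIS, emulating markers (actin, FasII) whose local
depletion demarcates the AIS.  Shot (Poisson) and read (Gaussian) noise
emulate confocal acquisition.

Coordinates are physical µm throughout, ordered (z, y, x) to match the
voxel grid; voxel indices are 0-based and voxel centres sit at
``(i + 0.5) * voxel_size``.  Positions along the peduncle axis are signed
in downstream profiles such that the distal direction (toward the lobe)
is negative.

Determinism: every sampling step takes a seed or ``numpy`` Generator;
cohorts derive one child seed per stack from the master seed via
``np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index,
stack_index))``, so adding stacks or groups never reshuffles existing
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ValidationError
from .io import ImageStack

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "CompartmentGeometry",
    "PunctaModel",
    "AcquisitionModel",
    "MarkerModel",
    "Punctum",
    "GroundTruth",
    "GroupSpec",
    "CohortSample",
    "build_label_volume",
    "sample_puncta",
    "render_stack",
    "simulate_stack",
    "generate_cohort",
    "small_geometry",
]

LABELS = {
    "background": 0,
    "calyx": 1,
    "ais": 2,
    "axon_proximal": 3,
    "axon_lobe": 4,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: Compartments that belong to the neuron (everything but background).
NEURON_LABELS = (LABELS["calyx"], LABELS["ais"], LABELS["axon_proximal"], LABELS["axon_lobe"])

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class CompartmentGeometry:
    """Physical layout of the synthetic mushroom body.

    All positions are (z, y, x) µm.  The peduncle axis runs from its
    distal end (``peduncle_axis[0]``, toward the lobe) to its proximal end
    (``peduncle_axis[1]``, toward the calyx); ``ais_interval`` gives the
    AIS (distal, proximal) as arc-length positions along that axis and
    must lie strictly inside the segment.  The default scene is a
    scaled-down mushroom body in a 20 x 40 x 120 µm field of view with the
    calyx at high x and the lobe at low x, so signed profile positions
    (distal negative) simply follow -x to +x.
    """

    calyx_center: tuple = (10.0, 20.0, 95.0)
    calyx_radius: float = 9.0
    peduncle_axis: tuple = ((10.0, 20.0, 45.0), (10.0, 20.0, 87.0))
    peduncle_radius: float = 3.0
    ais_interval: tuple = (15.0, 29.0)
    lobe_axis: tuple = ((10.0, 20.0, 7.0), (10.0, 20.0, 45.0))
    lobe_radius: float = 6.0
    field_of_view: tuple = (20.0, 40.0, 120.0)
    voxel_size: tuple = (1.0, 0.25, 0.25)

    def __post_init__(self):
        self.calyx_center = tuple(float(c) for c in self.calyx_center)
        self.peduncle_axis = tuple(tuple(float(c) for c in p) for p in self.peduncle_axis)
        self.lobe_axis = tuple(tuple(float(c) for c in p) for p in self.lobe_axis)
        self.ais_interval = tuple(float(t) for t in self.ais_interval)
        self.field_of_view = tuple(float(c) for c in self.field_of_view)
        self.voxel_size = tuple(float(c) for c in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ConfigurationError("voxel_size components must be > 0")
        if any(f <= 0 for f in self.field_of_view):
            raise ConfigurationError("field_of_view components must be > 0")
        if min(self.calyx_radius, self.peduncle_radius, self.lobe_radius) < 0:
            raise ConfigurationError("radii must be >= 0")
        d, p = self.ais_interval
        if not (0.0 < d < p < self.peduncle_length):
            raise ConfigurationError(
                "ais_interval must lie strictly within the peduncle axis segment"
            )
        self._check_fits()

    # -- axis helpers -------------------------------------------------------

    @property
    def peduncle_length(self) -> float:
        p0, p1 = (np.asarray(p) for p in self.peduncle_axis)
        return float(np.linalg.norm(p1 - p0))

    @property
    def peduncle_direction(self) -> np.ndarray:
        """Unit vector (z, y, x) from distal to proximal end."""
        p0, p1 = (np.asarray(p) for p in self.peduncle_axis)
        return (p1 - p0) / np.linalg.norm(p1 - p0)

    def axis_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Arc-length position of (z, y, x) points along the peduncle axis."""
        p0 = np.asarray(self.peduncle_axis[0])
        return np.asarray(points - p0) @ self.peduncle_direction

    @property
    def ais_center_point(self) -> np.ndarray:
        """(z, y, x) µm of the AIS midpoint."""
        p0 = np.asarray(self.peduncle_axis[0])
        t = 0.5 * (self.ais_interval[0] + self.ais_interval[1])
        return p0 + t * self.peduncle_direction

    @property
    def ais_half_length(self) -> float:
        return 0.5 * (self.ais_interval[1] - self.ais_interval[0])

    @property
    def shape_zyx(self) -> tuple:
        return tuple(
            int(round(f / s)) for f, s in zip(self.field_of_view, self.voxel_size)
        )

    # -- validation ---------------------------------------------------------

    def _check_fits(self):
        fov = np.asarray(self.field_of_view)

        def check(lo, hi, what):
            if np.any(np.asarray(lo) < -1e-9) or np.any(np.asarray(hi) > fov + 1e-9):
                raise ConfigurationError(f"{what} exceeds the field of view")

        if self.calyx_radius > 0:
            c = np.asarray(self.calyx_center)
            check(c - self.calyx_radius, c + self.calyx_radius, "calyx")
        for name, axis, r in (
            ("peduncle", self.peduncle_axis, self.peduncle_radius),
            ("lobe", self.lobe_axis, self.lobe_radius),
        ):
            if r > 0:
                p0, p1 = (np.asarray(p) for p in axis)
                check(np.minimum(p0, p1) - r, np.maximum(p0, p1) + r, name)


def small_geometry() -> CompartmentGeometry:
    """A reduced scene (12 x 24 x 80 µm) for quick tests and fixtures."""
    return CompartmentGeometry(
        calyx_center=(6.0, 12.0, 62.0),
        calyx_radius=5.5,
        peduncle_axis=((6.0, 12.0, 28.0), (6.0, 12.0, 57.0)),
        peduncle_radius=2.5,
        ais_interval=(10.0, 20.0),
        lobe_axis=((6.0, 12.0, 4.0), (6.0, 12.0, 28.0)),
        lobe_radius=4.0,
        field_of_view=(12.0, 24.0, 80.0),
        voxel_size=(1.0, 0.25, 0.25),
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class PunctaModel:
    """Puncta placement model.

    ``density`` is puncta per µm³ per compartment.  Inside the AIS the
    base density is thinned by ``1 - d * w(u)`` where ``d`` is the
    exclusion depth, ``u`` the normalised axial position (0 at the distal
    edge, 1 at the proximal edge) and ``w`` the exclusion weight:
    ``"uniform"`` (w = 1, the larval pattern of depletion throughout the
    AIS) or ``"proximal-weighted"`` (w = u, a linear ramp strongest at the
    proximal edge, the adult pattern).  ``punctum_amplitude`` is the
    (mean, sd) of the rendered peak intensity; ``punctum_sigma`` the
    physical Gaussian radius of one punctum in µm.
    """

    density: dict = field(default_factory=lambda: {
        "calyx": 1.0, "ais": 1.0, "axon_proximal": 1.0, "axon_lobe": 1.0,
    })
    ais_exclusion_depth: float = 0.8
    ais_exclusion_weight: str = "uniform"
    punctum_amplitude: tuple = (100.0, 20.0)
    punctum_sigma: float = 0.5

    def __post_init__(self):
        for k, v in self.density.items():
            if k not in LABELS or k == "background":
                raise ValidationError(f"unknown compartment {k!r} in density map")
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"density for {k!r} must be finite and >= 0")
        if not (0.0 <= self.ais_exclusion_depth <= 1.0):
            raise ValidationError("ais_exclusion_depth must lie in [0, 1]")
        if self.ais_exclusion_weight not in ("uniform", "proximal-weighted"):
            raise ValidationError(
                f"unknown exclusion weight {self.ais_exclusion_weight!r}"
            )
        if self.punctum_sigma <= 0:
            raise ValidationError("punctum_sigma must be > 0")


@dataclass
class AcquisitionModel:
    """Confocal acquisition: PSF blur, background and noise.

    ``psf_sigma`` is the Gaussian PSF sigma (z, y, x) in µm (None disables
    blur).  ``poisson_scale`` converts intensity to expected photon counts
    (0 disables shot noise); ``read_noise_sd`` is additive Gaussian noise;
    ``bit_depth_clip`` optionally saturates intensities.
    """

    psf_sigma: Optional[tuple] = (1.0, 0.25, 0.25)
    background_level: float = 5.0
    poisson_scale: float = 2.0
    read_noise_sd: float = 1.0
    bit_depth_clip: Optional[float] = None

    def __post_init__(self):
        if self.psf_sigma is not None:
            self.psf_sigma = tuple(float(s) for s in self.psf_sigma)
            if any(s <= 0 for s in self.psf_sigma):
                raise ValidationError("psf_sigma components must be > 0 when blur is enabled")
        if self.background_level < 0 or self.poisson_scale < 0 or self.read_noise_sd < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class MarkerModel:
    """Structural AIS marker channel: fills the neuron, dims inside the AIS."""

    level: float = 100.0
    ais_attenuation: float = 0.3

    def __post_init__(self):
        if self.level < 0 or not (0.0 <= self.ais_attenuation <= 1.0):
            raise ValidationError("marker level >= 0 and attenuation in [0, 1] required")


@dataclass
class Punctum:
    position: tuple       # (z, y, x) µm
    amplitude: float
    compartment: str


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    label_volume: np.ndarray
    puncta: list
    true_ais_interval: tuple      # (distal, proximal) signed µm on the profile axis
    true_density_ratio: float     # calyx density / lobe density
    ais_center: tuple             # (z, y, x) µm
    geometry: CompartmentGeometry

    def compartment_counts(self) -> dict:
        out = {}
        for p in self.puncta:
            out[p.compartment] = out.get(p.compartment, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _voxel_centers(geom: CompartmentGeometry):
    nz, ny, nx = geom.shape_zyx
    dz, dy, dx = geom.voxel_size
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    return z, y, x


def _cylinder_mask(z, y, x, p0, p1, radius):
    """Boolean mask of voxel centres inside a finite cylinder (broadcast grid)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if radius <= 0 or length == 0:
        return None
    u = axis / length
    rz = z[:, None, None] - p0[0]
    ry = y[None, :, None] - p0[1]
    rx = x[None, None, :] - p0[2]
    t = rz * u[0] + ry * u[1] + rx * u[2]
    d2 = (rz - t * u[0]) ** 2 + (ry - t * u[1]) ** 2 + (rx - t * u[2]) ** 2
    return (t >= 0) & (t <= length) & (d2 <= radius ** 2)


def build_label_volume(geometry: CompartmentGeometry) -> np.ndarray:
    """Per-voxel compartment labels partitioning the volume.

    Labels: 0 background, 1 calyx, 2 AIS, 3 proximal axon (peduncle
    outside the AIS), 4 axonal lobe.  Where structures overlap the
    priority is calyx > AIS > proximal axon > lobe, so every voxel carries
    exactly one label.
    """
    z, y, x = _voxel_centers(geometry)
    labels = np.zeros(geometry.shape_zyx, dtype=np.uint8)

    lobe = _cylinder_mask(z, y, x, *geometry.lobe_axis, geometry.lobe_radius)
    if lobe is not None:
        labels[lobe] = LABELS["axon_lobe"]

    ped = _cylinder_mask(z, y, x, *geometry.peduncle_axis, geometry.peduncle_radius)
    if ped is not None:
        labels[ped] = LABELS["axon_proximal"]
        p0 = np.asarray(geometry.peduncle_axis[0])
        u = geometry.peduncle_direction
        t = (
            (z[:, None, None] - p0[0]) * u[0]
            + (y[None, :, None] - p0[1]) * u[1]
            + (x[None, None, :] - p0[2]) * u[2]
        )
        d, p = geometry.ais_interval
        labels[ped & (t >= d) & (t < p)] = LABELS["ais"]

    if geometry.calyx_radius > 0:
        c = np.asarray(geometry.calyx_center)
        d2 = (
            (z[:, None, None] - c[0]) ** 2
            + (y[None, :, None] - c[1]) ** 2
            + (x[None, None, :] - c[2]) ** 2
        )
        labels[d2 <= geometry.calyx_radius ** 2] = LABELS["calyx"]

    return labels


def sample_puncta(
    label_volume: np.ndarray,
    geometry: CompartmentGeometry,
    model: PunctaModel,
    seed: SeedLike,
) -> list:
    """Sample puncta positions/amplitudes per compartment.

    Per-compartment counts are Poisson with mean density x compartment
    volume; puncta are uniform over the compartment's voxels (with
    sub-voxel jitter).  AIS puncta are thinned by ``1 - d * w(u)``.
    Deterministic for a fixed seed.
    """
    rng = _rng(seed)
    vox_vol = float(np.prod(geometry.voxel_size))
    vs = np.asarray(geometry.voxel_size)
    shape = label_volume.shape
    puncta: list = []
    amp_mean, amp_sd = model.punctum_amplitude
    d = model.ais_exclusion_depth
    t_d, t_p = geometry.ais_interval

    for comp in ("calyx", "ais", "axon_proximal", "axon_lobe"):
        density = model.density.get(comp, 0.0)
        idx = np.flatnonzero(label_volume == LABELS[comp])
        if density == 0.0 or idx.size == 0:
            continue
        lam = density * idx.size * vox_vol
        n = rng.poisson(lam)
        if n == 0:
            continue
        chosen = idx[rng.integers(0, idx.size, size=n)]
        ijk = np.column_stack(np.unravel_index(chosen, shape))
        pos = (ijk + rng.uniform(0.0, 1.0, size=(n, 3))) * vs
        amps = np.clip(rng.normal(amp_mean, amp_sd, size=n), 0.0, None)
        if comp == "ais" and d > 0:
            t = geometry.axis_coordinate(pos)
            u = np.clip((t - t_d) / (t_p - t_d), 0.0, 1.0)
            w = np.ones_like(u) if model.ais_exclusion_weight == "uniform" else u
            keep = rng.uniform(size=n) < 1.0 - d * w
            pos, amps = pos[keep], amps[keep]
        for p, a in zip(pos, amps):
            puncta.append(Punctum(position=tuple(p), amplitude=float(a), compartment=comp))
    return puncta


def _render_puncta(
    volume: np.ndarray,
    voxel_size: tuple,
    puncta: Sequence[Punctum],
    sigma_zyx: np.ndarray,
    cutoff: float = 6.0,
) -> None:
    """Add separable Gaussian spots (peak amplitude) evaluated at voxel centres.

    Truncated at ``cutoff`` sigmas; the default keeps truncation error
    below 2e-8 of the peak amplitude.
    """
    axes_centers = [
        (np.arange(n) + 0.5) * s for n, s in zip(volume.shape, voxel_size)
    ]
    for p in puncta:
        lo, hi, gs = [], [], []
        skip = False
        for ax in range(3):
            c = p.position[ax]
            s = sigma_zyx[ax]
            step = voxel_size[ax]
            i0 = max(0, int(math.floor((c - cutoff * s) / step)))
            i1 = min(volume.shape[ax], int(math.ceil((c + cutoff * s) / step)) + 1)
            if i1 <= i0:
                skip = True
                break
            centers = axes_centers[ax][i0:i1]
            gs.append(np.exp(-0.5 * ((centers - c) / s) ** 2))
            lo.append(i0)
            hi.append(i1)
        if skip:
            continue
        volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += p.amplitude * np.einsum(
            "i,j,k->ijk", gs[0], gs[1], gs[2]
        )


def _apply_noise(channel: np.ndarray, acq: AcquisitionModel, rng: np.random.Generator) -> np.ndarray:
    if acq.poisson_scale > 0:
        channel = rng.poisson(np.clip(channel, 0.0, None) * acq.poisson_scale) / acq.poisson_scale
    if acq.read_noise_sd > 0:
        channel = channel + rng.normal(0.0, acq.read_noise_sd, size=channel.shape)
    if acq.bit_depth_clip is not None:
        channel = np.clip(channel, None, acq.bit_depth_clip)
    return channel


def render_stack(
    label_volume: np.ndarray,
    voxel_size: tuple,
    puncta: Sequence[Punctum],
    acquisition: AcquisitionModel,
    marker: MarkerModel,
    seed: SeedLike,
    punctum_sigma: float = 0.5,
) -> ImageStack:
    """Render the two-channel stack.

    Channel 0 ("mito"): background + Gaussian puncta whose per-axis sigma
    combines the punctum size with the PSF (a Gaussian spot imaged through
    a Gaussian PSF stays Gaussian); amplitude is the post-blur peak.
    Channel 1 ("marker"): background + structural marker filling the
    neuron, attenuated inside the AIS, blurred by the PSF.  Identical
    seeds give identical stacks.
    """
    rng = _rng(seed)
    shape = label_volume.shape
    fov = np.asarray(shape) * np.asarray(voxel_size)
    for p in puncta:
        if any(c < 0 or c > f for c, f in zip(p.position, fov)):
            raise ValidationError(f"punctum at {p.position} lies outside the volume")

    if acquisition.psf_sigma is not None:
        sigma = np.sqrt(np.asarray(acquisition.psf_sigma) ** 2 + punctum_sigma ** 2)
        psf_vox = np.asarray(acquisition.psf_sigma) / np.asarray(voxel_size)
    else:
        sigma = np.full(3, float(punctum_sigma))
        psf_vox = None

    mito = np.full(shape, float(acquisition.background_level))
    _render_puncta(mito, voxel_size, puncta, sigma)

    m = np.isin(label_volume, NEURON_LABELS).astype(float)
    m[label_volume == LABELS["ais"]] *= marker.ais_attenuation
    if psf_vox is not None:
        m = gaussian_filter(m, sigma=psf_vox, mode="nearest")
    mark = acquisition.background_level + marker.level * m

    mito = _apply_noise(mito, acquisition, rng)
    mark = _apply_noise(mark, acquisition, rng)
    return ImageStack(
        np.stack([mito, mark]), tuple(voxel_size), ["mito", "marker"]
    )


def simulate_stack(
    geometry: CompartmentGeometry,
    puncta_model: PunctaModel,
    acquisition: AcquisitionModel,
    marker: MarkerModel,
    seed: SeedLike,
) -> tuple:
    """Build labels, sample puncta and render; returns (stack, ground truth)."""
    rng = _rng(seed)
    labels = build_label_volume(geometry)
    puncta = sample_puncta(labels, geometry, puncta_model, rng)
    stack = render_stack(
        labels, geometry.voxel_size, puncta, acquisition, marker, rng,
        punctum_sigma=puncta_model.punctum_sigma,
    )
    h = geometry.ais_half_length
    dens = puncta_model.density
    lobe_d = dens.get("axon_lobe", 0.0)
    ratio = dens.get("calyx", 0.0) / lobe_d if lobe_d > 0 else float("nan")
    truth = GroundTruth(
        label_volume=labels,
        puncta=puncta,
        true_ais_interval=(-h, h),
        true_density_ratio=ratio,
        ais_center=tuple(geometry.ais_center_point),
        geometry=geometry,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One experimental group: a genotype-like condition at an age-like level.

    Wild-type-like groups use a positive ``exclusion_depth`` (mitochondria
    kept out of the AIS); knockout-like groups use ~0 (exclusion lost).
    """

    name: str
    genotype: str
    age: str = "larva"
    exclusion_depth: float = 0.8
    exclusion_weight: str = "uniform"
    density: Optional[dict] = None

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown group keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CohortSample:
    group: GroupSpec
    index: int
    fly_id: str
    stack: ImageStack
    truth: GroundTruth


def generate_cohort(
    groups: Sequence[GroupSpec],
    n_per_group: int,
    master_seed: int,
    geometry: Optional[CompartmentGeometry] = None,
    puncta_model: Optional[PunctaModel] = None,
    acquisition: Optional[AcquisitionModel] = None,
    marker: Optional[MarkerModel] = None,
) -> list:
    """Simulate ``n_per_group`` independent stacks for each group.

    Per-stack seeds derive from the master seed by the spawn-key rule
    documented in the module docstring, so cohorts are reproducible and
    extensible without reshuffling existing stacks.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if not groups:
        raise ValidationError("at least one group is required")
    geometry = geometry or CompartmentGeometry()
    puncta_model = puncta_model or PunctaModel()
    acquisition = acquisition or AcquisitionModel()
    marker = marker or MarkerModel()

    samples = []
    for gi, group in enumerate(groups):
        dens = dict(puncta_model.density)
        if group.density:
            dens.update(group.density)
        gmodel = PunctaModel(
            density=dens,
            ais_exclusion_depth=group.exclusion_depth,
            ais_exclusion_weight=group.exclusion_weight,
            punctum_amplitude=puncta_model.punctum_amplitude,
            punctum_sigma=puncta_model.punctum_sigma,
        )
        for si in range(n_per_group):
            ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(gi, si))
            stack, truth = simulate_stack(
                geometry, gmodel, acquisition, marker, np.random.default_rng(ss)
            )
            samples.append(
                CohortSample(
                    group=group,
                    index=si,
                    fly_id=f"{group.name}_{si:02d}",
                    stack=stack,
                    truth=truth,
                )
            )
    return samples
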