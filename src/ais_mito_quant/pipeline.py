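"""End-to-end orchestration: simulate -> quantify -> profile -> dropout -> stats.

A run takes one :class:`~ais_mito_quant.io.AnalysisConfig`, simulates (or
loads) a cohort, measures every stack, aggregates profiles per group,
runs the configured statistics, and writes everything as CSV plus a JSON
manifest.  The manifest records the full configuration snapshot, the
master seed and a SHA-256 hash of every output file, because the one
fixed intensity threshold and the ROI/interval constants are otherwise
unrecoverable from the outputs.  Reruns with the same config and seed
produce byte-identical CSVs and therefore identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compartments import somatodendritic_axonal_ratio, threshold_to_missing
from .dropout import (
    AisInterval,
    TroughNotFoundError,
    chord_dropout_area,
    detect_ais_interval,
    integrated_ais_intensity,
)
from .errors import ConfigurationError, PipelineError, ValidationError
from .io import (
    AnalysisConfig,
    ImageStack,
    PolyROI,
    RectROI,
    write_roi,
    write_stack,
    write_table,
)
from .profiles import aggregate_group, extract_profile, max_project, normalize_profile
from .stats import collapse_replicates, compare_two_groups, compare_two_way
from .synthetic import (
    AcquisitionModel,
    CompartmentGeometry,
    GroupSpec,
    MarkerModel,
    PunctaModel,
    generate_cohort,
    simulate_stack,
    small_geometry,
)

__all__ = [
    "RunManifest",
    "PipelineResult",
    "default_calyx_roi",
    "default_lobe_roi",
    "profile_roi",
    "analyze_sample",
    "run_pipeline",
    "make_fixtures",
]

METRICS = ["ratio", "dropout_area", "integrated_intensity"]


# ---------------------------------------------------------------------------
# Geometry-derived ROIs
# ---------------------------------------------------------------------------


def default_calyx_roi(geometry: CompartmentGeometry, n_vertices: int = 24) -> PolyROI:
    """Polygonal ROI inscribed in the calyx (75% of its radius)."""
    cz, cy, cx = geometry.calyx_center
    r = 0.75 * geometry.calyx_radius
    ang = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    return PolyROI(vertices=verts)


def default_lobe_roi(geometry: CompartmentGeometry, end_inset: float = 3.0) -> PolyROI:
    """Rectangular ROI inside the lobe cylinder, inset from both ends."""
    p0 = np.asarray(geometry.lobe_axis[0])
    p1 = np.asarray(geometry.lobe_axis[1])
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length
    a = p0 + end_inset * u
    b = p1 - end_inset * u
    # in-plane (x, y) frame
    uxy = np.array([u[2], u[1]])
    nxy = np.array([-uxy[1], uxy[0]])
    hw = 0.67 * geometry.lobe_radius
    axy = np.array([a[2], a[1]])
    bxy = np.array([b[2], b[1]])
    verts = np.array([
        axy - hw * nxy, bxy - hw * nxy, bxy + hw * nxy, axy + hw * nxy,
    ])
    return PolyROI(vertices=verts)


def profile_roi(
    geometry: CompartmentGeometry,
    length: float,
    width: Optional[float] = None,
) -> RectROI:
    """Rectangular profile ROI across the AIS, centred on the AIS midpoint.

    The long axis follows the peduncle from distal to proximal, so signed
    profile positions are negative toward the distal axon.
    """
    c = geometry.ais_center_point      # (z, y, x)
    u = geometry.peduncle_direction    # (z, y, x)
    angle = float(np.degrees(np.arctan2(u[1], u[2])))
    return RectROI(
        center=(float(c[2]), float(c[1])),
        length=length,
        width=width if width is not None else 2.0 * geometry.peduncle_radius,
        angle_deg=angle,
    )


# ---------------------------------------------------------------------------
# Per-sample measurement
# ---------------------------------------------------------------------------


def analyze_sample(
    stack: ImageStack,
    geometry: CompartmentGeometry,
    config: AnalysisConfig,
    age: str,
    fly_id: str = "",
    genotype: str = "",
    true_interval: Optional[tuple] = None,
    hemisphere: str = "L",
) -> dict:
    """Measure one stack: compartment ratio, AIS profile, dropout statistics.

    Returns a flat row dict plus the normalised mitochondrial profile
    (under key ``"profile"``) for group aggregation.
    """
    if age not in config.roi_length:
        raise ConfigurationError(f"no roi_length configured for age {age!r}")

    meas = somatodendritic_axonal_ratio(
        stack,
        default_calyx_roi(geometry),
        default_lobe_roi(geometry),
        config.threshold,
        fly_id=fly_id,
        hemisphere=hemisphere,
        genotype=genotype,
        age=age,
    )

    roi = profile_roi(geometry, config.roi_length[age], config.roi_width)
    masked = threshold_to_missing(stack, config.threshold, channel=0)
    mito_img = max_project(masked, channel=0)
    mito_profile = normalize_profile(
        extract_profile(mito_img, stack.voxel_size[1:], roi, config.bin_width,
                        source_id=fly_id)
    )
    marker_img = max_project(stack, channel=1)
    marker_profile = normalize_profile(
        extract_profile(marker_img, stack.voxel_size[1:], roi, config.bin_width,
                        source_id=fly_id)
    )

    interval = _resolve_interval(config, marker_profile, true_interval)
    area = chord_dropout_area(mito_profile, interval)
    integral = integrated_ais_intensity(mito_profile, interval)

    return {
        "fly_id": fly_id,
        "hemisphere": hemisphere,
        "genotype": genotype,
        "age": age,
        "calyx_mean": meas.calyx_mean,
        "lobe_mean": meas.lobe_mean,
        "ratio": meas.ratio,
        "nonmissing_area_calyx": meas.nonmissing_area_calyx,
        "nonmissing_area_lobe": meas.nonmissing_area_lobe,
        "dropout_area": area,
        "integrated_intensity": integral,
        "interval_distal": interval.distal_edge,
        "interval_proximal": interval.proximal_edge,
        "interval_method": interval.method,
        "profile": mito_profile,
        "marker_profile": marker_profile,
    }


def _resolve_interval(
    config: AnalysisConfig,
    marker_profile,
    true_interval: Optional[tuple],
) -> AisInterval:
    if config.boundary_method == "marker-trough":
        try:
            return detect_ais_interval(marker_profile)
        except TroughNotFoundError:
            pass  # fall back to the manual/config interval below
    if config.ais_interval is not None:
        d, p = config.ais_interval
        return AisInterval(d, p, method="manual")
    if true_interval is not None:
        d, p = true_interval
        return AisInterval(float(d), float(p), method="manual")
    raise ConfigurationError(
        "no AIS interval available: set ais_interval, use marker-trough "
        "detection, or provide ground truth"
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    master_seed: int
    config: dict
    version: str
    created: str
    files: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "config": self.config,
                "version": self.version,
                "created": self.created,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class PipelineResult:
    manifest: RunManifest
    measurements: pd.DataFrame
    comparisons: pd.DataFrame
    group_profiles: pd.DataFrame
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _build_components(config: AnalysisConfig):
    geometry = CompartmentGeometry(**config.geometry) if config.geometry else CompartmentGeometry()
    acquisition = AcquisitionModel(**config.acquisition) if config.acquisition else AcquisitionModel()
    puncta = PunctaModel(**config.puncta) if config.puncta else PunctaModel()
    marker = MarkerModel(**config.marker) if config.marker else MarkerModel()
    groups = [GroupSpec.from_dict(g) for g in config.groups]
    return geometry, acquisition, puncta, marker, groups


def run_pipeline(config: AnalysisConfig, out_dir) -> PipelineResult:
    """Execute the whole analysis over a synthetic cohort and write results.

    Outputs in ``out_dir``: ``measurements.csv`` (one row per
    hemisphere), ``profiles.csv`` (per-fly normalised traces),
    ``group_profiles.csv`` (mean ± SEM per group), ``comparisons.csv``
    (test outcomes with decision trails), ``report.txt`` and
    ``manifest.json``.  Any stage failure aborts with the stage name and
    offending input.
    """
    if config.n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if not config.groups:
        raise ValidationError("config defines no groups")
    geometry, acquisition, puncta, marker, groups = _build_components(config)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        cohort = generate_cohort(
            groups, config.n_per_group, config.seed,
            geometry=geometry, puncta_model=puncta,
            acquisition=acquisition, marker=marker,
        )
    except Exception as e:
        raise PipelineError(f"stage simulate failed: {e}") from e

    rows = []
    profiles_by_group: dict = {}
    for sample in cohort:
        try:
            row = analyze_sample(
                sample.stack, geometry, config,
                age=sample.group.age,
                fly_id=sample.fly_id,
                genotype=sample.group.genotype,
                true_interval=sample.truth.true_ais_interval,
            )
        except Exception as e:
            raise PipelineError(
                f"stage measure failed on {sample.fly_id}: {e}"
            ) from e
        profiles_by_group.setdefault(sample.group.name, []).append(row.pop("profile"))
        row.pop("marker_profile")
        rows.append(row)

    measurements = pd.DataFrame(rows)
    write_table(measurements, out_dir / "measurements.csv")

    profile_rows = []
    group_rows = []
    for gname, profs in profiles_by_group.items():
        for p in profs:
            for pos, val in zip(p.positions, p.values):
                profile_rows.append(
                    {"group": gname, "source_id": p.source_id,
                     "position_um": pos, "value": val}
                )
        gp = aggregate_group(profs)
        for pos, mean, sem, nb in zip(gp.positions, gp.mean, gp.sem, gp.n_per_bin):
            group_rows.append(
                {"group": gname, "position_um": pos, "mean": mean,
                 "sem": sem, "n": int(nb)}
            )
    write_table(profile_rows, out_dir / "profiles.csv")
    group_profiles = pd.DataFrame(group_rows)
    write_table(group_profiles, out_dir / "group_profiles.csv")

    comparisons = _run_stats(measurements, config)
    write_table(comparisons, out_dir / "comparisons.csv")

    if config.make_plots:
        _plot_group_profiles(group_profiles, config, out_dir / "profiles.png")

    report = _write_report(measurements, comparisons, config, out_dir / "report.txt")

    files = {}
    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            files[f.name] = _sha256(f)
    manifest = RunManifest(
        master_seed=config.seed,
        config=config.to_dict(),
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
        files=files,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return PipelineResult(
        manifest=manifest,
        measurements=measurements,
        comparisons=pd.DataFrame(comparisons),
        group_profiles=group_profiles,
        out_dir=out_dir,
    )


def _run_stats(measurements: pd.DataFrame, config: AnalysisConfig) -> list:
    long = measurements.melt(
        id_vars=["fly_id", "hemisphere", "genotype", "age"],
        value_vars=METRICS,
        var_name="metric",
        value_name="value",
    )
    per_fly = collapse_replicates(long)
    genotypes = sorted(per_fly["genotype"].unique())
    ages = sorted(per_fly["age"].unique())
    results = []
    for metric in METRICS:
        sub = per_fly[per_fly["metric"] == metric]
        try:
            if len(genotypes) >= 2 and len(ages) >= 2:
                results.extend(
                    compare_two_way(sub, metric=metric, alpha=config.alpha)
                )
            elif len(genotypes) == 2:
                g0 = sub[sub["genotype"] == genotypes[0]]["value"].to_numpy()
                g1 = sub[sub["genotype"] == genotypes[1]]["value"].to_numpy()
                results.append(
                    compare_two_groups(
                        g0, g1, alpha=config.alpha,
                        labels=(genotypes[0], genotypes[1]), metric=metric,
                    )
                )
        except Exception as e:
            raise PipelineError(f"stage stats failed on metric {metric}: {e}") from e
    return [r.to_row() for r in results]


def _write_report(measurements, comparisons, config, path) -> str:
    lines = ["AIS mitochondrial distribution analysis", ""]
    summary = (
        measurements.groupby(["genotype", "age"])[METRICS]
        .agg(["mean", "sem"])
        .round(4)
    )
    lines.append(summary.to_string())
    lines.append("")
    for row in comparisons:
        flag = "*" if row["adjusted_p"] < config.alpha else "ns"
        lines.append(
            f"{row['metric']:22s} {row['contrast']:28s} {row['test_name']:40s} "
            f"p={row['p_value']:.4g} p_adj={row['adjusted_p']:.4g} [{flag}]"
        )
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def _plot_group_profiles(group_profiles: pd.DataFrame, config: AnalysisConfig, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for gname, sub in group_profiles.groupby("group"):
        ax.plot(sub["position_um"], sub["mean"], label=gname)
        ax.fill_between(
            sub["position_um"],
            sub["mean"] - sub["sem"],
            sub["mean"] + sub["sem"],
            alpha=0.3,
        )
    if config.ais_interval is not None:
        ax.axvspan(*config.ais_interval, color="0.8", zorder=0)
    ax.set_xlabel("position along AIS axis (µm; distal negative)")
    ax.set_ylabel("normalized mitochondrial intensity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Fixture cohorts
# ---------------------------------------------------------------------------


def make_fixtures(out_dir, seed: int, n_per_group: int = 2) -> dict:
    """Write a small deterministic cohort for tests and demos.

    Uses the reduced-scene geometry: two groups (exclusion depth 0.8 vs
    0.0), ``n_per_group`` stacks each, stored as TIFF with JSON ground
    truth sidecars, plus the ROIs and a matching config file.  Re-running
    with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = small_geometry()
    config = AnalysisConfig(
        seed=seed,
        n_per_group=n_per_group,
        roi_length={"larva": 24.0},
        geometry={
            "calyx_center": list(geometry.calyx_center),
            "calyx_radius": geometry.calyx_radius,
            "peduncle_axis": [list(p) for p in geometry.peduncle_axis],
            "peduncle_radius": geometry.peduncle_radius,
            "ais_interval": list(geometry.ais_interval),
            "lobe_axis": [list(p) for p in geometry.lobe_axis],
            "lobe_radius": geometry.lobe_radius,
            "field_of_view": list(geometry.field_of_view),
            "voxel_size": list(geometry.voxel_size),
        },
    )
    _, acquisition, puncta, marker, groups = _build_components(config)
    cohort = generate_cohort(
        groups, n_per_group, seed,
        geometry=geometry, puncta_model=puncta,
        acquisition=acquisition, marker=marker,
    )
    paths = {"stacks": [], "truths": []}
    for sample in cohort:
        spath = out_dir / f"{sample.fly_id}.tif"
        write_stack(sample.stack, spath)
        truth_doc = {
            "fly_id": sample.fly_id,
            "group": sample.group.name,
            "genotype": sample.group.genotype,
            "age": sample.group.age,
            "true_ais_interval": list(sample.truth.true_ais_interval),
            "true_density_ratio": sample.truth.true_density_ratio,
            "ais_center_zyx": list(sample.truth.ais_center),
            "puncta_per_compartment": sample.truth.compartment_counts(),
        }
        tpath = out_dir / f"{sample.fly_id}.truth.json"
        tpath.write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
        paths["stacks"].append(spath)
        paths["truths"].append(tpath)
    write_roi(default_calyx_roi(geometry), out_dir / "calyx.roi.json")
    write_roi(default_lobe_roi(geometry), out_dir / "lobe.roi.json")
    write_roi(
        profile_roi(geometry, config.roi_length["larva"]),
        out_dir / "ais_profile.roi.json",
    )
    config.to_yaml(out_dir / "config.yaml")
    paths["config"] = out_dir / "config.yaml"
    return paths
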