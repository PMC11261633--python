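import numpy as np
import pytest

import ais_mito_quant as amq


@pytest.fixture(scope="session")
def small_geom():
    return amq.small_geometry()


@pytest.fixture(scope="session")
def small_labels(small_geom):
    return amq.build_label_volume(small_geom)


@pytest.fixture(scope="session")
def small_config():
    """Analysis config matching the reduced-scene geometry."""
    return amq.AnalysisConfig(roi_length={"larva": 24.0})


@pytest.fixture(scope="session")
def quiet_acquisition():
    """Noise-free acquisition for deterministic rendering checks."""
    return amq.AcquisitionModel(
        psf_sigma=(1.0, 0.25, 0.25),
        background_level=0.0,
        poisson_scale=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_sample(small_geom):
    """One wild-type-like stack (exclusion depth 0.8) on the reduced scene."""
    stack, truth = amq.simulate_stack(
        small_geom, amq.PunctaModel(), amq.AcquisitionModel(), amq.MarkerModel(), seed=5
    )
    return stack, truth


@pytest.fixture(scope="session")
def small_cohort(small_geom):
    """Two groups (exclusion 0.8 vs 0.0) x 4 stacks on the reduced scene."""
    groups = [
        amq.GroupSpec(name="WT", genotype="WT", exclusion_depth=0.8),
        amq.GroupSpec(name="KO", genotype="KO", exclusion_depth=0.0),
    ]
    return amq.generate_cohort(groups, 4, master_seed=17, geometry=small_geom)


def small_geometry_overrides():
    g = amq.small_geometry()
    return {
        "calyx_center": list(g.calyx_center),
        "calyx_radius": g.calyx_radius,
        "peduncle_axis": [list(p) for p in g.peduncle_axis],
        "peduncle_radius": g.peduncle_radius,
        "ais_interval": list(g.ais_interval),
        "lobe_axis": [list(p) for p in g.lobe_axis],
        "lobe_radius": g.lobe_radius,
        "field_of_view": list(g.field_of_view),
        "voxel_size": list(g.voxel_size),
    }


@pytest.fixture(scope="session")
def small_run_config():
    """Full pipeline config on the reduced scene (2 groups x 3 flies)."""
    return amq.AnalysisConfig(
        seed=3,
        n_per_group=3,
        roi_length={"larva": 24.0},
        geometry=small_geometry_overrides(),
    )


def make_profile(values, bin_width=0.41, start=None, normalized=False, source_id=None):
    """Profile helper with bin centres symmetric about 0 unless start is given."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if start is None:
        positions = (np.arange(n) + 0.5) * bin_width - n * bin_width / 2.0
    else:
        positions = start + np.arange(n) * bin_width
    return amq.IntensityProfile(
        positions=positions,
        values=values,
        bin_width=bin_width,
        normalized=normalized,
        source_id=source_id,
    )
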