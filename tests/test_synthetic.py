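import numpy as np
import pytest

import ais_mito_quant as amq
from ais_mito_quant.errors import ConfigurationError, ValidationError
from ais_mito_quant.synthetic import LABELS


def _bare_cylinder_geometry():
    """Isotropic 0.5 µm voxels, a single peduncle cylinder r=2, L=10 µm."""
    return amq.CompartmentGeometry(
        calyx_center=(4.0, 6.0, 8.0),
        calyx_radius=0.0,
        peduncle_axis=((4.0, 6.0, 3.0), (4.0, 6.0, 13.0)),
        peduncle_radius=2.0,
        ais_interval=(1.0, 9.0),
        lobe_axis=((4.0, 6.0, 1.0), (4.0, 6.0, 3.0)),
        lobe_radius=0.0,
        field_of_view=(8.0, 12.0, 16.0),
        voxel_size=(0.5, 0.5, 0.5),
    )


class TestLabelVolume:
    def test_zero_radius_structures_give_all_background(self):
        geom = amq.CompartmentGeometry(
            calyx_center=(4.0, 6.0, 8.0),
            calyx_radius=0.0,
            peduncle_axis=((4.0, 6.0, 3.0), (4.0, 6.0, 13.0)),
            peduncle_radius=0.0,
            ais_interval=(1.0, 9.0),
            lobe_axis=((4.0, 6.0, 1.0), (4.0, 6.0, 3.0)),
            lobe_radius=0.0,
            field_of_view=(8.0, 12.0, 16.0),
            voxel_size=(0.5, 0.5, 0.5),
        )
        labels = amq.build_label_volume(geom)
        assert np.all(labels == LABELS["background"])

    def test_labels_partition_the_volume(self, small_geom, small_labels):
        counts = np.bincount(small_labels.ravel(), minlength=5)
        assert counts.sum() == np.prod(small_geom.shape_zyx)
        # all five compartments present in the default scene
        assert np.all(counts[1:] > 0)

    def test_cylinder_voxel_count_matches_bruteforce_and_analytic(self):
        geom = _bare_cylinder_geometry()
        labels = amq.build_label_volume(geom)
        cyl = np.isin(labels, [LABELS["ais"], LABELS["axon_proximal"]])

        # independent per-voxel membership loop
        p0 = np.array(geom.peduncle_axis[0])
        u = geom.peduncle_direction
        expected = np.zeros_like(cyl)
        nz, ny, nx = geom.shape_zyx
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    p = (np.array([iz, iy, ix]) + 0.5) * 0.5 - p0
                    t = p @ u
                    r2 = p @ p - t * t
                    expected[iz, iy, ix] = (0 <= t <= 10.0) and r2 <= 4.0 + 1e-12
        assert np.array_equal(cyl, expected)

        analytic = np.pi * 2.0**2 * 10.0 / 0.5**3
        assert abs(cyl.sum() - analytic) / analytic < 0.05

    def test_ais_interval_must_sit_inside_peduncle(self):
        with pytest.raises(ConfigurationError):
            amq.CompartmentGeometry(ais_interval=(0.0, 50.0))

    def test_structure_outside_field_of_view_rejected(self):
        with pytest.raises(ConfigurationError, match="field of view"):
            amq.CompartmentGeometry(calyx_center=(10.0, 20.0, 118.0))


class TestSamplePuncta:
    def test_zero_density_gives_empty_list(self, small_geom, small_labels):
        model = amq.PunctaModel(density={k: 0.0 for k in
                                         ("calyx", "ais", "axon_proximal", "axon_lobe")})
        assert amq.sample_puncta(small_labels, small_geom, model, seed=0) == []

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            amq.PunctaModel(density={"calyx": -0.1})

    def test_full_uniform_exclusion_empties_the_ais(self, small_geom, small_labels):
        model = amq.PunctaModel(ais_exclusion_depth=1.0, ais_exclusion_weight="uniform")
        puncta = amq.sample_puncta(small_labels, small_geom, model, seed=1)
        assert all(p.compartment != "ais" for p in puncta)

    def test_counts_are_poisson_with_density_times_volume(self, small_geom, small_labels):
        density = 0.05
        model = amq.PunctaModel(density={"calyx": density})
        lam = density * (small_labels == LABELS["calyx"]).sum() * np.prod(small_geom.voxel_size)
        counts = np.array([
            len(amq.sample_puncta(small_labels, small_geom, model, seed=s))
            for s in range(100)
        ])
        assert abs(counts.mean() - lam) < 3.0 * np.sqrt(lam)
        assert 0.5 < counts.var(ddof=1) / lam < 1.6   # Poisson: variance = mean

    def test_puncta_lie_in_their_claimed_compartment(self, small_geom, small_labels):
        puncta = amq.sample_puncta(small_labels, small_geom, amq.PunctaModel(), seed=2)
        vs = np.asarray(small_geom.voxel_size)
        for p in puncta:
            ijk = tuple((np.asarray(p.position) / vs).astype(int))
            assert small_labels[ijk] == LABELS[p.compartment]

    def test_expected_ais_count_nonincreasing_in_exclusion_depth(self, small_geom, small_labels):
        means = []
        for d in (0.0, 0.5, 1.0):
            model = amq.PunctaModel(density={"ais": 2.0}, ais_exclusion_depth=d)
            n = [
                sum(p.compartment == "ais"
                    for p in amq.sample_puncta(small_labels, small_geom, model, seed=s))
                for s in range(30)
            ]
            means.append(np.mean(n))
        assert means[0] > means[1] > means[2]
        assert means[2] == 0.0

    def test_total_count_equals_sum_of_compartment_counts(self, small_sample):
        _, truth = small_sample
        assert len(truth.puncta) == sum(truth.compartment_counts().values())


class TestRenderStack:
    def test_background_only_when_no_puncta_and_no_noise(
        self, small_labels, small_geom, quiet_acquisition
    ):
        acq = amq.AcquisitionModel(
            psf_sigma=(1.0, 0.25, 0.25), background_level=7.0,
            poisson_scale=0.0, read_noise_sd=0.0,
        )
        stack = amq.render_stack(small_labels, small_geom.voxel_size, [],
                                 acq, amq.MarkerModel(), seed=0)
        assert np.all(stack.voxels[0] == 7.0)

    def test_single_punctum_matches_dense_gaussian_evaluation(self):
        labels = np.zeros((8, 32, 32), dtype=np.uint8)
        voxel_size = (1.0, 0.25, 0.25)
        acq = amq.AcquisitionModel(psf_sigma=(1.0, 0.25, 0.25), background_level=0.0,
                                   poisson_scale=0.0, read_noise_sd=0.0)
        amp, psigma = 50.0, 0.4
        pos = (4.2, 3.7, 3.3)
        punctum = amq.Punctum(position=pos, amplitude=amp, compartment="calyx")
        stack = amq.render_stack(labels, voxel_size, [punctum], acq,
                                 amq.MarkerModel(), seed=0, punctum_sigma=psigma)

        sigma = np.sqrt(np.asarray(acq.psf_sigma) ** 2 + psigma**2)
        z = (np.arange(8) + 0.5) * 1.0
        y = (np.arange(32) + 0.5) * 0.25
        x = (np.arange(32) + 0.5) * 0.25
        oracle = amp * np.exp(
            -0.5 * (
                ((z[:, None, None] - pos[0]) / sigma[0]) ** 2
                + ((y[None, :, None] - pos[1]) / sigma[1]) ** 2
                + ((x[None, None, :] - pos[2]) / sigma[2]) ** 2
            )
        )
        assert np.max(np.abs(stack.voxels[0] - oracle)) < 1e-6 * amp

    def test_punctum_outside_volume_rejected(self, small_labels, small_geom):
        bad = amq.Punctum(position=(99.0, 0.0, 0.0), amplitude=1.0, compartment="calyx")
        with pytest.raises(ValidationError, match="outside"):
            amq.render_stack(small_labels, small_geom.voxel_size, [bad],
                             amq.AcquisitionModel(), amq.MarkerModel(), seed=0)

    def test_identical_seed_gives_identical_stack(self, small_labels, small_geom):
        model = amq.PunctaModel()
        puncta = amq.sample_puncta(small_labels, small_geom, model, seed=3)
        s1 = amq.render_stack(small_labels, small_geom.voxel_size, puncta,
                              amq.AcquisitionModel(), amq.MarkerModel(), seed=9)
        s2 = amq.render_stack(small_labels, small_geom.voxel_size, puncta,
                              amq.AcquisitionModel(), amq.MarkerModel(), seed=9)
        assert np.array_equal(s1.voxels, s2.voxels)

    def test_poisson_noise_variance_matches_mean_over_scale(self):
        labels = np.zeros((2, 6, 6), dtype=np.uint8)
        acq = amq.AcquisitionModel(psf_sigma=(1.0, 0.5, 0.5), background_level=50.0,
                                   poisson_scale=2.0, read_noise_sd=0.0)
        stacks = np.stack([
            amq.render_stack(labels, (1.0, 0.5, 0.5), [], acq, amq.MarkerModel(), seed=s)
            .voxels[0]
            for s in range(200)
        ])
        per_voxel_var = stacks.var(axis=0, ddof=1)
        expected = 50.0 / 2.0
        assert abs(per_voxel_var.mean() - expected) / expected < 0.1

    def test_marker_channel_dims_inside_ais(self, small_sample, small_geom):
        stack, truth = small_sample
        labels = truth.label_volume
        marker = stack.voxels[1]
        ais_mean = marker[labels == LABELS["ais"]].mean()
        ped_mean = marker[labels == LABELS["axon_proximal"]].mean()
        assert ais_mean < 0.6 * ped_mean


class TestCohort:
    def test_single_group_single_stack(self, small_geom):
        out = amq.generate_cohort(
            [amq.GroupSpec(name="g", genotype="g")], 1, 0, geometry=small_geom
        )
        assert len(out) == 1 and out[0].fly_id == "g_00"

    def test_same_master_seed_is_byte_identical(self, small_geom):
        groups = [amq.GroupSpec(name="g", genotype="g")]
        a = amq.generate_cohort(groups, 2, 5, geometry=small_geom)
        b = amq.generate_cohort(groups, 2, 5, geometry=small_geom)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.stack.voxels, sb.stack.voxels)
            assert sa.truth.true_ais_interval == sb.truth.true_ais_interval

    def test_extending_cohort_keeps_existing_stacks(self, small_geom):
        groups = [amq.GroupSpec(name="g", genotype="g")]
        short = amq.generate_cohort(groups, 1, 5, geometry=small_geom)
        longer = amq.generate_cohort(groups, 2, 5, geometry=small_geom)
        assert np.array_equal(short[0].stack.voxels, longer[0].stack.voxels)

    def test_empty_cohort_rejected(self, small_geom):
        with pytest.raises(ValidationError):
            amq.generate_cohort([amq.GroupSpec(name="g", genotype="g")], 0, 0,
                                geometry=small_geom)
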