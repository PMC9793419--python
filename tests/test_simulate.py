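"""Synthetic embryo generator: geometry, molecule placement, rendering."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import fcluster, linkage

from memfish import (
    GroundTruth,
    LocalizationModel,
    generate_geometry,
    place_spots,
    render_stack,
)
from memfish.simulate import NoiseModel, PlacementError, RenderError, SizingError, add_gaussian_spots

from conftest import ANISO_VOXEL, ISO_VOXEL, NOISELESS, snr_noise


class TestGeometry:
    def test_stage_label_count_and_connectivity(self):
        geom = generate_geometry(4, (32, 192, 192), ANISO_VOXEL, seed=7)
        labels = geom.label_volume
        ids = sorted(np.unique(labels[labels > 0]))
        assert ids == [1, 2, 3, 4]
        for k in ids:
            assert ndi.label(labels == k)[1] == 1, f"cell {k} disconnected"

    def test_deterministic_for_fixed_seed(self):
        a = generate_geometry(4, (24, 128, 128), ANISO_VOXEL, seed=7)
        b = generate_geometry(4, (24, 128, 128), ANISO_VOXEL, seed=7)
        assert np.array_equal(a.label_volume, b.label_volume)
        assert np.array_equal(a.nuclei_centers, b.nuclei_centers)

    def test_digital_sphere_volume_matches_analytic(self, sphere):
        # rasterized ball of radius 30 voxels vs (4/3)*pi*30^3 = 113097.3
        geom, _ = sphere
        count = int((geom.label_volume > 0).sum())
        assert abs(count - 4 / 3 * np.pi * 30**3) / (4 / 3 * np.pi * 30**3) < 0.01

    def test_nuclei_inside_their_cells(self):
        geom = generate_geometry(8, (40, 200, 200), ANISO_VOXEL, seed=2)
        voxel = np.asarray(geom.voxel_size)
        for k, c in enumerate(geom.nuclei_centers, start=1):
            idx = tuple(np.floor(c / voxel).astype(int))
            assert geom.label_volume[idx] == k

    def test_too_small_shape_raises(self):
        with pytest.raises((SizingError, ValueError)):
            generate_geometry(8, (6, 10, 10), ISO_VOXEL, seed=0)

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            generate_geometry(3, (24, 128, 128), ANISO_VOXEL, seed=0)


class TestPlacement:
    def test_uniform_shell_fraction_matches_sphere_geometry(self, sphere):
        # analytic outer-10% shell of a ball holds 1 - 0.9^3 = 0.271 of the
        # volume; the voxelized field puts it at ~0.263, and 50k uniform draws
        # must land within Monte-Carlo error of the analytic value
        geom, field = sphere
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 50_000, seed=1, dist=field)
        frac = float((truth.true_normalized_distance < 0.1).mean())
        assert frac == pytest.approx(1 - 0.9**3, abs=0.01)

    def test_membrane_mode_full_fraction_all_in_shell(self, sphere):
        geom, field = sphere
        model = LocalizationModel(mode="membrane", membrane_fraction=1.0, membrane_shell=0.1)
        truth = place_spots(geom, model, 2_000, seed=2, dist=field)
        assert (truth.true_normalized_distance < 0.1).all()

    def test_clustered_mode_recovers_planted_groups(self, embryo4):
        # single linkage at 3*sigma must find exactly the planted clusters
        geom, field = embryo4
        model = LocalizationModel(
            mode="clustered", n_clusters=5, molecules_per_cluster=20, cluster_sigma=0.15
        )
        truth = place_spots(geom, model, 100, seed=4, dist=field)
        assert len(truth) == 100
        groups = fcluster(linkage(truth.positions, "single"), t=3 * 0.15, criterion="distance")
        assert len(np.unique(groups)) == 5

    @pytest.mark.parametrize("mode", ["uniform", "membrane", "clustered"])
    def test_placement_conservation(self, embryo4, mode):
        geom, field = embryo4
        truth = place_spots(geom, LocalizationModel(mode=mode), 120, seed=5, dist=field)
        assert len(truth) == 120
        # every molecule lies inside its reported cell
        voxel = np.asarray(geom.voxel_size)
        idx = np.floor(truth.positions / voxel).astype(int)
        labs = geom.label_volume[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.array_equal(labs, truth.cell_id)

    def test_sphere_shell_volumes_near_analytic(self, sphere):
        # voxel-counted shell fractions vs analytic concentric-shell volumes;
        # the voxel-center distance convention carries an O(h/R) surface bias,
        # so outer/inner bins deviate by a few percent at radius 30
        geom, field = sphere
        nd = field.normalized[geom.label_volume > 0]
        bins = np.minimum((nd * 10).astype(int), 9)
        frac = np.bincount(bins, minlength=10) / nd.size
        analytic = np.array([(1 - b / 10) ** 3 - (1 - (b + 1) / 10) ** 3 for b in range(10)])
        assert np.all(np.abs(frac[:9] / analytic[:9] - 1) < 0.05)
        assert abs(frac[9] / analytic[9] - 1) < 0.15

    def test_min_distance_thinning(self, box_cell):
        from scipy.spatial.distance import pdist

        geom, field = box_cell
        truth = place_spots(
            geom, LocalizationModel(mode="uniform"), 150, seed=6, dist=field, min_distance=0.75
        )
        assert len(truth) == 150
        assert pdist(truth.positions).min() >= 0.75


class TestRendering:
    def test_single_molecule_peak_at_its_voxel(self, box_cell):
        geom, field = box_cell
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 1, seed=8, dist=field)
        stack = render_stack(geom, truth, noise=NOISELESS, seed=0)
        fish = stack.channel("smFISH")
        peak = np.unravel_index(np.argmax(fish), fish.shape)
        expected = tuple(np.floor(truth.positions[0] / np.asarray(geom.voxel_size)).astype(int))
        assert np.all(np.abs(np.asarray(peak) - np.asarray(expected)) <= 1)

    def test_summed_intensity_equals_amplitude_times_kernel_sum(self, box_cell):
        # brute-force: evaluate the same anisotropic kernel on the full grid
        geom, field = box_cell
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 1, seed=9, dist=field)
        amp, psf = 200.0, (0.35, 0.13, 0.13)
        stack = render_stack(geom, truth, psf_sigma=psf, spot_amplitude=amp,
                             noise=NOISELESS, seed=0)
        ref = np.zeros(geom.shape)
        add_gaussian_spots(ref, truth.positions, 1.0, psf, geom.voxel_size, truncate=4.0)
        assert stack.channel("smFISH").sum() == pytest.approx(amp * ref.sum(), rel=1e-3)

    def test_render_deterministic(self, box_cell):
        geom, field = box_cell
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 20, seed=10, dist=field)
        a = render_stack(geom, truth, noise=snr_noise(150, 5), seed=3)
        b = render_stack(geom, truth, noise=snr_noise(150, 5), seed=3)
        assert np.array_equal(a.data, b.data)

    def test_positions_outside_volume_raise(self, box_cell):
        geom, _ = box_cell
        bad = GroundTruth(
            positions=np.array([[100.0, 1.0, 1.0]]),
            cell_id=np.array([1]),
            true_normalized_distance=np.array([0.5]),
            cluster_id=np.array([0]),
        )
        with pytest.raises(RenderError):
            render_stack(geom, bad, seed=0)

    def test_gfp_channel_optional(self, box_cell):
        geom, field = box_cell
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 5, seed=11, dist=field)
        stack = render_stack(geom, truth, noise=NOISELESS, seed=0, gfp_amplitude=50.0)
        assert stack.channel_names == ("smFISH", "membrane", "DAPI", "GFP")


class TestModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "banana"},
            {"membrane_shell": 0.0},
            {"membrane_fraction": 1.2},
            {"mode": "clustered", "n_clusters": 0},
            {"cluster_sigma": -1.0},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LocalizationModel(**kwargs)

    def test_clustered_budget_exceeding_n_raises(self, embryo4):
        geom, field = embryo4
        model = LocalizationModel(mode="clustered", n_clusters=5, molecules_per_cluster=20)
        with pytest.raises(PlacementError):
            place_spots(geom, model, 50, seed=0, dist=field)
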