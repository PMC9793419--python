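"""Annotation rasterization, distance fields, enrichment profiles."""

import numpy as np
import pytest

from memfish import (
    CellAnnotation,
    LocalizationModel,
    assign_and_profile,
    distance_field,
    membrane_fraction,
    place_spots,
    rasterize_annotation,
)
from memfish.enrich import (
    AnnotationConflictError,
    DegenerateCellError,
    auto_exclude_slices,
)


def square(y0, x0, side):
    return np.array([[y0, x0], [y0, x0 + side], [y0 + side, x0 + side], [y0 + side, x0]], float)


class TestRasterize:
    def test_square_polygon_pixel_count(self):
        ann = CellAnnotation(polygons={1: {z: square(2, 3, 6) for z in range(10)}})
        labels = rasterize_annotation(ann, (10, 16, 16))
        assert (labels == 1).sum() == 6 * 6 * 10  # pixel-center fill, half-open edges

    def test_label_mask_passthrough_with_exclusion(self):
        mask = np.zeros((6, 8, 8), dtype=np.int32)
        mask[:, 2:6, 2:6] = 1
        ann = CellAnnotation(label_mask=mask, excluded_slices=frozenset({0, 5}))
        labels = rasterize_annotation(ann, mask.shape)
        assert labels[0].sum() == 0 and labels[5].sum() == 0
        assert np.array_equal(labels[1:5], mask[1:5])

    def test_edge_sharing_cells_deterministic_ownership(self):
        # two squares sharing the x=9 edge: no pixel is claimed twice and the
        # shared column belongs to exactly one cell, deterministically
        ann = CellAnnotation(
            polygons={
                1: {0: square(2, 3, 6)},
                2: {0: np.array([[2, 9], [2, 15], [8, 15], [8, 9]], float)},
            }
        )
        labels = rasterize_annotation(ann, (1, 20, 20))
        assert (labels == 1).sum() == 36 and (labels == 2).sum() == 36
        assert set(labels[0, 3:8, 9]) == {2}  # half-open: boundary column owned by cell 2
        again = rasterize_annotation(ann, (1, 20, 20))
        assert np.array_equal(labels, again)

    def test_overlapping_interiors_raise(self):
        ann = CellAnnotation(polygons={1: {0: square(2, 3, 6)}, 2: {0: square(4, 5, 6)}})
        with pytest.raises(AnnotationConflictError):
            rasterize_annotation(ann, (1, 20, 20))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [6, 6], [0, 6], [6, 0]], float)
        ann = CellAnnotation(polygons={1: {0: bowtie}})
        with pytest.raises(ValueError, match="simple"):
            rasterize_annotation(ann, (1, 10, 10))

    def test_auto_exclusion_flags_thin_slices(self):
        mask = np.zeros((5, 10, 10), dtype=np.int32)
        mask[1:4, 1:9, 1:9] = 1
        mask[0, 4:6, 4:6] = 1  # tiny cap slice
        assert auto_exclude_slices(mask)[1] == {0}


class TestDistanceField:
    def test_sphere_center_normalized_to_one(self, sphere):
        geom, field = sphere
        assert field.normalized.max() == pytest.approx(1.0)
        # max raw distance ~ radius * voxel within one voxel
        assert field.max_distance[1] == pytest.approx(30 * 0.1, abs=0.1)

    def test_anisotropic_step_to_background(self):
        # slab cell: a voxel whose nearest background lies one step away in z
        # has raw distance equal to the z spacing
        labels = np.zeros((6, 20, 20), dtype=np.int32)
        labels[1:5, 2:18, 2:18] = 1
        field = distance_field(labels, (0.3, 0.1, 0.1))
        assert field.distance[1, 10, 10] == pytest.approx(0.3)
        assert field.distance[2, 10, 10] == pytest.approx(0.6)

    def test_matches_brute_force_on_small_cell(self):
        # oracle: minimum anisotropic distance to any non-cell voxel center
        rng = np.random.default_rng(0)
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        zz, yy, xx = np.mgrid[:20, :20, :20]
        blob = ((zz - 10) / 6.0) ** 2 + ((yy - 9) / 7.5) ** 2 + ((xx - 11) / 5.0) ** 2 <= 1
        labels[blob] = 1
        voxel = (0.2, 0.1, 0.1)
        field = distance_field(labels, voxel)
        cell = np.argwhere(labels == 1)
        bg = np.argwhere(labels == 0)
        sample = cell[rng.choice(len(cell), 60, replace=False)]
        w = np.asarray(voxel)
        for v in sample:
            brute = np.sqrt((((bg - v) * w) ** 2).sum(axis=1)).min()
            assert field.distance[tuple(v)] == pytest.approx(brute, abs=1e-9)

    def test_neighbor_cells_count_as_boundary(self):
        labels = np.zeros((3, 10, 20), dtype=np.int32)
        labels[:, 2:8, 1:10] = 1
        labels[:, 2:8, 10:19] = 2
        field = distance_field(labels, (0.1, 0.1, 0.1))
        # voxel of cell 1 adjacent to cell 2 sits at one-voxel distance
        assert field.distance[1, 5, 9] == pytest.approx(0.1)

    def test_degenerate_cell_raises_with_id(self):
        labels = np.zeros((4, 6, 6), dtype=np.int32)
        with pytest.raises(DegenerateCellError):
            distance_field(labels, (0.1, 0.1, 0.1))

    def test_fixed_radius_normalization(self):
        labels = np.zeros((8, 12, 12), dtype=np.int32)
        labels[2:6, 3:9, 3:9] = 1
        field = distance_field(labels, (0.1, 0.1, 0.1), normalization="fixed_radius", fixed_radius=1.0)
        inside = labels > 0
        assert np.allclose(field.normalized[inside], field.distance[inside] / 1.0)


class TestProfiles:
    def test_uniform_baseline_outer_bins(self, sphere):
        # a uniform sample must sit at frequency ~1; outer bins are tight,
        # inner bins are volume-starved so only a multinomial bound applies
        geom, field = sphere
        truth = place_spots(geom, LocalizationModel(mode="uniform"), 50_000, seed=1, dist=field)
        prof = assign_and_profile(truth, field, geom.label_volume).pooled
        freq = prof.normalized_frequency
        assert np.all(np.abs(freq[:6] - 1) < 0.05)
        expected = 50_000 * prof.volume_fractions
        assert np.all(np.abs(prof.counts - expected) < 4 * np.sqrt(expected))

    def test_all_membrane_profile_concentrated_in_bin1(self, sphere):
        geom, field = sphere
        model = LocalizationModel(mode="membrane", membrane_fraction=1.0, membrane_shell=0.1)
        truth = place_spots(geom, model, 5_000, seed=3, dist=field)
        prof = assign_and_profile(truth, field, geom.label_volume).pooled
        freq = prof.normalized_frequency
        assert np.all(freq[1:] == 0)
        # freq of bin 1 is exactly 1/volume-fraction; near analytic 3.69
        assert freq[0] == pytest.approx(1 / prof.volume_fractions[0])
        assert freq[0] == pytest.approx(1 / (1 - 0.9**3), rel=0.05)

    def test_planted_fraction_recovered(self, sphere):
        geom, field = sphere
        model = LocalizationModel(mode="membrane", membrane_fraction=0.4)
        truth = place_spots(geom, model, 20_000, seed=5, dist=field)
        prof = assign_and_profile(truth, field, geom.label_volume).pooled
        assert membrane_fraction(prof) == pytest.approx(0.4, abs=0.03)

    @pytest.mark.parametrize("mode,seed", [("uniform", 1), ("membrane", 2), ("clustered", 3)])
    def test_conservation_exact(self, embryo4, mode, seed):
        geom, field = embryo4
        truth = place_spots(geom, LocalizationModel(mode=mode), 400, seed=seed, dist=field)
        ps = assign_and_profile(truth, field, geom.label_volume)
        for prof in [ps.pooled, *ps.per_cell.values()]:
            if prof.total_count > 0:
                assert np.dot(prof.normalized_frequency, prof.volume_fractions) == pytest.approx(
                    1.0, abs=1e-12
                )
        assert ps.pooled.total_count + ps.n_discarded == 400

    def test_scale_invariance(self, sphere):
        geom, field = sphere
        truth = place_spots(geom, LocalizationModel(mode="membrane"), 3_000, seed=6, dist=field)
        prof = assign_and_profile(truth, field, geom.label_volume).pooled
        scale = 2.5
        field2 = distance_field(geom.label_volume, np.asarray(geom.voxel_size) * scale)
        prof2 = assign_and_profile(truth.positions * scale, field2, geom.label_volume).pooled
        assert np.allclose(prof.volume_fractions, prof2.volume_fractions)
        # same voxel bins up to float rounding of the scaled field
        assert np.allclose(prof2.normalized_frequency,
                           assign_and_profile(truth.positions, field, geom.label_volume)
                           .pooled.normalized_frequency, atol=0.02)

    def test_background_spot_rescued_within_one_voxel(self):
        labels = np.zeros((8, 12, 12), dtype=np.int32)
        labels[2:6, 3:9, 3:9] = 1
        field = distance_field(labels, (0.1, 0.1, 0.1))
        hugging = np.array([[0.4, 0.25, 0.55]])   # one voxel outside the cell face
        far = np.array([[0.05, 0.05, 0.05]])
        ps = assign_and_profile(np.vstack([hugging, far]), field, labels)
        assert ps.n_reassigned == 1 and ps.n_discarded == 1
        assert ps.pooled.total_count == 1
        # the rescued spot inherits the adjacent in-cell voxel's distance bin
        expected_bin = min(int(field.normalized[4, 3, 5] * 10), 9)
        assert ps.pooled.counts[expected_bin] == 1

    def test_membrane_fraction_counting_and_errors(self):
        from memfish.enrich import EnrichmentProfile

        prof = EnrichmentProfile(1, 10, np.array([10.0] + [90 / 9] * 9), np.full(10, 1.0))
        assert membrane_fraction(prof, 0.1) == pytest.approx(0.10)
        with pytest.raises(ValueError, match="bin edge"):
            membrane_fraction(prof, 0.15)
        empty = EnrichmentProfile(1, 10, np.zeros(10), np.full(10, 1.0))
        with pytest.raises(ValueError, match="zero spots"):
            membrane_fraction(empty)

    def test_molecule_counts_weight_the_profile(self, sphere):
        from memfish.decompose import CountedSpot
        from memfish.detect import Spot

        geom, field = sphere
        spot = Spot(position=(3.2, 3.2, 3.2), integrated_intensity=300.0,
                    fit_sigma=(0.35, 0.13), background=0.0, quality=1.0)
        counted = [CountedSpot(spot=spot, molecule_count=3, posterior_score=1.0)]
        prof = assign_and_profile(counted, field, geom.label_volume).pooled
        assert prof.total_count == 3
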