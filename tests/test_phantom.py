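"""Phantom generation: determinism, ground truth, manifests, acquisition gaps."""

import numpy as np
import pytest

import ctcomp as cc
from ctcomp.phantom import TISSUES, recount_ground_truth

from conftest import constant_spec, small_geometry, tapered_spec


class TestGeneration:
    def test_determinism_bit_identical(self, small_spec):
        v1, g1 = cc.generate_phantom(small_spec, seed=42)
        v2, g2 = cc.generate_phantom(small_spec, seed=42)
        assert np.array_equal(v1.data, v2.data)
        assert g1 == g2

    def test_different_seeds_differ(self, small_spec):
        v1, _ = cc.generate_phantom(small_spec, seed=1)
        v2, _ = cc.generate_phantom(small_spec, seed=2)
        assert not np.array_equal(v1.data, v2.data)

    def test_background_is_exactly_air(self, small_spec):
        vol, _, labels = cc.generate_phantom(small_spec, seed=0, return_labels=True)
        assert (vol.data[labels == 0] == -1024).all()

    def test_every_body_voxel_has_one_label(self, small_spec):
        _, gt, labels = cc.generate_phantom(small_spec, seed=0, return_labels=True)
        body = (labels >= 1) & (labels <= 3)
        assert body.sum() == sum(gt.voxel_counts.values())

    def test_zero_fat_rim_gives_zero_fat(self):
        spec = tapered_spec(fat_rim_mm=0.0)
        _, gt = cc.generate_phantom(spec, seed=0)
        assert gt.voxel_counts["fat"] == 0
        assert gt.weights_kg["fat"] == 0.0
        assert gt.volumes_cm3["fat"] == 0.0

    def test_volume_equals_count_times_voxel_volume(self, small_spec):
        _, gt = cc.generate_phantom(small_spec, seed=9)
        for t in TISSUES:
            assert gt.volumes_cm3[t] == gt.voxel_counts[t] * gt.voxel_volume_mm3 / 1000.0

    def test_ground_truth_matches_voxel_recount(self, small_spec):
        vol, gt, labels = cc.generate_phantom(small_spec, seed=13, return_labels=True)
        recounted = recount_ground_truth(
            labels, vol.data, small_spec.geometry, small_spec.true_densities
        )
        assert recounted == gt

    def test_classifiable_sampler_values_stay_in_range(self, small_spec):
        assert small_spec.is_classifiable()
        vol, _, labels = cc.generate_phantom(small_spec, seed=3, return_labels=True)
        assert vol.data[labels == 1].min() >= -214 and vol.data[labels == 1].max() <= 7
        assert vol.data[labels == 2].min() >= 8 and vol.data[labels == 2].max() <= 187
        assert vol.data[labels == 3].min() >= 188

    def test_realistic_samplers_not_classifiable(self):
        spec = tapered_spec(samplers=cc.realistic_samplers())
        assert not spec.is_classifiable()


class TestSpecValidation:
    def test_body_larger_than_field_of_view(self):
        g = small_geometry(matrix=32)  # 64 mm field
        with pytest.raises(ValueError, match="field-of-view"):
            cc.PhantomSpec(geometry=g, body_axes_mm=np.tile([50.0, 20.0], (g.n_slices, 1)))

    def test_fat_rim_swallows_lean_core(self):
        with pytest.raises(ValueError, match="fat rim"):
            tapered_spec(fat_rim_mm=35.0)  # narrowest slice semi-axis is 24 mm

    def test_bone_rod_does_not_fit(self):
        with pytest.raises(ValueError, match="bone rod"):
            tapered_spec(bone_rod_radius_mm=20.0)

    def test_sampler_bounds_validated(self):
        with pytest.raises(ValueError):
            cc.TissueSampler(mean_hu=100, sd_hu=10, lo_hu=-50, hi_hu=50)


class TestLabelClassificationAgreement:
    def test_partition_recovers_labels_per_slice(self, small_spec):
        """With classifiable samplers, threshold partitioning recovers the
        generator's per-tissue voxel counts exactly on every slice."""
        vol, gt = cc.generate_phantom(small_spec, seed=21)
        stats = cc.partition_tissues(cc.convert_volume(vol))
        for j, t in enumerate(TISSUES):
            assert np.array_equal(stats.tissue_counts(t), gt.slice_counts[:, j])

    def test_self_consistent_weight_recovery_continuous(self, small_spec):
        """Continuous acquisition: pipeline weights match ground truth under
        the same density model to within 0.1%."""
        assert small_spec.geometry.is_continuous
        vol, gt = cc.generate_phantom(small_spec, seed=22)
        comp = cc.calc_totals(cc.partition_tissues(cc.convert_volume(vol)))
        for t in TISSUES:
            assert comp.weights_kg[t] == pytest.approx(gt.weights_kg[t], rel=1e-3)


class TestGappedAcquisition:
    def test_constant_shape_recovered_exactly(self):
        """Spacing = 2x thickness on a constant cross-section recovers the
        dense-acquisition volume exactly."""
        gapped = constant_spec(n_slices=6, spacing=10.0)
        dense = constant_spec(n_slices=12, spacing=5.0)
        _, gt_gap = cc.generate_phantom(gapped, seed=0)
        _, gt_dense = cc.generate_phantom(dense, seed=0)
        for t in TISSUES:
            assert gt_gap.volumes_cm3[t] == pytest.approx(gt_dense.volumes_cm3[t], abs=1e-12)
        vol, _ = cc.generate_phantom(gapped, seed=0)
        comp = cc.calc_totals(cc.partition_tissues(cc.convert_volume(vol)))
        for t in TISSUES:
            assert comp.volumes_cm3[t] == pytest.approx(gt_dense.volumes_cm3[t], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_taper_error_bounded_by_largest_area_step(self, seed):
        """For tapering shapes the gapped-vs-dense volume error is bounded by
        the gap width times the number of gaps times the largest area change
        between adjacent dense slices."""
        n_gapped = 6 + seed
        g_dense = small_geometry(n_slices=2 * n_gapped, spacing=5.0)
        g_gapped = small_geometry(n_slices=n_gapped, spacing=10.0)
        length = 5.0 * (2 * n_gapped - 1)
        axes_dense = cc.elliptical_taper_profile(
            g_dense.default_positions(), length, 50.0, 40.0, taper=0.4
        )
        axes_gapped = cc.elliptical_taper_profile(
            g_gapped.default_positions(), length, 50.0, 40.0, taper=0.4
        )
        dense = cc.PhantomSpec(
            geometry=g_dense, body_axes_mm=axes_dense, cradle=False, bone_rod_radius_mm=3.0
        )
        gapped = cc.PhantomSpec(
            geometry=g_gapped, body_axes_mm=axes_gapped, cradle=False, bone_rod_radius_mm=3.0
        )
        _, gt_d = cc.generate_phantom(dense, seed=seed)
        _, gt_g = cc.generate_phantom(gapped, seed=seed)
        pixel_area = g_dense.pixel_area_mm2
        for j, t in enumerate(TISSUES):
            areas_dense = gt_d.slice_counts[:, j] * pixel_area
            max_step = np.abs(np.diff(areas_dense)).max()
            err_mm3 = abs(gt_g.volumes_cm3[t] - gt_d.volumes_cm3[t]) * 1000.0
            assert err_mm3 <= n_gapped * 5.0 * max_step + 1e-9


class TestManifest:
    def test_round_trip(self, small_spec, tmp_path):
        _, gt = cc.generate_phantom(small_spec, seed=5)
        path = tmp_path / "gt.tsv"
        cc.write_ground_truth(gt, path)
        assert cc.read_ground_truth(path) == gt

    def test_empty_composition_round_trips_as_zero(self, tmp_path):
        gt = cc.GroundTruth(
            voxel_counts={t: 0 for t in TISSUES},
            slice_counts=np.zeros((2, 3), dtype=np.int64),
            volumes_cm3={t: 0.0 for t in TISSUES},
            mean_hu={t: float("nan") for t in TISSUES},
            weights_kg={t: 0.0 for t in TISSUES},
            physical_weights_kg={t: 0.0 for t in TISSUES},
            voxel_volume_mm3=40.0,
        )
        path = tmp_path / "gt.tsv"
        cc.write_ground_truth(gt, path)
        back = cc.read_ground_truth(path)
        assert back == gt
        assert sum(back.voxel_counts.values()) == 0

    def test_manifest_counts_match_emitted_volume(self, tmp_path):
        spec = tapered_spec(fat_rim_mm=6.0, n_bone_rods=2)
        vol, gt, labels = cc.generate_phantom(spec, seed=17, return_labels=True)
        cc.write_ground_truth(gt, tmp_path / "gt.tsv")
        back = cc.read_ground_truth(tmp_path / "gt.tsv")
        recounted = recount_ground_truth(labels, vol.data, spec.geometry, spec.true_densities)
        assert back == recounted

    def test_unwritable_path(self, small_spec, tmp_path):
        _, gt = cc.generate_phantom(small_spec, seed=5)
        with pytest.raises(OSError):
            cc.write_ground_truth(gt, tmp_path / "no" / "such" / "dir" / "gt.tsv")


def test_phantom_spec_from_yaml(tmp_path):
    cfg = tmp_path / "phantom.yaml"
    cfg.write_text(
        "geometry:\n"
        "  pixel_spacing_mm: [2.0, 2.0]\n"
        "  slice_thickness_mm: 5.0\n"
        "  slice_spacing_mm: 5.0\n"
        "  n_slices: 8\n"
        "  matrix_size: [64, 64]\n"
        "body:\n"
        "  a_max_mm: 45.0\n"
        "  b_max_mm: 35.0\n"
        "fat_rim_mm: 6.0\n"
        "cradle: false\n"
        "seed: 3\n"
    )
    spec = cc.load_phantom_spec(cfg)
    assert spec.geometry.n_slices == 8
    assert spec.fat_rim_mm == 6.0
    assert not spec.cradle
    assert 40.0 < spec.body_axes_mm[:, 0].max() <= 45.0
    vol, gt = cc.generate_phantom(spec)
    assert vol.n_slices == 8
    assert gt.voxel_counts["lean"] > 0
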