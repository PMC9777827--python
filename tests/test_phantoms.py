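"""Phantom generator: determinism, geometry, ground-truth consistency."""

import numpy as np
import pytest

from follikit.phantoms import (generate_dataset, generate_phantom,
                               regenerate_from_manifest, sample_scene)
from follikit.quantify import counting_report, extract_follicles
from skimage.measure import label as cc_label


class TestGeneratePhantom:
    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(3, size_px=128, spacing_mm=0.3, seed=42)
        b = generate_phantom(3, size_px=128, spacing_mm=0.3, seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.follicle_mask, b.follicle_mask)
        assert a.follicles == b.follicles

    def test_component_count_matches_request(self):
        scene = generate_phantom(3, size_px=192, spacing_mm=0.2, seed=5)
        n_components = cc_label(scene.follicle_mask, connectivity=2).max()
        assert n_components == 3
        assert len(scene.follicles) == 3

    def test_follicles_lie_inside_the_ovary(self):
        scene = generate_phantom(5, size_px=192, spacing_mm=0.2, seed=11)
        assert np.all(scene.ovary_mask[scene.follicle_mask.astype(bool)] == 1)

    def test_round_trip_diameter_through_quantify(self):
        # every measured diameter should agree with the generator's truth
        scene = generate_phantom(4, size_px=256, spacing_mm=0.15, seed=2)
        recs = extract_follicles(scene.follicle_mask, scene.pixel_spacing_mm)
        measured = sorted(r.diameter_mm for r in recs)
        truth = sorted(f.diameter_mm for f in scene.follicles)
        for m, t in zip(measured, truth):
            assert m == pytest.approx(t, abs=scene.pixel_spacing_mm)

    def test_requested_axes_recover_expected_diameter(self):
        # semi-axes (30, 20) px at 0.1 mm/px -> (6.0 + 4.0)/2 = 5.0 mm
        rr, cc = np.mgrid[0:101, 0:101].astype(float) - 50.0
        mask = ((rr / 30.0) ** 2 + (cc / 20.0) ** 2 <= 1.0).astype(np.uint8)
        rec, = extract_follicles(mask, 0.1)
        assert rec.diameter_mm == pytest.approx(5.0, abs=0.1)

    def test_intensity_ordering_anechoic_hypoechoic_echogenic(self):
        scene = generate_phantom(4, size_px=192, spacing_mm=0.2, seed=9)
        fol = scene.follicle_mask.astype(bool)
        ov = scene.ovary_mask.astype(bool) & ~fol
        bg = ~scene.ovary_mask.astype(bool)
        assert scene.image[fol].mean() < scene.image[ov].mean() < scene.image[bg].mean()

    def test_ground_truth_count_matches_counting_report(self):
        for seed in range(5):
            scene = generate_phantom(4, size_px=192, spacing_mm=0.2, seed=seed)
            rep = counting_report(scene.follicle_mask, scene.follicle_mask,
                                  scene.pixel_spacing_mm)
            assert rep.n_real == scene.true_antral_count

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(-1)

    def test_infeasible_packing_fails_explicitly(self):
        with pytest.raises(RuntimeError):
            generate_phantom(60, size_px=96, spacing_mm=0.4,
                             diameter_range_mm=(8.0, 14.0), seed=0,
                             max_attempts=20)

    def test_artifact_options_keep_image_in_range(self):
        scene = generate_phantom(2, size_px=96, spacing_mm=0.4, seed=3,
                                 shadow=True, contrast=0.7)
        assert scene.image.min() >= 0.0 and scene.image.max() <= 1.0

    def test_sampled_diameters_span_the_requested_range(self):
        # over many draws the diameters cover antral and dominant scales
        diameters = []
        rng = np.random.default_rng(0)
        for _ in range(60):
            scene = sample_scene(rng, size_px=96, spacing_mm=0.4,
                                 n_follicles_range=(1, 4),
                                 diameter_range_mm=(2.0, 14.0))
            diameters += [f.diameter_mm for f in scene.follicles]
        diameters = np.array(diameters)
        assert diameters.min() >= 2.0 and diameters.max() <= 14.0
        assert (diameters < 5).any() and (diameters > 10).any()


class TestGenerateDataset:
    def test_split_sizes_and_manifest_round_trip(self, tmp_path):
        out = tmp_path / "data"
        manifest = generate_dataset(
            10, out, split_fractions=(0.6, 0.2, 0.2), seed=1,
            size_px=96, spacing_mm=0.4, n_follicles_range=(0, 3),
            diameter_range_mm=(2.0, 12.0))
        counts = manifest.groupby("split").size()
        assert counts["train"] == 6 and counts["val"] == 2 and counts["test"] == 2
        assert (out / "manifest.csv").exists()

        out2 = tmp_path / "regen"
        regenerate_from_manifest(out / "manifest.json", out2)
        for split_dir in sorted(out.glob("*/images")):
            for img in sorted(split_dir.glob("*.png")):
                twin = out2 / img.relative_to(out)
                assert twin.exists()
                assert twin.read_bytes() == img.read_bytes()

    def test_bad_fractions_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(10, tmp_path, split_fractions=(0.5, 0.2), seed=0)

    def test_fewer_images_than_splits_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(2, tmp_path, split_fractions=(0.6, 0.2, 0.2), seed=0)
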