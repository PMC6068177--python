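"""Scene generator: determinism, growth monotonicity, rasterization oracle,
modality-specific rendering artifacts."""

import numpy as np
import pytest

from corneavasc import (
    GrowthParams,
    ModalityRenderConfig,
    RegionOfInterest,
    VesselSegment,
    generate_tree,
    make_study,
    rasterize_truth,
    render_modality,
    vessel_density,
)

from _oracles import capsule_mask


class TestGenerateTree:
    def test_same_seed_is_byte_identical(self):
        a = generate_tree(7)
        b = generate_tree(7)
        assert a.segments == b.segments

    def test_different_seeds_differ(self):
        assert generate_tree(1).segments != generate_tree(2).segments

    def test_zero_weeks_gives_empty_scene(self):
        tree = generate_tree(7, GrowthParams(weeks=0))
        assert tree.segments == []
        density = rasterize_truth(tree, 1, (64, 64)).mask.mean()
        assert density == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(1, field_width_mm=0.0)
        with pytest.raises(ValueError):
            GrowthParams(weeks=4, branches_per_week=0)
        with pytest.raises(ValueError):
            generate_tree(1, limbus_edge="diagonal")

    def test_tree_is_connected_and_in_field(self):
        tree = generate_tree(3)
        w = tree.field_width_mm
        for seg in tree.segments:
            for x, y in (seg.start_point, seg.end_point):
                assert -1e-9 <= x <= w + 1e-9 and -1e-9 <= y <= w + 1e-9
        # non-root segments start on a parent segment
        roots = [s for s in tree.segments if s.appearance_week == 1]
        assert roots, "week-1 roots expected"

    def test_segment_invariants_enforced(self):
        with pytest.raises(ValueError):
            VesselSegment((0, 0), (1, 1), -0.1, 1)
        with pytest.raises(ValueError):
            VesselSegment((0, 0), (0, 0), 0.1, 1)
        with pytest.raises(ValueError):
            VesselSegment((0, 0), (1, 1), 0.1, 0)


class TestRasterizeTruth:
    def test_matches_brute_force_capsule_oracle(self):
        tree = generate_tree(7, GrowthParams(weeks=2, branches_per_week=4, roots=4))
        assert len(tree.segments) <= 20
        fast = rasterize_truth(tree, 2, (64, 64)).mask
        pitch = tree.field_width_mm / 64
        segs = [(s.start_point, s.end_point, s.radius) for s in tree.segments]
        slow = capsule_mask(segs, (64, 64), pitch)
        assert np.array_equal(fast, slow)

    def test_horizontal_segment_three_pixel_band(self, tiny_tree):
        """A radius of one pixel pitch gives a three-pixel-thick band."""
        from corneavasc import VesselTree

        pitch = 3.0 / 30
        # radius of one pixel pitch (nudged off the exact pixel-center
        # distance so float rounding cannot flip the inclusive boundary)
        seg = VesselSegment((0.2, 4.5 * pitch), (2.8, 4.5 * pitch), 1.02 * pitch, 1)
        tree = VesselTree(segments=[seg], field_width_mm=3.0)
        mask = rasterize_truth(tree, 1, (30, 30)).mask
        rows = np.unique(np.where(mask)[0])
        assert list(rows) == [3, 4, 5]
        slow = capsule_mask(
            [(seg.start_point, seg.end_point, seg.radius)], (30, 30), pitch
        )
        assert np.array_equal(mask, slow)

    def test_week_masks_nest(self, tree):
        m3 = rasterize_truth(tree, 3, (128, 128)).mask
        m4 = rasterize_truth(tree, 4, (128, 128)).mask
        assert np.array_equal(m3 & m4, m3)

    def test_density_nondecreasing_over_weeks(self):
        roi = RegionOfInterest.full_frame((152, 152))
        for seed in (0, 5):
            tree = generate_tree(seed)
            dens = [
                vessel_density(rasterize_truth(tree, w, (152, 152)), roi).density_percent
                for w in range(1, 9)
            ]
            assert all(b >= a for a, b in zip(dens, dens[1:]))

    def test_week_out_of_range(self, tree):
        with pytest.raises(ValueError):
            rasterize_truth(tree, 0)
        with pytest.raises(ValueError):
            rasterize_truth(tree, 9)

    def test_caliber_filter_partitions_mask(self, tiny_tree):
        full = rasterize_truth(tiny_tree, 3, (64, 64)).mask
        large = rasterize_truth(tiny_tree, 3, (64, 64), "large").mask
        small = rasterize_truth(tiny_tree, 3, (64, 64), "small").mask
        assert np.array_equal(full, large | small)


class TestRenderModality:
    def test_noiseless_midpoint_threshold_reproduces_truth(self, tree):
        cfg = ModalityRenderConfig.clean("OCTA")
        img = render_modality(tree, 6, cfg, noise_seed=0)
        truth = rasterize_truth(tree, 6, cfg.image_size_px).mask
        midpoint = cfg.background_level + 0.5 * cfg.vessel_contrast
        assert np.array_equal(img.pixels > midpoint, truth)

    def test_noiseless_midpoint_dark_polarity(self, tree):
        cfg = ModalityRenderConfig.clean("SLP")
        img = render_modality(tree, 6, cfg, noise_seed=0)
        truth = rasterize_truth(tree, 6, cfg.image_size_px).mask
        midpoint = cfg.background_level - 0.5 * cfg.vessel_contrast
        assert np.array_equal(img.pixels < midpoint, truth)

    def test_iris_bands_bright_rows_absent_from_truth(self, tree):
        cfg = ModalityRenderConfig.clean(
            "ICGA", iris_bands=2, iris_band_intensity=0.3
        )
        img = render_modality(tree, 6, cfg, noise_seed=5)
        truth = rasterize_truth(tree, 6, cfg.image_size_px).mask
        extra = (img.pixels > cfg.background_level + 0.1) & ~truth
        # bands sit in the lower half and cover (almost) all background
        # pixels of their rows
        bg_frac = extra.sum(axis=1) / np.maximum((~truth).sum(axis=1), 1)
        rows_hit = np.where(bg_frac > 0.9)[0]
        assert len(rows_hit) >= 2
        assert np.ptp(rows_hit) >= 3  # two separate bands, each several rows
        assert rows_hit.min() > cfg.image_size_px[0] // 2

    def test_small_caliber_attenuation_favors_octa(self):
        """With 90% ICGA attenuation, more small-vessel pixels clear the
        background + 3 sigma level in OCTA than in ICGA."""
        wins = 0
        for seed in range(5):
            tree = generate_tree(seed)
            octa_cfg = ModalityRenderConfig.for_modality("OCTA")
            icga_cfg = ModalityRenderConfig.for_modality("ICGA")
            octa = render_modality(tree, 6, octa_cfg, noise_seed=seed)
            icga = render_modality(tree, 6, icga_cfg, noise_seed=seed)
            truth = rasterize_truth(tree, 6).mask
            frac = {}
            for name, img, cfg in (
                ("octa", octa, octa_cfg),
                ("icga", icga, icga_cfg),
            ):
                bg = ~truth
                level = img.pixels[bg].mean() + 3 * img.pixels[bg].std()
                frac[name] = (img.pixels[truth] > level).mean()
            wins += frac["octa"] > frac["icga"]
        assert wins >= 4

    def test_repeat_scans_share_scene_but_not_noise(self, tree):
        cfg = ModalityRenderConfig.for_modality("OCTA")
        a = render_modality(tree, 6, cfg, noise_seed=1)
        b = render_modality(tree, 6, cfg, noise_seed=2)
        c = render_modality(tree, 6, cfg, noise_seed=1)
        assert not np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.pixels, c.pixels)

    def test_polarity_consistency_enforced(self):
        with pytest.raises(ValueError):
            ModalityRenderConfig(modality="SLP", vessel_polarity="bright")
        with pytest.raises(ValueError):
            ModalityRenderConfig(modality="OCTA", vessel_polarity="dark")


class TestMakeStudy:
    def test_empty_weeks_empty_manifest(self, tmp_path):
        manifest = make_study(1, [], ["OCTA"], tmp_path)
        assert len(manifest) == 0
        assert list(manifest.columns) == [
            "file", "week", "modality", "repeat", "pixel_pitch_mm", "seed",
        ]

    def test_row_count_and_files(self, tmp_path):
        weeks = list(range(3, 9))
        manifest = make_study(
            1, weeks, ["OCTA", "ICGA", "SLP"], tmp_path,
            repeats=2, image_size_px=(64, 64),
        )
        assert len(manifest) == 36
        for fname in manifest.file:
            assert (tmp_path / fname).exists()
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "truth_week3.png").exists()

    def test_rerun_same_seed_identical_truth(self, tmp_path):
        import imageio.v3 as iio

        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_study(9, [4], ["OCTA"], d1, image_size_px=(64, 64))
        make_study(9, [4], ["OCTA"], d2, image_size_px=(64, 64))
        m1 = iio.imread(d1 / "truth_week4.png")
        m2 = iio.imread(d2 / "truth_week4.png")
        assert np.array_equal(m1, m2)
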