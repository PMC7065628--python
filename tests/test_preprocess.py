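"""Preprocessing cascade: segmentation, filters, padding, augmentation."""

import numpy as np
import pytest

from tcellact.preprocess import (AUGMENTATION_TAGS, FilterThresholds,
                                 ProcessedCell, SegmentedCell, augment,
                                 cells_from_synthetic,
                                 entropy_intensity_filter, image_entropy,
                                 lifetime_filter, pad_to_square,
                                 run_preprocessing, segment_scene)
from tcellact.synthetic import (CellClassParams, DonorProfile,
                                generate_donor)


def _disk_scene(centers, radius=8, value=180, shape=(100, 100)):
    scene = np.zeros(shape, dtype=np.uint8)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (y, x) in centers:
        scene[(rr - y) ** 2 + (cc - x) ** 2 <= radius**2] = value
    return scene


def _cell(image, mask=None, lifetime=None, **kw):
    image = np.asarray(image, dtype=np.uint8)
    mask = np.ones_like(image, dtype=bool) if mask is None else mask
    return SegmentedCell(image=image, mask=mask, mean_lifetime_ps=lifetime,
                         **kw)


class TestSegmentScene:
    def test_two_disjoint_disks_two_cells(self):
        scene = _disk_scene([(25, 25), (70, 70)])
        cells = segment_scene(scene)
        assert len(cells) == 2
        # masks disjoint: bounding boxes of the two objects do not overlap
        total = sum(c.mask.sum() for c in cells)
        assert total == (scene > 0).sum()

    def test_uniform_scene_yields_nothing(self):
        assert segment_scene(np.zeros((50, 50), dtype=np.uint8)) == []

    def test_disk_area_recovered_within_boundary_tolerance(self):
        radius = 10
        scene = _disk_scene([(40, 40)], radius=radius)
        expected = ((np.mgrid[0:100, 0:100][0] - 40) ** 2
                    + (np.mgrid[0:100, 0:100][1] - 40) ** 2
                    <= radius**2).sum()
        [cell] = segment_scene(scene)
        assert abs(cell.mask.sum() - expected) / expected < 0.05

    def test_mean_lifetime_taken_over_mask(self):
        scene = _disk_scene([(40, 40)])
        lt = np.full(scene.shape, 500.0)
        lt[scene == 0] = 0.0
        [cell] = segment_scene(scene, lifetime_map=lt)
        assert cell.mean_lifetime_ps == pytest.approx(500.0)


class TestLifetimeFilter:
    def test_below_200_removed_at_200_kept(self):
        cells = [_cell(np.full((5, 5), 50), lifetime=150.0, cell_id="low"),
                 _cell(np.full((5, 5), 50), lifetime=200.0, cell_id="edge"),
                 _cell(np.full((5, 5), 50), lifetime=500.0, cell_id="high")]
        kept = lifetime_filter(cells)
        assert [c.cell_id for c in kept] == ["edge", "high"]

    def test_identity_when_all_pass(self):
        cells = [_cell(np.full((5, 5), 50), lifetime=500.0)
                 for _ in range(4)]
        assert lifetime_filter(cells) == cells

    def test_missing_lifetime_passes_unchanged(self):
        cells = [_cell(np.full((5, 5), 50))]
        assert lifetime_filter(cells) == cells

    def test_negative_lifetime_is_corrupt(self):
        with pytest.raises(ValueError, match="corrupt"):
            lifetime_filter([_cell(np.full((5, 5), 50), lifetime=-1.0)])


class TestImageEntropy:
    def test_constant_image_zero_bits(self):
        assert image_entropy(np.full((10, 10), 7, dtype=np.uint8)) == 0.0

    def test_two_equal_values_one_bit(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:, :2] = 200
        assert image_entropy(img) == pytest.approx(1.0)

    def test_uniform_256_values_eight_bits(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert image_entropy(img) == pytest.approx(8.0)

    def test_bounded_in_0_8(self, rng):
        img = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        assert 0.0 <= image_entropy(img) <= 8.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            image_entropy(np.empty((0, 0), dtype=np.uint8))


class TestEntropyIntensityFilter:
    def test_dim_frames_removed_clean_retained(self, rng):
        """5% near-black frames are removed and >= 97% of clean frames
        survive a k_sigma=2 fit."""
        clean = [_cell(rng.integers(60, 200, size=(20, 20)), cell_id=f"c{i}")
                 for i in range(190)]
        dim = [_cell(rng.integers(0, 3, size=(20, 20)), cell_id=f"d{i}")
               for i in range(10)]
        kept, cutoffs = entropy_intensity_filter(clean + dim,
                                                 FilterThresholds(k_sigma=2))
        kept_ids = {c.cell_id for c in kept}
        assert not any(i.startswith("d") for i in kept_ids)
        assert sum(1 for c in clean if c.cell_id in kept_ids) >= 0.97 * 190
        assert cutoffs["entropy_min_bits"] > 0

    def test_explicit_zero_cutoffs_are_identity(self):
        cells = [_cell(np.full((5, 5), 100)) for _ in range(3)]
        kept, _ = entropy_intensity_filter(
            cells, FilterThresholds(entropy_min_bits=0.0,
                                    total_intensity_min=0.0))
        assert kept == cells

    def test_single_dim_cell_below_explicit_cutoffs_removed(self, rng):
        bright = [_cell(rng.integers(100, 200, size=(10, 10)))
                  for _ in range(3)]
        dim = _cell(np.zeros((10, 10)), cell_id="dim")
        kept, _ = entropy_intensity_filter(
            bright + [dim], FilterThresholds(entropy_min_bits=0.5,
                                             total_intensity_min=100.0))
        assert len(bright + [dim]) - len(kept) == 1
        assert all(c.cell_id != "dim" for c in kept)

    def test_too_few_cells_without_explicit_cutoffs(self):
        with pytest.raises(ValueError, match=">= 10"):
            entropy_intensity_filter([_cell(np.full((5, 5), 9))])


class TestPadding:
    def test_pad_preserves_pixel_sum_and_centers(self, rng):
        img = rng.integers(1, 255, size=(40, 30)).astype(np.uint8)
        cell = _cell(img)
        out = pad_to_square(cell)
        assert out.image.shape == (82, 82)
        assert int(out.image.sum()) == int(img.sum())
        assert out.mask.sum() == cell.mask.sum()
        # border introduced by padding is identically zero
        assert out.image[0, :].sum() == 0 and out.image[:, 0].sum() == 0
        # centered: content rows start at (82-40)//2
        assert out.image[21 : 61, 26 : 56].sum() == int(img.sum())

    def test_exact_size_crop_unchanged(self, rng):
        img = rng.integers(1, 255, size=(82, 82)).astype(np.uint8)
        out = pad_to_square(_cell(img))
        assert np.array_equal(out.image, img)

    def test_oversize_crop_discarded(self):
        out = pad_to_square(_cell(np.ones((90, 40), dtype=np.uint8)))
        assert out is None


class TestAugment:
    def _processed(self, rng):
        img = rng.integers(0, 255, size=(82, 82)).astype(np.uint8)
        return ProcessedCell(image=img, donor_id="d1", label="activated",
                             source_id="c0")

    def test_exactly_six_outputs_sharing_metadata(self, rng):
        outs = augment(self._processed(rng))
        assert len(outs) == 6
        assert [o.augmentation_tag for o in outs] == list(AUGMENTATION_TAGS)
        assert all(o.image.shape == (82, 82) for o in outs)
        assert all(o.donor_id == "d1" and o.label == "activated"
                   for o in outs)

    def test_rot180_equals_flip_h_then_flip_v(self, rng):
        cell = self._processed(rng)
        outs = {o.augmentation_tag: o.image for o in augment(cell)}
        assert np.array_equal(outs["rot180"],
                              outs["flip_h"][::-1, :])

    def test_histogram_invariant_across_augments(self, rng):
        outs = augment(self._processed(rng))
        ref = np.bincount(outs[0].image.ravel(), minlength=256)
        for o in outs[1:]:
            assert np.array_equal(
                np.bincount(o.image.ravel(), minlength=256), ref)

    def test_non_square_rejected(self):
        cell = ProcessedCell.__new__(ProcessedCell)
        cell.image = np.zeros((82, 40), dtype=np.uint8)
        cell.donor_id, cell.label = "d", "activated"
        cell.augmentation_tag, cell.source_id, cell.mask = "original", "", None
        with pytest.raises(ValueError, match="square"):
            augment(cell)


class TestRunPreprocessing:
    def _donor_cells(self, n=30, low_lifetime=0, seed=0):
        p = CellClassParams(radius_mean=10.0, base_intensity_mean=120.0)
        profile = DonorProfile(
            donor_id="d1", n_cells=n, class_skew=0.5,
            activated_params=p, quiescent_params=p,
            low_lifetime_rate=low_lifetime / n if n else 0.0)
        return cells_from_synthetic(generate_donor(profile, rng_seed=seed))

    def test_clean_cohort_output_is_six_times_input(self):
        cells = self._donor_cells(n=30)
        processed, report = run_preprocessing(
            cells, FilterThresholds(entropy_min_bits=0.0,
                                    total_intensity_min=0.0))
        assert len(processed) == 6 * len(cells)
        assert report.attrs["n_oversize_discarded"] == 0

    def test_lifetime_contaminants_counted_at_their_stage(self):
        cells = self._donor_cells(n=200, seed=3)
        # force exactly 10 contaminant lifetimes
        for c in cells[:10]:
            c.mean_lifetime_ps = 150.0
        processed, report = run_preprocessing(
            cells, FilterThresholds(entropy_min_bits=0.0,
                                    total_intensity_min=0.0))
        counts = report.set_index("stage")["d1"]
        assert counts["original"] - counts["after_lifetime_filter"] == 10

    def test_stage_counts_non_increasing(self):
        cells = self._donor_cells(n=60, seed=1)
        _, report = run_preprocessing(cells, FilterThresholds(k_sigma=2))
        counts = report.set_index("stage")["d1"]
        filters = counts[["original", "after_lifetime_filter",
                          "after_entropy_intensity_filter",
                          "after_padding"]].to_numpy()
        assert (np.diff(filters) <= 0).all()
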