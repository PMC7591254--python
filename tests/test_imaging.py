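"""Imaging: adaptive threshold, segmentation, colocalization, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from microrepop.imaging import (
    LabelImage,
    adaptive_threshold,
    colocalize,
    count_phenotypes,
    marker_fraction,
    mean_intensity_per_object,
    segment,
    synth_image,
)

PHENOTYPES = {
    "IBA1+MAC2+": {"IBA1": 100.0, "MAC2": 80.0},
    "IBA1+MAC2-": {"IBA1": 100.0},
}


def _labels_from_mask(mask):
    return segment(mask, min_size=1)


class TestSynthImage:
    def test_zero_cells_gives_blank_field(self):
        stack, truth = synth_image({}, PHENOTYPES)
        assert truth.empty
        assert all(not ch.any() for ch in stack.channels.values())

    def test_truth_counts_exact(self):
        stack, truth = synth_image(
            {"IBA1+MAC2+": 10, "IBA1+MAC2-": 30}, PHENOTYPES, seed=1
        )
        assert truth["phenotype"].value_counts().to_dict() == {
            "IBA1+MAC2-": 30, "IBA1+MAC2+": 10,
        }

    def test_noiseless_render_has_exact_intensities(self):
        stack, truth = synth_image({"IBA1+MAC2+": 5}, PHENOTYPES, seed=2)
        iba1 = stack.channels["IBA1"]
        assert set(np.unique(iba1)) == {0.0, 100.0}
        assert set(np.unique(stack.channels["MAC2"])) == {0.0, 80.0}

    def test_impossible_density_raises(self):
        with pytest.raises(RuntimeError, match="density"):
            synth_image({"IBA1+MAC2-": 500}, PHENOTYPES, shape=(64, 64),
                        radius=10, max_tries=50)


class TestAdaptiveThreshold:
    def test_constant_image_with_positive_offset_is_empty(self):
        assert not adaptive_threshold(np.full((30, 30), 7.0), 5, offset=1.0).any()

    def test_bright_square_matches_sliding_window_oracle(self, rng):
        image = np.zeros((24, 24))
        image[8:16, 8:16] = 50.0
        image += rng.random((24, 24))
        window = 17  # window well beyond the object so its interior stays lit
        mask = adaptive_threshold(image, window=window, offset=2.0)
        padded = np.pad(image, window // 2, mode="reflect")
        oracle = np.zeros_like(mask)
        for i in range(24):
            for j in range(24):
                local = padded[i:i + window, j:j + window].mean()
                oracle[i, j] = image[i, j] > local + 2.0
        np.testing.assert_array_equal(mask, oracle)
        assert mask[8:16, 8:16].all()  # square interior is foreground

    def test_negative_offset_saturates(self):
        image = np.full((20, 20), 3.0)
        assert adaptive_threshold(image, 5, offset=-4.0).all()

    @pytest.mark.parametrize("window", [2, 4, 1])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((10, 10)), window=window)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            adaptive_threshold(np.zeros((10, 10)), window=11)


class TestSegment:
    def test_two_squares_exact_areas(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:8, 2:8] = True  # 36 px
        mask[20:30, 20:25] = True  # 50 px
        lab = segment(mask, min_size=10)
        assert lab.n_objects == 2
        assert sorted(lab.objects["area"]) == [36, 50]

    def test_small_components_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:2, 0:2] = True  # 4 px, below min_size
        mask[10:16, 10:16] = True
        lab = segment(mask, min_size=5)
        assert lab.n_objects == 1

    def test_empty_mask(self):
        lab = segment(np.zeros((10, 10), dtype=bool))
        assert lab.n_objects == 0

    def test_translation_invariance(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:12, 5:12] = True
        shifted = np.roll(mask, (20, 15), axis=(0, 1))
        a = segment(mask, min_size=5)
        b = segment(shifted, min_size=5)
        assert sorted(a.objects["area"]) == sorted(b.objects["area"])

    def test_eight_connectivity(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0] = mask[1, 1] = True  # diagonal touch: one 8-connected object
        lab = segment(mask, min_size=1)
        assert lab.n_objects == 1


class TestColocalize:
    def test_disjoint_masks_give_no_pairs(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[0:5, 0:5] = True
        b[10:15, 10:15] = True
        pairs = colocalize(_labels_from_mask(a), _labels_from_mask(b))
        assert pairs.empty

    def test_exact_ten_percent_overlap_excluded(self):
        # Smaller mask 10 px; intersection exactly 1 px = 10%.
        a = np.zeros((30, 30), dtype=bool)
        b = np.zeros((30, 30), dtype=bool)
        a[0, 0:10] = True  # 10 px strip
        b[0:10, 0] = True  # 10 px strip; overlap pixel (0, 0)
        pairs = colocalize(_labels_from_mask(a), _labels_from_mask(b), min_overlap=0.10)
        assert pairs.empty
        pairs = colocalize(_labels_from_mask(a), _labels_from_mask(b), min_overlap=0.09)
        assert len(pairs) == 1

    def test_nested_masks_have_fraction_one(self):
        a = np.zeros((30, 30), dtype=bool)
        b = np.zeros((30, 30), dtype=bool)
        a[5:20, 5:20] = True
        b[8:12, 8:12] = True  # fully inside a
        pairs = colocalize(_labels_from_mask(a), _labels_from_mask(b))
        assert pairs["fraction"].iloc[0] == pytest.approx(1.0)

    def test_symmetry_under_channel_swap(self):
        a = np.zeros((30, 30), dtype=bool)
        b = np.zeros((30, 30), dtype=bool)
        a[0:10, 0:10] = True
        b[5:15, 5:15] = True
        ab = colocalize(_labels_from_mask(a), _labels_from_mask(b))
        ba = colocalize(_labels_from_mask(b), _labels_from_mask(a))
        assert ab["fraction"].iloc[0] == ba["fraction"].iloc[0]
        assert len(ab) == len(ba)

    def test_one_to_one_pairing_keeps_largest_overlap(self):
        a = np.zeros((30, 30), dtype=bool)
        a[0:10, 0:20] = True  # one big object in a
        b = np.zeros((30, 30), dtype=bool)
        b[0:10, 0:12] = True
        b[0:10, 14:20] = True  # two objects in b, both overlapping a
        pairs = colocalize(_labels_from_mask(a), _labels_from_mask(b))
        assert len(pairs) == 1  # a's object pairs once, with the larger overlap
        assert pairs["n_pixels"].iloc[0] == 120

    def test_shape_mismatch_rejected(self):
        a = _labels_from_mask(np.zeros((10, 10), dtype=bool))
        b = _labels_from_mask(np.zeros((12, 12), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            colocalize(a, b)


def _segment_stack(stack, window=51, offset=5.0, min_size=20):
    return {
        name: segment(adaptive_threshold(img, window=window, offset=offset),
                      min_size=min_size)
        for name, img in stack.channels.items()
    }


class TestPhenotypeCounts:
    def test_noiseless_recovery_is_exact(self):
        stack, truth = synth_image(
            {"IBA1+MAC2+": 20, "IBA1+MAC2-": 60}, PHENOTYPES, shape=(700, 700),
            seed=3,
        )
        counts = count_phenotypes(_segment_stack(stack), anchor="IBA1")
        got = counts.set_index("phenotype")["count"].to_dict()
        assert got == {"IBA1+MAC2+": 20, "IBA1+MAC2-": 60}
        assert marker_fraction(counts, "MAC2") == pytest.approx(25.0)

    def test_absent_marker_channel_gives_zero_positives(self):
        stack, _ = synth_image({"IBA1+MAC2-": 15}, PHENOTYPES, seed=4)
        counts = count_phenotypes(_segment_stack(stack), anchor="IBA1")
        assert marker_fraction(counts, "MAC2") == 0.0

    def test_counts_partition_anchor_objects(self):
        stack, _ = synth_image(
            {"IBA1+MAC2+": 12, "IBA1+MAC2-": 18}, PHENOTYPES, shape=(600, 600),
            seed=5,
        )
        labels = _segment_stack(stack)
        counts = count_phenotypes(labels, anchor="IBA1")
        assert counts["count"].sum() == labels["IBA1"].n_objects

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            count_phenotypes({}, anchor="IBA1")

    def test_noisy_recovery_within_five_percent(self):
        stack, truth = synth_image(
            {"IBA1+MAC2+": 40, "IBA1+MAC2-": 120}, PHENOTYPES, shape=(900, 900),
            noise_sd=20.0, seed=6,  # 20% of the IBA1 signal
        )
        # Offset sits above the noise floor (~1 SD) so background stays dark.
        counts = count_phenotypes(_segment_stack(stack, offset=25.0), anchor="IBA1")
        total = counts["count"].sum()
        mac2 = counts.loc[counts["phenotype"] == "IBA1+MAC2+", "count"].sum()
        assert abs(total - 160) / 160 <= 0.05
        assert abs(mac2 - 40) / 40 <= 0.05


class TestMeanIntensity:
    def test_uniform_channel(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:8, 2:8] = True
        lab = _labels_from_mask(mask)
        out = mean_intensity_per_object(np.full((20, 20), 7.5), lab)
        assert out["mean_intensity"].iloc[0] == pytest.approx(7.5)

    def test_two_objects_with_planted_intensities(self):
        img = np.zeros((30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        img[2:8, 2:8] = 10.0
        img[20:26, 20:26] = 50.0
        lab = _labels_from_mask(mask)
        out = mean_intensity_per_object(img, lab)
        assert sorted(out["mean_intensity"]) == [10.0, 50.0]

    def test_empty_anchor_gives_empty_table(self):
        lab = _labels_from_mask(np.zeros((10, 10), dtype=bool))
        assert mean_intensity_per_object(np.zeros((10, 10)), lab).empty
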