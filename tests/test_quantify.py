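"""Follicle sizing, recruitable filtering, matching and counting."""

import itertools

import numpy as np
import pytest

from follikit.quantify import (FollicleRecord, counting_rates,
                               counting_report, extract_follicles,
                               match_follicles, pairwise_dice,
                               recruitable_filter)
from tests.conftest import rasterized_disk


def place(canvas, mask, row, col):
    h, w = mask.shape
    canvas[row:row + h, col:col + w] |= mask
    return canvas


class TestExtractFollicles:
    def test_empty_mask_gives_empty_list(self):
        assert extract_follicles(np.zeros((10, 10)), 0.1) == []

    def test_disk_diameter_within_one_pixel_spacing(self):
        # radius 25 px at 0.1 mm/px: true diameter 5.0 mm
        mask = rasterized_disk(25)
        recs = extract_follicles(mask, 0.1)
        assert len(recs) == 1
        assert recs[0].diameter_mm == pytest.approx(5.0, abs=0.1)
        assert recs[0].recruitable

    @pytest.mark.parametrize("radius", [10, 15, 30, 50])
    def test_moment_diameter_converges_with_radius(self, radius):
        mask = rasterized_disk(radius)
        recs = extract_follicles(mask, 0.1)
        true_mm = 2 * radius * 0.1
        assert recs[0].diameter_mm == pytest.approx(true_mm, abs=0.1)

    def test_two_separated_disks_give_two_records(self):
        canvas = np.zeros((80, 80), dtype=np.uint8)
        place(canvas, rasterized_disk(8, pad=1), 5, 5)
        place(canvas, rasterized_disk(8, pad=1), 50, 50)
        recs = extract_follicles(canvas, 0.1)
        assert len(recs) == 2
        assert recs[0].centroid != recs[1].centroid

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            extract_follicles(np.zeros((5, 5)), 0.0)


def _record(diameter_mm, label=1, pixels=None):
    return FollicleRecord(
        label=label, centroid=(0.0, 0.0), major_axis_px=10, minor_axis_px=8,
        diameter_mm=diameter_mm, recruitable=2 <= diameter_mm <= 10,
        pixel_set=pixels if pixels is not None else np.ones((2, 2), bool))


class TestRecruitableFilter:
    @pytest.mark.parametrize("diameter,kept", [
        (5.0, True),     # mid antral range
        (2.0, True),     # inclusive lower bound
        (10.0, True),    # inclusive upper bound
        (15.0, False),   # dominant follicle
        (1.5, False),    # sub-antral / vessel scale
    ])
    def test_range_membership(self, diameter, kept):
        out = recruitable_filter([_record(diameter)])
        assert (len(out) == 1) is kept

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            recruitable_filter([], low=10, high=2)


class TestMatchFollicles:
    def _records_from_mask(self, mask):
        return extract_follicles(mask, 0.1)

    def test_identical_masks_match_every_component_at_dice_one(self):
        canvas = np.zeros((80, 80), dtype=np.uint8)
        for pos in [(5, 5), (40, 10), (50, 50)]:
            place(canvas, rasterized_disk(7, pad=1), *pos)
        recs = self._records_from_mask(canvas)
        matches = match_follicles(recs, recs)
        assert len(matches) == 3
        assert all(d == pytest.approx(1.0) for _, _, d in matches)

    def test_dice_exactly_half_is_not_a_match(self):
        # two rectangles overlapping at exactly Dice 0.5
        gt = np.zeros((10, 20), dtype=np.uint8)
        pred = np.zeros((10, 20), dtype=np.uint8)
        gt[2:6, 0:8] = 1       # 32 px
        pred[2:6, 4:12] = 1    # 32 px, overlap 16 -> Dice = 32/64 = 0.5
        g = extract_follicles(gt, 0.1)
        p = extract_follicles(pred, 0.1)
        assert pairwise_dice(g[0].pixel_set, p[0].pixel_set) == pytest.approx(0.5)
        assert match_follicles(g, p) == []

    def test_straddling_prediction_matched_one_to_one(self):
        # 3 gt disks, 2 preds; one pred overlaps two gt components.
        gt = np.zeros((60, 140), dtype=np.uint8)
        for col in (5, 45, 100):
            place(gt, rasterized_disk(9, pad=1), 20, col)
        pred = np.zeros((60, 140), dtype=np.uint8)
        pred[20 + 2:20 + 19, 5:60] = 1   # straddles gt disks 1 and 2
        place(pred, rasterized_disk(9, pad=1), 20, 100)
        g = extract_follicles(gt, 0.1)
        p = extract_follicles(pred, 0.1)
        matches = match_follicles(g, p)
        assert len(matches) <= 2
        # one-to-one: no pred (or gt) label appears twice
        assert len({m[1] for m in matches}) == len(matches)
        assert len({m[0] for m in matches}) == len(matches)
        # greedy equals exhaustive optimal assignment here
        best = 0
        for perm in itertools.permutations(g, len(p)):
            score = sum(
                1 for gg, pp in zip(perm, p)
                if pairwise_dice(gg.pixel_set, pp.pixel_set) > 0.5)
            best = max(best, score)
        assert len(matches) == best

    def test_geometry_mismatch_rejected(self):
        a = [_record(5.0, pixels=np.ones((4, 4), bool))]
        b = [_record(5.0, pixels=np.ones((5, 5), bool))]
        with pytest.raises(ValueError, match="geometr"):
            match_follicles(a, b)


class TestCountingReport:
    def test_self_match_is_perfect(self):
        canvas = np.zeros((100, 100), dtype=np.uint8)
        for pos in [(10, 10), (10, 60), (60, 35)]:
            place(canvas, rasterized_disk(10, pad=1), *pos)
        rep = counting_report(canvas, canvas, 0.2)
        assert rep.n_real == rep.n_detected == rep.n_correct == 3
        assert rep.precision == rep.recall == 1.0

    def test_empty_prediction_is_flagged_degenerate(self):
        gt = np.zeros((40, 40), dtype=np.uint8)
        place(gt, rasterized_disk(10, pad=1), 5, 5)
        rep = counting_report(gt, np.zeros_like(gt), 0.2)
        assert rep.recall == 0.0 and rep.precision == 0.0
        assert rep.degenerate

    def test_oversized_components_are_filtered_from_both_masks(self):
        # a 60-px-radius blob at 0.2 mm/px is 24 mm: dominant, not counted
        gt = np.zeros((200, 200), dtype=np.uint8)
        place(gt, rasterized_disk(60, pad=1), 20, 20)
        place(gt, rasterized_disk(10, pad=1), 170, 170)
        rep = counting_report(gt, gt, 0.2)
        assert rep.n_real == rep.n_detected == 1

    def test_counting_is_intensity_free(self):
        # depends only on masks and spacing by construction of the API
        gt = np.zeros((60, 60), dtype=np.uint8)
        place(gt, rasterized_disk(12, pad=1), 10, 10)
        rep1 = counting_report(gt, gt, 0.2)
        rep2 = counting_report(gt.astype(bool).astype(np.uint8), gt, 0.2)
        assert rep1.n_correct == rep2.n_correct == 1


class TestCountingRates:
    def test_fraction_arithmetic(self):
        precision, recall = counting_rates(344, 448, 378)
        assert recall == pytest.approx(344 / 378)
        assert precision == pytest.approx(344 / 448)

    def test_zero_denominators_give_zero(self):
        assert counting_rates(0, 0, 5) == (0.0, 0.0)
        assert counting_rates(0, 5, 0) == (0.0, 0.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            counting_rates(10, 5, 20)
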