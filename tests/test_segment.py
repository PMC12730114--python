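"""Segmentation, ROI filtering, ring morphology and full-res projection."""

import numpy as np
import pytest

from hpastack.segment import (
    DISK_5X5,
    NucleusROI,
    SegmentationBackend,
    crop_roi,
    filter_rois,
    project_to_fullres,
    representative_cell,
    ring_from_nucleus,
    segment_nuclei,
)


# --- independent brute-force morphology oracle -----------------------------


def _brute_dilate(mask, se):
    """Set-definition dilation: OR of mask shifted by every SE offset."""
    r = se.shape[0] // 2
    out = np.zeros_like(mask)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not se[dy + r, dx + r]:
                continue
            shifted = np.zeros_like(mask)
            ys = slice(max(0, dy), mask.shape[0] + min(0, dy))
            xs = slice(max(0, dx), mask.shape[1] + min(0, dx))
            ys_src = slice(max(0, -dy), mask.shape[0] + min(0, -dy))
            xs_src = slice(max(0, -dx), mask.shape[1] + min(0, -dx))
            shifted[ys, xs] = mask[ys_src, xs_src]
            out |= shifted
    return out


def _brute_erode(mask, se):
    se = se.astype(bool)
    r = se.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    out = np.zeros_like(mask)
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            window = padded[y : y + 2 * r + 1, x : x + 2 * r + 1]
            out[y, x] = bool(np.all(window[se]))
    return out


class TestRingMorphology:
    def test_structuring_element_is_the_13_pixel_discrete_disk(self):
        assert DISK_5X5.shape == (5, 5)
        assert int(DISK_5X5.sum()) == 13

    def test_empty_mask_gives_empty_ring(self):
        ring = ring_from_nucleus(np.zeros((9, 9), dtype=bool))
        assert not ring.mask.any()

    def test_single_pixel_mask_ring_is_the_disk_footprint(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        ring = ring_from_nucleus(mask)
        # erosion of a single pixel is empty, so the ring is the dilation
        assert int(ring.mask.sum()) == 13
        np.testing.assert_array_equal(ring.mask, _brute_dilate(mask, DISK_5X5))

    @pytest.mark.parametrize("shape", ["square", "blob", "two_blobs"])
    def test_ring_matches_brute_force_oracle_exhaustively(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        mask = np.zeros((24, 24), dtype=bool)
        if shape == "square":
            mask[5:19, 4:18] = True
        elif shape == "blob":
            yy, xx = np.mgrid[0:24, 0:24]
            mask = (yy - 12) ** 2 + (xx - 11) ** 2 <= 49
        else:
            mask[3:9, 3:9] = True
            mask[14:21, 13:20] = True
        ring = ring_from_nucleus(mask)
        expected = _brute_dilate(mask, DISK_5X5) & ~_brute_erode(mask, DISK_5X5)
        np.testing.assert_array_equal(ring.mask, expected)
        # invariants: ring excludes the eroded core, stays inside the dilation
        assert not (ring.mask & _brute_erode(mask, DISK_5X5)).any()
        assert (ring.mask <= _brute_dilate(mask, DISK_5X5)).all()
        _ = rng

    def test_solid_square_ring_is_a_closed_band(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[6:26, 6:26] = True
        ring = ring_from_nucleus(mask)
        from scipy import ndimage as ndi

        filled = ndi.binary_fill_holes(ring.mask)
        assert filled.sum() > ring.mask.sum()  # it encloses a hole


class TestSegmentation:
    def test_blank_image_yields_no_rois(self):
        assert segment_nuclei(np.zeros((64, 64), dtype=np.uint8)) == []

    def test_planted_nuclei_are_recovered_with_good_iou(self, clean_synth):
        """>= 95% of planted non-border nuclei found at IoU >= 0.5
        (noise sigma 5)."""
        index, truth = clean_synth
        found, total = 0, 0
        for rec in index.records:
            rois = segment_nuclei(rec.channels["blue"])
            for planted in truth.nucleus_masks[rec.sample_id]:
                border = (
                    planted[0, :].any() or planted[-1, :].any()
                    or planted[:, 0].any() or planted[:, -1].any()
                )
                if border:
                    continue
                total += 1
                best = 0.0
                for roi in rois:
                    inter = (roi.mask & planted).sum()
                    union = (roi.mask | planted).sum()
                    best = max(best, inter / union)
                if best >= 0.5:
                    found += 1
        assert total > 20
        assert found / total >= 0.95

    def test_detected_masks_are_pairwise_disjoint(self, clean_synth):
        index, _ = clean_synth
        rec = index.records[0]
        rois = segment_nuclei(rec.channels["blue"])
        union = np.zeros(rec.shape, dtype=int)
        for roi in rois:
            union += roi.mask
        assert union.max() <= 1

    def test_border_touching_nucleus_is_detected_and_flagged(self):
        img = np.full((64, 64), 8, dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 64] = 200  # interior
        img[(yy - 0) ** 2 + (xx - 55) ** 2 <= 64] = 200   # clipped at row 0
        rois = segment_nuclei(img)
        assert len(rois) == 2
        flags = sorted(r.touches_border for r in rois)
        assert flags == [False, True]

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="unknown segmentation backend"):
            segment_nuclei(np.zeros((32, 32), dtype=np.uint8),
                           SegmentationBackend(name="nope"))


class TestFiltering:
    def _roi(self, area, at_border=False, roi_id=0, frame=40):
        mask = np.zeros((frame, frame), dtype=bool)
        side = int(np.ceil(np.sqrt(area)))
        r0 = 0 if at_border else 5
        flat = np.zeros(side * side, dtype=bool)
        flat[:area] = True
        mask[r0 : r0 + side, 5 : 5 + side] = flat.reshape(side, side)
        return NucleusROI.from_mask(roi_id, mask)

    def test_minimum_area_boundary_is_inclusive_at_100(self):
        removed = self._roi(99)
        kept = self._roi(100, roi_id=1)
        out = filter_rois([removed, kept])
        assert [r.roi_id for r in out] == [1]

    def test_border_pixel_in_row_zero_removes_roi(self):
        roi = self._roi(150, at_border=True)
        assert filter_rois([roi]) == []

    def test_empty_input_and_idempotence(self):
        assert filter_rois([]) == []
        rois = [self._roi(120, roi_id=1), self._roi(99, roi_id=2)]
        once = filter_rois(rois)
        assert filter_rois(once) == once


class TestProjection:
    def test_identity_shape_returns_equal_mask(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        out = project_to_fullres(mask, (16, 16))
        np.testing.assert_array_equal(out, mask)

    def test_2x_upscale_doubles_stripe_width(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[:, 20:30] = True  # 10 px wide stripe
        out = project_to_fullres(mask, (128, 128))
        widths = out.sum(axis=1)
        assert (widths == 20).all()
        assert out.dtype == bool

    def test_crop_sum_equals_mask_area_times_intensity(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 8:18] = True
        full = project_to_fullres(mask, (64, 64))
        green = np.full((64, 64), 255, dtype=np.uint8)
        crop = crop_roi(green, full)
        assert int(crop.astype(np.int64).sum()) == 255 * int(full.sum())

    def test_crop_zeroes_background(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        img = np.full((16, 16), 7, dtype=np.uint8)
        crop = crop_roi(img, mask, bbox=(2, 2, 10, 10))
        assert crop.shape == (8, 8)
        assert crop.sum() == 7 * 16  # only the masked 4x4 survives

    def test_empty_mask_cannot_be_cropped(self):
        with pytest.raises(ValueError, match="empty mask"):
            crop_roi(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestRepresentativeCell:
    def _roi_with_area(self, area, roi_id):
        mask = np.zeros((60, 60), dtype=bool)
        side = int(np.sqrt(area))
        rest = area - side * side
        mask[5 : 5 + side, 5 : 5 + side] = True
        if rest:
            mask[5 + side, 5 : 5 + rest] = True
        return NucleusROI.from_mask(roi_id, mask)

    def test_odd_count_picks_the_median_area(self):
        rois = [self._roi_with_area(a, i) for i, a in enumerate([50, 100, 150])]
        assert representative_cell(rois).area_px == 100

    def test_even_count_picks_the_lower_median(self):
        rois = [self._roi_with_area(a, i) for i, a in enumerate([100, 200])]
        assert representative_cell(rois).area_px == 100

    def test_area_ties_break_by_lowest_roi_id(self):
        rois = [self._roi_with_area(100, 5), self._roi_with_area(100, 2)]
        assert representative_cell(rois).roi_id == 2

    def test_single_roi_returns_itself(self):
        roi = self._roi_with_area(64, 3)
        assert representative_cell([roi]) is roi

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            representative_cell([])
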