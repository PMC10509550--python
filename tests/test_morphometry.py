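from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from _oracles import (
    brute_force_min_distance_px,
    brute_force_width_px,
    flood_fill_count,
    random_blob,
    random_multi_blob,
)
from conftest import make_mask, tumor_mask_from_bool
from fragmetrics import (
    DEFAULT_LABEL_MAP,
    LuminalSurface,
    classify_pattern,
    extract_fragments,
    fragment_width,
    lumen_distance,
    slide_tumor_area,
)
from fragmetrics.morphometry import PatternCall


def disk(radius_px: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    rr, cc = np.mgrid[:n, :n] - (radius_px + pad)
    return rr * rr + cc * cc <= radius_px * radius_px


def flat_surface(row: int, n_cols: int) -> LuminalSurface:
    pts = np.column_stack([np.full(n_cols, row), np.arange(n_cols)])
    return LuminalSurface(points=pts, source="annotated")


class TestExtractFragments:
    def test_no_tumor_gives_empty_list(self):
        mask = tumor_mask_from_bool(np.zeros((10, 10), bool))
        assert extract_fragments(mask) == []

    def test_two_separated_disks_give_two_fragments(self):
        occ = np.zeros((40, 80), bool)
        occ[10:20, 10:20] = True
        occ[10:20, 50:60] = True
        frags = extract_fragments(tumor_mask_from_bool(occ))
        assert len(frags) == 2
        assert all(f.pixel_count == 100 for f in frags)

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            occ = random_multi_blob(rng)
            frags = extract_fragments(tumor_mask_from_bool(occ), min_area_mm2=0.0)
            assert len(frags) == flood_fill_count(occ)

    def test_min_area_filter_drops_specks(self):
        occ = np.zeros((30, 30), bool)
        occ[5, 5] = True  # single pixel: 0.0004 mm^2 at 0.02 mm/px
        occ[15:25, 15:25] = True
        frags = extract_fragments(tumor_mask_from_bool(occ), min_area_mm2=0.001)
        assert len(frags) == 1
        assert frags[0].pixel_count == 100

    def test_fragment_invariants(self):
        rng = np.random.default_rng(23)
        px = 0.02
        for _ in range(10):
            occ = random_blob(rng)
            frags = extract_fragments(tumor_mask_from_bool(occ, pixel_size_mm=px))
            for f in frags:
                assert f.area_mm2 == pytest.approx(f.pixel_count * px * px)
                # the inscribed disk fits inside the fragment
                assert np.pi * (f.width_mm / 2) ** 2 <= f.area_mm2 + np.pi * px * f.width_mm
                assert f.width_mm >= px


class TestFragmentWidth:
    def test_digital_disk_width_is_its_diameter(self):
        occ = disk(25)
        assert fragment_width(occ, 0.01) == pytest.approx(0.50, abs=0.02)

    def test_long_thin_rectangle_width_is_short_axis(self):
        # a 3 mm x 0.05 mm sliver: its width, not its length, is what an
        # imaging technique must resolve
        occ = np.zeros((11, 306), bool)
        occ[3:8, 3:303] = True  # 300 x 5 px at 0.01 mm/px
        assert fragment_width(occ, 0.01) == pytest.approx(0.05, abs=0.02)

    def test_matches_brute_force_oracle_on_random_blobs(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            occ = random_blob(rng, size=30)
            got = fragment_width(occ, 1.0)
            assert got == pytest.approx(brute_force_width_px(occ), abs=0.5)

    def test_min_feret_of_rectangle(self):
        occ = np.zeros((11, 306), bool)
        occ[3:8, 3:303] = True
        got = fragment_width(occ, 0.01, method="min_feret")
        assert got == pytest.approx(0.05, abs=0.001)

    def test_dilation_never_shrinks_width(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            occ = random_blob(rng, size=30)
            grown = ndimage.binary_dilation(occ, np.ones((3, 3), bool))
            grown[0, :] = grown[-1, :] = grown[:, 0] = grown[:, -1] = False
            assert fragment_width(grown, 1.0) >= fragment_width(occ, 1.0)

    def test_empty_fragment_is_an_error(self):
        with pytest.raises(ValueError):
            fragment_width(np.zeros((5, 5), bool), 0.02)


class TestLumenDistance:
    def test_touching_fragment_is_within_one_pixel(self):
        occ = np.zeros((20, 20), bool)
        occ[5:10, 5:10] = True  # top row = surface row
        surface = flat_surface(5, 20)
        frags = extract_fragments(tumor_mask_from_bool(occ), surface=surface)
        assert frags[0].min_lumen_dist_mm <= 0.02

    def test_known_offset_recovered(self):
        occ = np.zeros((60, 30), bool)
        occ[30:40, 10:20] = True
        surface = flat_surface(5, 30)
        # nearest fragment pixel row 30 vs surface row 5 -> 25 px
        d = lumen_distance(np.argwhere(occ), surface, 0.02)
        assert d == pytest.approx(25 * 0.02)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(37)
        occ = random_blob(rng, size=30)
        occ[:2, :] = False
        surface = flat_surface(0, 30)
        d = lumen_distance(np.argwhere(occ), surface, 0.02)
        d_flipped = lumen_distance(np.argwhere(occ[:, ::-1]), surface, 0.02)
        assert d == pytest.approx(d_flipped)

    def test_matches_brute_force_pairwise_minimum(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            occ = random_blob(rng, size=25)
            occ[0, :] = False
            surface = flat_surface(0, 25)
            got = lumen_distance(np.argwhere(occ), surface, 1.0)
            want = brute_force_min_distance_px(np.argwhere(occ), surface.points)
            assert got == pytest.approx(want, rel=1e-12)

    def test_empty_surface_is_an_error(self):
        with pytest.raises(ValueError, match="surface undefined"):
            lumen_distance(np.array([[1, 1]]), None, 0.02)


def two_square_fragments(gap_px: int, px: float = 0.02):
    """Two 10x10 squares with an edge-to-edge distance of gap_px pixels."""
    occ = np.zeros((30, 40 + gap_px), bool)
    occ[10:20, 5:15] = True
    occ[10:20, 14 + gap_px : 24 + gap_px] = True
    return extract_fragments(tumor_mask_from_bool(occ, pixel_size_mm=px))


class TestClassifyPattern:
    def test_single_fragment_is_shrinkage(self):
        occ = np.zeros((20, 20), bool)
        occ[5:15, 5:15] = True
        frags = extract_fragments(tumor_mask_from_bool(occ))
        call = classify_pattern(frags, pixel_size_mm=0.02)
        assert call.pattern == "shrinkage"
        assert call.n_clusters == 1

    def test_two_fragments_5mm_apart_is_fragmentation(self):
        frags = two_square_fragments(gap_px=250)  # 5.0 mm
        call = classify_pattern(frags, pixel_size_mm=0.02)
        assert call.pattern == "fragmentation"
        assert call.n_clusters == 2

    @pytest.mark.parametrize(
        "gap_mm,expected", [(2.9, "shrinkage"), (3.1, "fragmentation")]
    )
    def test_three_mm_threshold(self, gap_mm, expected):
        frags = two_square_fragments(gap_px=int(round(gap_mm / 0.02)))
        call = classify_pattern(frags, pixel_size_mm=0.02)
        assert call.pattern == expected

    def test_single_linkage_chain(self):
        # A-B at 2 mm merge, B-C at 4 mm stays apart: clusters {A,B},{C}
        px = 0.02
        occ = np.zeros((30, 500), bool)
        occ[10:20, 5:15] = True  # A ends col 14
        occ[10:20, 115:125] = True  # B starts col 115: 100 px = 2 mm
        occ[10:20, 325:335] = True  # C starts col 325: 200 px = 4 mm
        frags = extract_fragments(tumor_mask_from_bool(occ, pixel_size_mm=px))
        call = classify_pattern(frags, pixel_size_mm=px)
        assert call.pattern == "fragmentation"
        assert call.n_clusters == 2
        ids = sorted(f.cluster_id for f in frags)
        assert ids[0] == ids[1] != ids[2]

    def test_bulk_on_serial_slides_stays_shrinkage(self):
        occ = np.zeros((20, 20), bool)
        occ[5:15, 5:15] = True
        frags = []
        for sid in ("S00", "S01", "S02"):
            frags += extract_fragments(
                tumor_mask_from_bool(occ, slide_id=sid), min_area_mm2=0.0
            )
        call = classify_pattern(frags, pixel_size_mm=0.02)
        assert call.pattern == "shrinkage"

    def test_no_fragments_is_an_error(self):
        with pytest.raises(ValueError, match="no residual tumor"):
            classify_pattern([], pixel_size_mm=0.02)

    def test_pattern_call_consistency_enforced(self):
        with pytest.raises(ValueError):
            PatternCall(pattern="fragmentation", n_clusters=1)


class TestSlideTumorArea:
    def test_no_tumor_is_zero(self):
        assert slide_tumor_area(tumor_mask_from_bool(np.zeros((5, 5), bool))) == 0.0

    def test_pixel_count_times_pixel_area(self):
        occ = np.zeros((120, 120), bool)
        occ[10:110, 10:110] = True  # 10,000 px at 0.01 mm/px -> 1 mm^2
        mask = tumor_mask_from_bool(occ, pixel_size_mm=0.01)
        assert slide_tumor_area(mask) == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(43)
        occ = random_blob(rng)
        a = slide_tumor_area(tumor_mask_from_bool(occ))
        b = slide_tumor_area(tumor_mask_from_bool(np.rot90(occ)))
        assert a == b
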