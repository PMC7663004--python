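"""Structuring elements and the four morphological operators."""

import numpy as np
import pytest

from agavecount import (
    DIAMOND2,
    SQUARE3,
    close_mask,
    dilate,
    erode,
    make_se,
    open_mask,
    se_from_string,
    separate_objects,
)
from conftest import (
    brute_force_dilate,
    brute_force_erode,
    draw_disk,
    random_blob_mask,
)


class TestStructuringElements:
    def test_square3_has_nine_offsets(self):
        se = make_se("square", 3)
        assert len(se.offsets) == 9
        assert se.offsets == frozenset(
            (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        )

    def test_diamond2_is_city_block_ball(self):
        se = make_se("diamond", 2)
        assert len(se.offsets) == 13
        assert all(abs(dy) + abs(dx) <= 2 for dy, dx in se.offsets)

    def test_identity_element(self):
        assert make_se("diamond", 0).offsets == frozenset({(0, 0)})

    @pytest.mark.parametrize("shape,size", [("square", 4), ("square", 0),
                                            ("diamond", -1), ("hex", 3)])
    def test_invalid_elements_rejected(self, shape, size):
        with pytest.raises(ValueError):
            make_se(shape, size)

    def test_string_round_trip(self):
        assert se_from_string("square:3").offsets == SQUARE3.offsets
        assert se_from_string("diamond:2").offsets == DIAMOND2.offsets
        with pytest.raises(ValueError):
            se_from_string("square3")


class TestOperators:
    def test_erode_shrinks_from_border(self):
        solid = np.ones((5, 5), bool)
        expect = np.zeros((5, 5), bool)
        expect[1:4, 1:4] = True
        np.testing.assert_array_equal(erode(solid, SQUARE3), expect)

    def test_dilate_single_pixel_to_diamond(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = dilate(m, DIAMOND2)
        assert out.sum() == 13
        ys, xs = np.nonzero(out)
        assert all(abs(y - 3) + abs(x - 3) <= 2 for y, x in zip(ys, xs))

    def test_identity_se_is_noop(self, rng):
        ident = make_se("diamond", 0)
        m = random_blob_mask(rng)
        np.testing.assert_array_equal(erode(m, ident), m)
        np.testing.assert_array_equal(dilate(m, ident), m)

    def test_empty_mask_fixed_point(self):
        empty = np.zeros((9, 9), bool)
        for op in (erode, dilate, open_mask, close_mask):
            assert not op(empty, SQUARE3).any()

    def test_opening_removes_thin_bridge(self):
        m = np.zeros((12, 32), bool)
        m[1:11, 1:11] = True
        m[1:11, 21:31] = True
        squares = m.copy()
        m[5:7, 11:21] = True  # 2-px-wide bridge
        np.testing.assert_array_equal(open_mask(m, SQUARE3), squares)

    def test_closing_fills_small_gap(self):
        solid = np.zeros((9, 9), bool)
        solid[1:8, 1:8] = True
        gap = solid.copy()
        gap[4, 4] = False
        np.testing.assert_array_equal(close_mask(gap, SQUARE3), solid)

    def test_close_of_full_foreground_keeps_interior(self):
        # outside-the-frame is background, so closing strips the 1-px rim
        # (the same policy that makes frame-touching plants erode); the
        # interior is untouched
        full = np.ones((8, 8), bool)
        out = close_mask(full, SQUARE3)
        assert out[1:7, 1:7].all()
        np.testing.assert_array_equal(close_mask(out, SQUARE3), out)


class TestAlgebraicProperties:
    @pytest.mark.parametrize("se", [SQUARE3, DIAMOND2], ids=str)
    def test_oracle_equivalence_random_masks(self, se, rng):
        """All four operators agree with the double-loop definition."""
        offs = sorted(se.offsets)
        for _ in range(20):
            m = random_blob_mask(rng)
            bf_e = brute_force_erode(m, offs)
            bf_d = brute_force_dilate(m, offs)
            np.testing.assert_array_equal(erode(m, se), bf_e)
            np.testing.assert_array_equal(dilate(m, se), bf_d)
            np.testing.assert_array_equal(
                open_mask(m, se), brute_force_dilate(bf_e, offs)
            )
            np.testing.assert_array_equal(
                close_mask(m, se), brute_force_erode(bf_d, offs)
            )

    @pytest.mark.parametrize("se", [SQUARE3, DIAMOND2], ids=str)
    def test_extensivity_and_idempotence(self, se, rng):
        # closing's extensivity is asserted on padded fixtures: at the frame
        # itself the outside-is-background policy removes rim pixels
        for _ in range(10):
            core = random_blob_mask(rng, shape=(24, 24))
            m = np.zeros((32, 32), bool)
            m[4:28, 4:28] = core
            opened, closed = open_mask(m, se), close_mask(m, se)
            assert not (erode(m, se) & ~m).any()
            assert not (m & ~dilate(m, se)).any()
            assert not (opened & ~m).any()  # open(X) subset of X
            assert not (m & ~closed).any()  # X subset of close(X)
            np.testing.assert_array_equal(open_mask(opened, se), opened)
            np.testing.assert_array_equal(close_mask(closed, se), closed)

    @pytest.mark.parametrize("op", [erode, dilate, open_mask, close_mask])
    def test_monotonicity(self, op, rng):
        for _ in range(10):
            small = random_blob_mask(rng, p=0.3)
            big = small | random_blob_mask(rng, p=0.2)
            assert not (op(small, SQUARE3) & ~op(big, SQUARE3)).any()

    def test_erosion_dilation_duality_away_from_border(self, rng):
        """erode(X) == ~dilate(~X) on the interior of padded masks."""
        for _ in range(10):
            core = random_blob_mask(rng, shape=(20, 20))
            m = np.zeros((28, 28), bool)
            m[4:24, 4:24] = core
            lhs = erode(m, DIAMOND2)
            rhs = ~dilate(~m, DIAMOND2)
            np.testing.assert_array_equal(lhs[3:25, 3:25], rhs[3:25, 3:25])


class TestSeparateObjects:
    def test_necks_cut_bodies_kept(self):
        m = draw_disk((40, 80), (20, 20), 12)
        m = draw_disk((40, 80), (20, 55), 12, mask=m)
        m[19:21, 32:44] = True  # 2-px neck between plant-sized disks
        out = separate_objects(m)
        from agavecount import label_components

        assert label_components(out).n_components == 2
        # disk bodies survive: erosion loss is only the 1-px rim
        inner = draw_disk((40, 80), (20, 20), 10) | draw_disk(
            (40, 80), (20, 55), 10
        )
        assert not (inner & ~out).any()

    def test_disjoint_disks_component_count_preserved(self):
        m = np.zeros((60, 60), bool)
        for c in [(15, 15), (15, 45), (45, 30)]:
            m = draw_disk((60, 60), c, 9, mask=m)
        from agavecount import label_components

        before = label_components(m).n_components
        assert label_components(separate_objects(m)).n_components == before

    def test_empty(self):
        assert not separate_objects(np.zeros((10, 10), bool)).any()
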