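import numpy as np
import pytest

from caliperase import annotate
from caliperase.annotate import (
    ContractError,
    MarkerGlyph,
    annotate_nodule,
    generate_pseudo_group,
    marker_mask,
    mixup_markers,
    tangency_points,
)
from caliperase.evalx import iou
from caliperase.phantom import Nodule, PlacementError, generate_background


class TestTangencyPoints:
    def test_two_marker_group_sits_on_left_and_right_sides(self):
        pts = tangency_points((10, 10, 50, 40), group_size=2, seed=0)
        assert sorted(p[1] for p in pts) == [10, 49]
        assert all(10 <= r < 40 for r, _ in pts)

    def test_four_marker_group_covers_four_distinct_sides(self):
        x0, y0, x1, y1 = 10, 10, 50, 40
        pts = tangency_points((x0, y0, x1, y1), group_size=4, seed=1)
        sides = set()
        for r, c in pts:
            if c == x0:
                sides.add("left")
            elif c == x1 - 1:
                sides.add("right")
            elif r == y0:
                sides.add("top")
            elif r == y1 - 1:
                sides.add("bottom")
        assert sides == {"left", "right", "top", "bottom"}

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ContractError):
            tangency_points((0, 0, 20, 20), group_size=3, seed=0)

    def test_top_bottom_orientation(self):
        pts = tangency_points((10, 10, 50, 40), group_size=2, seed=0,
                              orientation="tb")
        assert sorted(p[0] for p in pts) == [10, 39]


class TestAnnotateNodule:
    def setup_method(self):
        self.img = generate_background(96, 96, seed=7)
        self.nod = Nodule(center=(48, 48), semi_axes=(10, 7), rotation=0.4,
                          contrast=0.3)

    def test_pixels_outside_mask_untouched(self):
        ann = annotate_nodule(self.img, self.nod, group_size=4, seed=2)
        np.testing.assert_array_equal(ann.image[~ann.mask], self.img[~ann.mask])

    def test_mask_counts_written_pixels(self):
        ann = annotate_nodule(self.img, self.nod, group_size=4, seed=2)
        changed = ann.image != self.img
        # every changed pixel is masked; mask may also cover glyph pixels that
        # happened to equal the glyph intensity already
        assert (changed & ~ann.mask).sum() == 0
        assert ann.mask.sum() <= 4 * len(ann.glyph.offsets())

    def test_group_size_records_centers(self):
        ann = annotate_nodule(self.img, self.nod, group_size=4, seed=2)
        assert len(ann.groups) == 1
        assert len(ann.groups[0].points) == 4

    def test_erase_by_mask_recovers_original(self):
        ann = annotate_nodule(self.img, self.nod, group_size=2, seed=3)
        restored = ann.image.copy()
        restored[ann.mask] = self.img[ann.mask]
        np.testing.assert_array_equal(restored, self.img)


class TestPseudoGroup:
    def test_constraints_hold_over_seeded_draws(self):
        img = generate_background(96, 96, seed=8)
        nodules = [Nodule(center=(30, 30), semi_axes=(9, 6), rotation=0.2,
                          contrast=0.3),
                   Nodule(center=(70, 66), semi_axes=(7, 7), rotation=0.0,
                          contrast=0.3)]
        max_dims = (24, 20)
        boxes = [n.bbox for n in nodules]
        for seed in range(100):
            grp = generate_pseudo_group(img, nodules, max_dims, seed=seed)
            x0, y0, x1, y1 = grp.rect
            assert x1 - x0 <= max_dims[0] and y1 - y0 <= max_dims[1]
            assert all(iou(grp.rect, b) == 0.0 for b in boxes)
            assert grp.group_size in (2, 4)
            assert grp.is_pseudo

    def test_infeasible_placement_raises(self):
        img = generate_background(64, 64, seed=9)
        giant = Nodule(center=(32, 32), semi_axes=(28, 28), rotation=0.0,
                       contrast=0.3)
        with pytest.raises(PlacementError):
            generate_pseudo_group(img, [giant], (30, 30), seed=0)


class TestMixup:
    def _annotated(self, seed, group_size):
        img = generate_background(96, 96, seed=seed)
        nod = Nodule(center=(48, 48), semi_axes=(10, 8), rotation=0.3,
                     contrast=0.3)
        return annotate_nodule(img, nod, group_size=group_size, seed=seed)

    def test_two_marker_group_keeps_exactly_one(self):
        for seed in range(10):
            ann = self._annotated(seed, 2)
            mixed = mixup_markers(ann, seed=seed)
            assert len(mixed.groups[0].points) == 1
            assert mixed.groups[0].points[0] in ann.groups[0].points

    def test_four_marker_group_keeps_one_to_three(self):
        for seed in range(20):
            ann = self._annotated(seed, 4)
            mixed = mixup_markers(ann, seed=seed)
            kept = len(mixed.groups[0].points)
            assert 1 <= kept <= 3
            assert len(mixed.loose_points) == 4 - kept

    def test_added_markers_outside_every_nodule_box(self):
        for seed in range(10):
            ann = self._annotated(seed, 4)
            mixed = mixup_markers(ann, seed=seed)
            boxes = [n.bbox for n in mixed.nodules]
            for pt in mixed.loose_points:
                fp = ann.glyph.footprint_bbox(pt)
                assert all(iou(fp, b) == 0.0 for b in boxes)

    def test_requires_a_group(self):
        img = generate_background(64, 64, seed=0)
        empty = annotate.AnnotatedImage(image=img, groups=[],
                                        mask=np.zeros_like(img, dtype=bool))
        with pytest.raises(ContractError):
            mixup_markers(empty, seed=0)


class TestMarkerMask:
    def test_zero_dilation_equals_burned_footprint(self, annotated_fixture):
        ann = annotated_fixture
        mask = marker_mask(ann.groups, ann.glyph, ann.image.shape, dilation=0)
        np.testing.assert_array_equal(mask, ann.mask)

    def test_area_monotone_in_dilation(self, annotated_fixture):
        ann = annotated_fixture
        areas = [marker_mask(ann.groups, ann.glyph, ann.image.shape, d).sum()
                 for d in range(4)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_empty_groups_give_empty_mask(self):
        glyph = MarkerGlyph()
        assert marker_mask([], glyph, (32, 32)).sum() == 0

    def test_negative_dilation_rejected(self, annotated_fixture):
        ann = annotated_fixture
        with pytest.raises(ContractError):
            marker_mask(ann.groups, ann.glyph, ann.image.shape, dilation=-1)


class TestGlyph:
    def test_bright_invariant(self):
        with pytest.raises(ValueError):
            MarkerGlyph(intensity=1.5)
        with pytest.raises(ValueError):
            MarkerGlyph(arm_length=1)

    def test_cross_shape_footprint_is_diagonal(self):
        g = MarkerGlyph(shape="cross", arm_length=3, thickness=1)
        off = {tuple(o) for o in g.offsets()}
        assert (3, 3) in off and (3, -3) in off and (0, 3) not in off
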