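"""Cell instance fallback rule, point-annotation rasterization, typing."""

import numpy as np
import pytest

from peerce.cells import (CellAnnotation, CellType, SourceBranch,
                          classify_cells, detect_instances_with_fallback,
                          rasterize_point_annotations)
from peerce.nets import IGNORE_LABEL


class StubDetector:
    """Emits a fixed number of single-pixel masks per call."""

    def __init__(self, n_original, n_transformed):
        self.n_original = n_original
        self.n_transformed = n_transformed

    def detect(self, patch, *, location=None):
        n = self.n_transformed if patch[0, 0, 0] == 0 else self.n_original
        masks = []
        for i in range(n):
            m = np.zeros(patch.shape[:2], bool)
            m[i // patch.shape[1], i % patch.shape[1]] = True
            masks.append(m)
        return masks


class StubHema:
    def transform(self, patch):
        out = patch.copy()
        out[0, 0] = 0  # marker the stub detector keys on
        return out


class FailingDetector:
    def detect(self, patch, *, location=None):
        raise RuntimeError("boom")


PATCH = np.full((16, 16, 3), 200, np.uint8)


class TestFallback:
    def test_transformed_branch_wins_with_more_cells(self):
        masks, branch = detect_instances_with_fallback(
            PATCH, StubDetector(50, 70), StubHema())
        assert branch == SourceBranch.HEMA_TRANSFORMED
        assert len(masks) == 70

    def test_tie_returns_original(self):
        masks, branch = detect_instances_with_fallback(
            PATCH, StubDetector(50, 50), StubHema())
        assert branch == SourceBranch.ORIGINAL

    def test_tie_rule_holds_for_any_equal_count(self, rng):
        for _ in range(10):
            n = int(rng.integers(0, 60))
            _, branch = detect_instances_with_fallback(
                PATCH, StubDetector(n, n), StubHema())
            assert branch == SourceBranch.ORIGINAL

    def test_without_hema_backend_only_original_runs(self):
        masks, branch = detect_instances_with_fallback(PATCH, StubDetector(5, 99))
        assert branch == SourceBranch.ORIGINAL
        assert len(masks) == 5

    def test_both_branches_failing_raises(self):
        with pytest.raises(RuntimeError):
            detect_instances_with_fallback(PATCH, FailingDetector(), StubHema())


class TestRasterize:
    def test_point_inside_instance_labels_whole_mask(self):
        inst = np.zeros((20, 20), bool)
        inst[5:10, 5:13] = True  # 40 px
        ann = [CellAnnotation(6, 7, CellType.TCPOS)]
        lab = rasterize_point_annotations(ann, (20, 20), [inst])
        assert (lab == 0).sum() == 40
        assert np.array_equal(lab == 0, inst)
        # everything else is background (no other instances to ignore)
        assert (lab[~inst] == 3).all()

    def test_unannotated_instance_is_ignored(self):
        a = np.zeros((20, 20), bool); a[2:5, 2:5] = True
        b = np.zeros((20, 20), bool); b[10:14, 10:14] = True
        ann = [CellAnnotation(3, 3, CellType.OC)]
        lab = rasterize_point_annotations(ann, (20, 20), [a, b])
        assert (lab[a] == 2).all()
        assert (lab[b] == IGNORE_LABEL).all()

    def test_disk_fallback_without_instance(self):
        ann = [CellAnnotation(10, 10, CellType.TCNEG)]
        lab = rasterize_point_annotations(ann, (30, 30), None, radius=7)
        n = (lab == 1).sum()
        assert 0 < n <= np.pi * 49 + 30  # discrete disk, radius 7
        assert lab[10, 10] == 1

    def test_two_points_same_class_union_matches_oracle(self):
        a = np.zeros((30, 30), bool); a[2:8, 2:8] = True
        b = np.zeros((30, 30), bool); b[20:26, 20:26] = True
        ann = [CellAnnotation(4, 4, CellType.TCPOS),
               CellAnnotation(22, 22, CellType.TCPOS)]
        lab = rasterize_point_annotations(ann, (30, 30), [a, b])
        assert np.array_equal(lab == 0, a | b)

    def test_conflicting_classes_on_one_instance_warns(self):
        inst = np.zeros((10, 10), bool)
        inst[2:8, 2:8] = True
        ann = [CellAnnotation(3, 3, CellType.TCPOS),
               CellAnnotation(7, 7, CellType.TCNEG)]
        with pytest.warns(UserWarning):
            lab = rasterize_point_annotations(ann, (10, 10), [inst])
        # nearest point wins per pixel inside the contested instance
        assert lab[3, 3] == 0 and lab[7, 7] == 1

    def test_out_of_bounds_annotation_rejected(self):
        with pytest.raises(ValueError):
            rasterize_point_annotations(
                [CellAnnotation(99, 1, CellType.OC)], (10, 10), None)


def oracle_classify(sm, masks):
    """Loop pixels, sum, divide, argmax over the first three classes."""
    out = []
    for m in masks:
        acc = np.zeros(4)
        n = 0
        for i in range(sm.shape[0]):
            for j in range(sm.shape[1]):
                if m[i, j]:
                    acc += sm[i, j]
                    n += 1
        mean = acc / n
        out.append(int(np.argmax(mean[:3])))
    return out


class TestClassify:
    def test_single_pixel_argmax(self):
        sm = np.zeros((1, 1, 4)); sm[0, 0] = (0.7, 0.1, 0.1, 0.1)
        m = np.ones((1, 1), bool)
        [cell] = classify_cells(sm, [m])
        assert cell.assigned_type == CellType.TCPOS

    def test_two_pixel_mean_hand_arithmetic(self):
        sm = np.zeros((1, 2, 4))
        sm[0, 0] = (0.6, 0.2, 0.1, 0.1)
        sm[0, 1] = (0.0, 0.8, 0.1, 0.1)
        [cell] = classify_cells(sm, [np.ones((1, 2), bool)])
        assert np.allclose(cell.class_probs, (0.3, 0.5, 0.1, 0.1))
        assert cell.assigned_type == CellType.TCNEG

    def test_matches_loop_oracle_on_random_maps(self, rng):
        raw = rng.random((16, 16, 4))
        sm = raw / raw.sum(axis=-1, keepdims=True)
        masks = [rng.random((16, 16)) < 0.2 for _ in range(5)]
        masks = [m for m in masks if m.any()]
        cells = classify_cells(sm, masks)
        order = [CellType.TCPOS, CellType.TCNEG, CellType.OC]
        assert [c.assigned_type for c in cells] == \
            [order[k] for k in oracle_classify(sm, masks)]

    def test_empty_mask_rejected(self):
        sm = np.full((4, 4, 4), 0.25)
        with pytest.raises(ValueError):
            classify_cells(sm, [np.zeros((4, 4), bool)])

    def test_background_never_assigned_and_count_preserved(self, rng):
        # background prob dominates every pixel, yet cells get a cell class
        sm = np.zeros((8, 8, 4))
        sm[...] = (0.05, 0.04, 0.01, 0.9)
        masks = [np.eye(8, dtype=bool), ~np.eye(8, dtype=bool)]
        cells = classify_cells(sm, masks)
        assert len(cells) == 2
        assert all(c.assigned_type in (CellType.TCPOS, CellType.TCNEG, CellType.OC)
                   for c in cells)

    def test_pixel_order_invariance(self, rng):
        sm = rng.random((10, 10, 4))
        sm /= sm.sum(axis=-1, keepdims=True)
        m = rng.random((10, 10)) < 0.3
        [c1] = classify_cells(sm, [m])
        # permuting rows of both map and mask leaves the mean unchanged
        perm = rng.permutation(10)
        [c2] = classify_cells(sm[perm], [m[perm]])
        assert np.allclose(np.sort(c1.class_probs), np.sort(c2.class_probs))
        assert c1.assigned_type == c2.assigned_type

    def test_tiebreak_priority_tcpos_first(self):
        sm = np.zeros((1, 1, 4)); sm[0, 0] = (0.4, 0.4, 0.2, 0.0)
        [cell] = classify_cells(sm, [np.ones((1, 1), bool)])
        assert cell.assigned_type == CellType.TCPOS
        sm[0, 0] = (0.1, 0.4, 0.4, 0.1)
        [cell] = classify_cells(sm, [np.ones((1, 1), bool)])
        assert cell.assigned_type == CellType.TCNEG

    def test_oracle_one_hot_map_recovers_true_types(self, rng):
        # build a tiny ground truth and a one-hot map from it
        types = rng.integers(0, 3, size=6)
        sm = np.zeros((24, 24, 4)); sm[..., 3] = 1.0
        masks = []
        for k, t in enumerate(types):
            m = np.zeros((24, 24), bool)
            m[(k // 3) * 8:(k // 3) * 8 + 6, (k % 3) * 8:(k % 3) * 8 + 6] = True
            sm[m] = np.eye(4)[t]
            masks.append(m)
        cells = classify_cells(sm, masks)
        order = [CellType.TCPOS, CellType.TCNEG, CellType.OC]
        assert [c.assigned_type for c in cells] == [order[t] for t in types]
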