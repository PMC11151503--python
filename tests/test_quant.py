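"""Segmentation, propagation, intensity quantification and morphometry."""

import heapq

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse
from skimage.transform import rotate

from stromascope.core import ChannelImage, LabelMap
from stromascope.quant import (
    fold_change,
    integrated_intensity,
    nuclear_circularity,
    propagate_cells,
    segment_nuclei,
)
from stromascope.simulate import CellSpec, SceneSpec, simulate_channel_scene


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return (a & b).sum() / (a | b).sum()


def _nuclei_scene(centers, seed=None, noise="none"):
    cells = [
        CellSpec(center=c, radius=16.0, nucleus_radius=6.0,
                 channel_means={"vimentin": 40.0},
                 nucleus_means={"DRAQ5": 120.0, "vimentin": 0.0})
        for c in centers
    ]
    scene = SceneSpec(image_shape=(96, 96), cells=cells, noise_model=noise,
                      seed=seed)
    return simulate_channel_scene(scene, ["DRAQ5", "vimentin"])


class TestSegmentNuclei:
    def test_recovers_k_disjoint_nuclei_with_high_jaccard(self):
        images, truth = _nuclei_scene([(25, 25), (25, 70), (70, 25), (70, 70)])
        labels = segment_nuclei(images["DRAQ5"], min_area_px=20)
        assert labels.ids.size == 4
        for cid in truth.nuclei_labels.ids:
            true_mask = truth.nuclei_labels.labels == cid
            # find the segmented label overlapping this nucleus
            seg_id = np.bincount(labels.labels[true_mask]).argmax()
            assert seg_id > 0
            assert _jaccard(true_mask, labels.labels == seg_id) >= 0.95

    def test_blank_image_with_one_bright_disk_gives_one_label(self):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 10)
        img[rr, cc] = 50.0
        labels = segment_nuclei(ChannelImage(img, "DRAQ5"), min_area_px=20)
        assert labels.ids.size == 1

    def test_min_area_filter_removes_small_objects(self):
        img = np.zeros((64, 64))
        rr, cc = disk((20, 20), 10)
        img[rr, cc] = 50.0
        rr, cc = disk((50, 50), 3)
        img[rr, cc] = 50.0
        big_only = segment_nuclei(ChannelImage(img, "DRAQ5"), min_area_px=100)
        both = segment_nuclei(ChannelImage(img, "DRAQ5"), min_area_px=5)
        assert both.ids.size == 2 and big_only.ids.size == 1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            segment_nuclei(ChannelImage(np.ones((16, 16)), "DRAQ5"))


def _bfs_geodesic_labels(seeds: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """Independent oracle: multi-source Dijkstra with pure geodesic cost."""
    h, w = fg.shape
    dist = np.full((h, w), np.inf)
    out = np.zeros((h, w), np.int32)
    heap = []
    for r, c in zip(*np.nonzero(seeds)):
        dist[r, c] = 0.0
        out[r, c] = seeds[r, c]
        heapq.heappush(heap, (0.0, int(seeds[r, c]), int(r), int(c)))
    while heap:
        d, lab, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and fg[rr, cc]:
                    nd = d + np.hypot(dr, dc)
                    if nd < dist[rr, cc] - 1e-12:
                        dist[rr, cc] = nd
                        out[rr, cc] = lab
                        heapq.heappush(heap, (nd, lab, rr, cc))
    return out


class TestPropagateCells:
    def test_each_cell_contains_its_nucleus(self):
        images, truth = _nuclei_scene([(30, 30), (65, 65)])
        nuclei = segment_nuclei(images["DRAQ5"], min_area_px=20)
        cells = propagate_cells(nuclei, images["vimentin"])
        for cid in nuclei.ids:
            nucleus = nuclei.labels == cid
            assert np.all(cells.labels[nucleus] == cid)

    def test_matches_ground_truth_masks(self):
        images, truth = _nuclei_scene([(30, 30), (65, 65)])
        nuclei = segment_nuclei(images["DRAQ5"], min_area_px=20)
        cells = propagate_cells(nuclei, images["vimentin"])
        for cid in truth.cell_labels.ids:
            true_mask = truth.cell_labels.labels == cid
            seg_id = np.bincount(cells.labels[true_mask]).argmax()
            assert _jaccard(true_mask, cells.labels == seg_id) >= 0.9

    def test_uniform_intensity_reduces_to_geodesic_nearest_seed(self):
        # two seeds in an L-shaped corridor; uniform cytoplasm intensity
        fg = np.zeros((40, 40), bool)
        fg[5:35, 5:12] = True
        fg[28:35, 5:35] = True
        seeds = np.zeros((40, 40), np.int32)
        seeds[6, 6] = 1
        seeds[33, 33] = 2
        img = np.where(fg, 10.0, 0.0)
        nuclei = LabelMap(seeds, kind="nuclei")
        cells = propagate_cells(nuclei, ChannelImage(img, "vimentin"),
                                regularization=1.0)
        oracle = _bfs_geodesic_labels(seeds, fg | (seeds > 0))
        agree = (cells.labels == oracle)[fg]
        assert agree.mean() > 0.99  # ties at the watershed line may differ

    def test_no_nuclei_rejected(self):
        empty = LabelMap(np.zeros((8, 8), np.int32), kind="nuclei")
        with pytest.raises(ValueError, match="seeds"):
            propagate_cells(empty, ChannelImage(np.ones((8, 8)), "vimentin"))


class TestIntegratedIntensity:
    def test_uniform_cell_integrates_to_mean_times_area(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:10, 5:10] = 1
        img = ChannelImage(np.full((20, 20), 3.0), "2NBDG")
        table = integrated_intensity(img, LabelMap(labels))
        assert table.integrated_intensity[0] == pytest.approx(3.0 * 25)
        assert table.area_px[0] == 25

    def test_linearity_under_channel_scaling(self, rng):
        labels = LabelMap((rng.uniform(0, 1, (16, 16)) > 0.5).astype(np.int32))
        img = rng.uniform(0, 5, (16, 16))
        a = integrated_intensity(ChannelImage(img, "2NBDG"), labels)
        b = integrated_intensity(ChannelImage(2 * img, "2NBDG"), labels)
        np.testing.assert_allclose(b.integrated_intensity,
                                   2 * a.integrated_intensity)

    def test_total_intensity_bookkeeping(self, rng):
        # sum over cells <= image total; equality when background is zero
        images, truth = _nuclei_scene([(30, 30), (65, 65)])
        table = integrated_intensity(images["vimentin"], truth.cell_labels)
        assert table.integrated_intensity.sum() == pytest.approx(
            images["vimentin"].pixels.sum()
        )


class TestFoldChange:
    def _table(self, values_by_condition):
        rows = []
        for cond, values in values_by_condition.items():
            for i, v in enumerate(values):
                rows.append({"cell_id": i, "condition": cond,
                             "integrated_intensity": v})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_unit_fold_change(self):
        table = fold_change(self._table({"a": [2, 2], "b": [2, 2]}), "a")
        assert np.allclose(table.fold_change, 1.0)

    def test_programmed_thirteen_percent_shift_recovered(self):
        table = fold_change(
            self._table({"random": [100, 100], "aligned": [113, 113]}), "random"
        )
        aligned = table[table.condition == "aligned"].fold_change
        assert aligned.mean() == pytest.approx(1.13)

    def test_single_cell_baseline(self):
        table = fold_change(self._table({"base": [4.0], "t": [6.0]}), "base")
        assert table[table.condition == "t"].fold_change.item() == pytest.approx(1.5)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            fold_change(self._table({"a": [1.0]}), "zzz")


class TestNuclearCircularity:
    def test_disk_square_and_ellipse_closed_forms(self):
        # disk r=100 -> 1.0; axis-aligned square -> pi/4; 2:1 ellipse ->
        # Ramanujan-perimeter oracle 0.841
        disk_img = np.zeros((256, 256), np.int32)
        rr, cc = disk((128, 128), 100)
        disk_img[rr, cc] = 1
        assert nuclear_circularity(LabelMap(disk_img, kind="nuclei")) \
            .circularity_raw[0] == pytest.approx(1.0, abs=0.02)

        sq = np.zeros((300, 300), np.int32)
        sq[50:250, 50:250] = 1
        assert nuclear_circularity(LabelMap(sq, kind="nuclei")) \
            .circularity_raw[0] == pytest.approx(np.pi / 4, abs=0.03)

        el = np.zeros((300, 300), np.int32)
        rr, cc = ellipse(150, 150, 50, 100)
        el[rr, cc] = 1
        a, b = 100.0, 50.0
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        oracle = 4 * np.pi * (np.pi * a * b) / perim**2
        assert nuclear_circularity(LabelMap(el, kind="nuclei")) \
            .circularity_raw[0] == pytest.approx(oracle, abs=0.03)

    def test_rotation_and_translation_invariance(self):
        sq = np.zeros((300, 300), float)
        sq[50:250, 50:250] = 1
        base = nuclear_circularity(
            LabelMap(sq.astype(np.int32), kind="nuclei")).circularity_raw[0]
        rot = rotate(sq, 30, resize=True, order=0).astype(np.int32)
        rotated = nuclear_circularity(LabelMap(rot, kind="nuclei")).circularity_raw[0]
        shifted = np.roll(sq.astype(np.int32), (13, -21), axis=(0, 1))
        trans = nuclear_circularity(LabelMap(shifted, kind="nuclei")).circularity_raw[0]
        assert rotated == pytest.approx(base, abs=0.03)
        assert trans == pytest.approx(base, abs=1e-9)

    def test_single_pixel_object_flagged_as_undefined(self):
        labels = np.zeros((8, 8), np.int32)
        labels[4, 4] = 1
        with pytest.warns(UserWarning, match="single-pixel"):
            table = nuclear_circularity(LabelMap(labels, kind="nuclei"))
        assert np.isnan(table.circularity[0])

    def test_reported_value_clipped_at_one_with_raw_retained(self):
        small = np.zeros((20, 20), np.int32)
        rr, cc = disk((10, 10), 5)
        small[rr, cc] = 1
        table = nuclear_circularity(LabelMap(small, kind="nuclei"))
        assert table.circularity[0] <= 1.0
        assert table.circularity_raw[0] >= table.circularity[0]
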