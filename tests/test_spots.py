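"""Spot detection, max-overlap attribution, positivity and the brute-force oracle."""
from __future__ import annotations

import numpy as np
import pytest

from mucospot.config import PipelineConfig
from mucospot.errors import EmptyTableError
from mucospot.objects import LabelMap
from mucospot.spots import (
    SpotRecord,
    assign_by_max_overlap,
    attribute_spots,
    brute_force_spot_count,
    detect_spots,
    percent_positive,
    summarize_spots_per_cell,
)


@pytest.fixture
def spot_cfg():
    return PipelineConfig(threshold_method="manual", manual_threshold=0.5)


class TestDetect:
    def test_three_squares_detected_with_areas(self, spot_cfg):
        g = np.zeros((32, 32))
        for r, c in ((4, 4), (4, 20), (20, 12)):
            g[r : r + 2, c : c + 2] = 0.9
        spot_map, recs = detect_spots(g, spot_cfg)
        assert spot_map.n_objects == 3
        assert all(r.area == 4 for r in recs)
        assert all(r.integrated_intensity == pytest.approx(4 * 0.9) for r in recs)

    def test_single_pixel_below_min_area_ignored(self, spot_cfg):
        g = np.zeros((16, 16))
        g[8, 8] = 0.9
        spot_map, recs = detect_spots(g, spot_cfg)  # spot_area_min = 2
        assert spot_map.n_objects == 0 and recs == []

    def test_oversized_component_rejected(self):
        cfg = PipelineConfig(
            threshold_method="manual", manual_threshold=0.5, spot_area_max=10
        )
        g = np.zeros((16, 16))
        g[2:8, 2:8] = 0.9  # 36 px > 10
        spot_map, _ = detect_spots(g, cfg)
        assert spot_map.n_objects == 0

    def test_zero_noise_scene_recovers_every_truth_spot(self, clean_scene, clean_cfg):
        image, truth = clean_scene
        spot_map, _ = detect_spots(image.channel("marker"), clean_cfg)
        assert spot_map.n_objects == len(truth.spots)


class TestBruteForceOracle:
    def test_blank_image_counts_zero(self):
        assert brute_force_spot_count(np.zeros((10, 10)), 0.5, (1, 100)) == 0

    def test_sparse_checkerboard_counts_every_pixel(self):
        g = np.zeros((12, 12))
        g[::3, ::3] = 1.0  # spacing 3: isolated under 8-connectivity
        assert brute_force_spot_count(g, 0.5, (1, 1)) == 16

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_detector_on_random_toys(self, seed, spot_cfg):
        rng = np.random.default_rng(seed)
        g = np.where(rng.uniform(0, 1, (48, 48)) > 0.75, 0.9, 0.05)
        spot_map, _ = detect_spots(g, spot_cfg)
        n = brute_force_spot_count(
            g, 0.5, (spot_cfg.spot_area_min, spot_cfg.spot_area_max)
        )
        assert spot_map.n_objects == n

    def test_agrees_with_detector_on_scene_crop(self, clean_scene):
        image, _ = clean_scene
        crop = image.channel("marker")[:192, :192]
        cfg = PipelineConfig(threshold_method="manual", manual_threshold=0.5)
        spot_map, _ = detect_spots(crop, cfg)
        n = brute_force_spot_count(crop, 0.5, (cfg.spot_area_min, cfg.spot_area_max))
        assert spot_map.n_objects == n


class TestMaxOverlap:
    def _maps(self):
        parents = np.zeros((12, 12), dtype=np.int32)
        parents[2:8, 2:8] = 7
        return parents

    def test_spot_fully_inside_parent(self):
        parents = self._maps()
        child = np.zeros((12, 12), dtype=np.int32)
        child[3:5, 3:5] = 1
        out = assign_by_max_overlap(LabelMap(child), LabelMap(parents))
        assert out == {1: 7}

    def test_background_spot_unassigned(self):
        parents = self._maps()
        child = np.zeros((12, 12), dtype=np.int32)
        child[10:12, 10:12] = 1
        out = assign_by_max_overlap(LabelMap(child), LabelMap(parents))
        assert out == {1: None}

    def test_edge_spot_goes_to_majority_compartment(self):
        # 6 px on nucleus, 4 px on cytoplasm -> nuclear
        nuc = np.zeros((10, 10), dtype=np.int32)
        cyt = np.zeros((10, 10), dtype=np.int32)
        cells = np.zeros((10, 10), dtype=np.int32)
        nuc[:, :6] = 3
        cyt[:, 6:] = 3
        cells[:, :] = 3
        spot = np.zeros((10, 10), dtype=np.int32)
        spot[4, 3:9] = 1  # one row: 3 px nuc
        spot[5, 4:8] = 1  # mixed; total 6 nuc + 4 cyt
        spot_lab = LabelMap(spot)
        recs = [SpotRecord(1, 10, (4.5, 5.5), 1.0)]
        attribute_spots(spot_lab, recs, LabelMap(nuc), LabelMap(cyt), LabelMap(cells))
        assert recs[0].parent_compartment == "nucleus"
        assert recs[0].parent_cell == 3

    def test_exact_tie_classifies_nuclear(self):
        nuc = np.zeros((8, 8), dtype=np.int32)
        cyt = np.zeros((8, 8), dtype=np.int32)
        cells = np.zeros((8, 8), dtype=np.int32)
        nuc[:, :4] = 2
        cyt[:, 4:] = 2
        cells[:, :] = 2
        spot = np.zeros((8, 8), dtype=np.int32)
        spot[3, 2:6] = 1  # 2 px each side
        recs = [SpotRecord(1, 4, (3.0, 3.5), 1.0)]
        attribute_spots(LabelMap(spot), recs, LabelMap(nuc), LabelMap(cyt), LabelMap(cells))
        assert recs[0].parent_compartment == "nucleus"

    def test_cell_tie_goes_to_lower_label(self):
        parents = np.zeros((6, 10), dtype=np.int32)
        parents[:, :5] = 4
        parents[:, 5:] = 9
        child = np.zeros((6, 10), dtype=np.int32)
        child[2, 3:7] = 1  # 2 px in each parent
        out = assign_by_max_overlap(LabelMap(child), LabelMap(parents))
        assert out == {1: 4}


class TestSummaries:
    def _records(self, counts_by_cell):
        recs = []
        sid = 1
        for cell, (n_nuc, n_cyt) in counts_by_cell.items():
            for _ in range(n_nuc):
                recs.append(
                    SpotRecord(sid, 4, (0, 0), 1.0, parent_cell=cell,
                               parent_compartment="nucleus")
                )
                sid += 1
            for _ in range(n_cyt):
                recs.append(
                    SpotRecord(sid, 6, (0, 0), 1.0, parent_cell=cell,
                               parent_compartment="cytoplasm")
                )
                sid += 1
        return recs

    def test_positivity_rule_two_spots(self, cfg):
        recs = self._records({1: (1, 1), 2: (0, 1), 3: (0, 0)})
        out = summarize_spots_per_cell(recs, cfg, [1, 2, 3])
        by_id = {s.cell_id: s for s in out}
        assert by_id[1].positive and by_id[1].n_spots_total == 2
        assert not by_id[2].positive
        assert not by_id[3].positive and by_id[3].n_spots_total == 0

    def test_compartment_counts_conserve(self, cfg):
        recs = self._records({1: (2, 3), 2: (1, 0)})
        for s in summarize_spots_per_cell(recs, cfg, [1, 2]):
            assert s.n_spots_total == s.n_spots_nuclear + s.n_spots_cytoplasmic

    def test_percent_positive_arithmetic(self, cfg):
        recs = self._records({1: (2, 0), 2: (1, 1), 3: (3, 0), 4: (0, 1)})
        out = summarize_spots_per_cell(recs, cfg, [1, 2, 3, 4])
        assert percent_positive(out) == pytest.approx(75.0)

    def test_percent_positive_extremes(self, cfg):
        zero = summarize_spots_per_cell([], cfg, [1, 2, 3])
        assert percent_positive(zero) == 0.0
        full = summarize_spots_per_cell(self._records({1: (2, 0), 2: (0, 2)}), cfg, [1, 2])
        assert percent_positive(full) == 100.0

    def test_percent_positive_empty_raises(self):
        with pytest.raises(EmptyTableError):
            percent_positive([])

    def test_positivity_monotone_in_threshold(self):
        recs = self._records({i: (i, 0) for i in range(1, 7)})
        prev = None
        for k in range(0, 8):
            c = PipelineConfig(min_spots_positive=k)
            out = summarize_spots_per_cell(recs, c, list(range(1, 7)))
            n_pos = sum(s.positive for s in out)
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos

    def test_percent_positive_invariant_under_relabeling(self, cfg):
        recs = self._records({1: (2, 0), 2: (0, 1)})
        out1 = percent_positive(summarize_spots_per_cell(recs, cfg, [1, 2]))
        relabeled = [
            SpotRecord(r.spot_id, r.area, r.centroid, r.integrated_intensity,
                       parent_cell={1: 20, 2: 10}[r.parent_cell],
                       parent_compartment=r.parent_compartment)
            for r in recs
        ]
        out2 = percent_positive(summarize_spots_per_cell(relabeled, cfg, [10, 20]))
        assert out1 == out2


def test_global_spot_conservation_on_scene(clean_lam):
    """Assigned + unassigned = detected; per-cell compartment sums = totals."""
    res = clean_lam
    n_assigned = sum(1 for r in res.spot_records if r.parent_cell is not None)
    n_unassigned = sum(1 for r in res.spot_records if r.parent_cell is None)
    assert n_assigned + n_unassigned == res.spot_map.n_objects
    for s in res.summaries:
        assert s.n_spots_total == s.n_spots_nuclear + s.n_spots_cytoplasmic
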