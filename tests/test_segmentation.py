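"""Nuclei identification, masking, cell delineation and cytoplasm identities."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from mucospot.config import PipelineConfig
from mucospot.errors import ConstantImageError
from mucospot.objects import LabelMap
from mucospot.segmentation import (
    EpithelialMask,
    derive_cytoplasm,
    epithelial_region_mask,
    expand_cells_pcp,
    identify_primary_objects,
    identify_secondary_cells_ecp,
    mask_objects,
)


def _disc(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


@pytest.fixture
def manual_cfg():
    return PipelineConfig(smoothing_sigma=0.0, threshold_method="manual", manual_threshold=0.5)


class TestPrimaryObjects:
    def test_single_disc_is_one_object_with_exact_pixels(self, manual_cfg):
        m = _disc((64, 64), (32, 32), 10)
        lab = identify_primary_objects(np.where(m, 1.0, 0.0), manual_cfg)
        assert lab.n_objects == 1
        np.testing.assert_array_equal(lab.labels > 0, m)

    def test_two_separated_discs_are_two_objects(self, manual_cfg):
        g = np.where(_disc((64, 64), (16, 16), 8) | _disc((64, 64), (48, 48), 8), 1.0, 0.0)
        lab = identify_primary_objects(g, manual_cfg)
        assert lab.n_objects == 2

    def test_overlapping_discs_declumped_to_two(self, manual_cfg):
        # centres 1.7 r apart: 30% of a radius overlap
        r = 10
        c1, c2 = (32, 24), (32, 41)
        g = np.where(_disc((64, 64), c1, r) | _disc((64, 64), c2, r), 1.0, 0.0)
        lab = identify_primary_objects(g, manual_cfg)
        assert lab.n_objects == 2
        cents = ndi.center_of_mass(np.ones_like(g), lab.labels, index=lab.object_ids)
        for found in cents:
            d = min(np.hypot(found[0] - c[0], found[1] - c[1]) for c in (c1, c2))
            assert d <= 2.0

    def test_diameter_band_discards_specks_and_blobs(self, manual_cfg):
        g = np.where(_disc((96, 96), (20, 20), 2) | _disc((96, 96), (64, 64), 10), 1.0, 0.0)
        lab = identify_primary_objects(g, manual_cfg)  # band [8, 40] px diameter
        assert lab.n_objects == 1

    def test_constant_grid_propagates_threshold_error(self):
        c = PipelineConfig(smoothing_sigma=0.0)
        with pytest.raises(ConstantImageError):
            identify_primary_objects(np.full((32, 32), 0.3), c)


class TestEpithelialMask:
    def test_bright_annulus_fills_to_outer_disc(self):
        cfg = PipelineConfig(smoothing_sigma=1.0)
        yy, xx = np.mgrid[0:128, 0:128]
        d = np.hypot(yy - 64, xx - 64)
        annulus = (d >= 30) & (d <= 45)
        mask = epithelial_region_mask(np.where(annulus, 0.9, 0.02), cfg)
        # oracle: flood fill of the thresholded annulus from outside
        outer = _disc((128, 128), (64, 64), 45)
        covered = mask.mask[outer].mean()
        assert covered >= 0.99
        assert mask.mask[64, 64]  # lumen enclosed
        assert not mask.mask[5, 5]

    def test_all_black_membrane_is_degenerate(self):
        with pytest.raises(ConstantImageError):
            epithelial_region_mask(np.zeros((64, 64)), PipelineConfig())

    def test_crypt_scene_band_covered(self, clean_scene):
        image, truth = clean_scene
        mask = epithelial_region_mask(image.channel("membrane"), PipelineConfig())
        frac = mask.mask[truth.epithelial_region].mean()
        assert frac >= 0.99


class TestMaskObjects:
    def _toy(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:7, 2:4] = 1  # 10 px; 4 inside region
        region = np.zeros((10, 10), dtype=bool)
        region[2:4, :] = True
        return LabelMap(lab), EpithelialMask(region)

    def test_fraction_rule_keep_inside_vs_outside(self):
        objects, region = self._toy()
        # 4/10 inside < 0.5 -> removed by keep_inside, retained by keep_outside
        assert mask_objects(objects, region, "keep_inside").n_objects == 0
        kept = mask_objects(objects, region, "keep_outside")
        assert kept.n_objects == 1
        np.testing.assert_array_equal(kept.labels, objects.labels)

    def test_full_inside_object(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:4, 2:4] = 5
        region = EpithelialMask(np.ones((10, 10), dtype=bool))
        assert mask_objects(LabelMap(lab), region, "keep_inside").n_objects == 1
        assert mask_objects(LabelMap(lab), region, "keep_outside").n_objects == 0

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(3)
        lab, _ = ndi.label(rng.uniform(0, 1, (64, 64)) > 0.7)
        region = EpithelialMask(_disc((64, 64), (32, 32), 20))
        lm = LabelMap(lab)
        inside = set(mask_objects(lm, region, "keep_inside").object_ids.tolist())
        outside = set(mask_objects(lm, region, "keep_outside").object_ids.tolist())
        assert inside & outside == set()
        assert inside | outside == set(lm.object_ids.tolist())


class TestSecondaryCells:
    def test_single_nucleus_claims_whole_region(self):
        region = EpithelialMask(_disc((64, 64), (32, 32), 20))
        nuc = np.zeros((64, 64), dtype=np.int32)
        nuc[_disc((64, 64), (32, 32), 5)] = 1
        cells = identify_secondary_cells_ecp(LabelMap(nuc), np.zeros((64, 64)), region)
        np.testing.assert_array_equal(cells.labels > 0, region.mask)

    def test_two_nuclei_split_near_equidistant_line(self):
        region = EpithelialMask(np.ones((21, 60), dtype=bool))
        nuc = np.zeros((21, 60), dtype=np.int32)
        nuc[_disc((21, 60), (10, 15), 4)] = 1
        nuc[_disc((21, 60), (10, 44), 4)] = 2
        cells = identify_secondary_cells_ecp(LabelMap(nuc), np.zeros((21, 60)), region)
        # uniform landscape: boundary within 1 px of the equidistant column 29.5
        cols1 = np.where(cells.labels == 1)[1]
        cols2 = np.where(cells.labels == 2)[1]
        assert cols1.max() <= 30.5 + 1
        assert cols2.min() >= 28.5 - 1

    def test_nucleus_contained_in_cell(self, clean_epi):
        seg = clean_epi.segmentation
        for lab in seg.nuclei.object_ids:
            nuc_m = seg.nuclei.labels == lab
            assert np.all(seg.cells.labels[nuc_m] == lab)

    def test_empty_nuclei_give_empty_cells(self):
        region = EpithelialMask(np.ones((16, 16), dtype=bool))
        cells = identify_secondary_cells_ecp(
            LabelMap.empty((16, 16)), np.zeros((16, 16)), region
        )
        assert cells.n_objects == 0


class TestExpandCells:
    def test_distance_zero_is_identity(self):
        nuc = np.zeros((32, 32), dtype=np.int32)
        nuc[_disc((32, 32), (16, 16), 5)] = 1
        out = expand_cells_pcp(LabelMap(nuc), 0.0)
        np.testing.assert_array_equal(out.labels, nuc)

    def test_isolated_disc_grows_to_expected_radius(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc((40, 40), (20, 20), 5)] = 1
        out = expand_cells_pcp(LabelMap(nuc), 3.0)
        target = _disc((40, 40), (20, 20), 8)
        # ±1 px rasterization band around the ideal disc
        inner = _disc((40, 40), (20, 20), 7)
        outer = _disc((40, 40), (20, 20), 9)
        got = out.labels > 0
        assert np.all(got[inner])
        assert not np.any(got & ~outer)
        assert abs(got.sum() - target.sum()) / target.sum() < 0.15

    def test_contested_pixels_go_to_nearer_seed_else_lower_label(self):
        nuc = np.zeros((21, 31), dtype=np.int32)
        nuc[10, 10] = 1
        nuc[10, 20] = 2
        out = expand_cells_pcp(LabelMap(nuc), 8.0)
        # brute-force nearest-seed oracle with lower-label ties
        yy, xx = np.mgrid[0:21, 0:31]
        d1 = np.hypot(yy - 10, xx - 10)
        d2 = np.hypot(yy - 10, xx - 20)
        expect = np.zeros((21, 31), dtype=np.int32)
        expect[(d1 <= 8) & (d1 <= d2)] = 1
        expect[(d2 <= 8) & (d2 < d1)] = 2
        np.testing.assert_array_equal(out.labels, expect)

    def test_forbidden_region_never_assigned_but_nucleus_kept(self):
        nuc = np.zeros((20, 20), dtype=np.int32)
        nuc[_disc((20, 20), (10, 10), 3)] = 1
        forbidden = EpithelialMask(np.zeros((20, 20), dtype=bool))
        forbidden.mask[:, 14:] = True
        forbidden.mask[10, 10] = True  # overlaps the nucleus itself
        out = expand_cells_pcp(LabelMap(nuc), 6.0, forbidden=forbidden)
        assert not np.any(out.labels[:, 14:])
        assert out.labels[10, 10] == 1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            expand_cells_pcp(LabelMap.empty((4, 4)), -1.0)


class TestCytoplasm:
    def test_cell_equals_nucleus_gives_empty_flagged(self):
        lab = np.zeros((12, 12), dtype=np.int32)
        lab[3:6, 3:6] = 1
        cyto, empty = derive_cytoplasm(LabelMap(lab), LabelMap(lab.copy()))
        assert cyto.n_objects == 0
        assert empty == (1,)

    def test_disc_in_disc_area_arithmetic(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        cell = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc((40, 40), (20, 20), 5)] = 1
        cell[_disc((40, 40), (20, 20), 8)] = 1
        cyto, empty = derive_cytoplasm(LabelMap(cell), LabelMap(nuc))
        assert empty == ()
        assert (cyto.labels > 0).sum() == (cell > 0).sum() - (nuc > 0).sum()

    def test_per_label_set_identities_on_scene(self, clean_lam):
        seg = clean_lam.segmentation
        for lab in seg.cells.object_ids:
            nuc_m = seg.nuclei.labels == lab
            cyt_m = seg.cytoplasm.labels == lab
            cell_m = seg.cells.labels == lab
            assert not np.any(nuc_m & cyt_m)
            np.testing.assert_array_equal(nuc_m | cyt_m, cell_m)
            assert cell_m.sum() == nuc_m.sum() + cyt_m.sum()


def test_segmentation_is_deterministic(clean_scene):
    image, _ = clean_scene
    cfg = PipelineConfig()
    a = identify_primary_objects(image.channel("nuclear"), cfg)
    b = identify_primary_objects(image.channel("nuclear"), cfg)
    np.testing.assert_array_equal(a.labels, b.labels)
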