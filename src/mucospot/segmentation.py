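"""Object segmentation: thresholding, nuclei, epithelial mask, cells, cytoplasm.

The stage sequence mirrors the standard primary/secondary/tertiary object
scheme of tissue-image analysis: nuclei are primary objects found in the
nuclear channel, cells are secondary objects grown from the nuclei, and the
cytoplasm is the tertiary object obtained by subtracting nucleus from cell.
Two secondary-object strategies are provided: a membrane-guided watershed for
epithelial cells packed inside crypts, and a fixed-distance expansion for the
sparser lamina propria, where no membrane marker outlines single cells.

All operations are deterministic: identical inputs and configuration yield
identical label maps, with labels assigned in raster-scan order of each
object's first pixel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, remove_small_objects
from skimage.segmentation import watershed

from .config import PipelineConfig
from .errors import ConstantImageError
from .objects import LabelMap, check_same_geometry, relabel_raster_order


@dataclass
class EpithelialMask:
    """Boolean raster of the epithelial region (marker-positive band plus its
    enclosed lumen)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("epithelial mask must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationResult:
    """Bundled per-image segmentation output."""

    nuclei: LabelMap
    cells: LabelMap
    cytoplasm: LabelMap
    epithelial_mask: EpithelialMask
    nucleus_to_cell: Dict[int, int]
    empty_cytoplasm: Tuple[int, ...] = ()


def otsu_threshold(grid: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The grid is histogrammed into ``n_bins`` equal bins over its own value
    range; every cut point between bins is scored by the between-class
    variance w0*w1*(mu0-mu1)^2 and the centre of the best cut bin is
    returned (first maximum on ties). Pixels strictly above the threshold
    are foreground.

    Raises
    ------
    ConstantImageError
        If the grid has no contrast at all.
    """
    g = np.asarray(grid, dtype=np.float64).ravel()
    lo, hi = float(g.min()), float(g.max())
    if hi <= lo:
        raise ConstantImageError("cannot threshold a constant image")
    hist, edges = np.histogram(g, bins=n_bins, range=(lo, hi))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)
    total = w0[-1]
    cum_mean = np.cumsum(hist * centers)
    grand = cum_mean[-1]
    # cut after bin i: class0 = bins[0..i], class1 = bins[i+1..]
    w0c = w0[:-1]
    w1c = total - w0c
    valid = (w0c > 0) & (w1c > 0)
    mu0 = np.where(w0c > 0, cum_mean[:-1] / np.where(w0c > 0, w0c, 1), 0.0)
    mu1 = np.where(w1c > 0, (grand - cum_mean[:-1]) / np.where(w1c > 0, w1c, 1), 0.0)
    bcv = np.where(valid, w0c * w1c * (mu0 - mu1) ** 2, -np.inf)
    i = int(np.argmax(bcv))
    return float(centers[i])


def _threshold_per_config(grid: np.ndarray, cfg: PipelineConfig) -> float:
    if cfg.threshold_method == "manual":
        return float(cfg.manual_threshold)
    return otsu_threshold(grid)


def identify_primary_objects(
    grid: np.ndarray,
    cfg: PipelineConfig,
    restrict: Optional[np.ndarray] = None,
) -> LabelMap:
    """Segment primary objects (nuclei) from one intensity channel.

    Pipeline: Gaussian smoothing -> threshold (Otsu or manual) -> hole
    filling -> declumping of touching objects by distance-transform maxima
    seeding a watershed -> rejection of objects whose equivalent diameter
    falls outside ``[nucleus_diameter_min, nucleus_diameter_max]``.
    """
    grid = np.asarray(grid, dtype=np.float64)
    sm = ndi.gaussian_filter(grid, cfg.smoothing_sigma) if cfg.smoothing_sigma > 0 else grid
    thr = _threshold_per_config(sm, cfg)
    fg = sm > thr
    if restrict is not None:
        fg &= np.asarray(restrict, dtype=bool)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return LabelMap.empty(grid.shape)

    dist = ndi.distance_transform_edt(fg)
    min_sep = max(1, int(round(cfg.nucleus_diameter_min)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=fg, exclude_border=False)
    markers = np.zeros(grid.shape, dtype=np.int32)
    if peaks.size == 0:
        # no interior maxima (thin foreground): fall back to plain labeling
        lab, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
        labels = lab
    else:
        order = np.lexsort((peaks[:, 1], peaks[:, 0]))  # raster order of seeds
        for k, idx in enumerate(order, start=1):
            markers[peaks[idx, 0], peaks[idx, 1]] = k
        labels = watershed(-dist, markers, mask=fg)

    labels = _filter_diameter_band(labels, cfg.nucleus_diameter_min, cfg.nucleus_diameter_max)
    return LabelMap(relabel_raster_order(labels))


def _filter_diameter_band(labels: np.ndarray, dmin: float, dmax: float) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.size, dtype=bool)
    for lab in range(1, counts.size):
        a = counts[lab]
        if a == 0:
            continue
        d = 2.0 * math.sqrt(a / math.pi)  # equivalent diameter
        keep[lab] = dmin <= d <= dmax
    out = np.where(keep[labels], labels, 0)
    return out


def epithelial_region_mask(membrane: np.ndarray, cfg: PipelineConfig) -> EpithelialMask:
    """Delineate the epithelial region from the membrane-marker channel.

    Smoothing -> Otsu -> morphological closing -> hole filling -> removal of
    specks smaller than ``nucleus_diameter_min**2`` px. A stained crypt
    cross-section (a bright annulus) therefore yields the filled outer disc,
    i.e. the epithelial band together with the lumen it encloses.
    """
    membrane = np.asarray(membrane, dtype=np.float64)
    sm = ndi.gaussian_filter(membrane, cfg.smoothing_sigma) if cfg.smoothing_sigma > 0 else membrane
    thr = otsu_threshold(sm)
    fg = sm > thr
    radius = max(1, int(math.ceil(cfg.smoothing_sigma)))
    fg = ndi.binary_closing(fg, structure=disk(radius))
    fg = ndi.binary_fill_holes(fg)
    # drop connected regions smaller than nucleus_diameter_min^2 pixels
    max_removed = int(math.ceil(cfg.nucleus_diameter_min**2)) - 1
    fg = remove_small_objects(fg, max_size=max_removed, connectivity=2)
    return EpithelialMask(fg)


def mask_objects(
    objects: LabelMap,
    region: EpithelialMask,
    mode: str = "keep_inside",
    min_fraction: float = 0.5,
) -> LabelMap:
    """Retain or discard whole objects by their overlap with a region.

    ``keep_inside`` retains an object iff the fraction of its pixels inside
    the region is >= ``min_fraction``; ``keep_outside`` retains it iff that
    fraction is < ``min_fraction`` (majority rule at the default 0.5).
    Retained objects keep their original labels and pixel sets.
    """
    if mode not in ("keep_inside", "keep_outside"):
        raise ValueError("mode must be 'keep_inside' or 'keep_outside'")
    check_same_geometry(objects, region)
    lab = objects.labels
    total = np.bincount(lab.ravel())
    inside = np.bincount(lab.ravel(), weights=region.mask.ravel().astype(np.float64))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inside / np.maximum(total, 1), 0.0)
    keep = frac >= min_fraction if mode == "keep_inside" else frac < min_fraction
    keep[0] = False
    return LabelMap(np.where(keep[lab], lab, 0))


def identify_secondary_cells_ecp(
    nuclei: LabelMap, membrane: np.ndarray, region: EpithelialMask
) -> LabelMap:
    """Grow epithelial cells from nuclei by watershed on the membrane channel.

    Membrane-marker ridges act as barriers between neighbouring cells; growth
    is confined to the epithelial region (plus the seed nuclei themselves,
    which are always contained in their cell).
    """
    check_same_geometry(nuclei, region)
    if nuclei.n_objects == 0:
        return LabelMap.empty(nuclei.shape)
    membrane = np.asarray(membrane, dtype=np.float64)
    grow_mask = region.mask | (nuclei.labels > 0)
    cells = watershed(membrane, markers=nuclei.labels, mask=grow_mask)
    return LabelMap(cells)


def expand_cells_pcp(
    nuclei: LabelMap,
    distance: float,
    forbidden: Optional[EpithelialMask] = None,
) -> LabelMap:
    """Define lamina-propria cells by isotropic expansion of each nucleus.

    Every pixel within Euclidean distance ``distance`` of a nucleus is
    claimed by the nearest nucleus; exact ties go to the lower nucleus label.
    Pixels inside ``forbidden`` (the epithelial region) are never assigned,
    but a nucleus always remains part of its own cell.
    """
    if distance < 0:
        raise ValueError("expansion distance must be >= 0")
    lab = nuclei.labels
    shape = lab.shape
    best_d = np.full(shape, np.inf)
    out = np.zeros(shape, dtype=np.int32)
    pad = int(math.ceil(distance)) + 1
    slices = ndi.find_objects(lab)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, shape[1])
        box = (slice(r0, r1), slice(c0, c1))
        m = lab[box] == idx
        if not m.any():
            continue
        d = ndi.distance_transform_edt(~m)
        # strict improvement only: ascending label order makes ties go to
        # the lower label
        upd = (d <= distance) & (d < best_d[box])
        best_d[box][upd] = d[upd]
        sub = out[box]
        sub[upd] = idx
        out[box] = sub
    if forbidden is not None:
        check_same_geometry(nuclei, forbidden)
        out[forbidden.mask] = 0
    out[lab > 0] = lab[lab > 0]  # nucleus always belongs to its cell
    return LabelMap(out)


def derive_cytoplasm(cells: LabelMap, nuclei: LabelMap) -> Tuple[LabelMap, Tuple[int, ...]]:
    """Tertiary objects: cytoplasm(L) = cell(L) minus nucleus(L).

    Returns the cytoplasm label map and the labels whose cytoplasm came out
    empty (cell identical to its nucleus), which are flagged rather than
    treated as errors.
    """
    check_same_geometry(cells, nuclei)
    cyt = cells.labels.copy()
    cyt[(nuclei.labels > 0) & (nuclei.labels == cells.labels)] = 0
    cyto = LabelMap(cyt)
    empty = tuple(
        int(lab) for lab in cells.object_ids if lab not in set(cyto.object_ids.tolist())
    )
    return cyto, empty


def segment_epithelial(image_channels: dict, cfg: PipelineConfig) -> SegmentationResult:
    """Convenience composition of the epithelial stage sequence I-V."""
    nuclear = image_channels["nuclear"]
    membrane = image_channels["membrane"]
    nuclei_all = identify_primary_objects(nuclear, cfg)
    region = epithelial_region_mask(membrane, cfg)
    nuclei = mask_objects(nuclei_all, region, "keep_inside", cfg.mask_min_fraction)
    nuclei = LabelMap(relabel_raster_order(nuclei.labels))
    cells = identify_secondary_cells_ecp(nuclei, membrane, region)
    cyto, empty = derive_cytoplasm(cells, nuclei)
    mapping = {int(l): int(l) for l in nuclei.object_ids}
    return SegmentationResult(nuclei, cells, cyto, region, mapping, empty)


def segment_lamina(image_channels: dict, cfg: PipelineConfig) -> SegmentationResult:
    """Convenience composition of the lamina-propria stage sequence I-IV."""
    nuclear = image_channels["nuclear"]
    membrane = image_channels["membrane"]
    nuclei_all = identify_primary_objects(nuclear, cfg)
    region = epithelial_region_mask(membrane, cfg)
    nuclei = mask_objects(nuclei_all, region, "keep_outside", cfg.mask_min_fraction)
    nuclei = LabelMap(relabel_raster_order(nuclei.labels))
    cells = expand_cells_pcp(nuclei, cfg.expansion_distance, forbidden=region)
    cyto, empty = derive_cytoplasm(cells, nuclei)
    mapping = {int(l): int(l) for l in nuclei.object_ids}
    return SegmentationResult(nuclei, cells, cyto, region, mapping, empty)
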