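"""End-to-end pipelines: epithelial (crypt) and lamina-propria workflows.

Each run returns an object table (one row per retained cell, with intensity,
shape, radial and spot columns), auxiliary per-spot records, the label maps,
and a :class:`RunManifest` snapshotting the configuration and per-stage
object counts so a rerun is fully determined.

Stage sequences
---------------
epithelial: nuclei -> epithelial mask -> keep nuclei inside -> membrane-
watershed cells -> cytoplasm -> spot detection -> max-overlap attribution ->
intensity / shape / radial measurements -> export.

lamina: nuclei -> epithelial mask -> keep nuclei outside -> fixed-distance
cell expansion -> spot detection / attribution -> positivity (>= 2 spots) ->
exclusion filters (oversize / epithelial overlap / border) with audit ->
percent positive over retained cells -> nuclear morphometrics -> export.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import ConstantImageError, StageError
from .filtering import FilterAudit, apply_cell_filters, kept_labels, removal_counts
from .image import MultichannelImage
from .measurements import (
    measure_intensity,
    measure_shape,
    radial_distribution,
)
from .objects import LabelMap
from .segmentation import (
    SegmentationResult,
    segment_epithelial,
    segment_lamina,
)
from .spots import (
    CellSpotSummary,
    SpotRecord,
    attribute_spots,
    detect_spots,
    percent_positive,
    summarize_spots_per_cell,
)


@dataclass
class RunManifest:
    pipeline: str  # 'epithelial' | 'lamina'
    image_id: str
    config: dict
    stage_counts: Dict[str, int]
    software_version: str = __version__
    seed: int = 0
    timestamp: str = ""
    percent_positive: Optional[float] = None
    percent_positive_prefilter: Optional[float] = None
    filter_removals: Dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineResult:
    objects: pd.DataFrame
    spots: pd.DataFrame
    segmentation: SegmentationResult
    spot_map: LabelMap
    spot_records: List[SpotRecord]
    summaries: List[CellSpotSummary]
    manifest: RunManifest
    audits: List[FilterAudit] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, e) from e

        return wrapper

    return deco


def _spot_table(records: List[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": r.spot_id,
                "area": r.area,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "integrated_intensity": r.integrated_intensity,
                "parent_cell": r.parent_cell,
                "parent_compartment": r.parent_compartment,
                "cell_by_whole_overlap": r.cell_by_whole_overlap,
            }
            for r in records
        ],
        columns=[
            "spot_id",
            "area",
            "centroid_row",
            "centroid_col",
            "integrated_intensity",
            "parent_cell",
            "parent_compartment",
            "cell_by_whole_overlap",
        ],
    )


def _measurement_frame(
    cell_ids: List[int],
    seg: SegmentationResult,
    marker: np.ndarray,
    summaries: List[CellSpotSummary],
    n_radial_bins: int,
) -> pd.DataFrame:
    shape_by_id = {s.object_id: s for s in measure_shape(seg.nuclei)}
    int_nuc = {r.object_id: r for r in measure_intensity(seg.nuclei, marker, "nucleus")}
    int_cyt = {r.object_id: r for r in measure_intensity(seg.cytoplasm, marker, "cytoplasm")}
    int_cell = {r.object_id: r for r in measure_intensity(seg.cells, marker, "cell")}
    radial = {
        r.cell_id: r
        for r in radial_distribution(
            marker, seg.nuclei, seg.cells, seg.cytoplasm, n_bins=n_radial_bins
        )
    }
    summ = {s.cell_id: s for s in summaries}
    rows = []
    for cid in cell_ids:
        sh = shape_by_id.get(cid)
        rn = int_nuc.get(cid)
        rc = int_cyt.get(cid)
        rw = int_cell.get(cid)
        rd = radial.get(cid)
        ss = summ.get(cid)
        row = {
            "cell_id": cid,
            "Area": sh.area if sh else np.nan,
            "Perimeter": sh.perimeter if sh else np.nan,
            "FormFactor": sh.form_factor if sh else np.nan,
            "Radius": sh.radius if sh else np.nan,
            "Compactness": sh.compactness if sh else np.nan,
            "TouchesBorder": bool(sh.touches_border) if sh else False,
            "IntegratedIntensity_Nucleus": rn.integrated_intensity if rn else 0.0,
            "MeanIntensity_Nucleus": rn.mean_intensity if rn else np.nan,
            "IntegratedIntensity_Cytoplasm": rc.integrated_intensity if rc else 0.0,
            "MeanIntensity_Cytoplasm": rc.mean_intensity if rc else np.nan,
            "IntegratedIntensity": rw.integrated_intensity if rw else 0.0,
            "MeanIntensity": rw.mean_intensity if rw else np.nan,
            "NSpots": ss.n_spots_total if ss else 0,
            "NSpotsNuclear": ss.n_spots_nuclear if ss else 0,
            "NSpotsCytoplasmic": ss.n_spots_cytoplasmic if ss else 0,
            "MeanSpotArea": ss.mean_spot_area if ss else np.nan,
            "Positive": bool(ss.positive) if ss else False,
        }
        for b in range(n_radial_bins):
            frac = rd.frac_at_d[b] if (rd and rd.frac_at_d is not None) else np.nan
            af = (
                rd.bin_area_fraction[b]
                if (rd and rd.bin_area_fraction is not None)
                else np.nan
            )
            row[f"FracAtD_{b + 1}"] = frac
            row[f"BinAreaFrac_{b + 1}"] = af
        rows.append(row)
    return pd.DataFrame(rows)


def _detect_spots_or_none(marker: np.ndarray, cfg: PipelineConfig):
    """A featureless (constant) marker channel means no spots, not a failure."""
    try:
        return detect_spots(marker, cfg)
    except ConstantImageError:
        h, w = marker.shape
        return LabelMap.empty((h, w)), []


def run_epithelial(image: MultichannelImage, cfg: PipelineConfig) -> PipelineResult:
    """Crypt workflow: per-epithelial-cell intensity, shape, spots, radial bins."""
    counts: Dict[str, int] = {}
    seg = _stage("segmentation")(segment_epithelial)(image.channels, cfg)
    counts["nuclei_retained"] = seg.nuclei.n_objects
    counts["cells"] = seg.cells.n_objects
    counts["cytoplasm"] = seg.cytoplasm.n_objects
    marker = image.channel("marker")
    spot_map, records = _stage("spot_detection")(_detect_spots_or_none)(marker, cfg)
    counts["spots_detected"] = spot_map.n_objects
    _stage("spot_attribution")(attribute_spots)(
        spot_map, records, seg.nuclei, seg.cytoplasm, seg.cells
    )
    counts["spots_assigned"] = sum(1 for r in records if r.parent_cell is not None)
    cell_ids = [int(i) for i in seg.cells.object_ids]
    summaries = summarize_spots_per_cell(records, cfg, cell_ids)
    table = _stage("measurements")(_measurement_frame)(
        cell_ids, seg, marker, summaries, cfg.n_radial_bins
    )
    counts["cells_measured"] = len(table)
    manifest = RunManifest(
        pipeline="epithelial",
        image_id=image.image_id,
        config=cfg.to_dict(),
        stage_counts=counts,
        seed=cfg.rng_seed,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        percent_positive=(percent_positive(summaries) if summaries else None),
    )
    return PipelineResult(
        objects=table,
        spots=_spot_table(records),
        segmentation=seg,
        spot_map=spot_map,
        spot_records=records,
        summaries=summaries,
        manifest=manifest,
    )


def run_lamina(image: MultichannelImage, cfg: PipelineConfig) -> PipelineResult:
    """Lamina-propria workflow: positivity calling, exclusion filters,
    nuclear morphometrics."""
    counts: Dict[str, int] = {}
    seg = _stage("segmentation")(segment_lamina)(image.channels, cfg)
    counts["nuclei_retained"] = seg.nuclei.n_objects
    counts["cells"] = seg.cells.n_objects
    marker = image.channel("marker")
    spot_map, records = _stage("spot_detection")(_detect_spots_or_none)(marker, cfg)
    counts["spots_detected"] = spot_map.n_objects
    _stage("spot_attribution")(attribute_spots)(
        spot_map, records, seg.nuclei, seg.cytoplasm, seg.cells
    )
    cell_ids = [int(i) for i in seg.cells.object_ids]
    summaries_all = summarize_spots_per_cell(records, cfg, cell_ids)
    pct_prefilter = percent_positive(summaries_all) if summaries_all else None

    audits = _stage("object_filters")(apply_cell_filters)(
        seg.cells,
        seg.epithelial_mask,
        factor=cfg.area_filter_factor,
        max_overlap=cfg.epcam_overlap_max,
    )
    kept = kept_labels(audits)
    counts["cells_after_filters"] = len(kept)
    summaries = [s for s in summaries_all if s.cell_id in set(kept)]
    pct = percent_positive(summaries) if summaries else None
    table = _stage("measurements")(_measurement_frame)(
        kept, seg, marker, summaries, cfg.n_radial_bins
    )
    counts["cells_measured"] = len(table)
    manifest = RunManifest(
        pipeline="lamina",
        image_id=image.image_id,
        config=cfg.to_dict(),
        stage_counts=counts,
        seed=cfg.rng_seed,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        percent_positive=pct,
        percent_positive_prefilter=pct_prefilter,
        filter_removals=removal_counts(audits) if audits else {},
    )
    return PipelineResult(
        objects=table,
        spots=_spot_table(records),
        segmentation=seg,
        spot_map=spot_map,
        spot_records=records,
        summaries=summaries,
        manifest=manifest,
        audits=audits,
    )


def audits_table(audits: List[FilterAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "object_id": a.object_id,
                "removed": a.removed,
                "reason": a.reason,
                "area": a.area,
                "overlap_fraction": a.overlap_fraction,
            }
            for a in audits
        ],
        columns=["object_id", "removed", "reason", "area", "overlap_fraction"],
    )
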