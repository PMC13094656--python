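"""Lamina-propria cell exclusion rules with full audit accounting.

Three reasons remove a segmented cell from quantification: (1) it is
oversized relative to the image mean cell area, which usually indicates a
segmentation merge; (2) it overlaps the epithelial region by more than the
tolerated fraction and is therefore an epithelial cell, not a lamina-propria
cell; (3) it touches the image border and is truncated. Reasons are
evaluated in that fixed order and the first match is recorded, so each
removal has exactly one auditable cause.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .errors import EmptyTableError
from .objects import LabelMap, check_same_geometry
from .segmentation import EpithelialMask

REASONS = ("none", "oversize", "epithelial_overlap", "border")


@dataclass
class FilterAudit:
    object_id: int
    removed: bool
    reason: str  # one of REASONS
    area: int
    overlap_fraction: float


def filter_by_area(areas: Dict[int, int], factor: float = 3.0) -> List[FilterAudit]:
    """Remove cells whose area exceeds ``factor`` times the image mean area.

    The mean is a single pass over all cells, candidate included; only the
    oversize side is removed (an undersized cell is not evidence of a
    segmentation merge).
    """
    if not areas:
        raise EmptyTableError("area filter needs at least one cell")
    mu = float(np.mean(list(areas.values())))
    cutoff = factor * mu
    return [
        FilterAudit(
            object_id=int(k),
            removed=a > cutoff,
            reason="oversize" if a > cutoff else "none",
            area=int(a),
            overlap_fraction=float("nan"),
        )
        for k, a in sorted(areas.items())
    ]


def filter_by_epithelial_overlap(
    cells: LabelMap, region: EpithelialMask, max_fraction: float = 0.5
) -> List[FilterAudit]:
    """Remove cells with more than ``max_fraction`` of their pixels inside
    the epithelial region."""
    check_same_geometry(cells, region)
    lab = cells.labels
    total = np.bincount(lab.ravel())
    inside = np.bincount(lab.ravel(), weights=region.mask.ravel().astype(np.float64))
    out: List[FilterAudit] = []
    for cid in cells.object_ids:
        frac = float(inside[cid] / total[cid])
        removed = frac > max_fraction
        out.append(
            FilterAudit(
                object_id=int(cid),
                removed=removed,
                reason="epithelial_overlap" if removed else "none",
                area=int(total[cid]),
                overlap_fraction=frac,
            )
        )
    return out


def filter_border_objects(cells: LabelMap) -> List[FilterAudit]:
    """Remove cells with any pixel on the first/last row or column."""
    lab = cells.labels
    border = np.zeros_like(lab, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = set(np.unique(lab[border]).tolist()) - {0}
    total = np.bincount(lab.ravel())
    return [
        FilterAudit(
            object_id=int(cid),
            removed=cid in touching,
            reason="border" if cid in touching else "none",
            area=int(total[cid]),
            overlap_fraction=float("nan"),
        )
        for cid in cells.object_ids
    ]


def apply_cell_filters(
    cells: LabelMap,
    region: EpithelialMask,
    factor: float = 3.0,
    max_overlap: float = 0.5,
) -> List[FilterAudit]:
    """Run the three rules in fixed order; first matching reason wins."""
    areas = cells.sizes()
    if not areas:
        return []
    by_area = {a.object_id: a for a in filter_by_area(areas, factor)}
    by_overlap = {a.object_id: a for a in filter_by_epithelial_overlap(cells, region, max_overlap)}
    by_border = {a.object_id: a for a in filter_border_objects(cells)}
    out: List[FilterAudit] = []
    for cid in sorted(areas):
        if by_area[cid].removed:
            out.append(by_area[cid])
        elif by_overlap[cid].removed:
            out.append(by_overlap[cid])
        elif by_border[cid].removed:
            out.append(by_border[cid])
        else:
            out.append(
                FilterAudit(
                    object_id=cid,
                    removed=False,
                    reason="none",
                    area=areas[cid],
                    overlap_fraction=by_overlap[cid].overlap_fraction,
                )
            )
    return out


def kept_labels(audits: Sequence[FilterAudit]) -> List[int]:
    return [a.object_id for a in audits if not a.removed]


def removal_counts(audits: Sequence[FilterAudit]) -> Dict[str, int]:
    """Removals tallied per reason; 'none' counts the kept objects."""
    counts = {r: 0 for r in REASONS}
    for a in audits:
        counts[a.reason] += 1
    return counts
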