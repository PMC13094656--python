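"""Image-level staining-quality metrics and segmentation-deviation accounting.

Staining quality drives segmentation accuracy: weakly or diffusely stained
membrane channels blur the epithelial boundary and inflate the difference
between automated and manual cell counts. This module provides whole-image
quality metrics (focus score, intensity statistics, saturation, histogram),
a threshold-based high/low quality call, the deviation between automated and
manual counts, and the Pearson machinery to correlate the two.

The focus score is defined as the normalized variance var/mean^2 of the
channel — a standard sharpness statistic that decreases monotonically under
Gaussian blur.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ZeroVarianceError
from .image import MultichannelImage


@dataclass
class QualityRecord:
    image_id: str
    role: str
    focus_score: Optional[float]  # None when the channel is all zero
    mean_intensity: float
    std_intensity: float
    mad_intensity: float
    percent_maximal: float
    histogram: np.ndarray  # 256 bin counts over [0, 1]


@dataclass
class DeviationRecord:
    image_id: str
    auto_count: int
    manual_count: int
    abs_deviation: int
    pct_deviation: Optional[float]  # None (flagged) when manual == 0


def quality_metrics(image: MultichannelImage, role: str) -> QualityRecord:
    """Whole-image quality statistics for one channel."""
    g = image.channel(role)
    mean = float(g.mean())
    std = float(g.std())
    mad = float(np.median(np.abs(g - np.median(g))))
    focus: Optional[float] = None if mean == 0.0 else (std**2) / (mean**2)
    gmax = float(g.max())
    pct_max = 100.0 * float((g == gmax).mean())
    hist, _ = np.histogram(g, bins=256, range=(0.0, 1.0))
    return QualityRecord(
        image_id=image.image_id,
        role=role,
        focus_score=focus,
        mean_intensity=mean,
        std_intensity=std,
        mad_intensity=mad,
        percent_maximal=pct_max,
        histogram=hist,
    )


def segmentation_deviation(image_id: str, auto: int, manual: int) -> DeviationRecord:
    """Absolute and percent difference between automated and manual counts."""
    if auto < 0 or manual < 0:
        raise ValueError("cell counts must be non-negative")
    absd = abs(auto - manual)
    pct = 100.0 * absd / manual if manual > 0 else None
    return DeviationRecord(image_id, int(auto), int(manual), int(absd), pct)


def correlate_metric_with_deviation(
    metrics: Sequence[float], deviations: Sequence[float]
) -> Tuple[float, float, float]:
    """Pearson r, R^2 and the two-sided p-value (t distribution, n-2 df)."""
    x = np.asarray(metrics, dtype=float)
    y = np.asarray(deviations, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def classify_staining_quality(
    record: QualityRecord, threshold_focus: float, threshold_std: float
) -> str:
    """'high' iff focus score and intensity SD both reach their thresholds."""
    if record.focus_score is None:
        return "low"
    ok = record.focus_score >= threshold_focus and record.std_intensity >= threshold_std
    return "high" if ok else "low"
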