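"""Pipeline configuration.

All tunable parameters of the epithelial and lamina-propria workflows live in
one flat dataclass that can round-trip through YAML, so a run manifest fully
determines a rerun.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """Parameters shared by both pipelines.

    Sizes are in pixels of the input image; intensity thresholds are on the
    normalized [0, 1] scale.

    Attributes
    ----------
    nucleus_diameter_min, nucleus_diameter_max
        Equivalent-diameter band for accepted nuclei (px).
    spot_area_min, spot_area_max
        Area band for accepted marker spots (px).
    smoothing_sigma
        Gaussian sigma applied before thresholding (px).
    expansion_distance
        Radial growth of lamina-propria cells from their nucleus (px).
    n_radial_bins
        Number of cytoplasmic distance bins for the radial intensity
        distribution (3 = perinuclear / intermediate / peripheral).
    min_spots_positive
        Minimum spot count for a cell to be called marker-positive.
    area_filter_factor
        A cell is discarded when its area exceeds this multiple of the image
        mean cell area.
    epcam_overlap_max
        Maximum tolerated fraction of a lamina cell's pixels inside the
        epithelial region before it is reclassified as epithelial and dropped.
    mask_min_fraction
        Majority-rule fraction used when keeping objects inside/outside the
        epithelial region.
    threshold_method
        'otsu' or 'manual'.
    manual_threshold
        Fixed threshold in [0, 1]; only used when threshold_method='manual'.
    loa_multiplier
        Limits-of-agreement multiplier for Bland-Altman summaries (1.96 for
        95% limits; 2.054 reaches 96%).
    rng_seed
        Seed for any stochastic helper (the pipelines themselves are
        deterministic).
    """

    nucleus_diameter_min: float = 8.0
    nucleus_diameter_max: float = 40.0
    spot_area_min: int = 2
    spot_area_max: int = 200
    smoothing_sigma: float = 1.0
    expansion_distance: float = 5.0
    n_radial_bins: int = 3
    min_spots_positive: int = 2
    area_filter_factor: float = 3.0
    epcam_overlap_max: float = 0.5
    mask_min_fraction: float = 0.5
    threshold_method: str = "otsu"
    manual_threshold: Optional[float] = None
    loa_multiplier: float = 1.96
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nucleus_diameter_min",
            "nucleus_diameter_max",
            "spot_area_min",
            "spot_area_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nucleus_diameter_min > self.nucleus_diameter_max:
            raise ValueError("nucleus diameter band inverted (min > max)")
        if self.spot_area_min > self.spot_area_max:
            raise ValueError("spot area band inverted (min > max)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.expansion_distance < 0:
            raise ValueError("expansion_distance must be >= 0")
        if self.n_radial_bins < 1:
            raise ValueError("n_radial_bins must be >= 1")
        if self.min_spots_positive < 0:
            raise ValueError("min_spots_positive must be >= 0")
        if self.area_filter_factor <= 0:
            raise ValueError("area_filter_factor must be > 0")
        for name in ("epcam_overlap_max", "mask_min_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.threshold_method not in ("otsu", "manual"):
            raise ValueError("threshold_method must be 'otsu' or 'manual'")
        if self.threshold_method == "manual":
            if self.manual_threshold is None or not 0.0 <= self.manual_threshold <= 1.0:
                raise ValueError("manual threshold_method needs manual_threshold in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
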