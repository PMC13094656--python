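"""Labelled-object rasters and object tables.

A :class:`LabelMap` is an integer raster (0 = background) aligned to the
image it was derived from; an object table is a plain pandas DataFrame with
one row per object, written/read as RFC-4180 CSV.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryMismatchError


@dataclass
class LabelMap:
    """Integer-labeled object raster; labels are positive, 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label map must be 2-D")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab.astype(np.int32)

    @classmethod
    def empty(cls, shape: tuple) -> "LabelMap":
        return cls(np.zeros(shape, dtype=np.int32))

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)

    def sizes(self) -> dict:
        """Pixel count per label."""
        counts = np.bincount(self.labels.ravel())
        return {i: int(counts[i]) for i in self.object_ids}

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


def check_same_geometry(*rasters) -> None:
    shapes = [np.asarray(getattr(r, "labels", getattr(r, "mask", r))).shape for r in rasters]
    if len(set(shapes)) > 1:
        raise GeometryMismatchError(f"rasters have mismatched shapes: {shapes}")


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in order of each object's first row-major pixel.

    Keeps segmentation deterministic: identical inputs give identical label
    assignments regardless of the order an upstream algorithm emitted them.
    """
    labels = np.asarray(labels)
    flat = labels.ravel()
    maxlab = int(flat.max(initial=0))
    if maxlab == 0:
        return labels.astype(np.int32)
    first = np.full(maxlab + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size))
    present = np.flatnonzero(first[1:] < flat.size) + 1
    order = present[np.argsort(first[present], kind="stable")]
    lut = np.zeros(maxlab + 1, dtype=np.int32)
    lut[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return lut[labels]


def export_object_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write one row per object, one column per measurement, as UTF-8 CSV.

    Floats are written at full repr precision so a read-back reproduces the
    table loss-free for all practical purposes.
    """
    if not isinstance(table, pd.DataFrame):
        raise TypeError("object table must be a pandas DataFrame")
    table.to_csv(path, index=False, encoding="utf-8")


def read_object_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_labelmap_tiff(lm: LabelMap, path: str | Path) -> None:
    """Store a label map as a single-channel 16-bit TIFF."""
    import tifffile

    lab = lm.labels
    if lab.max(initial=0) > 65535:
        raise ValueError("more than 65535 objects cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def read_labelmap_tiff(path: str | Path) -> LabelMap:
    import tifffile

    return LabelMap(tifffile.imread(str(path)).astype(np.int32))
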