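"""Multichannel image container, TIFF ingestion and intensity normalization.

A stained section arrives as a single- or multi-page TIFF holding the nuclear
stain (e.g. DAPI), an epithelial membrane marker (e.g. EpCAM) and the target
protein channel. Channels are addressed by *role*, never by acquisition
order: exports from different microscopes shuffle channel order, so the
caller supplies an explicit role -> page mapping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import tifffile

from .errors import ChannelIndexError, ChannelShapeMismatchError

#: channel roles understood by the pipelines
ROLES = ("nuclear", "membrane", "marker")


@dataclass
class MultichannelImage:
    """Role-keyed 2-D intensity grids sharing one geometry.

    All intensities are unitless and normalized to [0, 1].
    """

    image_id: str
    channels: Dict[str, np.ndarray]
    pixel_size: Optional[float] = None  # micrometres per pixel, if known

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image needs at least one channel")
        shapes = {role: np.asarray(g).shape for role, g in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 2 or ref[0] < 1 or ref[1] < 1:
            raise ValueError(f"channels must be 2-D with positive size, got {ref}")
        for role, shp in shapes.items():
            if shp != ref:
                raise ChannelShapeMismatchError(
                    f"channel '{role}' has shape {shp}, expected {ref}"
                )
        for role, g in self.channels.items():
            g = np.asarray(g, dtype=np.float64)
            if g.min() < 0.0 or g.max() > 1.0:
                raise ValueError(f"channel '{role}' has intensities outside [0, 1]")
            self.channels[role] = g

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple:
        return (self.height, self.width)

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"channel role '{role}' not present (have {sorted(self.channels)})")
        return self.channels[role]


def normalize_channel(arr: np.ndarray) -> np.ndarray:
    """Map raw pixel values onto [0, 1].

    Integer data are divided by the dtype full scale (255 for 8-bit, 65535
    for 16-bit), so the dtype minimum/maximum map to exactly 0/1 and the map
    is monotone. Float data are assumed already on an absolute scale and are
    clipped into [0, 1].
    """
    arr = np.asarray(arr)
    if arr.dtype.kind in "ui":
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale
    if arr.dtype.kind == "f":
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise TypeError(f"unsupported pixel dtype {arr.dtype}")


def _stack_pages(raw: np.ndarray) -> np.ndarray:
    """Coerce a TIFF array to (n_pages, H, W)."""
    if raw.ndim == 2:
        return raw[None, ...]
    if raw.ndim == 3:
        # channels-last exports keep the channel axis small and trailing
        if raw.shape[-1] <= 8 < raw.shape[0]:
            return np.moveaxis(raw, -1, 0)
        return raw
    raise ValueError(f"cannot interpret TIFF with {raw.ndim} dimensions as 2-D channels")


def load_image(
    path: str | Path,
    channel_map: Mapping[str, int],
    image_id: Optional[str] = None,
    pixel_size: Optional[float] = None,
) -> MultichannelImage:
    """Read a single- or multi-page TIFF and assemble the requested roles.

    Parameters
    ----------
    path
        TIFF file (8/16-bit integer or float pixels).
    channel_map
        role -> page/channel index, e.g. ``{"nuclear": 0, "membrane": 1,
        "marker": 2}``. Only the mapped roles are loaded.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ChannelIndexError
        A mapped index is outside the file's page range.
    ChannelShapeMismatchError
        Pages of unequal size were mapped together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    raw = tifffile.imread(str(path))
    pages = _stack_pages(np.asarray(raw))
    n = pages.shape[0]
    channels: Dict[str, np.ndarray] = {}
    for role, idx in channel_map.items():
        if not 0 <= int(idx) < n:
            raise ChannelIndexError(
                f"channel index {idx} for role '{role}' out of range (file has {n} page(s))"
            )
        channels[role] = normalize_channel(pages[int(idx)])
    return MultichannelImage(
        image_id=image_id or path.stem, channels=channels, pixel_size=pixel_size
    )


def write_channel_tiff(grid: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write one normalized channel back to disk as an integer TIFF."""
    grid = np.clip(np.asarray(grid, dtype=np.float64), 0.0, 1.0)
    if dtype == "uint16":
        out = np.round(grid * 65535).astype(np.uint16)
    elif dtype == "uint8":
        out = np.round(grid * 255).astype(np.uint8)
    else:
        raise ValueError("dtype must be 'uint8' or 'uint16'")
    tifffile.imwrite(str(path), out)
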