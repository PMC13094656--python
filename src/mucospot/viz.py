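"""Overlay figures: segmentation outlines and spot markers on the merged image."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage.segmentation import find_boundaries

from .image import MultichannelImage
from .objects import LabelMap


def _merge_rgb(image: MultichannelImage) -> np.ndarray:
    h, w = image.shape
    rgb = np.zeros((h, w, 3))
    if "membrane" in image.channels:  # cyan
        m = image.channel("membrane")
        rgb[..., 1] += m
        rgb[..., 2] += m
    if "nuclear" in image.channels:  # gray
        n = image.channel("nuclear")
        rgb += n[..., None] * 0.8
    if "marker" in image.channels:  # magenta
        g = image.channel("marker")
        rgb[..., 0] += g
        rgb[..., 2] += g
    return np.clip(rgb, 0, 1)


def save_overlay(
    image: MultichannelImage,
    path: str | Path,
    nuclei: Optional[LabelMap] = None,
    cells: Optional[LabelMap] = None,
    spots: Optional[LabelMap] = None,
    dpi: int = 150,
) -> None:
    """Write a PNG of the merged channels with object outlines.

    Nuclei outlines are drawn cyan, cell outlines gray, spot outlines
    magenta/yellow, echoing the usual workflow figures.
    """
    rgb = _merge_rgb(image)
    if nuclei is not None and nuclei.n_objects:
        b = find_boundaries(nuclei.labels, mode="outer")
        rgb[b] = (0.0, 1.0, 1.0)
    if cells is not None and cells.n_objects:
        b = find_boundaries(cells.labels, mode="outer")
        rgb[b] = (0.8, 0.8, 0.8)
    if spots is not None and spots.n_objects:
        b = find_boundaries(spots.labels, mode="outer")
        rgb[b] = (1.0, 1.0, 0.0)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def save_bland_altman_plot(a, b, result, path: str | Path) -> None:
    """Difference-vs-mean scatter with bias and limits-of-agreement lines."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    m = (a + b) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=18, color="tab:orange")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    if result.outlier_ids:
        idx = list(result.outlier_ids)
        ax.scatter(m[idx], d[idx], s=26, color="red")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (automated − reference)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
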