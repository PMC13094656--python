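"""Seeded generator of mucosa-like multichannel scenes with ground truth.

A scene emulates a colonic mucosa cross-section: one or more crypts rendered
as annular epithelial bands (membrane-marker positive) with nuclei arranged
on the ring, a surrounding lamina propria with scattered nuclei, and
marker-protein spots scattered per cell with Poisson counts. The rendered
channels mimic a three-colour stain (nuclear / membrane / marker); Gaussian
blur and additive noise model optics and detector noise, and a separate
quality-degradation operation models weak membrane staining.

What it does *not* emulate: out-of-focus light, anisotropic point-spread
functions, autofluorescence texture, touching nuclei inside the lamina
propria, or tissue folds. Every random draw flows from a single seeded
generator; identical specs give bit-identical scenes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import InfeasiblePackingError
from .image import MultichannelImage
from .objects import LabelMap

#: multipliers applied to a 'remission'-group scene relative to 'control'
REMISSION_MULTIPLIERS = {
    "spot_rate": 1.6,
    # chosen to cross a pixel rasterization boundary: radius 1.5 -> 2.1 px
    # grows the rendered spot from 9 to 13 pixels
    "spot_radius": 1.4,
    "marker_scale": 1.4,
    "nucleus_radius": 1.15,
    "irregularity": 1.6,
}


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene.

    All geometry is in pixels; intensity scales are on the normalized [0, 1]
    scale (AU).
    """

    shape: Tuple[int, int] = (512, 512)
    n_crypts: int = 1
    crypt_inner_radius: float = 60.0
    crypt_outer_radius: float = 110.0
    nuclei_per_crypt: int = 18
    lamina_density: float = 5.0  # nuclei per 10^4 px^2 of lamina area
    nucleus_radius_mean: float = 7.0
    nucleus_radius_sd: float = 0.8
    irregularity: float = 0.08  # radial Fourier amplitude, dimensionless
    membrane_band_width: float = 4.0  # bright membrane outline thickness, px
    spot_rate_cytoplasm: float = 4.0  # Poisson lambda per cell
    spot_rate_nucleus: float = 1.0
    spot_radius: float = 1.5
    expansion_distance: float = 5.0  # lamina cell radius beyond nucleus, px
    nuclear_scale: float = 0.85
    membrane_scale: float = 0.80
    marker_scale: float = 0.90
    marker_background: float = 0.06  # diffuse marker level inside cells
    noise_sigma: float = 0.01
    blur_sigma: float = 0.6
    border_margin: float = 16.0  # nuclei keep this distance from the frame
    group: str = "control"  # 'control' | 'remission'
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "crypt_inner_radius",
            "crypt_outer_radius",
            "nucleus_radius_mean",
            "spot_radius",
            "membrane_band_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.crypt_inner_radius >= self.crypt_outer_radius:
            raise ValueError("crypt_inner_radius must be < crypt_outer_radius")
        if min(self.spot_rate_cytoplasm, self.spot_rate_nucleus) < 0:
            raise ValueError("spot rates must be >= 0")
        if self.group not in ("control", "remission"):
            raise ValueError("group must be 'control' or 'remission'")


@dataclass
class TruthSpot:
    spot_id: int
    cell: int
    compartment: str  # 'nucleus' | 'cytoplasm'
    center: Tuple[int, int]
    pixels: np.ndarray  # (N, 2) row/col


@dataclass
class GroundTruth:
    nuclei: LabelMap
    cells: LabelMap
    epithelial_region: np.ndarray  # bool; the marker-positive band (annulus)
    compartment_class: Dict[int, str]  # label -> 'epithelial' | 'lamina'
    spot_counts: Dict[int, int]
    spot_counts_nuclear: Dict[int, int]
    spot_counts_cytoplasmic: Dict[int, int]
    spots: List[TruthSpot]
    nucleus_area: Dict[int, int]
    nucleus_centroid: Dict[int, Tuple[float, float]]
    group: str

    @property
    def n_nuclei(self) -> int:
        return len(self.compartment_class)


def _effective(spec: SceneSpec) -> dict:
    """Apply group multipliers to the affected parameters."""
    eff = {
        "spot_rate_cytoplasm": spec.spot_rate_cytoplasm,
        "spot_rate_nucleus": spec.spot_rate_nucleus,
        "spot_radius": spec.spot_radius,
        "marker_scale": spec.marker_scale,
        "nucleus_radius_mean": spec.nucleus_radius_mean,
        "irregularity": spec.irregularity,
    }
    if spec.group == "remission":
        m = REMISSION_MULTIPLIERS
        eff["spot_rate_cytoplasm"] *= m["spot_rate"]
        eff["spot_rate_nucleus"] *= m["spot_rate"]
        eff["spot_radius"] *= m["spot_radius"]
        eff["marker_scale"] *= m["marker_scale"]
        eff["nucleus_radius_mean"] *= m["nucleus_radius"]
        eff["irregularity"] *= m["irregularity"]
    return eff


def _crypt_centers(spec: SceneSpec) -> List[Tuple[float, float]]:
    h, w = spec.shape
    if spec.n_crypts == 0:
        return []
    if spec.n_crypts == 1:
        return [(h / 2.0, w / 2.0)]
    # coarse grid packing; enough for the small crypt counts used in tests
    need = 2.0 * (spec.crypt_outer_radius + spec.border_margin)
    per_row = max(1, int(w // need))
    centers = []
    for k in range(spec.n_crypts):
        r, c = divmod(k, per_row)
        cy = spec.border_margin + spec.crypt_outer_radius + r * need
        cx = spec.border_margin + spec.crypt_outer_radius + c * need
        if cy + spec.crypt_outer_radius > h - 1 or cx + spec.crypt_outer_radius > w - 1:
            raise InfeasiblePackingError(
                f"{spec.n_crypts} crypts of outer radius {spec.crypt_outer_radius} "
                f"do not fit in a {h}x{w} scene"
            )
        centers.append((cy, cx))
    return centers


def _render_nucleus(
    labels: np.ndarray,
    label: int,
    center: Tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> None:
    """Rasterize one nucleus as a disc with a low-order radial perturbation."""
    cy, cx = center
    amp = irregularity
    weights = rng.uniform(0.4, 1.0, size=2)
    weights = weights / weights.sum()
    phases = rng.uniform(0.0, 2.0 * math.pi, size=2)
    rmax = radius * (1.0 + amp)
    h, w = labels.shape
    r0 = max(int(math.floor(cy - rmax)) - 1, 0)
    r1 = min(int(math.ceil(cy + rmax)) + 2, h)
    c0 = max(int(math.floor(cx - rmax)) - 1, 0)
    c1 = min(int(math.ceil(cx + rmax)) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = radius * (
        1.0
        + amp
        * (
            weights[0] * np.cos(2.0 * theta + phases[0])
            + weights[1] * np.cos(3.0 * theta + phases[1])
        )
    )
    inside = rho <= r_theta
    sub = labels[r0:r1, c0:c1]
    sub[inside & (sub == 0)] = label


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    m = np.hypot(yy, xx) <= radius
    return np.stack([yy[m], xx[m]], axis=1)


def generate_scene(spec: SceneSpec) -> Tuple[MultichannelImage, GroundTruth]:
    """Render a scene and its ground truth.

    Ground truth (label maps, compartment classes, per-cell spot counts and
    spot pixel sets) is recorded before blur and noise are applied.
    """
    rng = np.random.default_rng(spec.seed)
    eff = _effective(spec)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]

    centers = _crypt_centers(spec)
    band = np.zeros((h, w), dtype=bool)
    lumen = np.zeros((h, w), dtype=bool)
    dist_center = np.full((h, w), np.inf)
    for cy, cx in centers:
        d = np.hypot(yy - cy, xx - cx)
        band |= (d >= spec.crypt_inner_radius) & (d <= spec.crypt_outer_radius)
        lumen |= d < spec.crypt_inner_radius
        dist_center = np.minimum(dist_center, d)

    # --- nucleus placement -------------------------------------------------
    positions: List[Tuple[float, float]] = []
    classes: List[str] = []
    min_sep = 2.6 * eff["nucleus_radius_mean"]
    r_mid = 0.5 * (spec.crypt_inner_radius + spec.crypt_outer_radius)
    for cy, cx in centers:
        n = spec.nuclei_per_crypt
        if n > 0:
            chord = 2.0 * r_mid * math.sin(math.pi / n)
            if chord < 2.2 * eff["nucleus_radius_mean"]:
                raise InfeasiblePackingError(
                    f"{n} epithelial nuclei do not fit on a ring of radius {r_mid:.0f}"
                )
            base = rng.uniform(0.0, 2.0 * math.pi)
            for k in range(n):
                ang = base + 2.0 * math.pi * k / n + rng.uniform(-0.25, 0.25) * (
                    2.0 * math.pi / n
                )
                rad = r_mid + rng.uniform(-0.15, 0.15) * (
                    spec.crypt_outer_radius - spec.crypt_inner_radius
                )
                positions.append((cy + rad * math.sin(ang), cx + rad * math.cos(ang)))
                classes.append("epithelial")

    lamina_area = float(((~band) & (~lumen)).sum())
    n_lamina = int(round(spec.lamina_density * lamina_area / 1.0e4))
    margin = spec.border_margin
    attempts = 0
    max_attempts = 400 * max(n_lamina, 1)
    placed = 0
    while placed < n_lamina:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasiblePackingError(
                f"could not place {n_lamina} lamina nuclei at separation {min_sep:.1f}"
            )
        py = rng.uniform(margin, h - 1 - margin)
        px = rng.uniform(margin, w - 1 - margin)
        if any(
            math.hypot(py - cy, px - cx)
            < spec.crypt_outer_radius + eff["nucleus_radius_mean"] + 3.0
            for cy, cx in centers
        ):
            continue
        if any(math.hypot(py - q[0], px - q[1]) < min_sep for q in positions):
            continue
        positions.append((py, px))
        classes.append("lamina")
        placed += 1

    # --- nucleus rendering -------------------------------------------------
    nuclei_lab = np.zeros((h, w), dtype=np.int32)
    radii: List[float] = []
    for i, (pos, cls) in enumerate(zip(positions, classes), start=1):
        r = float(
            np.clip(
                rng.normal(eff["nucleus_radius_mean"], spec.nucleus_radius_sd),
                3.0,
                2.5 * eff["nucleus_radius_mean"],
            )
        )
        radii.append(r)
        _render_nucleus(nuclei_lab, i, pos, r, eff["irregularity"], rng)

    # --- true cells --------------------------------------------------------
    d_nuc, (inds_r, inds_c) = ndi.distance_transform_edt(
        nuclei_lab == 0, return_indices=True
    )
    nearest = nuclei_lab[inds_r, inds_c]
    cells_lab = np.zeros((h, w), dtype=np.int32)
    is_epi = np.zeros(len(positions) + 1, dtype=bool)
    for i, cls in enumerate(classes, start=1):
        is_epi[i] = cls == "epithelial"
    epi_cell = band & is_epi[nearest]
    lam_cell = (~band) & (~lumen) & (~is_epi[nearest]) & (
        d_nuc <= spec.expansion_distance + 0.0
    )
    cells_lab[epi_cell] = nearest[epi_cell]
    cells_lab[lam_cell] = nearest[lam_cell]
    cells_lab[nuclei_lab > 0] = nuclei_lab[nuclei_lab > 0]

    # --- spots -------------------------------------------------------------
    inside_nuc = ndi.distance_transform_edt(nuclei_lab > 0)
    offsets = _disc_offsets(eff["spot_radius"])
    spot_sep = 2.0 * eff["spot_radius"] + 2.0
    spot_centers: List[Tuple[int, int]] = []
    spots: List[TruthSpot] = []
    counts_n: Dict[int, int] = {}
    counts_c: Dict[int, int] = {}
    marker_spots = np.zeros((h, w), dtype=bool)
    cell_ids = sorted(set(np.unique(cells_lab)) - {0})
    for cid in cell_ids:
        counts_n[cid] = 0
        counts_c[cid] = 0
        cell_m = cells_lab == cid
        nuc_m = nuclei_lab == cid
        # candidate centres keep the rendered disc inside its compartment
        cyt_cand = np.argwhere(cell_m & (~nuc_m) & (d_nuc >= eff["spot_radius"]))
        if cyt_cand.size == 0:
            cyt_cand = np.argwhere(cell_m & (~nuc_m))
        nuc_cand = np.argwhere(nuc_m & (inside_nuc >= eff["spot_radius"]))
        if nuc_cand.size == 0:
            nuc_cand = np.argwhere(nuc_m)
        for compartment, cand, lam in (
            ("cytoplasm", cyt_cand, eff["spot_rate_cytoplasm"]),
            ("nucleus", nuc_cand, eff["spot_rate_nucleus"]),
        ):
            k = int(rng.poisson(lam)) if lam > 0 else 0
            if k == 0 or cand.size == 0:
                continue
            for _ in range(k):
                ok = None
                for _try in range(60):
                    c = cand[int(rng.integers(0, cand.shape[0]))]
                    if all(
                        math.hypot(float(c[0]) - s[0], float(c[1]) - s[1]) >= spot_sep
                        for s in spot_centers
                    ):
                        ok = (int(c[0]), int(c[1]))
                        break
                if ok is None:
                    continue  # compartment saturated; truth records what fits
                spot_centers.append(ok)
                px = offsets + np.array(ok)
                px = px[(px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)]
                marker_spots[px[:, 0], px[:, 1]] = True
                spots.append(
                    TruthSpot(
                        spot_id=len(spots) + 1,
                        cell=cid,
                        compartment=compartment,
                        center=ok,
                        pixels=px,
                    )
                )
                if compartment == "nucleus":
                    counts_n[cid] += 1
                else:
                    counts_c[cid] += 1

    # --- channel rendering -------------------------------------------------
    nuclear = np.full((h, w), 0.02)
    for i in range(1, len(positions) + 1):
        m = nuclei_lab == i
        nuclear[m] = spec.nuclear_scale * rng.uniform(0.85, 1.0)

    membrane = np.full((h, w), 0.02)
    membrane[band] = 0.55 * spec.membrane_scale
    ring = np.zeros((h, w), dtype=bool)
    half = spec.membrane_band_width / 2.0
    finite = np.isfinite(dist_center)
    ring[finite] = (
        np.abs(dist_center[finite] - spec.crypt_inner_radius) <= half
    ) | (np.abs(dist_center[finite] - spec.crypt_outer_radius) <= half)
    membrane[ring] = spec.membrane_scale

    marker = np.full((h, w), 0.02)
    marker[cells_lab > 0] = spec.marker_background * (eff["marker_scale"] / spec.marker_scale)
    marker[marker_spots] = np.clip(eff["marker_scale"], 0.0, 1.0)

    channels = {}
    for role, grid in (("nuclear", nuclear), ("membrane", membrane), ("marker", marker)):
        g = grid
        if spec.blur_sigma > 0:
            g = ndi.gaussian_filter(g, spec.blur_sigma)
        if spec.noise_sigma > 0:
            g = g + rng.normal(0.0, spec.noise_sigma, size=g.shape)
        channels[role] = np.clip(g, 0.0, 1.0)

    image = MultichannelImage(
        image_id=f"synthetic-{spec.group}-{spec.seed}", channels=channels
    )
    nuclei_map = LabelMap(nuclei_lab)
    areas = nuclei_map.sizes()
    cents = ndi.center_of_mass(
        np.ones((h, w)), nuclei_lab, index=nuclei_map.object_ids
    )
    truth = GroundTruth(
        nuclei=nuclei_map,
        cells=LabelMap(cells_lab),
        epithelial_region=band,
        compartment_class={i: c for i, c in enumerate(classes, start=1)},
        spot_counts={c: counts_n[c] + counts_c[c] for c in counts_n},
        spot_counts_nuclear=counts_n,
        spot_counts_cytoplasmic=counts_c,
        spots=spots,
        nucleus_area=areas,
        nucleus_centroid={
            int(i): (float(c[0]), float(c[1]))
            for i, c in zip(nuclei_map.object_ids, cents)
        },
        group=spec.group,
    )
    return image, truth


def degrade_quality(
    image: MultichannelImage, blur_sigma: float = 3.0, contrast_factor: float = 0.5
) -> MultichannelImage:
    """Emulate weak membrane staining: blur and compress the membrane channel
    about its mean. Nuclear and marker channels are untouched."""
    if not 0.0 < contrast_factor <= 1.0:
        raise ValueError("contrast_factor must be in (0, 1]")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    channels = {k: v.copy() for k, v in image.channels.items()}
    mem = channels["membrane"]
    if blur_sigma > 0:
        mem = ndi.gaussian_filter(mem, blur_sigma)
    mu = mem.mean()
    mem = mu + contrast_factor * (mem - mu)
    channels["membrane"] = np.clip(mem, 0.0, 1.0)
    return MultichannelImage(
        image_id=image.image_id + "-degraded",
        channels=channels,
        pixel_size=image.pixel_size,
    )
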