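"""Shared fixtures: synthetic scenes and pipeline runs reused across tests."""
from __future__ import annotations

import numpy as np
import pytest

from mucospot.config import PipelineConfig
from mucospot.pipeline import run_epithelial, run_lamina
from mucospot.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_cfg() -> PipelineConfig:
    """Fixed threshold for zero-noise scenes, where the rendering scale is
    known exactly; per-image Otsu is meant for images whose histogram is
    spread by optics and noise."""
    return PipelineConfig(threshold_method="manual", manual_threshold=0.5)


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise, zero-blur scene: segmentation ground truth is crisp."""
    spec = SceneSpec(seed=11, noise_sigma=0.0, blur_sigma=0.0)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default (mildly noisy, mildly blurred) control scene."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def clean_epi(clean_scene, clean_cfg):
    image, _ = clean_scene
    return run_epithelial(image, clean_cfg)


@pytest.fixture(scope="session")
def clean_lam(clean_scene, clean_cfg):
    image, _ = clean_scene
    return run_lamina(image, clean_cfg)


def match_labels(detected_labels: np.ndarray, truth_labels: np.ndarray) -> dict:
    """detected label -> truth label by maximum pixel overlap (0 -> unmatched)."""
    out = {}
    for lab in np.unique(detected_labels):
        if lab == 0:
            continue
        overlap = truth_labels[detected_labels == lab]
        overlap = overlap[overlap > 0]
        out[int(lab)] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return out
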