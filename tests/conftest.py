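"""Shared fixtures: generated image sets are cached per session because the
mosaic generator plus pipelines dominate the suite's runtime."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from myometrics.fibers import FiberPipelineConfig, segment_fibers
from myometrics.synthetic import MosaicSpec, generate_muscle_image_set


@lru_cache(maxsize=16)
def mosaic(seed: int, gap: float = 0.1, noise: float = 0.05, **kwargs):
    spec = MosaicSpec(rng_seed=seed, gap_fraction=gap, noise_sd=noise, **kwargs)
    return generate_muscle_image_set(spec)


@lru_cache(maxsize=8)
def segmented(seed: int, gap: float = 0.1, noise: float = 0.05):
    lam, _, _, truth = mosaic(seed, gap, noise)
    return segment_fibers(lam, FiberPipelineConfig(um_per_px=1.0)), truth


@pytest.fixture(scope="session")
def clean_set():
    """Gap-free, noise-free mosaic (seed 1) with its ground truth."""
    return mosaic(1, 0.0, 0.0)


@pytest.fixture(scope="session")
def degraded_set():
    """Mosaic with 10% membrane gaps and noise sd 0.05 (seed 1)."""
    return mosaic(1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
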