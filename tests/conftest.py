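"""Shared fixtures: synthetic pipelines and fabricated feature matrices."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from histomap import (
    ExtractorSpec,
    FeatureMatrix,
    extract_features,
    filter_background,
    scale_features,
    three_region_slide,
    tile_slide,
)

TILE = 64


def make_fm(values, slide_id="s", scaled=True, tile_ids=None) -> FeatureMatrix:
    """Fabricate a FeatureMatrix around an arbitrary (n, d) array."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    fm = FeatureMatrix(
        slide_id=slide_id,
        tile_ids=tile_ids or [f"{slide_id}_t{i:04d}" for i in range(n)],
        values=values,
        extractor=ExtractorSpec("test", max(8, d), True),
        scaled=scaled,
    )
    return fm


@lru_cache(maxsize=16)
def pipeline(seed: int):
    """Synthetic three-region slide run through tiling + features + scaling."""
    slide = three_region_slide(seed)
    grid = filter_background(tile_slide(slide.as_handle(f"syn{seed}"), TILE))
    fm = scale_features(extract_features(grid, "texture"))
    return slide, grid, fm


@pytest.fixture(scope="session")
def three_region():
    return pipeline(1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
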