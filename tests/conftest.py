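"""Shared fixtures: small synthetic corpora sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from slidegraph import (
    SlideImage,
    TilingConfig,
    detect_tissue,
    extract_features,
    filter_patches,
    generate_slide,
    graph_from_features,
    make_encoder,
    tile_slide,
)
from slidegraph.synthetic import SyntheticSlideSpec


@pytest.fixture(scope="session")
def small_slide():
    """One single-section nodular slide on a 1024px canvas."""
    return generate_slide(SyntheticSlideSpec(
        width_px=1024, height_px=1024, n_sections=1, subtype="nodular",
        tumor_fraction=0.35, seed=42))


def _patchset(slide, slide_id):
    mask = detect_tissue(slide.image)
    img = SlideImage(pixels=slide.image, native_magnification=10.0,
                     slide_id=slide_id)
    return filter_patches(tile_slide(img, mask, TilingConfig()), 0.15)


@pytest.fixture(scope="session")
def small_corpus():
    """3 classes x 4 single-section slides with retained patch sets + labels."""
    slides, patch_sets, labels = [], [], []
    for ci, subtype in enumerate(("healthy", "nodular", "high")):
        for k in range(4):
            frac = 0.0 if subtype == "healthy" else 0.35
            slide = generate_slide(SyntheticSlideSpec(
                width_px=1024, height_px=1024, n_sections=1, subtype=subtype,
                tumor_fraction=frac, seed=1000 * ci + k))
            slides.append(slide)
            patch_sets.append(_patchset(slide, f"{subtype}_{k}"))
            labels.append(ci)
    return slides, patch_sets, labels


@pytest.fixture(scope="session")
def small_graphs(small_corpus):
    """Slide graphs from a fixed (untrained) encoder over the small corpus."""
    _, patch_sets, labels = small_corpus
    encoder = make_encoder("small_cnn", np.random.default_rng(0), width=32)
    graphs = [graph_from_features(extract_features(encoder, ps))
              for ps in patch_sets]
    return graphs, np.asarray(labels)
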