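"""From a slide to its patch graph.

Tiles a two-section synthetic slide into 224x224 patches at 10X, keeps
patches with at least 15% tissue, and builds the 8-connectivity graph —
disconnected tissue sections become disconnected graph components.
"""

import numpy as np

from slidegraph import (SlideImage, TilingConfig, build_adjacency,
                        connected_components, detect_tissue, filter_patches,
                        generate_slide, tile_slide)
from slidegraph.synthetic import SyntheticSlideSpec

slide = generate_slide(SyntheticSlideSpec(
    width_px=2048, height_px=2048, n_sections=2, subtype="nodular",
    tumor_fraction=0.35, seed=3))
image = SlideImage(pixels=slide.image, native_magnification=10.0,
                   slide_id="demo")
mask = detect_tissue(slide.image)

cfg = TilingConfig()  # 224 px, 10X, 15% tissue
all_tiles = tile_slide(image, mask, cfg)
kept = filter_patches(all_tiles, cfg.min_tissue_fraction)
print(f"grid tiles: {len(all_tiles)}, retained with >= "
      f"{cfg.min_tissue_fraction:.0%} tissue: {len(kept)}")

adj = build_adjacency(kept.grid_coords)
labels = connected_components(adj)
print(f"edges: {adj.n_edges}, max degree: {adj.degrees().max()} (bound 8)")
print(f"graph components: {len(np.unique(labels))} "
      f"(= number of tissue sections on the slide)")
for comp in np.unique(labels):
    print(f"  component {comp}: {np.sum(labels == comp)} patches")
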