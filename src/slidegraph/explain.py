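"""Graph-based class-activation maps (GraphCAM).

Relevance of the class decision is propagated back to patches in two steps:

1. gradient-weighted attention rollout through the transformer blocks —
   per block, W_b = mean over heads of relu(grad * attention), then
   A_b = row-normalised (I + W_b), and R = A_L ... A_1; the class-token row
   of R (excluding the class token itself) is the per-token relevance;
2. projection through the pooling assignment S used at inference:
   patch score = S @ r, max-normalised to [0, 1].

The resulting per-patch scores are rendered as a colormapped overlay on a
slide thumbnail; background stays untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .graph import SlideGraph
from .model import GraphTransformer

__all__ = ["RelevanceMap", "transformer_relevance", "project_relevance",
           "graphcam", "render_heatmap"]


@dataclass
class RelevanceMap:
    slide_id: str
    scores: np.ndarray      # (N,) in [0, 1], aligned with the retained-patch order
    target_class: int

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        if len(s) and s.max() > 0:
            s = s / s.max()
        self.scores = s

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "slide_id": self.slide_id,
            "target_class": int(self.target_class),
            "scores": self.scores.tolist(),
        }, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def transformer_relevance(attentions: list[np.ndarray],
                          gradients: list[np.ndarray]) -> np.ndarray:
    """Per-token relevance via gradient-weighted attention rollout.

    `attentions`/`gradients` are per-block (heads, T, T) arrays from a forward
    and a backward pass for the target class (token 0 is the class token).
    Returns T-1 nonnegative values, one per pooled token.
    """
    if not attentions or len(attentions) != len(gradients):
        raise ValueError("need cached attention and gradient maps per block")
    t = attentions[0].shape[-1]
    rollout = np.eye(t)
    for attn, grad in zip(attentions, gradients):
        if grad is None:
            raise ValueError("missing attention gradients; run a backward pass first")
        w = np.maximum(grad * attn, 0.0).mean(axis=0)   # (T, T)
        a_bar = np.eye(t) + w
        a_bar = a_bar / a_bar.sum(axis=1, keepdims=True)
        rollout = a_bar @ rollout
    rel = rollout[0, 1:]
    return np.maximum(rel, 0.0)


def project_relevance(token_relevance: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Distribute pooled-token relevance back to patches: S @ r, max-normalised."""
    r = np.asarray(token_relevance, dtype=np.float64)
    s = np.asarray(assignment, dtype=np.float64)
    if s.shape[1] != len(r):
        raise ValueError(f"assignment has {s.shape[1]} clusters, relevance has {len(r)}")
    scores = s @ r
    m = scores.max()
    return scores / m if m > 0 else scores


def graphcam(model: GraphTransformer, graph: SlideGraph,
             target_class: int | None = None) -> RelevanceMap:
    """Class-activation map of `target_class` (default: the predicted class)."""
    res = model.forward(graph)
    if target_class is None:
        target_class = int(np.argmax(res.logits.data))
    res.logits[target_class].backward()
    token_rel = transformer_relevance(
        [a.data for a in res.attentions],
        [a.grad for a in res.attentions],
    )
    scores = project_relevance(token_rel, res.assignment)
    model.zero_grad()
    return RelevanceMap(slide_id=graph.slide_id, scores=scores,
                        target_class=target_class)


def render_heatmap(relevance: RelevanceMap, grid_coords: np.ndarray,
                   slide_image: np.ndarray, patch_px: int,
                   out_dims: tuple[int, int] | None = None,
                   colormap: str = "jet", alpha: float = 0.5) -> np.ndarray:
    """Colormapped overlay of per-patch scores on a slide thumbnail.

    `grid_coords` are the (row, col) grid positions of the scored patches at
    the magnification where one patch spans `patch_px` pixels; `slide_image`
    is the RGB slide at that same magnification. `out_dims` (height, width)
    sets the thumbnail size (defaults to 1/4 scale). Only patch boxes are
    blended; background pixels are returned untouched.
    """
    grid_coords = np.asarray(grid_coords)
    if len(grid_coords) != len(relevance.scores):
        raise ValueError("coords and scores must align")
    h, w = slide_image.shape[:2]
    if out_dims is None:
        out_dims = (max(1, h // 4), max(1, w // 4))
    oh, ow = out_dims
    thumb = resize(slide_image, (oh, ow), anti_aliasing=True, preserve_range=True)
    out = thumb.astype(np.float64)
    cmap = colormaps[colormap]
    sy, sx = oh / h, ow / w
    for (r, c), score in zip(grid_coords, relevance.scores):
        y0, y1 = int(round(r * patch_px * sy)), int(round((r + 1) * patch_px * sy))
        x0, x1 = int(round(c * patch_px * sx)), int(round((c + 1) * patch_px * sx))
        y1, x1 = min(y1, oh), min(x1, ow)
        if y1 <= y0 or x1 <= x0:
            raise ValueError("requested thumbnail smaller than the patch extent")
        color = np.array(cmap(float(score))[:3]) * 255.0
        out[y0:y1, x0:x1] = (1 - alpha) * out[y0:y1, x0:x1] + alpha * color
    return np.clip(out, 0, 255).astype(np.uint8)
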