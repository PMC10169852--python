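"""Tissue detection, tiling and tissue-fraction filtering.

Slides are tiled into fixed-size non-overlapping patches (default 224 px) at
a target magnification (default 10X); patches with at least 15% tissue are
kept, the rest discarded. Tissue detection works in HSV space: tissue pixels
are saturated and not near-white, while background and ink pen marks (blue /
green hues or low-chroma black strokes) are excluded — pen marks must never
enter the training patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from skimage.filters import threshold_otsu
from skimage.measure import block_reduce

__all__ = [
    "SlideImage",
    "TilingConfig",
    "Patch",
    "PatchSet",
    "read_slide",
    "detect_tissue",
    "tile_slide",
    "filter_patches",
]


@dataclass
class SlideImage:
    pixels: np.ndarray           # (H, W, 3) uint8
    native_magnification: float  # e.g. 40 for a 40X scan
    slide_id: str = ""

    def __post_init__(self):
        if self.native_magnification <= 0:
            raise ValueError("native_magnification must be positive")


@dataclass
class TilingConfig:
    patch_px: int = 224
    target_magnification: float = 10.0
    min_tissue_fraction: float = 0.15

    def __post_init__(self):
        if self.patch_px <= 0:
            raise ValueError("patch_px must be positive")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must lie in [0, 1]")


@dataclass
class Patch:
    image: np.ndarray        # (patch_px, patch_px, 3) uint8, at target magnification
    grid_row: int
    grid_col: int
    origin_x: int            # = grid_col * patch_px (half-open box [x, x+patch_px))
    origin_y: int            # = grid_row * patch_px
    tissue_fraction: float


@dataclass
class PatchSet:
    slide_id: str
    patches: list[Patch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    @property
    def grid_coords(self) -> np.ndarray:
        """(N, 2) int array of (grid_row, grid_col)."""
        return np.array([[p.grid_row, p.grid_col] for p in self.patches],
                        dtype=np.int64).reshape(len(self.patches), 2)

    def images(self) -> list[np.ndarray]:
        return [p.image for p in self.patches]


def read_slide(path: str | Path, native_magnification: float,
               slide_id: str | None = None) -> SlideImage:
    """Read a plain raster slide (PNG/TIFF).

    If `openslide` happens to be importable, pyramidal formats (.ndpi, .svs,
    .tiff pyramids) are read at their base level through the same interface;
    otherwise Pillow handles the flat raster.
    """
    path = Path(path)
    slide_id = slide_id or path.stem
    if path.suffix.lower() in {".ndpi", ".svs", ".mrxs"}:
        try:
            import openslide  # optional backend
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                f"{path.suffix} slides need the optional 'openslide' backend"
            ) from exc
        osl = openslide.OpenSlide(str(path))  # pragma: no cover
        region = osl.read_region((0, 0), 0, osl.dimensions)  # pragma: no cover
        pixels = np.asarray(region.convert("RGB"))  # pragma: no cover
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(pixels=pixels, native_magnification=native_magnification,
                      slide_id=slide_id)


# HSV tissue rule constants
_NEAR_WHITE_V = 0.95          # value above which a pixel is background glass
_SAT_FLOOR = 0.08             # minimal saturation for tissue
_SAT_CEIL = 0.20              # Otsu is clipped into [floor, ceil]: stains far more
                              # saturated than glass must not push the cut above tissue
_INK_HUE = (0.25, 0.72)       # green..blue ink hue band (H&E pinks/violets are >0.75)
_INK_SAT = 0.35
_BLACK_V = 0.25               # low-chroma dark strokes (black ink)


def detect_tissue(image: np.ndarray) -> np.ndarray:
    """Binary tissue mask for an RGB slide.

    Tissue = saturation above a bounded Otsu threshold AND value below a
    near-white cutoff, minus ink: saturated green/blue hues and low-chroma
    dark strokes. Pure background and pen marks yield an empty mask.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("detect_tissue expects an (H, W, 3) RGB image")
    rgb = image.astype(np.float32) / 255.0
    val = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    delta = val - mn
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(val > 0, delta / val, 0.0)
    thr = _SAT_FLOOR
    if sat.max() - sat.min() > 0.05:
        thr = float(np.clip(threshold_otsu(sat), _SAT_FLOOR, _SAT_CEIL))
    mask = (sat > thr) & (val < _NEAR_WHITE_V)
    mask &= ~((val < _BLACK_V) & (sat < _INK_SAT))  # black ink strokes
    # colored ink: evaluate hue only on still-masked, saturated pixels
    cand = np.flatnonzero(mask.ravel() & (sat.ravel() > _INK_SAT))
    if len(cand):
        flat = rgb.reshape(-1, 3)[cand]
        fmx = flat.max(axis=1)
        fd = fmx - flat.min(axis=1)
        r, g, b = flat[:, 0], flat[:, 1], flat[:, 2]
        hue = np.where(
            fmx == r, ((g - b) / fd) % 6.0,
            np.where(fmx == g, (b - r) / fd + 2.0, (r - g) / fd + 4.0),
        ) / 6.0
        ink_idx = cand[(hue >= _INK_HUE[0]) & (hue <= _INK_HUE[1])]
        mask.ravel()[ink_idx] = False
    return mask


def _downsample(slide: SlideImage, mask: np.ndarray,
                cfg: TilingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Area-averaged downsampling of image and mask to the target magnification."""
    factor_f = slide.native_magnification / cfg.target_magnification
    if factor_f < 1.0 - 1e-9:
        raise ValueError(
            f"target magnification {cfg.target_magnification} exceeds native "
            f"{slide.native_magnification}"
        )
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6:
        raise ValueError("native/target magnification ratio must be an integer")
    if factor == 1:
        return slide.pixels, mask.astype(np.float64)
    h, w = mask.shape
    h2, w2 = (h // factor) * factor, (w // factor) * factor
    img = block_reduce(slide.pixels[:h2, :w2].astype(np.float64),
                       (factor, factor, 1), np.mean)
    frac = block_reduce(mask[:h2, :w2].astype(np.float64), (factor, factor), np.mean)
    return np.clip(img, 0, 255).astype(np.uint8), frac


def tile_slide(slide: SlideImage, mask: np.ndarray, cfg: TilingConfig) -> PatchSet:
    """Cut the slide into a non-overlapping patch grid at target magnification.

    `mask` is the tissue mask at native resolution. Every full tile is
    returned with its tissue fraction (mean of the mask over the tile box);
    incomplete tiles at the right/bottom edges are dropped. Use
    :func:`filter_patches` to apply the tissue-fraction rule.
    """
    if mask.shape != slide.pixels.shape[:2]:
        raise ValueError("mask dimensions must match the slide")
    img, frac = _downsample(slide, mask, cfg)
    p = cfg.patch_px
    n_rows, n_cols = img.shape[0] // p, img.shape[1] // p
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            box = (slice(r * p, (r + 1) * p), slice(c * p, (c + 1) * p))
            patches.append(Patch(
                image=img[box],
                grid_row=r,
                grid_col=c,
                origin_x=c * p,
                origin_y=r * p,
                tissue_fraction=float(frac[box].mean()),
            ))
    return PatchSet(slide_id=slide.slide_id, patches=patches)


def filter_patches(patch_set: PatchSet, min_tissue_fraction: float) -> PatchSet:
    """Keep patches with tissue_fraction >= threshold ("at least"), in order."""
    kept = [p for p in patch_set.patches if p.tissue_fraction >= min_tissue_fraction]
    return PatchSet(slide_id=patch_set.slide_id, patches=kept)
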