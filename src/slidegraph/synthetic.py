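"""Synthetic whole-slide images with known tissue and tumor geometry.

Real BCC slides are gigapixel scans with several disconnected tissue sections
per glass, a near-white background, occasional pen marks, and a slide-level
label in {healthy, superficial, nodular, medium, high} (Swedish Sabbatsberg
grading: superficial/nodular are low-aggressive, medium and high are the
aggressive infiltrative patterns). This module emulates those structural
properties at desk scale so the whole pipeline — tissue detection, tiling,
contrastive features, patch graphs, the graph-transformer and the activation
maps — can be exercised and tested without the multi-terabyte archive.

Each subtype plants a distinct texture motif inside the tumor region:

* superficial — a dark band hugging the section border,
* nodular     — large rounded dark nests,
* medium      — dispersed medium-width strands,
* high        — fine infiltrative strands,

with per-subtype darkening so that simple intensity statistics (and hence a
small contrastive encoder) can separate the classes. The motifs are seeded
stand-ins, not histology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

SUBTYPES = ("healthy", "superficial", "nodular", "medium", "high")
"""Severity order: index in this tuple ranks aggressiveness (worst last)."""

# Per-subtype darkening of tumor pixels, RGB. Magnitudes are spaced so the
# mean tumor intensity orders the grades, and the directions differ in hue
# (mimicking the differing basophilia of the growth patterns) so that a small
# encoder can discriminate the classes.
_TUMOR_DELTA = {
    "superficial": np.array([40.0, 80.0, 50.0]),    # keeps a pink cast
    "nodular": np.array([120.0, 140.0, 60.0]),      # violet nests
    "medium": np.array([110.0, 150.0, 130.0]),      # dark red strands
    "high": np.array([165.0, 185.0, 150.0]),        # near-black infiltrate
}

# Smoothing of the random field whose upper quantile becomes the tumor mask:
# large isotropic sigma -> round nests, small/anisotropic -> fine strands.
_TUMOR_FIELD_SIGMA = {
    "nodular": (16.0, 16.0),
    "medium": (4.0, 11.0),
    "high": (1.2, 4.5),
}

_TISSUE_BASE = np.array([228.0, 172.0, 198.0])  # pale pink
_BACKGROUND = 249.0
_PEN_COLORS = (np.array([30.0, 40.0, 170.0]), np.array([25.0, 25.0, 30.0]))


class SlideSizingError(ValueError):
    """Requested section count cannot fit the canvas at the separation rule."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    `min_separation_px` is the guaranteed background gap between any two
    tissue sections (and between tissue and the canvas border). Keeping it
    above twice the tile size means separate sections can never share or
    neighbour a tile, so the downstream patch graph stays disconnected.
    """

    width_px: int = 2048
    height_px: int = 2048
    n_sections: int = 2
    subtype: str = "nodular"
    tumor_fraction: float = 0.35
    pen_marks: bool = False
    seed: int = 0
    min_separation_px: int = 480
    max_section_radius_px: int = 300

    def validate(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.n_sections < 0:
            raise ValueError("n_sections must be >= 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if (self.subtype == "healthy") != (self.tumor_fraction == 0.0):
            raise ValueError("tumor_fraction must be 0 exactly for healthy slides")


@dataclass
class SyntheticSlide:
    image: np.ndarray          # (H, W, 3) uint8
    tissue_mask: np.ndarray    # (H, W) bool
    tumor_mask: np.ndarray     # (H, W) bool
    label: str
    spec: SyntheticSlideSpec

    @property
    def tumor_over_tissue(self) -> float:
        tissue = int(self.tissue_mask.sum())
        return float(self.tumor_mask.sum()) / tissue if tissue else 0.0


def _section_layout(spec: SyntheticSlideSpec) -> tuple[list[tuple[float, float]], float]:
    """Cell-grid placement: section centres and the maximal blob radius."""
    n = spec.n_sections
    aspect = spec.width_px / spec.height_px
    cols = max(1, int(np.ceil(np.sqrt(n * aspect))))
    rows = int(np.ceil(n / cols))
    cell_w = spec.width_px / cols
    cell_h = spec.height_px / rows
    half_gap = spec.min_separation_px / 2.0
    max_r = min(cell_w, cell_h) / 2.0 - half_gap
    if max_r < 12:
        raise SlideSizingError(
            f"cannot place {n} sections on a {spec.width_px}x{spec.height_px} canvas "
            f"with {spec.min_separation_px}px separation"
        )
    centres = []
    for idx in range(n):
        r, c = divmod(idx, cols)
        centres.append(((c + 0.5) * cell_w, (r + 0.5) * cell_h))
    return centres, max_r


def _blob_mask(h: int, w: int, cy: float, cx: float, rx: float, ry: float,
               rng: np.random.Generator) -> np.ndarray:
    """Star-shaped (hence connected) blob: ellipse with angular perturbation."""
    y0, y1 = int(max(0, cy - ry - 4)), int(min(h, cy + ry + 5))
    x0, x1 = int(max(0, cx - rx - 4)), int(min(w, cx + rx + 5))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = (yy - cy) / ry
    dx = (xx - cx) / rx
    theta = np.arctan2(dy, dx)
    k1 = rng.integers(2, 4)
    k2 = rng.integers(4, 8)
    pert = 1.0 + 0.10 * np.sin(k1 * theta + rng.uniform(0, 2 * np.pi)) \
               + 0.06 * np.sin(k2 * theta + rng.uniform(0, 2 * np.pi))
    local = dx**2 + dy**2 <= pert**2
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _tumor_mask_for_section(section: np.ndarray, subtype: str, fraction: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Exactly `round(fraction * area)` tumor pixels inside one section."""
    area = int(section.sum())
    n_target = int(round(fraction * area))
    out = np.zeros_like(section)
    if n_target == 0:
        return out
    # work on the section bounding box only
    rows = np.flatnonzero(section.any(axis=1))
    cols = np.flatnonzero(section.any(axis=0))
    box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    local = section[box]
    idx = np.flatnonzero(local)
    if subtype == "superficial":
        # band hugging the section border: n_target pixels closest to it
        dist = ndimage.distance_transform_edt(local)
        vals = dist[local]
    else:
        sy, sx = _TUMOR_FIELD_SIGMA[subtype]
        field = ndimage.gaussian_filter(rng.standard_normal(local.shape), sigma=(sy, sx))
        # negate: take the highest field values
        vals = -field[local]
    order = np.argsort(vals, kind="stable")[:n_target]
    patch = np.zeros_like(local)
    patch.flat[idx[order]] = True
    out[box] = patch
    return out


def _draw_pen_marks(image: np.ndarray, tissue: np.ndarray, rng: np.random.Generator) -> None:
    """Saturated ink strokes on the background margin, mimicking the handwritten
    extraction index; never over tissue (sections are inset from the border)."""
    h, w = tissue.shape
    color = _PEN_COLORS[rng.integers(0, len(_PEN_COLORS))]
    n_strokes = rng.integers(2, 5)
    band_h = min(140, h // 8)
    for _ in range(n_strokes):
        x = rng.uniform(0.05 * w, 0.75 * w)
        y = rng.uniform(8, band_h)
        n_pts = rng.integers(3, 6)
        pts = np.cumsum(rng.uniform(-28, 28, size=(n_pts, 2)), axis=0) + (x, y)
        thick = rng.integers(3, 6)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            steps = int(max(abs(x1 - x0), abs(y1 - y0))) + 1
            xs = np.clip(np.linspace(x0, x1, steps).astype(int), 0, w - 1)
            ys = np.clip(np.linspace(y0, y1, steps).astype(int), 0, h - 1)
            for oy in range(-thick, thick + 1):
                for ox in range(-thick, thick + 1):
                    yy = np.clip(ys + oy, 0, h - 1)
                    xx = np.clip(xs + ox, 0, w - 1)
                    keep = ~tissue[yy, xx]
                    image[yy[keep], xx[keep]] = color


def generate_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    """Render one synthetic slide with its ground-truth tissue/tumor masks.

    Deterministic for a fixed spec (including `seed`): two calls return
    byte-identical images. Raises :class:`SlideSizingError` when the section
    count cannot fit the canvas at the configured separation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    image = np.full((h, w, 3), _BACKGROUND, dtype=np.float64)
    image += rng.uniform(-3.0, 3.0, size=(h, w, 1))
    tissue = np.zeros((h, w), dtype=bool)
    tumor = np.zeros((h, w), dtype=bool)

    if spec.n_sections > 0:
        centres, max_r = _section_layout(spec)
        max_r = min(max_r, spec.max_section_radius_px)
        for cx, cy in centres:
            rx = rng.uniform(0.78, 0.98) * max_r
            ry = rng.uniform(0.78, 0.98) * max_r
            jx = rng.uniform(-0.04, 0.04) * max_r
            jy = rng.uniform(-0.04, 0.04) * max_r
            section = _blob_mask(h, w, cy + jy, cx + jx, rx, ry, rng)
            tissue |= section
            if spec.subtype != "healthy":
                tumor |= _tumor_mask_for_section(section, spec.subtype,
                                                 spec.tumor_fraction, rng)

        # tissue rendering: pale pink with gentle texture noise
        ty, tx = np.nonzero(tissue)
        tex = ndimage.uniform_filter(rng.standard_normal((h, w)), size=7)[ty, tx]
        noise = rng.uniform(-5, 5, size=(len(ty), 3))
        image[ty, tx] = _TISSUE_BASE + 7.0 * tex[:, None] * 2.6 + noise

        if spec.subtype != "healthy" and tumor.any():
            delta = _TUMOR_DELTA[spec.subtype]
            uy, ux = np.nonzero(tumor)
            mod = 0.8 + 0.4 * (rng.standard_normal(len(uy)) > 0)
            image[uy, ux] -= delta * mod[:, None]

    if spec.pen_marks:
        _draw_pen_marks(image, tissue, rng)

    image = np.clip(image, 5, 255).astype(np.uint8)
    return SyntheticSlide(image=image, tissue_mask=tissue, tumor_mask=tumor,
                          label=spec.subtype, spec=spec)


@dataclass
class DatasetRanges:
    """Sampling ranges for :func:`generate_dataset` (the study conditions)."""

    width_px: int = 2048
    height_px: int = 2048
    n_sections: tuple[int, int] = (1, 3)
    tumor_fraction: tuple[float, float] = (0.28, 0.42)
    pen_mark_prob: float = 0.25
    min_separation_px: int = 480
    max_slides_per_case: int = 2


def generate_dataset(
    n_per_class: int,
    subtypes: tuple[str, ...] = SUBTYPES,
    ranges: DatasetRanges | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticSlide], pd.DataFrame]:
    """Balanced labelled corpus plus its manifest.

    Slides are grouped into cases of 1–`max_slides_per_case` slides (all
    slides of a case share the subtype), so case-level grouped splitting has
    something to exercise. Returns `(slides, manifest)`; the manifest has one
    row per slide: slide_id, case_id, subtype, seed and geometry columns.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not subtypes:
        raise ValueError("subtypes must be non-empty")
    ranges = ranges or DatasetRanges()
    rng = np.random.default_rng(seed)
    slides: list[SyntheticSlide] = []
    rows = []
    case_counter = 0
    for subtype in subtypes:
        made = 0
        while made < n_per_class:
            case_id = f"case_{case_counter:04d}"
            case_counter += 1
            take = min(int(rng.integers(1, ranges.max_slides_per_case + 1)),
                       n_per_class - made)
            for _ in range(take):
                slide_seed = int(rng.integers(0, 2**31 - 1))
                frac = 0.0 if subtype == "healthy" else float(
                    rng.uniform(*ranges.tumor_fraction))
                spec = SyntheticSlideSpec(
                    width_px=ranges.width_px,
                    height_px=ranges.height_px,
                    n_sections=int(rng.integers(ranges.n_sections[0],
                                                ranges.n_sections[1] + 1)),
                    subtype=subtype,
                    tumor_fraction=frac,
                    pen_marks=bool(rng.uniform() < ranges.pen_mark_prob),
                    seed=slide_seed,
                    min_separation_px=ranges.min_separation_px,
                )
                slide = generate_slide(spec)
                slide_id = f"{subtype}_{made:03d}"
                rows.append({
                    "slide_id": slide_id,
                    "case_id": case_id,
                    "subtype": subtype,
                    "seed": slide_seed,
                    "n_sections": spec.n_sections,
                    "tumor_fraction": frac,
                    "pen_marks": spec.pen_marks,
                })
                slides.append(slide)
                made += 1
    return slides, pd.DataFrame(rows)


def write_dataset(slides: list[SyntheticSlide], manifest: pd.DataFrame,
                  out_dir: str | Path) -> pd.DataFrame:
    """Write PNG images + masks + manifest CSV; returns manifest with paths."""
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths, tissue_paths, tumor_paths = [], [], []
    for slide, slide_id in zip(slides, manifest["slide_id"]):
        img_path = out / "slides" / f"{slide_id}.png"
        Image.fromarray(slide.image).save(img_path)
        tp = out / "masks" / f"{slide_id}_tissue.png"
        up = out / "masks" / f"{slide_id}_tumor.png"
        Image.fromarray((slide.tissue_mask * 255).astype(np.uint8)).save(tp)
        Image.fromarray((slide.tumor_mask * 255).astype(np.uint8)).save(up)
        paths.append(str(img_path))
        tissue_paths.append(str(tp))
        tumor_paths.append(str(up))
    manifest["path"] = paths
    manifest["tissue_mask_path"] = tissue_paths
    manifest["tumor_mask_path"] = tumor_paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def spec_to_dict(spec: SyntheticSlideSpec) -> dict:
    return dataclasses.asdict(spec)
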