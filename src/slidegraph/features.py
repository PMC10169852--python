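"""Contrastive (SimCLR-style) patch representation learning.

Two stochastic augmented views of each patch form a positive pair; all other
views in the batch are negatives. The encoder is trained with the normalized
temperature-scaled cross entropy (NT-Xent) on a projection head, after which
`extract_features` reads one backbone feature vector per patch.

Default hyperparameters follow the full-scale recipe (batch 512, 32 epochs,
Adam lr 1e-4 cosine-annealed, weight decay 1e-6, temperature 0.5); the
desk-scale runs in this repository pass explicit small configs instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from skimage.color import rgb2gray
from skimage.filters import gaussian
from skimage.transform import resize

from ._autodiff import Tensor, concat
from .nn import Adam, Conv2d, Linear, Module
from .tiling import PatchSet

__all__ = [
    "PretrainConfig",
    "FeatureMatrix",
    "augment_views",
    "nt_xent_loss",
    "pretrain_encoder",
    "extract_features",
    "make_encoder",
    "save_features",
    "load_features",
]


@dataclass
class PretrainConfig:
    batch_size: int = 512
    epochs: int = 32
    learning_rate: float = 1e-4     # cosine-annealed to 0 over all steps
    weight_decay: float = 1e-6
    temperature: float = 0.5
    encoder: str = "resnet18"       # 18-layer residual backbone; "small_cnn" at desk scale
    input_px: int = 32              # patches are resized to this before encoding
    encoder_width: int = 64         # base channel width of the backbone

    def __post_init__(self):
        for name in ("batch_size", "epochs", "learning_rate", "weight_decay",
                     "temperature", "input_px", "encoder_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FeatureMatrix:
    slide_id: str
    matrix: np.ndarray       # (N, d), rows aligned with the PatchSet order
    grid_coords: np.ndarray  # (N, 2) int

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


# ---------------------------------------------------------------------------
# encoders


class SmallCnnEncoder(Module):
    """Three-conv desk-scale encoder with a two-layer projection head.

    No batch statistics anywhere, so features are exactly batch-invariant.
    """

    def __init__(self, rng: np.random.Generator, width: int = 32, input_px: int = 32):
        w = width
        self.conv1 = Conv2d(3, w // 2, 3, 2, rng)
        self.conv2 = Conv2d(w // 2, w, 3, 2, rng)
        self.conv3 = Conv2d(w, w, 3, 2, rng)
        self.proj1 = Linear(w, w, rng)
        self.proj2 = Linear(w, max(16, w // 2), rng)
        self.feature_dim = w
        self.input_px = input_px
        self.name = "small_cnn"

    def features(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        # global average pool
        return h.reshape(h.shape[0], h.shape[1], -1).mean(axis=2)

    def project(self, feats: Tensor) -> Tensor:
        return self.proj2(self.proj1(feats).relu())


class _ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng)
        self.down = Conv2d(in_ch, out_ch, 1, stride, rng) if (stride != 1 or in_ch != out_ch) else None
        self.pad = 1

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(_pad2d(x, 1)).relu()
        h = self.conv2(_pad2d(h, 1))
        skip = self.down(x) if self.down is not None else x
        return (h + skip).relu()


def _pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an NCHW tensor."""
    B, C, H, W = x.shape
    zeros_h = Tensor(np.zeros((B, C, p, W)))
    zeros_w = Tensor(np.zeros((B, C, H + 2 * p, p)))
    body = concat([zeros_h, x, zeros_h], axis=2)
    return concat([zeros_w, body, zeros_w], axis=3)


class ResNet18Encoder(Module):
    """18-layer residual convolutional backbone (stem + 8 two-conv blocks + head).

    Feature width is 8x the base width (512 at the full-scale default of 64).
    """

    def __init__(self, rng: np.random.Generator, width: int = 64, input_px: int = 32):
        w = width
        self.stem = Conv2d(3, w, 3, 1, rng)
        stages = []
        in_ch = w
        for i, ch in enumerate((w, 2 * w, 4 * w, 8 * w)):
            stride = 1 if i == 0 else 2
            stages.append(_ResidualBlock(in_ch, ch, stride, rng))
            stages.append(_ResidualBlock(ch, ch, 1, rng))
            in_ch = ch
        self.stages = stages
        self.proj1 = Linear(8 * w, 4 * w, rng)
        self.proj2 = Linear(4 * w, max(16, w), rng)
        self.feature_dim = 8 * w
        self.input_px = input_px
        self.name = "resnet18"

    def features(self, x: Tensor) -> Tensor:
        h = self.stem(_pad2d(x, 1)).relu()
        for block in self.stages:
            h = block(h)
        return h.reshape(h.shape[0], h.shape[1], -1).mean(axis=2)

    def project(self, feats: Tensor) -> Tensor:
        return self.proj2(self.proj1(feats).relu())


_ENCODERS = {"small_cnn": SmallCnnEncoder, "resnet18": ResNet18Encoder}


def make_encoder(name: str, rng: np.random.Generator, width: int | None = None,
                 input_px: int = 32) -> Module:
    if name not in _ENCODERS:
        raise ValueError(f"unknown encoder {name!r}; choose from {sorted(_ENCODERS)}")
    kwargs = {"input_px": input_px}
    if width is not None:
        kwargs["width"] = width
    return _ENCODERS[name](rng, **kwargs)


# ---------------------------------------------------------------------------
# augmentation


def _to_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def _one_view(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape[:2]
    # random resized crop
    scale = rng.uniform(0.6, 1.0)
    ar = rng.uniform(0.8, 1.25)
    ch = min(h, max(4, int(round(h * np.sqrt(scale) / np.sqrt(ar)))))
    cw = min(w, max(4, int(round(w * np.sqrt(scale) * np.sqrt(ar)))))
    y0 = rng.integers(0, h - ch + 1)
    x0 = rng.integers(0, w - cw + 1)
    view = resize(img[y0:y0 + ch, x0:x0 + cw], (h, w), anti_aliasing=False,
                  preserve_range=True)
    # flips
    if rng.uniform() < 0.5:
        view = view[:, ::-1]
    if rng.uniform() < 0.5:
        view = view[::-1, :]
    # color jitter: brightness / contrast / saturation (mild, so augmentation
    # does not erase the stain-intensity cues the classes live on)
    view = view * rng.uniform(0.85, 1.15)
    mean = view.mean()
    view = (view - mean) * rng.uniform(0.8, 1.2) + mean
    gray = rgb2gray(np.clip(view, 0, 1))[..., None]
    view = gray + (view - gray) * rng.uniform(0.6, 1.4)
    # random grayscale
    if rng.uniform() < 0.2:
        view = np.repeat(rgb2gray(np.clip(view, 0, 1))[..., None], 3, axis=2)
    # gaussian blur
    if rng.uniform() < 0.5:
        view = gaussian(view, sigma=rng.uniform(0.1, 1.0), channel_axis=2,
                        preserve_range=True)
    return np.clip(view, 0.0, 1.0)


def augment_views(patch: np.ndarray, seed: int | np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two stochastic views of one patch, same shape as the input.

    Deterministic for a fixed seed; pass a Generator to share a stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = _to_float(patch)
    return _one_view(img, rng), _one_view(img, rng)


# ---------------------------------------------------------------------------
# NT-Xent


def default_pairing(n: int) -> np.ndarray:
    """Pairing for row layout (view_a_0, view_b_0, view_a_1, ...)."""
    pairs = np.arange(n)
    pairs[0::2] += 1
    pairs[1::2] -= 1
    return pairs


def nt_xent_loss(embeddings: Tensor | np.ndarray, pairing: np.ndarray,
                 temperature: float = 0.5) -> Tensor:
    """Normalized temperature-scaled cross entropy over a batch of views.

    For each anchor i with positive p(i), the loss is
    -log exp(cos(z_i, z_p(i))/t) / sum_{k != i} exp(cos(z_i, z_k)/t),
    averaged over all 2B anchors; the self-similarity term is excluded from
    the denominator. A single positive pair gives exactly zero.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    n = z.shape[0]
    pairing = np.asarray(pairing)
    if pairing.shape != (n,) or np.any(pairing == np.arange(n)):
        raise ValueError("pairing must map each row to a distinct positive row")
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    zn = z / norm
    sim = (zn @ zn.T) * (1.0 / temperature)
    eye = np.eye(n)
    pos_mask = np.zeros((n, n))
    pos_mask[np.arange(n), pairing] = 1.0
    exp_sim = sim.exp()
    denom = (exp_sim * (1.0 - eye)).sum(axis=1)
    pos = (sim * pos_mask).sum(axis=1)
    return (denom.log() - pos).mean()


# ---------------------------------------------------------------------------
# pretraining and extraction


def _thumbnails(images: list[np.ndarray], px: int) -> np.ndarray:
    """Resize patch images to (n, 3, px, px) float in [0, 1]."""
    out = np.empty((len(images), 3, px, px), dtype=np.float64)
    for i, img in enumerate(images):
        f = _to_float(img)
        if f.shape[:2] != (px, px):
            f = resize(f, (px, px), anti_aliasing=True, preserve_range=True)
        out[i] = np.moveaxis(f, -1, 0)
    return out


def _collect_images(patch_stream) -> list[np.ndarray]:
    images: list[np.ndarray] = []
    if isinstance(patch_stream, PatchSet):
        patch_stream = [patch_stream]
    for item in patch_stream:
        if isinstance(item, PatchSet):
            images.extend(item.images())
        else:
            images.append(np.asarray(item))
    return images


def pretrain_encoder(patch_stream, cfg: PretrainConfig, seed: int = 0
                     ) -> tuple[Module, list[float]]:
    """Train the encoder contrastively; returns (encoder, per-epoch mean loss).

    `patch_stream` is a PatchSet, a list of PatchSets, or a list of RGB patch
    arrays — the caller is responsible for excluding held-out test patches.
    """
    images = _collect_images(patch_stream)
    if len(images) < 2:
        raise ValueError("contrastive pretraining needs at least 2 patches")
    if cfg.batch_size > len(images):
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds corpus size {len(images)}")
    rng = np.random.default_rng(seed)
    encoder = make_encoder(cfg.encoder, rng, width=cfg.encoder_width,
                           input_px=cfg.input_px)
    thumbs = _thumbnails(images, cfg.input_px)
    opt = Adam(encoder.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    steps_per_epoch = len(images) // cfg.batch_size
    total_steps = max(1, cfg.epochs * steps_per_epoch)
    trace: list[float] = []
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(images))
        losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            views = np.empty((2 * len(idx),) + thumbs.shape[1:])
            for j, i in enumerate(idx):
                img = np.moveaxis(thumbs[i], 0, -1)
                va, vb = augment_views(img, rng)
                views[2 * j] = np.moveaxis(va, -1, 0)
                views[2 * j + 1] = np.moveaxis(vb, -1, 0)
            x = Tensor(views)
            z = encoder.project(encoder.features(x))
            loss = nt_xent_loss(z, default_pairing(2 * len(idx)), cfg.temperature)
            opt.zero_grad()
            loss.backward()
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * step / total_steps))
            opt.step()
            losses.append(loss.item())
            step += 1
        trace.append(float(np.mean(losses)))
    return encoder, trace


def extract_features(encoder: Module, patches: PatchSet,
                     batch_size: int = 64) -> FeatureMatrix:
    """One backbone feature vector per retained patch, in PatchSet order.

    The encoder has no batch statistics, so the output is independent of the
    batching used here.
    """
    if len(patches) == 0:
        raise ValueError("cannot extract features from an empty PatchSet")
    thumbs = _thumbnails(patches.images(), encoder.input_px)
    rows = []
    for b in range(0, len(thumbs), batch_size):
        feats = encoder.features(Tensor(thumbs[b:b + batch_size]))
        rows.append(feats.data)
    return FeatureMatrix(slide_id=patches.slide_id,
                         matrix=np.vstack(rows),
                         grid_coords=patches.grid_coords)


# ---------------------------------------------------------------------------
# encoder checkpoints


def save_encoder(encoder: Module, path: str | Path, seed: int | None = None) -> None:
    """Single-file .npz weights + JSON sidecar (architecture + seed)."""
    import json

    path = Path(path)
    np.savez(path, **encoder.state_dict())
    sidecar = {
        "encoder": encoder.name,
        "width": encoder.feature_dim if encoder.name == "small_cnn" else encoder.feature_dim // 8,
        "input_px": encoder.input_px,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_encoder(path: str | Path) -> Module:
    import json

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"encoder checkpoint not found: {path}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    encoder = make_encoder(sidecar["encoder"], np.random.default_rng(0),
                           width=sidecar["width"], input_px=sidecar["input_px"])
    with np.load(path) as data:
        encoder.load_state_dict({k: data[k] for k in data.files})
    return encoder


# ---------------------------------------------------------------------------
# HDF5 feature bundles


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=fm.matrix)
        f.create_dataset("grid_coords", data=fm.grid_coords)
        f.attrs["slide_id"] = fm.slide_id


def load_features(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            slide_id=str(f.attrs["slide_id"]),
            matrix=f["features"][()],
            grid_coords=f["grid_coords"][()],
        )
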