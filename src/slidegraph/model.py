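"""Graph-transformer slide classifier.

Pipeline per slide: graph convolution over patch nodes using the symmetric
renormalised adjacency (H' = relu(A_hat H W)), spectral min-cut pooling down
to a digestible token count, then a transformer encoder (multi-head
self-attention + MLP blocks, pre-LayerNorm, residual) over the pooled tokens
with a prepended class token. There are NO sequence positional embeddings —
spatial context is carried entirely by the graph, which is what makes the
logits invariant to token permutation and to where disconnected tissue
sections happen to sit on the glass.

Min-cut pooling learns a row-stochastic soft assignment S of nodes to k
clusters and returns two auxiliary losses: the relaxed normalised-cut term
-tr(S^T A S) / tr(S^T D S) in [-1, 0] and the orthogonality penalty
|| S^T S / ||S^T S||_F - I_k / sqrt(k) ||_F in [0, 2]. When a graph has fewer
nodes than clusters, pooling degrades to the identity assignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat
from .nn import Linear, Module, TransformerBlock
from .graph import SlideGraph

__all__ = ["ModelConfig", "Prediction", "GraphTransformer", "ForwardResult",
           "model_forward", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_classes: int = 3
    in_dim: int = 32                 # width of the node feature vectors
    gcn_layers: int = 1
    embed_dim: int = 64
    mlp_dim: int = 128
    n_attention_blocks: int = 3
    n_heads: int = 8
    pool_clusters: int = 100         # desk scale typically 8

    def __post_init__(self):
        if self.n_classes not in (2, 3, 5):
            raise ValueError("n_classes must be 2, 3 or 5")
        for name in ("in_dim", "gcn_layers", "embed_dim", "mlp_dim",
                     "n_attention_blocks", "n_heads", "pool_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Prediction:
    slide_id: str
    probabilities: np.ndarray      # (n_classes,), sums to 1
    predicted_class: int
    attention_maps: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be a simplex vector")
        self.probabilities = p


@dataclass
class PoolResult:
    """Output of min-cut pooling: k tokens, S^T A S, auxiliary losses and S."""

    tokens: Tensor                  # (k, embed) pooled node embeddings
    pooled_adjacency: np.ndarray    # (k, k)
    cut_loss: Tensor                # scalar in [-1, 0]
    ortho_loss: Tensor              # scalar in [0, 2]
    assignment: np.ndarray          # (N, k), rows sum to 1


@dataclass
class ForwardResult:
    """Everything one forward pass produces, kept differentiable for training
    and for gradient-weighted attention relevance."""

    logits: Tensor                     # (n_classes,)
    cut_loss: Tensor                   # scalar in [-1, 0]
    ortho_loss: Tensor                 # scalar in [0, 2]
    attentions: list[Tensor]           # per block, (heads, T, T), grad-retaining
    assignment: np.ndarray             # (N, k) pooling assignment used

    @property
    def probabilities(self) -> np.ndarray:
        z = self.logits.data - self.logits.data.max()
        e = np.exp(z)
        return e / e.sum()


class GraphTransformer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        dims = [cfg.in_dim] + [cfg.embed_dim] * cfg.gcn_layers
        self.gcn = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.pool = Linear(cfg.embed_dim, cfg.pool_clusters, rng)
        self.cls_token = Tensor(rng.normal(0.0, 0.02, size=(1, cfg.embed_dim)),
                                requires_grad=True)
        self.blocks = [TransformerBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_dim, rng)
                       for _ in range(cfg.n_attention_blocks)]
        self.ln_g = Tensor(np.ones(cfg.embed_dim), requires_grad=True)
        self.ln_b = Tensor(np.zeros(cfg.embed_dim), requires_grad=True)
        self.head = Linear(cfg.embed_dim, cfg.n_classes, rng)

    # -- stages -----------------------------------------------------------

    def gcn_forward(self, graph: SlideGraph) -> Tensor:
        a_hat = Tensor(graph.normalized_adjacency)
        h = Tensor(graph.features)
        for layer in self.gcn:
            h = (a_hat @ layer(h)).relu()
        return h

    def mincut_pool(self, h: Tensor, graph: SlideGraph) -> "PoolResult":
        """Soft-cluster nodes into `pool_clusters` tokens (identity when N <= k)."""
        n = h.shape[0]
        k = self.cfg.pool_clusters
        a_dense = graph.adjacency.to_dense()
        if n <= k:
            zero = Tensor(0.0)
            return PoolResult(tokens=h, pooled_adjacency=a_dense,
                              cut_loss=zero, ortho_loss=zero, assignment=np.eye(n))
        s = self.pool(h).softmax(axis=-1)          # (N, k) row-stochastic
        tokens = s.T @ h                           # (k, embed)
        a = Tensor(a_dense)
        deg = Tensor(np.diag(graph.adjacency.degrees().astype(np.float64)))
        eye = np.eye(k)
        sas = s.T @ a @ s
        sds = s.T @ deg @ s
        tr_sas = (sas * eye).sum()
        tr_sds = (sds * eye).sum()
        if graph.adjacency.n_edges == 0:
            cut = Tensor(0.0)
        else:
            cut = -(tr_sas / tr_sds)
        ss = s.T @ s
        fro = ((ss * ss).sum()).sqrt()
        diff = ss / fro - Tensor(eye / np.sqrt(k))
        ortho = ((diff * diff).sum()).sqrt()
        return PoolResult(tokens=tokens, pooled_adjacency=sas.data.copy(),
                          cut_loss=cut, ortho_loss=ortho, assignment=s.data.copy())

    def transformer_forward(self, tokens: Tensor) -> tuple[Tensor, list[Tensor]]:
        x = concat([self.cls_token, tokens], axis=0)
        attns = []
        for block in self.blocks:
            x = block(x)
            attns.append(block.attn.last_attention)
        x = x.layer_norm() * self.ln_g + self.ln_b
        logits = self.head(x[0])
        return logits, attns

    # -- full model -------------------------------------------------------

    def forward(self, graph: SlideGraph) -> ForwardResult:
        if graph.n_nodes == 0:
            raise ValueError(
                f"slide {graph.slide_id!r} has no retained patches; "
                "cannot classify an empty graph"
            )
        if graph.features.shape[1] != self.cfg.in_dim:
            raise ValueError(
                f"feature width {graph.features.shape[1]} != model in_dim "
                f"{self.cfg.in_dim}"
            )
        h = self.gcn_forward(graph)
        pooled = self.mincut_pool(h, graph)
        logits, attns = self.transformer_forward(pooled.tokens)
        return ForwardResult(logits=logits, cut_loss=pooled.cut_loss,
                             ortho_loss=pooled.ortho_loss, attentions=attns,
                             assignment=pooled.assignment)

    __call__ = forward


def model_forward(model: GraphTransformer, graph: SlideGraph) -> Prediction:
    """Inference wrapper returning a Prediction with cached attention maps."""
    res = model.forward(graph)
    probs = res.probabilities
    return Prediction(
        slide_id=graph.slide_id,
        probabilities=probs,
        predicted_class=int(np.argmax(probs)),
        attention_maps=[a.data.copy() for a in res.attentions],
    )


def save_checkpoint(model: GraphTransformer, path: str | Path,
                    seed: int | None = None, extra: dict | None = None) -> None:
    """Single-file .npz weights plus a JSON sidecar with the config and seed."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"model_config": asdict(model.cfg), "seed": seed}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> GraphTransformer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"checkpoint sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    cfg = ModelConfig(**sidecar["model_config"])
    model = GraphTransformer(cfg, rng=np.random.default_rng(0))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
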