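"""Train the graph-transformer with case-grouped CV and explain a prediction.

A compact version of the full study: 3 classes, grouped five-fold
cross-validation, majority-vote ensembling on held-out slides, and a
GraphCAM heatmap written next to this script's temporary directory.
"""

import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from slidegraph import (ModelConfig, TrainConfig, cross_validate,
                        ensemble_predict, evaluate, extract_features,
                        graph_from_features, graphcam, map_label, model_forward,
                        pretrain_encoder, render_heatmap)
from slidegraph.features import PretrainConfig
from slidegraph.study import StudyConfig, _prepare
from slidegraph.synthetic import DatasetRanges, generate_dataset

cfg = StudyConfig()
ranges = DatasetRanges(width_px=1024, height_px=1024, n_sections=(1, 1))
train_slides, train_manifest = generate_dataset(
    8, subtypes=("healthy", "nodular", "high"), ranges=ranges, seed=0)
test_slides, test_manifest = generate_dataset(
    3, subtypes=("healthy", "nodular", "high"), ranges=ranges, seed=99)
cfg.ranges = ranges
train_ps, _ = _prepare(train_slides, train_manifest, cfg)
test_ps, _ = _prepare(test_slides, test_manifest, cfg)

encoder, _ = pretrain_encoder(train_ps, PretrainConfig(
    batch_size=16, epochs=3, learning_rate=1e-3, encoder="small_cnn",
    encoder_width=32, input_px=32), seed=0)
train_graphs = [graph_from_features(extract_features(encoder, ps))
                for ps in train_ps]
test_graphs = [graph_from_features(extract_features(encoder, ps))
               for ps in test_ps]

labels = [map_label(s, "T2") for s in train_manifest["subtype"]]
model_cfg = ModelConfig(n_classes=3, in_dim=32, embed_dim=32, mlp_dim=128,
                        n_attention_blocks=3, n_heads=4, pool_clusters=8)
train_cfg = TrainConfig(epochs=100, lr_decay_steps=(40, 80), k_folds=5)
results, _ = cross_validate(train_graphs, labels,
                            list(train_manifest["case_id"]), model_cfg,
                            train_cfg, seed=0)

truths = [map_label(s, "T2") for s in test_manifest["subtype"]]
finals = [ensemble_predict([model_forward(r.model, g) for r in results])
          for g in test_graphs]
report = evaluate(np.array(finals), truths, "T2")
print(f"held-out slides: {len(truths)}, ensemble accuracy: "
      f"{100 * report.accuracy:.1f}%")
print("confusion matrix (rows = truth: healthy, low-risk, high-risk):")
print(report.confusion)

# explain the first tumor slide with the first fold's model
idx = next(i for i, t in enumerate(truths) if t != 0)
relmap = graphcam(results[0].model, test_graphs[idx])
print(f"\nGraphCAM for slide {test_graphs[idx].slide_id} "
      f"(target class {relmap.target_class}): "
      f"scores in [{relmap.scores.min():.2f}, {relmap.scores.max():.2f}]")
overlay = render_heatmap(relmap, test_graphs[idx].grid_coords,
                         test_slides[idx].image, patch_px=224,
                         out_dims=(256, 256))
out = Path(tempfile.mkdtemp()) / "heatmap.png"
Image.fromarray(overlay).save(out)
print(f"heatmap overlay written to {out}")
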