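"""Pipeline configuration and stage runner tying the library into a tool.

One config (YAML or dict) drives all stages; every stage writes its artifacts
under the configured workdir and appends a structured JSON line (stage, seed,
config hash, timing) to `log.jsonl`. Stages:

    simulate -> tile -> pretrain -> featurize -> graph -> train
             -> predict -> evaluate -> explain

Each stage reads only the previous stages' on-disk artifacts, so any prefix
of the pipeline can be rerun; a missing upstream artifact raises an error
naming the missing file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import explain as explain_mod
from . import features as features_mod
from . import graph as graph_mod
from . import synthetic, tiling, training
from .model import (ModelConfig, Prediction, load_checkpoint, model_forward,
                    save_checkpoint)

__all__ = ["PipelineConfig", "run_stage", "run_pipeline", "STAGES"]

STAGES = ("simulate", "tile", "pretrain", "featurize", "graph", "train",
          "predict", "evaluate", "explain")


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    n_per_class: int = 4
    test_per_class: int = 2
    subtypes: tuple = ("healthy", "nodular", "high")
    width_px: int = 2048
    height_px: int = 2048
    n_sections: tuple = (1, 3)
    tumor_fraction: tuple = (0.28, 0.42)
    pen_mark_prob: float = 0.25
    min_separation_px: int = 480
    native_magnification: float = 10.0


@dataclass
class PretrainStageConfig:
    encoder: str = "small_cnn"
    encoder_width: int = 32
    input_px: int = 32
    batch_size: int = 32
    epochs: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    temperature: float = 0.5


@dataclass
class ModelStageConfig:
    gcn_layers: int = 1
    embed_dim: int = 32
    mlp_dim: int = 128
    n_attention_blocks: int = 3
    n_heads: int = 4
    pool_clusters: int = 8


@dataclass
class TrainStageConfig:
    task: str = "T2"
    batch_size: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    lr_decay_steps: tuple = (40, 80)
    lr_decay_factor: float = 0.1
    k_folds: int = 5
    aux_loss_weight: float = 1.0
    class_weighting: bool = False


@dataclass
class ExplainStageConfig:
    colormap: str = "jet"
    alpha: float = 0.5
    thumbnail_scale: float = 0.25


@dataclass
class PipelineConfig:
    workdir: str = "slidegraph_out"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    tiling: tiling.TilingConfig = field(default_factory=tiling.TilingConfig)
    pretrain: PretrainStageConfig = field(default_factory=PretrainStageConfig)
    model: ModelStageConfig = field(default_factory=ModelStageConfig)
    train: TrainStageConfig = field(default_factory=TrainStageConfig)
    explain: ExplainStageConfig = field(default_factory=ExplainStageConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in (("simulate", SimulateConfig),
                         ("tiling", tiling.TilingConfig),
                         ("pretrain", PretrainStageConfig),
                         ("model", ModelStageConfig),
                         ("train", TrainStageConfig),
                         ("explain", ExplainStageConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub, data[key])
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# artifact helpers


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path} — run the '{hint}' stage first")
    return path


def _manifest(work: Path) -> pd.DataFrame:
    return pd.read_csv(_require(work / "data" / "manifest.csv", "simulate"))


def _log(work: Path, stage: str, cfg: PipelineConfig, t0: float, **extra) -> None:
    entry = {"stage": stage, "seed": cfg.seed, "config_hash": cfg.config_hash(),
             "elapsed_s": round(time.time() - t0, 3), **extra}
    with open(work / "log.jsonl", "a") as f:
        f.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, work: Path) -> dict:
    sc = cfg.simulate
    ranges = synthetic.DatasetRanges(
        width_px=sc.width_px, height_px=sc.height_px, n_sections=tuple(sc.n_sections),
        tumor_fraction=tuple(sc.tumor_fraction), pen_mark_prob=sc.pen_mark_prob,
        min_separation_px=sc.min_separation_px,
    )
    parts = []
    all_slides = []
    for split, n, seed in (("train", sc.n_per_class, cfg.seed),
                           ("test", sc.test_per_class, cfg.seed + 100_003)):
        slides, manifest = synthetic.generate_dataset(
            n, subtypes=tuple(sc.subtypes), ranges=ranges, seed=seed)
        manifest["split"] = split
        manifest["slide_id"] = split + "_" + manifest["slide_id"]
        manifest["case_id"] = split + "_" + manifest["case_id"]
        parts.append(manifest)
        all_slides.extend(slides)
    manifest = pd.concat(parts, ignore_index=True)
    manifest = synthetic.write_dataset(all_slides, manifest, work / "data")
    return {"n_slides": len(manifest)}


def _stage_tile(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    patch_root = work / "patches"
    patch_root.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        slide = tiling.read_slide(row["path"], cfg.simulate.native_magnification,
                                  slide_id=row["slide_id"])
        mask = tiling.detect_tissue(slide.pixels)
        patches = tiling.filter_patches(
            tiling.tile_slide(slide, mask, cfg.tiling),
            cfg.tiling.min_tissue_fraction,
        )
        slide_dir = patch_root / row["slide_id"]
        slide_dir.mkdir(exist_ok=True)
        for p in patches:
            p_path = slide_dir / f"r{p.grid_row}_c{p.grid_col}.png"
            Image.fromarray(p.image).save(p_path)
            rows.append({
                "slide_id": row["slide_id"], "grid_row": p.grid_row,
                "grid_col": p.grid_col, "origin_x": p.origin_x,
                "origin_y": p.origin_y, "tissue_fraction": p.tissue_fraction,
                "patch_path": str(p_path),
            })
    pd.DataFrame(rows).to_csv(patch_root / "manifest.csv", index=False)
    return {"n_patches": len(rows)}


def _load_patchset(work: Path, slide_id: str) -> tiling.PatchSet:
    pm = pd.read_csv(_require(work / "patches" / "manifest.csv", "tile"))
    sub = pm[pm["slide_id"] == slide_id]
    patches = [
        tiling.Patch(
            image=np.asarray(Image.open(r["patch_path"]).convert("RGB")),
            grid_row=int(r["grid_row"]), grid_col=int(r["grid_col"]),
            origin_x=int(r["origin_x"]), origin_y=int(r["origin_y"]),
            tissue_fraction=float(r["tissue_fraction"]),
        )
        for _, r in sub.iterrows()
    ]
    return tiling.PatchSet(slide_id=slide_id, patches=patches)


def _stage_pretrain(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    train_ids = manifest.loc[manifest["split"] == "train", "slide_id"]
    # hold-out test patches are excluded from contrastive pretraining
    patch_sets = [_load_patchset(work, sid) for sid in train_ids]
    pc = cfg.pretrain
    pretrain_cfg = features_mod.PretrainConfig(
        batch_size=pc.batch_size, epochs=pc.epochs, learning_rate=pc.learning_rate,
        weight_decay=pc.weight_decay, temperature=pc.temperature,
        encoder=pc.encoder, input_px=pc.input_px, encoder_width=pc.encoder_width,
    )
    encoder, trace = features_mod.pretrain_encoder(patch_sets, pretrain_cfg,
                                                   seed=cfg.seed)
    features_mod.save_encoder(encoder, work / "encoder.npz", seed=cfg.seed)
    (work / "pretrain_trace.json").write_text(json.dumps(trace))
    return {"final_loss": trace[-1], "epochs": len(trace)}


def _stage_featurize(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    encoder = features_mod.load_encoder(_require(work / "encoder.npz", "pretrain"))
    out = work / "features"
    out.mkdir(exist_ok=True)
    for sid in manifest["slide_id"]:
        fm = features_mod.extract_features(encoder, _load_patchset(work, sid))
        features_mod.save_features(fm, out / f"{sid}.h5")
    return {"n_slides": len(manifest), "dim": encoder.feature_dim}


def _stage_graph(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    out = work / "graphs"
    out.mkdir(exist_ok=True)
    for sid in manifest["slide_id"]:
        fm = features_mod.load_features(
            _require(work / "features" / f"{sid}.h5", "featurize"))
        graph_mod.save_graph(graph_mod.graph_from_features(fm), out / f"{sid}.h5")
    return {"n_graphs": len(manifest)}


def _load_graphs(work: Path, slide_ids) -> list:
    return [graph_mod.load_graph(_require(work / "graphs" / f"{sid}.h5", "graph"))
            for sid in slide_ids]


def _train_configs(cfg: PipelineConfig, in_dim: int):
    tc = cfg.train
    task = training.TaskSpec.for_task(tc.task)
    model_cfg = ModelConfig(
        n_classes=task.n_classes, in_dim=in_dim,
        gcn_layers=cfg.model.gcn_layers, embed_dim=cfg.model.embed_dim,
        mlp_dim=cfg.model.mlp_dim, n_attention_blocks=cfg.model.n_attention_blocks,
        n_heads=cfg.model.n_heads, pool_clusters=cfg.model.pool_clusters,
    )
    train_cfg = training.TrainConfig(
        batch_size=tc.batch_size, epochs=tc.epochs, learning_rate=tc.learning_rate,
        weight_decay=tc.weight_decay, lr_decay_steps=tuple(tc.lr_decay_steps),
        lr_decay_factor=tc.lr_decay_factor, k_folds=tc.k_folds,
        aux_loss_weight=tc.aux_loss_weight, class_weighting=tc.class_weighting,
        seed=cfg.seed,
    )
    return task, model_cfg, train_cfg


def _stage_train(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    train_rows = manifest[manifest["split"] == "train"]
    graphs = _load_graphs(work, train_rows["slide_id"])
    task, model_cfg, train_cfg = _train_configs(cfg, graphs[0].features.shape[1])
    labels = [training.map_label(s, task) for s in train_rows["subtype"]]
    results, assignment = training.cross_validate(
        graphs, labels, list(train_rows["case_id"]), model_cfg, train_cfg)
    models_dir = work / "models"
    models_dir.mkdir(exist_ok=True)
    for fold, res in enumerate(results):
        save_checkpoint(res.model, models_dir / f"fold{fold}.npz", seed=cfg.seed,
                        extra={"fold": fold, "task": task.task})
    (models_dir / "folds.json").write_text(json.dumps(assignment.fold_of, indent=2))
    (models_dir / "training_trace.json").write_text(json.dumps(
        {f"fold{f}": r.loss_trace for f, r in enumerate(results)}))
    return {"k_folds": train_cfg.k_folds,
            "final_losses": [r.loss_trace[-1] for r in results]}


def _load_fold_models(cfg: PipelineConfig, work: Path) -> list:
    models_dir = work / "models"
    models = []
    for fold in range(cfg.train.k_folds):
        models.append(load_checkpoint(_require(models_dir / f"fold{fold}.npz",
                                               "train")))
    return models


def _stage_predict(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    test_rows = manifest[manifest["split"] == "test"]
    graphs = _load_graphs(work, test_rows["slide_id"])
    models = _load_fold_models(cfg, work)
    task = training.TaskSpec.for_task(cfg.train.task)
    rows = []
    for graph in graphs:
        fold_preds = []
        for fold, model in enumerate(models):
            pred = model_forward(model, graph)
            fold_preds.append(pred)
            rows.append(_pred_row(graph.slide_id, task, pred, fold))
        final = training.ensemble_predict(fold_preds)
        mean_probs = np.mean([p.probabilities for p in fold_preds], axis=0)
        ens = Prediction(slide_id=graph.slide_id, probabilities=mean_probs,
                         predicted_class=final)
        rows.append(_pred_row(graph.slide_id, task, ens, "ensemble"))
    pd.DataFrame(rows).to_csv(work / "predictions.csv", index=False)
    return {"n_slides": len(graphs)}


def _pred_row(slide_id: str, task, pred: Prediction, fold) -> dict:
    row = {"slide_id": slide_id, "task": task.task, "fold": fold,
           "predicted_class": pred.predicted_class}
    for c, name in enumerate(task.class_names):
        row[f"p_{name}"] = pred.probabilities[c]
    return row


def _stage_evaluate(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    preds = pd.read_csv(_require(work / "predictions.csv", "predict"))
    task = training.TaskSpec.for_task(cfg.train.task)
    ens = preds[preds["fold"] == "ensemble"].set_index("slide_id")
    test_rows = manifest[manifest["split"] == "test"]
    truth = [training.map_label(s, task) for s in test_rows["subtype"]]
    prob_cols = [f"p_{n}" for n in task.class_names]
    predictions = [
        Prediction(slide_id=sid,
                   probabilities=ens.loc[sid, prob_cols].to_numpy(dtype=float),
                   predicted_class=int(ens.loc[sid, "predicted_class"]))
        for sid in test_rows["slide_id"]
    ]
    report = training.evaluate(predictions, truth, task)
    report.to_json(work / "report.json")
    pd.DataFrame(report.confusion,
                 index=task.class_names, columns=task.class_names
                 ).to_csv(work / "confusion.csv")
    return {"accuracy": report.accuracy}


def _stage_explain(cfg: PipelineConfig, work: Path) -> dict:
    manifest = _manifest(work)
    test_rows = manifest[manifest["split"] == "test"]
    model = _load_fold_models(cfg, work)[0]
    out = work / "heatmaps"
    out.mkdir(exist_ok=True)
    n = 0
    for _, row in test_rows.iterrows():
        graph = _load_graphs(work, [row["slide_id"]])[0]
        relmap = explain_mod.graphcam(model, graph)
        relmap.to_json(out / f"{row['slide_id']}_scores.json")
        slide_img = np.asarray(Image.open(row["path"]).convert("RGB"))
        scale = cfg.explain.thumbnail_scale
        dims = (max(1, int(slide_img.shape[0] * scale)),
                max(1, int(slide_img.shape[1] * scale)))
        overlay = explain_mod.render_heatmap(
            relmap, graph.grid_coords, slide_img, cfg.tiling.patch_px,
            out_dims=dims, colormap=cfg.explain.colormap, alpha=cfg.explain.alpha)
        Image.fromarray(overlay).save(out / f"{row['slide_id']}.png")
        n += 1
    return {"n_heatmaps": n}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "tile": _stage_tile,
    "pretrain": _stage_pretrain,
    "featurize": _stage_featurize,
    "graph": _stage_graph,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "explain": _stage_explain,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Run one pipeline stage; returns a small summary dict (also logged)."""
    if stage not in _STAGE_FNS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary = _STAGE_FNS[stage](cfg, work)
    _log(work, stage, cfg, t0, **summary)
    return summary


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> dict:
    """Run the stages in order; returns {stage: summary}."""
    return {stage: run_stage(stage, cfg) for stage in stages}
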