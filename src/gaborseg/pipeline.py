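"""End-to-end orchestration: simulate → features → train → segment → evaluate.

A :class:`RunConfig` gathers every knob of the other modules (with their
defaults unchanged) plus experiment-level choices: how many phantoms, how
many pixels to sample per class, which classifier, and how the operating
threshold is chosen (fixed 0.5 or the validation-ROC point maximizing
Youden's J). :func:`run_experiment` executes the whole flow reproducibly
from (config, seed) and emits a JSON report, a plain-text metrics table,
the ROC points as CSV, and optional per-image segmentations.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import features as feat
from . import io as gio
from .classifiers import (predict_proba, classify, train_qg, train_knn,
                          train_mlp, select_architecture)
from .dataset import LabeledDataset, sample_pixels, split_dataset, DEFAULT_RATIOS
from .evaluation import confusion, metrics, roc, youden_threshold, format_report_table
from .features import FeatureLayout, assemble_features, standardize
from .gabor import GaborParams, extract_working_channel, filter_bank_response
from .phantom import PhantomConfig, generate_benchmark_set

__all__ = ["RunConfig", "segment_image", "run_experiment", "image_features"]


@dataclass
class RunConfig:
    """Everything a run needs; serializes losslessly to/from JSON."""

    gabor: GaborParams = field(default_factory=GaborParams)
    layout: FeatureLayout = field(default_factory=FeatureLayout)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    channel: str = "inverted-green"
    n_images: int = 20
    n_vessel: int = 12500
    n_nonvessel: int = 12540
    ratios: tuple[float, float, float] = DEFAULT_RATIOS
    classifier: str = "mlp"            # qg | knn | mlp | all
    k: int = 5
    hidden: int | None = None          # None → select over hidden_grid
    hidden_grid: tuple[int, ...] = tuple(range(2, 21))
    learning_rate: float = 0.05
    max_epochs: int = 300
    patience: int = 15
    batch_size: int = 128
    threshold: float = 0.5
    threshold_policy: str = "fixed"    # fixed | youden
    seed: int = 0
    drive_dir: str | None = None
    out_dir: str | None = None
    tile_px: int = 65536
    fov_policy: str = "exclude"        # exclude | include non-FOV pixels in metrics
    segment_images: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["gabor"] = GaborParams(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d["gabor"].items()})
        d["layout"] = FeatureLayout(**d["layout"])
        ph = d["phantom"]
        ph["width_range"] = tuple(ph["width_range"])
        d["phantom"] = PhantomConfig(**ph)
        d["ratios"] = tuple(d["ratios"])
        d["hidden_grid"] = tuple(d["hidden_grid"])
        return cls(**d)


def _log(msg: str, t0: float | None = None) -> float:
    now = time.time()
    if t0 is not None:
        print(f"[gaborseg] {msg} ({now - t0:.1f} s)", file=sys.stderr)
    else:
        print(f"[gaborseg] {msg}", file=sys.stderr)
    return now


def image_features(img: gio.FundusImage, cfg: RunConfig):
    """Response stack and Luv map for one image (the per-image heavy step)."""
    channel = extract_working_channel(img, cfg.channel)
    stack = filter_bank_response(channel, cfg.gabor)
    luv = feat.rgb_to_luv(img)
    return stack, luv


def segment_image(img: gio.FundusImage, model, cfg: RunConfig,
                  precomputed=None) -> tuple[np.ndarray, np.ndarray]:
    """Score every field-of-view pixel and threshold to a binary vessel map.

    Features are assembled in tiles of ``cfg.tile_px`` pixels to bound
    memory; the result is tile-size-invariant. Non-FOV pixels score 0 and
    are labeled background.
    """
    if model.standardization is None:
        raise ValueError("model carries no standardization stats; train via the "
                         "pipeline or attach (mean, sd) first")
    if len(model.standardization[0]) != cfg.layout.dim:
        raise ValueError(
            f"model dimensionality {len(model.standardization[0])} does not match "
            f"feature layout dimensionality {cfg.layout.dim}"
        )
    stack, luv = precomputed if precomputed is not None else image_features(img, cfg)
    h, w = img.shape
    scores = np.zeros((h, w))
    pix = np.argwhere(img.fov_mask)
    for start in range(0, pix.shape[0], max(cfg.tile_px, 1)):
        tile = pix[start:start + max(cfg.tile_px, 1)]
        fm = assemble_features(stack, luv, tile, cfg.layout, image_id=img.id)
        fm, _ = standardize(fm, model.standardization)
        scores[tile[:, 0], tile[:, 1]] = predict_proba(model, fm.features)
    mask = classify(scores, cfg.threshold)
    mask &= img.fov_mask
    return scores, mask


def _build_dataset(samples, cfg: RunConfig) -> LabeledDataset:
    """Sample balanced pixels across images and assemble their features."""
    images = [(s.image, s.truth) for s in samples]
    rows = sample_pixels(images, cfg.n_vessel, cfg.n_nonvessel, seed=cfg.seed + 1)
    by_image: dict[str, list] = {}
    for image_id, r, c, label in rows:
        by_image.setdefault(image_id, []).append((r, c, label))
    mats, labels = [], []
    id_map = {s.image.id: s for s in samples}
    cache = {}
    for image_id in sorted(by_image):
        s = id_map[image_id]
        if image_id not in cache:
            cache[image_id] = image_features(s.image, cfg)
        stack, luv = cache[image_id]
        pts = np.array([(r, c) for r, c, _ in by_image[image_id]])
        mats.append(assemble_features(stack, luv, pts, cfg.layout, image_id=image_id))
        labels.extend(l for _, _, l in by_image[image_id])
    fm = feat.concat(mats)
    return LabeledDataset(features=fm, labels=np.array(labels), seed=cfg.seed)


def _train_one(name: str, train: LabeledDataset, val: LabeledDataset, cfg: RunConfig):
    if name == "qg":
        return train_qg(train)
    if name == "knn":
        return train_knn(train, k=cfg.k)
    if name == "mlp":
        kwargs = dict(learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
                      patience=cfg.patience, batch_size=cfg.batch_size)
        if cfg.hidden is not None:
            return train_mlp(train, val, hidden=cfg.hidden, seed=cfg.seed + 3, **kwargs)
        return select_architecture(train, val, h_grid=cfg.hidden_grid,
                                   seed=cfg.seed + 3, **kwargs)
    raise ValueError(f"unknown classifier {name!r}; expected qg, knn, mlp or all")


def _classifier_label(name: str, model, cfg: RunConfig) -> str:
    if name == "knn":
        return f"KNN (K={cfg.k})"
    if name == "qg":
        return "QG"
    return f"NN (H={model.hidden})"


def _load_drive(cfg: RunConfig):
    """Read a DRIVE-style directory as (image, truth) sample objects."""
    from .phantom import PhantomSample

    pairs = gio.walk_drive_layout(cfg.drive_dir)
    if not pairs:
        raise FileNotFoundError(f"no image/truth pairs found under {cfg.drive_dir}")
    samples = []
    for p in pairs:
        img = gio.read_image(p.image_path, fov_path=p.fov_path)
        truth = gio.read_mask(p.truth_path, shape=img.shape)
        samples.append(PhantomSample(image=img, truth=truth, config=cfg.phantom))
    return samples


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report.

    Stages: simulate (or load ``cfg.drive_dir``) → balanced pixel sampling →
    65:10:25 stratified split → z-scoring on train statistics → training
    (with hidden-layer selection when ``cfg.hidden`` is None) → threshold
    selection → test-partition evaluation. Fully reproducible from
    (config, seed); identical configs give byte-identical report JSON.
    """
    t0 = time.time()
    stage = "simulate"
    try:
        if cfg.drive_dir:
            samples = _load_drive(cfg)
        else:
            samples = generate_benchmark_set(cfg.n_images, cfg.phantom, seed=cfg.seed)
        t = _log(f"stage {stage}: {len(samples)} images", t0)

        stage = "features"
        ds = _build_dataset(samples, cfg)
        t = _log(f"stage {stage}: {ds.n} labeled pixels", t)

        stage = "split"
        ds = split_dataset(ds, ratios=cfg.ratios, seed=cfg.seed + 2)
        train, val, test = (ds.partition(p) for p in ("train", "val", "test"))
        train.features, stats = standardize(train.features, "fit")
        val.features, _ = standardize(val.features, stats)
        test.features, _ = standardize(test.features, stats)
        t = _log(f"stage {stage}: train {train.n} / val {val.n} / test {test.n}", t)

        names = ["knn", "qg", "mlp"] if cfg.classifier == "all" else [cfg.classifier]
        table_rows, report_rows, models = {}, {}, {}
        for name in names:
            stage = f"train[{name}]"
            model = _train_one(name, train, val, cfg)
            models[name] = model
            t = _log(f"stage {stage} done", t)

            stage = f"evaluate[{name}]"
            val_scores = predict_proba(model, val.features.features)
            if cfg.threshold_policy == "youden":
                thr = youden_threshold(roc(val_scores, val.labels))
            else:
                thr = cfg.threshold
            test_scores = predict_proba(model, test.features.features)
            curve = roc(test_scores, test.labels)
            cm = confusion(classify(test_scores, thr), test.labels)
            sens, spec, acc = metrics(cm)
            label = _classifier_label(name, model, cfg)
            table_rows[label] = (sens, spec, acc)
            report_rows[name] = {
                "label": label,
                "threshold": float(thr),
                "sensitivity": sens, "specificity": spec, "accuracy": acc,
                "az": curve.az,
                "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            }
            if name == "mlp":
                report_rows[name]["hidden"] = model.hidden
                report_rows[name]["best_val_error"] = model.record.best_val_error
            t = _log(f"stage {stage}: Az={curve.az:.4f} sens={sens:.3f} "
                     f"spec={spec:.3f} acc={acc:.3f} @thr={thr:.3f}", t)

        report = {
            "config": json.loads(cfg.to_json()),
            "n_images": len(samples),
            "partitions": {"train": train.n, "val": val.n, "test": test.n},
            "classifiers": report_rows,
        }

        if cfg.out_dir:
            stage = "write"
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            (out / "report.txt").write_text(format_report_table(table_rows) + "\n")
            main_name = names[-1]
            main_scores = predict_proba(models[main_name], test.features.features)
            curve = roc(main_scores, test.labels)
            import pandas as pd
            pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr,
                          "tpr": curve.tpr}).to_csv(out / "roc.csv", index=False)
            gio.save_model(models[main_name], out / f"model_{main_name}.json")
            if cfg.segment_images:
                seg_cfg = dataclasses.replace(
                    cfg, threshold=report_rows[main_name]["threshold"])
                seg_dir = out / "segmentations"
                seg_dir.mkdir(exist_ok=True)
                for s in samples:
                    _, mask = segment_image(s.image, models[main_name], seg_cfg)
                    gio.write_mask(mask, seg_dir / f"{s.image.id}.png")
            _log("stage write done", t)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
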