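"""End-to-end orchestration: fixtures (or ingested images) -> test
hold-out -> 21x augmentation -> optional per-class GAN -> filtration ->
train/val split -> classifier training -> evaluation.

A single global seed fans out to per-stage seeds (stable hash of the stage
name), so any stage can be rerun independently and deterministically.  The
``dry_run`` mode runs the full bookkeeping — every manifest record, every
count — without touching a single pixel, which makes the 70,400-image
partition arithmetic instant.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augmentation, data_manager, dcgan, evaluate, filter_bank, fixtures
from .classifier import (ClassifierSpec, TrainConfig, load_dataset_arrays,
                         train_classifier)
from .manifest import DatasetManifest


@dataclass
class PipelineConfig:
    out_root: str = "runs/demo"
    data_root: str | None = None          # ingest real data instead of fixtures
    n_classes: int = 8
    n_per_class: int = 50
    image_size: int = 32
    test_fraction: float = 0.2
    train_fraction: float = 0.8
    gan_per_class: int = 0                # synthetic GAN images added per class
    gan_epochs: int = 2
    gray_mode: str = "paper"
    rendering: str = "ckpf"               # classifier input rendering
    classifier: dict = field(default_factory=lambda: {
        "atrous_channels": 32, "use_pre_context": True,
        "use_post_context": True})
    epochs: int = 8
    batch_size: int = 64
    lr: float = 3e-3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage derived seed: stable, independent across stages, < 2^31."""
    return (global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def validate_config(config: PipelineConfig, policy=None) -> list[str]:
    issues = []
    if not 0 <= config.test_fraction < 1:
        issues.append(f"test_fraction {config.test_fraction} outside [0, 1)")
    if not 0 < config.train_fraction <= 1:
        issues.append(f"train_fraction {config.train_fraction} outside (0, 1]")
    s = config.image_size
    if s < 8 or (s & (s - 1)) != 0:
        issues.append(f"image_size {s} is not a power of two >= 8")
    if config.n_classes < 1:
        issues.append("n_classes must be >= 1")
    if config.n_per_class < 0:
        issues.append("n_per_class must be >= 0")
    if config.data_root is not None and not Path(config.data_root).is_dir():
        issues.append(f"data_root {config.data_root} not found")
    if config.rendering not in ("ckpf", "sobel", "canny", "kernel", "gray",
                                "raw", "stacked"):
        issues.append(f"unknown rendering {config.rendering!r}")
    if config.gray_mode not in ("paper", "standard"):
        issues.append(f"unknown gray_mode {config.gray_mode!r}")
    if policy is not None and len(policy) != 21:
        issues.append(f"augmentation policy has {len(policy)} transforms, not 21")
    return issues


def ingest_directory(data_root: Path | str) -> DatasetManifest:
    """Build a manifest from a directory of per-class image folders."""
    from .manifest import LabeledImage
    data_root = Path(data_root)
    classes = sorted(p.name for p in data_root.iterdir() if p.is_dir())
    manifest = DatasetManifest(tuple(classes))
    for cname in classes:
        for i, p in enumerate(sorted((data_root / cname).glob("*"))):
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
                manifest.add(LabeledImage(id=f"{cname}_{i:05d}", path=str(p),
                                          class_label=cname))
    return manifest


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the full pipeline; returns the summary dict (also written
    to ``<out_root>/summary.json``).  Any stage failure aborts with the
    stage name; completed stages' outputs are preserved on disk."""
    out_root = Path(config.out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    summary: dict = {"seed": config.seed, "dry_run": dry_run, "stages": {}}
    log_path = out_root / "pipeline.log"

    def log(stage, t0, **counts):
        line = (f"stage={stage} seed={stage_seed(config.seed, stage)} "
                f"elapsed={time.perf_counter() - t0:.2f}s "
                + " ".join(f"{k}={v}" for k, v in counts.items()))
        with open(log_path, "a") as fh:
            fh.write(line + "\n")
        summary["stages"][stage] = counts

    stage = "fixtures"
    try:
        t0 = time.perf_counter()
        if config.data_root:
            manifest = ingest_directory(config.data_root)
        else:
            spec = fixtures.FixtureSpec(
                config.n_classes, config.n_per_class, config.image_size,
                seed=stage_seed(config.seed, stage))
            manifest = fixtures.generate_fixture_dataset(
                spec, out_root / "fixtures", write_images=not dry_run)
        log(stage, t0, images=len(manifest))

        stage = "holdout"
        t0 = time.perf_counter()
        manifest = data_manager.holdout_test(
            manifest, config.test_fraction, stage_seed(config.seed, stage))
        s = data_manager.split_summary(manifest)
        log(stage, t0, test=s["test"], pool=s["pool"])

        stage = "augment"
        t0 = time.perf_counter()
        manifest = augmentation.augment_pool(
            manifest, augmentation.default_policy(), out_root / "augmented",
            write_images=not dry_run)
        s = data_manager.split_summary(manifest)
        log(stage, t0, augmented=s["augmented"], total=s["total"])

        if config.gan_per_class > 0 and not dry_run:
            stage = "gan"
            t0 = time.perf_counter()
            gspec = dcgan.GanSpec(image_size=max(32, config.image_size),
                                  epochs=config.gan_epochs, batch_size=32)
            n_gan = 0
            for cname in manifest.class_names:
                ckpt, _ = dcgan.train_dcgan(
                    manifest, cname, gspec, out_root / "gan",
                    seed=stage_seed(config.seed, f"gan_{cname}"))
                recs = dcgan.generate_labeled(
                    ckpt, config.gan_per_class,
                    stage_seed(config.seed, f"gan_sample_{cname}"),
                    out_root / "gan_images")
                manifest.extend(recs)
                n_gan += len(recs)
            log(stage, t0, gan_images=n_gan)

        stage = "split"
        t0 = time.perf_counter()
        manifest = data_manager.train_val_split(
            manifest, config.train_fraction, stage_seed(config.seed, stage))
        s = data_manager.split_summary(manifest)
        log(stage, t0, train=s["train"], val=s["val"])

        stage = "isolation"
        report = data_manager.verify_isolation(manifest)
        if not report.passed:
            raise RuntimeError(f"leakage: {report.violations[:5]}")
        summary["stages"]["isolation"] = {"violations": 0}

        if dry_run:
            summary["counts"] = s
            manifest.save(out_root / "manifest")
            (out_root / "summary.json").write_text(
                json.dumps(summary, indent=1))
            return summary

        stage = "filtration"
        t0 = time.perf_counter()
        if config.rendering == "stacked":
            renderings = ("sobel", "canny", "ckpf", "kernel")
        elif config.rendering == "raw":
            renderings = ("gray",)
        else:
            renderings = (config.rendering,)
        fconfig = filter_bank.FilterConfig(
            gray_mode=config.gray_mode, renderings=renderings)
        manifest = filter_bank.run_filtration(
            manifest, fconfig, out_root / "filtered")
        log(stage, t0, filtered=manifest.count(provenance="filtered"))

        stage = "train"
        t0 = time.perf_counter()
        rendering = None if config.rendering == "raw" else config.rendering
        x_tr, y_tr = _split_arrays(manifest, "train", rendering)
        x_val, y_val = _split_arrays(manifest, "val", rendering)
        in_ch = {None: 3, "stacked": 4}.get(rendering, 1)
        cspec = ClassifierSpec(
            in_channels=in_ch,
            n_classes=len(manifest.class_names), **config.classifier)
        result = train_classifier(
            x_tr, y_tr, cspec,
            TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                        lr=config.lr, seed=stage_seed(config.seed, stage)),
            x_val, y_val, out_dir=out_root / "classifier")
        log(stage, t0, train_images=len(x_tr), val_images=len(x_val),
            best_val_acc=round(result.best_val_acc, 4))

        stage = "evaluate"
        t0 = time.perf_counter()
        x_te, y_te = _split_arrays(manifest, "test", rendering)
        probs = _predict(result.model, x_te)
        y_pred = probs.argmax(axis=1)
        cm = evaluate.confusion(y_te, y_pred, len(manifest.class_names))
        report = evaluate.metrics_from_confusion(cm)
        failures = evaluate.failure_summary(cm, manifest.class_names)
        log(stage, t0, test_images=len(x_te),
            test_accuracy=round(report.accuracy / 100, 4))
        summary["counts"] = data_manager.split_summary(manifest)
        summary["metrics"] = {"test_accuracy_pct": report.accuracy,
                              "macro": report.macro}
        summary["confusion"] = cm.tolist()
        failures.to_csv(out_root / "failure_summary.csv", index=False)
        manifest.save(out_root / "manifest")
        (out_root / "summary.json").write_text(json.dumps(summary, indent=1,
                                                          default=str))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def run_ablation(variants, n_per_class: int = 16, image_size: int = 32,
                 epochs: int = 15, seed: int = 0):
    """Execute ablation variants on an in-memory fixture dataset.

    Supported toggles per variant: ``input`` (raw | ckpf), ``color``
    (rgb | grayscale, raw input only), ``pre_context`` / ``post_context``.
    Returns the ablation table (one row per variant with accuracy and
    macro metrics on a held-out fixture split).
    """
    from .filter_bank import FilterConfig, apply_filters
    from .fixtures import render_fixture_image

    rgb_imgs, labels = [], []
    for ci in range(8):
        for i in range(n_per_class):
            rng = np.random.default_rng([seed, ci, i])
            rgb_imgs.append(render_fixture_image(ci, image_size, rng))
            labels.append(ci)
    y = np.asarray(labels)
    cache: dict[str, np.ndarray] = {}

    def arrays(variant):
        key = f"{variant.get('input', 'ckpf')}_{variant.get('color', 'grayscale')}"
        if key not in cache:
            if variant.get("input", "ckpf") == "ckpf":
                fc = FilterConfig()
                cache[key] = np.stack(
                    [apply_filters(im, fc).ckpf[None] for im in rgb_imgs])
            elif variant.get("color", "grayscale") == "rgb":
                cache[key] = np.stack(
                    [im.transpose(2, 0, 1) / 255.0 for im in rgb_imgs])
            else:
                cache[key] = np.stack(
                    [im.mean(axis=2)[None] / 255.0 for im in rgb_imgs])
        return cache[key].astype(np.float32)

    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(y))
    n_hold = len(y) // 4
    hold, tr = order[:n_hold], order[n_hold:]

    def run_one(variant):
        x = arrays(variant)
        spec = ClassifierSpec(
            in_channels=x.shape[1], stem_channels=8, atrous_channels=16,
            use_pre_context=bool(variant.get("pre_context", False)),
            use_post_context=bool(variant.get("post_context", False)))
        res = train_classifier(
            x[tr], y[tr], spec,
            TrainConfig(epochs=epochs, batch_size=16, lr=1e-2, seed=seed))
        probs = _predict(res.model, x[hold])
        cm = evaluate.confusion(y[hold], probs.argmax(axis=1), 8)
        rep = evaluate.metrics_from_confusion(cm)
        return {"accuracy": rep.accuracy, "precision": rep.macro["precision"],
                "recall": rep.macro["recall"], "iou": rep.macro["iou"],
                "f_score": rep.macro["f1"]}

    return evaluate.ablation_grid(variants, run_one)


def _split_arrays(manifest, split, rendering):
    return load_dataset_arrays(manifest, split, rendering)


def _predict(model, x, batch: int = 256):
    from .nn.functional import softmax
    model.train(False)
    out = []
    for i in range(0, len(x), batch):
        out.append(softmax(model.forward(x[i:i + batch].astype(np.float32)),
                           axis=1))
    return (np.concatenate(out) if out
            else np.zeros((0, model.spec.n_classes)))
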