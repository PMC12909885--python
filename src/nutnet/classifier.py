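"""Atrous-context classifier: stem -> optional pre-context block ->
dilated 3x3 stack at rates (2, 4, 6) with additive fusion -> 1x1
projection -> optional post-context block -> global average pool ->
dropout -> dense softmax.

The dilated stack is *sequential* (rate 2 feeds rate 4 feeds rate 6, each
with same-padding equal to its rate and Swish activation) and the three
stage outputs are fused by element-wise addition before the 1x1
projection.  Its receptive field is 1 + sum(d * (k - 1)) = 25 pixels per
side for rates (2, 4, 6) with 3x3 kernels.  A parallel-branch fusion mode
is available for comparison.

Context blocks add a global-average-pooled, 1x1-convolved (no
nonlinearity) summary back onto the feature map, injecting image-level
information before and after the dilated stack; both are toggleable, which
yields the ablation variants (default atrous / +pre / +post / both).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .manifest import DatasetManifest


@dataclass(frozen=True)
class ClassifierSpec:
    in_channels: int = 1
    stem_channels: int = 32
    atrous_channels: int = 64
    dilation_rates: tuple[int, ...] = (2, 4, 6)
    dropout: float = 0.3
    weight_decay: float = 1e-5
    n_classes: int = 8
    use_pre_context: bool = True
    use_post_context: bool = True
    fusion: str = "sequential"          # or "parallel"

    def __post_init__(self):
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.fusion not in ("sequential", "parallel"):
            raise ValueError("fusion must be sequential|parallel")


def receptive_field(spec: ClassifierSpec, kernel: int = 3) -> int:
    """Receptive field of the dilated stack: 1 + sum(d_i * (k - 1))."""
    return 1 + sum(d * (kernel - 1) for d in spec.dilation_rates)


class AtrousStack(nn.Layer):
    """Sequential dilated convolutions with additive fusion of the stage
    outputs, then a 1x1 projection."""

    def __init__(self, in_ch: int, ch: int, rates, fusion: str,
                 rng: np.random.Generator):
        super().__init__()
        self.fusion = fusion
        self.convs = []
        self.acts = []
        prev = in_ch
        for d in rates:
            self.convs.append(nn.Conv2d(prev, ch, k=3, dilation=d, pad=d, rng=rng))
            self.acts.append(nn.Swish())
            prev = ch if fusion == "sequential" else in_ch
        self.proj = nn.Conv2d(ch, ch, k=1, rng=rng)

    # -- Sequential protocol: expose sublayers for parameter traversal
    def iter_sublayers(self):
        for c, a in zip(self.convs, self.acts):
            yield c
            yield a
        yield self.proj

    def forward(self, x):
        outs = []
        h = x
        for conv, act in zip(self.convs, self.acts):
            src = h if self.fusion == "sequential" else x
            h = act.forward(conv.forward(src))
            outs.append(h)
        fused = outs[0]
        for o in outs[1:]:
            fused = fused + o
        self._n_stages = len(outs)
        return self.proj.forward(fused)

    def backward(self, grad):
        gfused = self.proj.backward(grad)
        if self.fusion == "parallel":
            gx = 0.0
            for conv, act in zip(self.convs, self.acts):
                gx = gx + conv.backward(act.backward(gfused))
            return gx
        # sequential: each stage receives the fusion grad plus the grad
        # flowing back from the next stage's input
        gx = None
        carry = np.zeros_like(gfused)
        for i in reversed(range(self._n_stages)):
            g_stage = gfused + carry
            carry = self.convs[i].backward(self.acts[i].backward(g_stage))
        return carry

    def train(self, mode=True):
        self.training = mode
        for l in self.iter_sublayers():
            l.train(mode)

    def zero_grad(self):
        for l in self.iter_sublayers():
            l.zero_grad()


class _AtrousSeq(nn.Sequential):
    """Sequential that knows how to recurse into AtrousStack."""

    def iter_layers(self):
        for l in self.layers:
            if isinstance(l, AtrousStack):
                yield from l.iter_sublayers()
            elif isinstance(l, nn.Sequential):
                yield from l.iter_layers()
            else:
                yield l


def build_classifier(spec: ClassifierSpec, seed: int = 0,
                     image_size: int = 64) -> _AtrousSeq:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv2d(spec.in_channels, spec.stem_channels, k=3, stride=2,
                  pad=1, rng=rng),
        nn.InstanceNorm2d(spec.stem_channels),
        nn.ReLU(),
    ]
    if spec.use_pre_context:
        layers.append(nn.ContextBlock(spec.stem_channels, rng=rng))
    layers.append(AtrousStack(spec.stem_channels, spec.atrous_channels,
                              spec.dilation_rates, spec.fusion, rng))
    if spec.use_post_context:
        layers.append(nn.ContextBlock(spec.atrous_channels, rng=rng))
    layers += [
        nn.GlobalAvgPool(),
        nn.Dropout(spec.dropout, rng=np.random.default_rng(seed + 1)),
        nn.Dense(spec.atrous_channels, spec.n_classes, rng=rng),
    ]
    model = _AtrousSeq(*layers)
    model.spec = spec
    return model


# named stages for feature-map export
def _stage_slices(spec: ClassifierSpec) -> dict[str, int]:
    """Index (exclusive) of the last layer of each named stage in the
    flat layer list of build_classifier."""
    idx = {"stem": 3}
    n = 3
    if spec.use_pre_context:
        n += 1
        idx["pre_context"] = n
    n += 1
    idx["atrous"] = n
    if spec.use_post_context:
        n += 1
        idx["post_context"] = n
    return idx


def classifier_forward(images: np.ndarray, model: _AtrousSeq,
                       train: bool = False) -> np.ndarray:
    """Class probabilities, rows summing to 1."""
    model.train(train)
    logits = model.forward(images.astype(np.float32))
    return nn.functional.softmax(logits, axis=1)


def atrous_stack(fm: np.ndarray, spec: ClassifierSpec, seed: int = 0):
    """Standalone dilated-stack application (inspection/testing hook)."""
    stack = AtrousStack(fm.shape[1], spec.atrous_channels,
                        spec.dilation_rates, spec.fusion,
                        np.random.default_rng(seed))
    return stack.forward(fm.astype(np.float32))


def context_block(fm: np.ndarray, weight: np.ndarray | None = None,
                  bias: np.ndarray | None = None) -> np.ndarray:
    """Standalone context block; weight defaults to identity, bias to 0,
    so the output is input + its own per-channel spatial mean."""
    c = fm.shape[1]
    blk = nn.ContextBlock(c)
    blk.params["w"][...] = np.eye(c) if weight is None else weight
    blk.params["b"][...] = 0.0 if bias is None else bias
    return blk.forward(fm.astype(np.float32))


def count_parameters(spec: ClassifierSpec) -> int:
    return build_classifier(spec, seed=0).num_parameters()


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-4
    seed: int = 0
    verbose: bool = False


@dataclass
class TrainResult:
    model: _AtrousSeq
    history: dict
    best_val_acc: float


def _iterate_batches(n, batch, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch):
        yield order[i:i + batch]


def evaluate_accuracy(model, x, y, batch: int = 256) -> float:
    model.train(False)
    correct = 0
    for i in range(0, x.shape[0], batch):
        p = model.forward(x[i:i + batch].astype(np.float32))
        correct += int((p.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / max(1, x.shape[0])


def train_classifier(x_train: np.ndarray, y_train: np.ndarray,
                     spec: ClassifierSpec, cfg: TrainConfig,
                     x_val: np.ndarray | None = None,
                     y_val: np.ndarray | None = None,
                     out_dir: Path | str | None = None) -> TrainResult:
    """Cross-entropy training with AdamW (weight decay on conv/dense
    weights), cosine annealing over the full run, seeded end to end.

    Tracks per-epoch train/val loss and accuracy; if a validation set and
    ``out_dir`` are given, the best-validation-accuracy checkpoint is
    saved (with a JSON sidecar) and restored into the returned model.
    """
    model = build_classifier(spec, seed=cfg.seed)
    if cfg.epochs == 0:
        return TrainResult(model, {"train_loss": [], "train_acc": [],
                                   "val_loss": [], "val_acc": []}, 0.0)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.AdamW(model, lr=cfg.lr, betas=(0.9, 0.999),
                   weight_decay=spec.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(x_train.shape[0] / cfg.batch_size)))
    sched = nn.CosineAnnealing(opt, cfg.epochs * steps_per_epoch)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        model.train(True)
        losses, correct, seen = [], 0, 0
        for idx in _iterate_batches(x_train.shape[0], cfg.batch_size, rng):
            xb = x_train[idx].astype(np.float32)
            yb = y_train[idx]
            logits = model.forward(xb)
            loss, grad = nn.cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            sched.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += len(idx)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / seen)
        if x_val is not None and len(x_val):
            va = evaluate_accuracy(model, x_val, y_val)
            model.train(False)
            vl = []
            for i in range(0, x_val.shape[0], 256):
                logits = model.forward(x_val[i:i + 256].astype(np.float32))
                vl.append(nn.cross_entropy(logits, y_val[i:i + 256])[0])
            history["val_loss"].append(float(np.mean(vl)))
            history["val_acc"].append(va)
            if va > best_val:
                best_val = va
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if cfg.verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"train_loss={history['train_loss'][-1]:.4f} "
                  f"train_acc={history['train_acc'][-1]:.4f}"
                  + (f" val_acc={history['val_acc'][-1]:.4f}"
                     if history["val_acc"] else ""))
    if best_state is not None:
        model.load_state_arrays(best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nn.save_params(model, out_dir / "classifier.npz")
        sidecar = {"spec": spec.__dict__ | {"dilation_rates": list(spec.dilation_rates)},
                   "seed": cfg.seed, "epochs": cfg.epochs,
                   "best_val_acc": best_val, "history": history}
        (out_dir / "classifier.json").write_text(json.dumps(sidecar, indent=1))
    return TrainResult(model, history, max(best_val, 0.0))


def export_feature_maps(model: _AtrousSeq, image: np.ndarray,
                        stages, out_dir: Path | str) -> dict[str, np.ndarray]:
    """Channel-averaged, min-max-normalized activation maps per stage,
    written as PNGs.  ``image`` is (C, H, W)."""
    spec = model.spec
    valid = _stage_slices(spec)
    for s in stages:
        if s not in valid:
            raise ValueError(f"unknown stage {s!r} (have {sorted(valid)})")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.train(False)
    x = image[None].astype(np.float32)
    maps = {}
    for i, layer in enumerate(model.layers):
        x = layer.forward(x)
        for name, end in valid.items():
            if i == end - 1 and name in stages:
                m = x[0].mean(axis=0)
                lo, hi = m.min(), m.max()
                norm = (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)
                maps[name] = norm
                Image.fromarray((norm * 255).astype(np.uint8)).save(
                    out_dir / f"fmap_{name}.png")
    return maps


def load_dataset_arrays(manifest: DatasetManifest, split: str,
                        rendering: str | None = "ckpf",
                        image_size: int | None = None):
    """Assemble (x, y) arrays for one split.

    With ``rendering`` set, filtered records whose tag matches are used
    (single-channel input); ``rendering="stacked"`` stacks the sobel,
    canny, ckpf and kernel renderings into a 4-channel input; with
    ``rendering=None`` raw originals are used as RGB.  Labels are class
    indices in manifest order.
    """
    if rendering == "stacked":
        return _load_stacked(manifest, split, image_size)
    label_of = {c: i for i, c in enumerate(manifest.class_names)}
    xs, ys = [], []
    by_id = manifest.by_id()
    for rec in manifest.records:
        if rendering is not None:
            if rec.provenance != "filtered" or not rec.id.endswith(f"__{rendering}"):
                continue
            src = by_id.get(rec.source_id)
            if src is None or src.split != split:
                continue
            im = Image.open(rec.path).convert("L")
            if image_size:
                im = im.resize((image_size, image_size))
            xs.append(np.asarray(im, dtype=np.float32)[None] / 255.0)
        else:
            if rec.split != split or rec.provenance == "filtered":
                continue
            im = Image.open(rec.path).convert("RGB")
            if image_size:
                im = im.resize((image_size, image_size))
            xs.append(np.asarray(im, dtype=np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(label_of[rec.class_label])
    if not xs:
        return (np.zeros((0, 1, 1, 1), dtype=np.float32),
                np.zeros(0, dtype=np.int64))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


_STACK_ORDER = ("sobel", "canny", "ckpf", "kernel")


def _load_stacked(manifest: DatasetManifest, split: str,
                  image_size: int | None):
    """4-channel (sobel, canny, ckpf, kernel) arrays per source image."""
    label_of = {c: i for i, c in enumerate(manifest.class_names)}
    by_source: dict[str, dict[str, str]] = {}
    for rec in manifest.records:
        if rec.provenance != "filtered":
            continue
        tag = rec.id.rsplit("__", 1)[-1]
        if tag in _STACK_ORDER:
            by_source.setdefault(rec.source_id, {})[tag] = rec.path
    by_id = manifest.by_id()
    xs, ys = [], []
    for src_id, paths in sorted(by_source.items()):
        src = by_id.get(src_id)
        if src is None or src.split != split or len(paths) < len(_STACK_ORDER):
            continue
        chans = []
        for tag in _STACK_ORDER:
            im = Image.open(paths[tag]).convert("L")
            if image_size:
                im = im.resize((image_size, image_size))
            chans.append(np.asarray(im, dtype=np.float32) / 255.0)
        xs.append(np.stack(chans))
        ys.append(label_of[src.class_label])
    if not xs:
        return (np.zeros((0, 4, 1, 1), dtype=np.float32),
                np.zeros(0, dtype=np.int64))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)
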