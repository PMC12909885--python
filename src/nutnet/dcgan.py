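"""Per-class DCGAN: transposed-convolution generator (tanh output) and
strided-convolution discriminator (sigmoid output) trained adversarially
with BCE plus a feature-matching penalty on the generator.

One unconditional GAN is trained per class so its samples carry the class
label directly.  Training recipe: AdamW (generator lr 1e-4, discriminator
lr 5e-4, betas (0.5, 0.999)), cosine-annealed, He-normal initialization,
batch norm in both networks, alternating one discriminator and one
generator step per batch.  Only training-pool images of the class are ever
shown to the discriminator — never test images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .manifest import DatasetManifest, LabeledImage


@dataclass(frozen=True)
class GanSpec:
    latent_dim: int = 100
    image_size: int = 64
    channels: int = 3
    base_channels: int = 64
    lr_generator: float = 1e-4
    lr_discriminator: float = 5e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 64
    epochs: int = 300
    fm_weight: float = 1.0

    def __post_init__(self):
        s = self.image_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 16")

    @property
    def n_stages(self) -> int:
        """Up/down-sampling stages between 4x4 and image_size."""
        return int(np.log2(self.image_size)) - 2


def sample_latent(batch: int, spec: GanSpec, seed: int) -> np.ndarray:
    """(batch, latent_dim) i.i.d. standard-normal draws, seeded."""
    if batch < 1:
        raise ValueError("batch must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((batch, spec.latent_dim)).astype(np.float32)


class Generator(nn.Sequential):
    """z -> dense to 4x4 feature map -> stride-2 transposed-conv stages
    (batch norm + ReLU) -> tanh image in [-1, 1]."""

    def __init__(self, spec: GanSpec, rng: np.random.Generator):
        ch = spec.base_channels * 2 ** (spec.n_stages - 1)
        layers = [nn.Dense(spec.latent_dim, ch * 16, rng=rng),
                  _Reshape((ch, 4, 4)), nn.BatchNorm2d(ch), nn.ReLU()]
        for _ in range(spec.n_stages - 1):
            layers += [nn.ConvTranspose2d(ch, ch // 2, rng=rng),
                       nn.BatchNorm2d(ch // 2), nn.ReLU()]
            ch //= 2
        layers += [nn.ConvTranspose2d(ch, spec.channels, rng=rng), nn.Tanh()]
        super().__init__(*layers)
        self.spec = spec


class Discriminator(nn.Sequential):
    """Stride-2 conv stack (LeakyReLU 0.2, batch norm after the first
    stage) down to a 4x4 penultimate feature map, then dense + sigmoid."""

    def __init__(self, spec: GanSpec, rng: np.random.Generator):
        layers = []
        ch_in, ch = spec.channels, spec.base_channels
        for stage in range(spec.n_stages):
            layers.append(nn.Conv2d(ch_in, ch, k=4, stride=2, pad=1, rng=rng))
            if stage > 0:
                layers.append(nn.BatchNorm2d(ch))
            layers.append(nn.LeakyReLU(0.2))
            ch_in, ch = ch, ch * 2
        self.feature_depth = len(layers)      # activations here are 4x4
        layers += [nn.Flatten(), nn.Dense(ch_in * 16, 1, rng=rng), nn.Sigmoid()]
        super().__init__(*layers)
        self.spec = spec

    def forward_with_features(self, x):
        feats = None
        for i, l in enumerate(self.layers):
            x = l.forward(x)
            if i == self.feature_depth - 1:
                feats = x
        return x[:, 0], feats

    def forward(self, x):
        scores, _ = self.forward_with_features(x)
        return scores


class _Reshape(nn.Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


def generator_forward(z: np.ndarray, gen: Generator,
                      train: bool = False) -> np.ndarray:
    gen.train(train)
    return gen.forward(z.astype(np.float32))


def discriminator_forward(images: np.ndarray, disc: Discriminator,
                          train: bool = False):
    disc.train(train)
    return disc.forward_with_features(images.astype(np.float32))


gan_loss = nn.gan_loss


@dataclass
class GanCheckpoint:
    spec: GanSpec
    class_label: str
    seed: int
    epoch: int
    generator: Generator
    discriminator: Discriminator

    def save(self, stem: Path | str):
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"g_{k}": v for k, v in self.generator.state_arrays().items()}
        arrays |= {f"d_{k}": v for k, v in self.discriminator.state_arrays().items()}
        np.savez(stem.with_suffix(".npz"), **arrays)
        sidecar = {"class_label": self.class_label, "seed": self.seed,
                   "epoch": self.epoch,
                   "spec": {k: getattr(self.spec, k) for k in
                            ("latent_dim", "image_size", "channels",
                             "base_channels", "batch_size", "epochs",
                             "fm_weight")}}
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem: Path | str) -> "GanCheckpoint":
        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        sc = dict(sidecar["spec"])
        sc["betas"] = (0.5, 0.999)
        spec = GanSpec(**sc)
        rng = np.random.default_rng(0)
        gen, disc = Generator(spec, rng), Discriminator(spec, rng)
        with np.load(stem.with_suffix(".npz")) as data:
            gen.load_state_arrays(
                {k[2:]: v for k, v in data.items() if k.startswith("g_")})
            disc.load_state_arrays(
                {k[2:]: v for k, v in data.items() if k.startswith("d_")})
        return cls(spec, sidecar["class_label"], sidecar["seed"],
                   sidecar["epoch"], gen, disc)


def _load_class_images(manifest: DatasetManifest, class_label: str,
                       size: int) -> np.ndarray:
    recs = [r for r in manifest.select(class_label=class_label)
            if r.split != "test" and r.provenance in ("original", "augmented")]
    if not recs:
        raise ValueError(f"class {class_label!r} absent from training pool")
    imgs = []
    for r in recs:
        im = Image.open(r.path).convert("RGB").resize((size, size))
        imgs.append(np.asarray(im, dtype=np.float32))
    x = np.stack(imgs) / 127.5 - 1.0            # [0,255] -> [-1,1]
    return x.transpose(0, 3, 1, 2)


def train_dcgan(manifest: DatasetManifest, class_label: str, spec: GanSpec,
                out_dir: Path | str, seed: int = 0, max_steps: int | None = None,
                images: np.ndarray | None = None) -> tuple[GanCheckpoint, dict]:
    """Train one class-conditional-by-construction DCGAN.

    ``images`` may be passed directly (NCHW in [-1,1]) to bypass disk I/O;
    otherwise non-test pool images of the class are loaded from the
    manifest.  Returns (checkpoint, history); history records per-step
    discriminator and generator losses.  ``epochs=0`` returns the
    initialized networks untouched.
    """
    out_dir = Path(out_dir)
    if images is None:
        images = _load_class_images(manifest, class_label, spec.image_size)
    if images.shape[0] < spec.batch_size:
        raise ValueError("need at least one full batch of images")
    rng = np.random.default_rng(seed)
    gen = Generator(spec, rng)
    disc = Discriminator(spec, rng)
    opt_g = nn.AdamW(gen, lr=spec.lr_generator, betas=spec.betas)
    opt_d = nn.AdamW(disc, lr=spec.lr_discriminator, betas=spec.betas)
    n_batches = max(1, images.shape[0] // spec.batch_size)
    total_steps = spec.epochs * n_batches if max_steps is None else max_steps
    sched_g = nn.CosineAnnealing(opt_g, total_steps)
    sched_d = nn.CosineAnnealing(opt_d, total_steps)
    history = {"loss_d": [], "loss_g": []}
    fixed_z = sample_latent(16, spec, seed + 1) if spec.epochs or max_steps else None

    step = 0
    epoch = 0
    while step < total_steps:
        order = rng.permutation(images.shape[0])
        for b in range(n_batches):
            if step >= total_steps:
                break
            real = images[order[b * spec.batch_size:(b + 1) * spec.batch_size]]
            nb = real.shape[0]
            z = rng.standard_normal((nb, spec.latent_dim)).astype(np.float32)

            # --- discriminator step
            gen.train(True), disc.train(True)
            fake = gen.forward(z)
            d_real, _ = disc.forward_with_features(real)
            ld_real, g_real = nn.bce(d_real, 1.0)
            disc.zero_grad()
            _backprop_scores(disc, g_real)
            d_fake, _ = disc.forward_with_features(fake)
            ld_fake, g_fake = nn.bce(d_fake, 0.0)
            _backprop_scores(disc, g_fake)
            opt_d.step()
            sched_d.step()

            # --- generator step (fresh graph through D)
            fake = gen.forward(z)
            _, real_feats = disc.forward_with_features(real)
            d_fake, fake_feats = disc.forward_with_features(fake)
            lg_adv, g_adv = nn.bce(d_fake, 1.0)
            fm_loss, g_fm = nn.feature_matching(real_feats, fake_feats)
            disc.zero_grad()
            grad_images = _backprop_through_disc(
                disc, g_adv, spec.fm_weight * g_fm)
            gen.zero_grad()
            gen.backward(grad_images)
            opt_g.step()
            sched_g.step()

            history["loss_d"].append(ld_real + ld_fake)
            history["loss_g"].append(lg_adv + spec.fm_weight * fm_loss)
            step += 1
        epoch += 1

    ckpt = GanCheckpoint(spec, class_label, seed, epoch, gen, disc)
    ckpt.save(out_dir / f"gan_{class_label}")
    if fixed_z is not None:
        grid = sample_grid(ckpt, fixed_z)
        Image.fromarray(grid).save(out_dir / f"gan_{class_label}_samples.png")
    return ckpt, history


def _backprop_scores(disc: Discriminator, grad_scores: np.ndarray):
    """Push d(loss)/d(score) back through the discriminator; grads
    accumulate in-place.  Returns grad wrt input images."""
    grad = grad_scores[:, None]
    for l in reversed(disc.layers):
        grad = l.backward(grad)
    return grad


def _backprop_through_disc(disc: Discriminator, grad_scores, grad_feats):
    """Backprop adversarial grad from the scores plus the feature-matching
    grad injected at the penultimate feature map; returns grad wrt images."""
    grad = grad_scores[:, None]
    for i in reversed(range(len(disc.layers))):
        grad = disc.layers[i].backward(grad)
        if i == disc.feature_depth:
            grad = grad + grad_feats
    return grad


def sample_grid(ckpt: GanCheckpoint, z: np.ndarray, ncol: int = 4) -> np.ndarray:
    ckpt.generator.train(False)
    imgs = ckpt.generator.forward(z.astype(np.float32))
    imgs = ((imgs + 1.0) * 127.5).clip(0, 255).astype(np.uint8)
    imgs = imgs.transpose(0, 2, 3, 1)
    n, h, w, c = imgs.shape
    nrow = int(np.ceil(n / ncol))
    grid = np.zeros((nrow * h, ncol * w, c), dtype=np.uint8)
    for i in range(n):
        r, cc = divmod(i, ncol)
        grid[r * h:(r + 1) * h, cc * w:(cc + 1) * w] = imgs[i]
    return grid.squeeze()


def generate_labeled(ckpt: GanCheckpoint, n: int, seed: int,
                     out_dir: Path | str) -> list[LabeledImage]:
    """Sample ``n`` images from a trained per-class generator and write
    them as PNGs with provenance ``gan``."""
    out_dir = Path(out_dir)
    records: list[LabeledImage] = []
    if n == 0:
        return records
    cls_dir = out_dir / ckpt.class_label
    cls_dir.mkdir(parents=True, exist_ok=True)
    z = sample_latent(n, ckpt.spec, seed)
    ckpt.generator.train(False)
    imgs = ckpt.generator.forward(z)
    imgs = ((imgs + 1.0) * 127.5).clip(0, 255).astype(np.uint8).transpose(0, 2, 3, 1)
    for i in range(n):
        gid = f"gan_{ckpt.class_label}_{seed}_{i:05d}"
        path = cls_dir / f"{gid}.png"
        Image.fromarray(imgs[i].squeeze()).save(path)
        records.append(LabeledImage(
            id=gid, path=str(path), class_label=ckpt.class_label,
            split="unassigned", provenance="gan", source_id=None))
    return records
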