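"""Deterministic synthetic image datasets and hand-checkable toy matrices.

Eight parametric shape/texture families stand in for the eight nut classes
(ellipse, ridged ellipse, hexagon, speckled blob, annulus, star, textured
rectangle, crescent).  The family is fixed per class index so repeated runs
and fold experiments see the same visual classes; per-image jitter
(position, scale +/-20%, brightness +/-0.1) is seeded per (dataset seed,
class, image index), which makes the generated pixel set a pure function of
the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import CLASS_NAMES, DatasetManifest, LabeledImage

# base (r, g, b) tint and background level per family, chosen well apart
_FAMILY_COLORS = [
    (0.85, 0.45, 0.20), (0.95, 0.85, 0.55), (0.55, 0.25, 0.10),
    (0.80, 0.65, 0.40), (0.60, 0.35, 0.30), (0.45, 0.75, 0.35),
    (0.90, 0.80, 0.70), (0.70, 0.55, 0.45),
]


@dataclass(frozen=True)
class FixtureSpec:
    n_classes: int = 8
    n_per_class: int = 500
    image_size: int = 64
    seed: int = 0
    color_mode: str = "rgb"

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        s = self.image_size
        if s < 8 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 8")
        if self.color_mode not in ("rgb", "grayscale"):
            raise ValueError("color_mode must be 'rgb' or 'grayscale'")


def _grid(size: int, cx: float, cy: float, scale: float, theta: float = 0.0):
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    x = (x - cx) / (scale * size / 2)
    y = (y - cy) / (scale * size / 2)
    if theta:
        c, s = np.cos(theta), np.sin(theta)
        x, y = c * x + s * y, -s * x + c * y
    return x, y


def _family_mask(family: int, size: int, rng: np.random.Generator):
    """Binary shape mask plus a texture field in [0,1] for one family."""
    cx = size / 2 + rng.uniform(-0.1, 0.1) * size
    cy = size / 2 + rng.uniform(-0.1, 0.1) * size
    scale = 0.72 * rng.uniform(0.8, 1.2)
    theta = rng.uniform(0, np.pi)
    x, y = _grid(size, cx, cy, scale, theta)
    r = np.hypot(x, y)
    texture = np.ones((size, size))
    if family == 0:                                    # smooth ellipse
        mask = (x ** 2 / 1.0 + y ** 2 / 0.45) <= 1.0
    elif family == 1:                                  # ridged ellipse
        mask = (x ** 2 / 1.0 + y ** 2 / 0.55) <= 1.0
        texture = 0.65 + 0.35 * np.cos(10 * np.pi * x) ** 2
    elif family == 2:                                  # hexagon
        ang = np.arctan2(y, x)
        rad = np.cos(np.pi / 6) / np.cos((ang % (np.pi / 3)) - np.pi / 6)
        mask = r <= 0.95 * rad
    elif family == 3:                                  # speckled blob
        mask = r <= 0.9
        texture = np.where(rng.random((size, size)) < 0.25, 0.35, 1.0)
    elif family == 4:                                  # annulus
        mask = (r <= 0.95) & (r >= 0.5)
    elif family == 5:                                  # 4-pointed star
        mask = (np.abs(x) ** 0.5 + np.abs(y) ** 0.5) <= 1.0
    elif family == 6:                                  # textured rectangle
        mask = (np.abs(x) <= 0.95) & (np.abs(y) <= 0.55)
        texture = 0.7 + 0.3 * (np.cos(8 * np.pi * x) * np.cos(8 * np.pi * y) > 0)
    else:                                              # crescent
        mask = (r <= 0.95) & (np.hypot(x - 0.45, y) >= 0.62)
    return mask, texture


def render_fixture_image(family: int, size: int, rng: np.random.Generator,
                         color_mode: str = "rgb") -> np.ndarray:
    """One uint8 image of the given family; all randomness comes from rng."""
    mask, texture = _family_mask(family % len(_FAMILY_COLORS), size, rng)
    color = np.array(_FAMILY_COLORS[family % len(_FAMILY_COLORS)])
    brightness = 1.0 + rng.uniform(-0.1, 0.1)
    background = 0.12 + 0.02 * (family % 4)
    img = np.full((size, size, 3), background)
    img += rng.normal(0.0, 0.015, size=(size, size, 3))
    fg = (color[None, None, :] * (texture * brightness)[:, :, None])
    img = np.where(mask[:, :, None], fg, img)
    img = np.clip(img, 0.0, 1.0)
    if color_mode == "grayscale":
        img = img.mean(axis=2, keepdims=True).repeat(3, axis=2)
    return (img * 255).round().astype(np.uint8)


def _image_rng(spec: FixtureSpec, class_idx: int, img_idx: int):
    return np.random.default_rng([spec.seed, class_idx, img_idx])


def fixture_class_names(n_classes: int) -> tuple[str, ...]:
    names = list(CLASS_NAMES)
    while len(names) < n_classes:
        names.append(f"class_{len(names)}")
    return tuple(names[:n_classes])


def generate_fixture_dataset(spec: FixtureSpec, out_dir: Path | str,
                             write_images: bool = True) -> DatasetManifest:
    """Write ``n_classes x n_per_class`` PNGs (one directory per class) and
    return the manifest.  With ``write_images=False`` only the bookkeeping
    records are produced (dry-run), at identical ids and paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = fixture_class_names(spec.n_classes)
    manifest = DatasetManifest(names)
    for ci, cname in enumerate(names):
        cls_dir = out_dir / cname
        if write_images:
            cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.n_per_class):
            path = cls_dir / f"{cname}_{i:05d}.png"
            if write_images:
                img = render_fixture_image(ci, spec.image_size,
                                           _image_rng(spec, ci, i),
                                           spec.color_mode)
                Image.fromarray(img).save(path)
            manifest.add(LabeledImage(
                id=f"{cname}_{i:05d}", path=str(path), class_label=cname))
    manifest.save(out_dir / "manifest")
    return manifest


def load_image(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


# --------------------------------------------------------------- toy matrices

TOY_KINDS = ("constant", "step_edge", "square", "l_shape")


def make_toy_matrix(kind: str, size: int = 9) -> np.ndarray:
    """Small hand-checkable intensity grids used as filter oracles.

    constant: all 0.5.  step_edge: vertical 0 -> 1 step (size 3 gives
    columns [0, 0, 1]).  square: odd-sided block of ones centered in zeros
    (size 7 gives a 3x3 block).  l_shape: an L-shaped region with six
    geometric corners.
    """
    if size > 9 or size < 3:
        raise ValueError("toy matrices are capped at 9x9")
    m = np.zeros((size, size))
    if kind == "constant":
        m[:] = 0.5
    elif kind == "step_edge":
        m[:, int(np.ceil(2 * size / 3)):] = 1.0
    elif kind == "square":
        side = size // 2
        if side % 2 == 0:
            side -= 1
        lo = (size - side) // 2
        m[lo:lo + side, lo:lo + side] = 1.0
    elif kind == "l_shape":
        t = max(2, size // 3)
        m[1:size - 1, 1:1 + t] = 1.0          # vertical bar
        m[size - 1 - t:size - 1, 1:size - 1] = 1.0  # horizontal bar
    else:
        raise ValueError(f"unknown toy matrix kind {kind!r}")
    return m
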