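"""Geometric augmentation: flips, rotations, and the 21-variant policy.

Every pool image yields exactly 21 augmented variants drawn from three
transform families — horizontal flip, vertical flip, rotation.  The default
policy takes the seven rotation angles 45..315 in 45-degree steps in three
flavours (plain, hflip-then-rotate, vflip-then-rotate), i.e. 3 x 7 = 21
non-identity transform specifications.

Conventions: 0-based row-major coordinates, origin top-left; positive
rotation is counter-clockwise.  Rotations by multiples of 90 degrees with
nearest interpolation are exact pixel permutations; other angles use
bilinear resampling with reflect padding at the source size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .manifest import DatasetManifest, LabeledImage


@dataclass(frozen=True)
class TransformSpec:
    family: str                      # hflip | vflip | rotate
    angle_deg: float | None = None   # rotation only
    compose_with: str | None = None  # optional flip applied before rotation

    def __post_init__(self):
        if self.family not in ("hflip", "vflip", "rotate"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "rotate":
            if not (self.angle_deg and 0 < self.angle_deg < 360):
                raise ValueError("rotation angle must be in (0, 360)")
        elif self.angle_deg is not None:
            raise ValueError("flips carry no angle")
        if self.compose_with not in (None, "hflip", "vflip"):
            raise ValueError("compose_with must be hflip/vflip")

    def label(self) -> str:
        if self.family != "rotate":
            return self.family
        prefix = f"{self.compose_with}_" if self.compose_with else ""
        return f"{prefix}rot{int(self.angle_deg):03d}"


@dataclass(frozen=True)
class AugmentationPolicy:
    transforms: tuple[TransformSpec, ...]

    def __post_init__(self):
        if len(set(self.transforms)) != len(self.transforms):
            raise ValueError("duplicate transforms in policy")

    def __len__(self):
        return len(self.transforms)


def apply_flip(image: np.ndarray, axis: str) -> np.ndarray:
    """horizontal = reverse column order; vertical = reverse row order."""
    if image.size == 0:
        raise ValueError("empty image")
    if axis == "horizontal":
        return image[:, ::-1].copy()
    if axis == "vertical":
        return image[::-1, :].copy()
    raise ValueError(f"unknown flip axis {axis!r}")


def apply_rotation(image: np.ndarray, angle_deg: float,
                   interpolation: str = "bilinear") -> np.ndarray:
    """Rotate counter-clockwise about the image center, output at source size."""
    if not 0 <= angle_deg < 360:
        raise ValueError("angle must be in [0, 360)")
    if angle_deg == 0:
        return image.copy()
    if angle_deg % 90 == 0 and interpolation == "nearest":
        return np.ascontiguousarray(np.rot90(image, int(angle_deg // 90)))
    order = 0 if interpolation == "nearest" else 1
    # scipy rotates CCW for positive angles in (row, col) axes order
    return ndimage.rotate(image, angle_deg, axes=(1, 0), reshape=False,
                          order=order, mode="reflect")


def apply_transform(image: np.ndarray, t: TransformSpec) -> np.ndarray:
    if t.family == "hflip":
        return apply_flip(image, "horizontal")
    if t.family == "vflip":
        return apply_flip(image, "vertical")
    out = image
    if t.compose_with == "hflip":
        out = apply_flip(out, "horizontal")
    elif t.compose_with == "vflip":
        out = apply_flip(out, "vertical")
    interp = "nearest" if t.angle_deg % 90 == 0 else "bilinear"
    return apply_rotation(out, t.angle_deg, interp)


def default_policy() -> AugmentationPolicy:
    """The canonical 21-transform policy: 7 angles x {plain, hflip, vflip}."""
    angles = (45, 90, 135, 180, 225, 270, 315)
    transforms = []
    for compose in (None, "hflip", "vflip"):
        for a in angles:
            transforms.append(TransformSpec("rotate", float(a), compose))
    return AugmentationPolicy(tuple(transforms))


def augment_pool(manifest: DatasetManifest, policy: AugmentationPolicy,
                 out_dir: Path | str, write_images: bool = True,
                 strict: bool = True) -> DatasetManifest:
    """Apply every policy transform to every pool image.

    Pool = originals not held out as test.  Augmented records get
    provenance ``augmented`` and carry their source id; class labels are
    inherited.  ``write_images=False`` produces records only (dry-run).
    """
    if strict and len(policy) != 21:
        raise ValueError(f"policy must have 21 transforms, got {len(policy)}")
    out_dir = Path(out_dir)
    out = manifest.copy()
    new_records = []
    for rec in manifest.records:
        if rec.provenance != "original" or rec.split == "test":
            continue
        src = None
        if write_images:
            src = np.asarray(Image.open(rec.path).convert("RGB"))
            cls_dir = out_dir / rec.class_label
            cls_dir.mkdir(parents=True, exist_ok=True)
        for t in policy.transforms:
            aug_id = f"{rec.id}__{t.label()}"
            path = out_dir / rec.class_label / f"{aug_id}.png"
            if write_images:
                arr = apply_transform(src, t)
                Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8)).save(path)
            new_records.append(LabeledImage(
                id=aug_id, path=str(path), class_label=rec.class_label,
                split="unassigned", provenance="augmented", source_id=rec.id))
    out.extend(new_records)
    return out


def policy_to_yaml(policy: AugmentationPolicy) -> str:
    import yaml
    return yaml.safe_dump([
        {"family": t.family, "angle_deg": t.angle_deg,
         "compose_with": t.compose_with}
        for t in policy.transforms])


def policy_from_yaml(text: str) -> AugmentationPolicy:
    import yaml
    entries = yaml.safe_load(text)
    return AugmentationPolicy(tuple(
        TransformSpec(e["family"], e.get("angle_deg"), e.get("compose_with"))
        for e in entries))
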