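"""Stratified split bookkeeping with strict test isolation.

The partition protocol: a stratified test fraction is held out from the
originals *before* any augmentation (those images are never augmented and
never seen by the GAN), the remainder forms the augmentation pool, and the
train/validation split is drawn *after* augmentation over pool + derived
images.  Per-class allocations use round-half-away-from-zero; at the
default 8x500 / 0.2 / 0.8 geometry all quotas are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .manifest import DatasetManifest


def round_half_away(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _stable_sorted(records):
    return sorted(records, key=lambda r: (r.path, r.id))


def holdout_test(manifest: DatasetManifest, test_fraction: float,
                 seed: int) -> DatasetManifest:
    """Mark a stratified, seeded test hold-out on an unsplit manifest.

    Returns a new manifest; per class, round(n * test_fraction) original
    records become ``test`` and the rest stay ``unassigned`` (the
    augmentation pool).
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    if any(r.split != "unassigned" for r in manifest.records):
        raise ValueError("manifest already has split assignments")
    out = manifest.copy()
    rng = np.random.default_rng(seed)
    for cname in out.class_names:
        recs = _stable_sorted(out.select(class_label=cname))
        n_test = round_half_away(len(recs) * test_fraction)
        order = rng.permutation(len(recs))
        for idx in order[:n_test]:
            recs[idx].split = "test"
    return out


def train_val_split(manifest: DatasetManifest, train_fraction: float,
                    seed: int, strict: bool = True) -> DatasetManifest:
    """Stratified train/val split over the pool plus derived images.

    Expects augmentation to have run already (strict mode errors if no
    augmented/gan records exist); test records are untouched.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    if any(r.split in ("train", "val") for r in manifest.records):
        raise ValueError("train/val already assigned")
    has_derived = any(r.provenance in ("augmented", "gan")
                      for r in manifest.records)
    if not has_derived:
        msg = "train_val_split called before augmentation"
        if strict:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
    out = manifest.copy()
    rng = np.random.default_rng(seed)
    for cname in out.class_names:
        recs = [r for r in _stable_sorted(out.select(class_label=cname))
                if r.split == "unassigned"]
        n_train = round_half_away(len(recs) * train_fraction)
        order = rng.permutation(len(recs))
        for pos, idx in enumerate(order):
            recs[idx].split = "train" if pos < n_train else "val"
    return out


@dataclass
class IsolationReport:
    passed: bool
    violations: list[str]

    def __bool__(self):
        return self.passed


def verify_isolation(manifest: DatasetManifest) -> IsolationReport:
    """Report-only leakage check; never mutates the manifest.

    Fails if any derived (augmented/gan) record traces back to a test
    image, if a test record is not an original, or if an id is duplicated.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for r in manifest.records:
        if r.id in seen:
            violations.append(f"duplicate id: {r.id}")
        seen.add(r.id)
    by_id = {}
    for r in manifest.records:
        by_id.setdefault(r.id, r)
    for r in manifest.records:
        if r.split == "test" and r.provenance in ("augmented", "gan"):
            violations.append(f"test record {r.id} has provenance {r.provenance}")
        if r.provenance in ("augmented", "gan") and r.source_id is not None:
            src = by_id.get(r.source_id)
            if src is not None and src.split == "test":
                violations.append(
                    f"derived record {r.id} sourced from test image {r.source_id}")
            if src is not None and src.class_label != r.class_label:
                violations.append(
                    f"derived record {r.id} label differs from source {r.source_id}")
    return IsolationReport(passed=not violations, violations=violations)


def split_summary(manifest: DatasetManifest) -> dict:
    """Counts used throughout reporting: totals per split and provenance."""
    base = [r for r in manifest.records if r.provenance != "filtered"]
    pool = sum(1 for r in base
               if r.provenance == "original" and r.split != "test")
    count = lambda **kw: sum(
        1 for r in base if all(getattr(r, k) == v for k, v in kw.items()))
    n_aug = count(provenance="augmented")
    n_gan = count(provenance="gan")
    # the "after augmentation" corpus is what train/val draw from: the
    # pool plus derived images, never the held-out test originals
    per_class_after = {
        c: sum(1 for r in base
               if r.class_label == c and r.split != "test")
        for c in manifest.class_names}
    return {
        "total": len(base),
        "test": count(split="test"),
        "pool": pool,
        "augmented": n_aug,
        "gan": n_gan,
        "after_augmentation": pool + n_aug + n_gan,
        "train": count(split="train"),
        "val": count(split="val"),
        "filtered": manifest.count(provenance="filtered"),
        "per_class_after_augmentation": per_class_after,
    }
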