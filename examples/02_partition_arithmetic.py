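"""The study's partition bookkeeping at full scale, without pixels.

20% of each class is held out for testing before any augmentation; the
remaining pool is expanded 21x by flips and rotations; the train/val
split (80/20) is drawn after augmentation.  A records-only (dry) run
makes the 70,400-image arithmetic instant.
"""

from nutnet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_root="runs/example_dryrun", n_classes=8,
                     n_per_class=500, image_size=64, seed=1)
counts = run_pipeline(cfg, dry_run=True)["counts"]

print(f"originals            {counts['total'] - counts['augmented']:>7,}")
print(f"test hold-out        {counts['test']:>7,}")
print(f"augmentation pool    {counts['pool']:>7,}")
print(f"augmented (21x pool) {counts['augmented']:>7,}")
print(f"after augmentation   {counts['after_augmentation']:>7,}")
print(f"train (80%)          {counts['train']:>7,}")
print(f"val (20%)            {counts['val']:>7,}")
print("The 800 test images never feed augmentation, GAN training or "
      "filter fitting — that is the leakage guarantee verify_isolation "
      "checks.")
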