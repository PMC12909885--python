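"""End-to-end demo: fixtures -> hold-out -> 21x augmentation ->
filtration (CKPF) -> train/val split -> classifier -> evaluation.

Uses a small geometry (8 classes x 20 images at 32x32, 8 epochs) so it
finishes in a few minutes on one CPU core; the acceptance smoke runs the
8x50 version.
"""

from nutnet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_root="runs/example_pipeline", n_per_class=20,
                     image_size=32, seed=1)
summary = run_pipeline(cfg)

c = summary["counts"]
print(f"test {c['test']} | pool {c['pool']} | augmented {c['augmented']} "
      f"(= 21 x pool) | train {c['train']} | val {c['val']}")
print(f"test accuracy: {summary['metrics']['test_accuracy_pct']:.1f}%")
print(f"macro F1:      {summary['metrics']['macro']['f1']:.1f}%")
print("Per-stage logs, the manifest, the confusion matrix and the "
      "failure table are under runs/example_pipeline/.")
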