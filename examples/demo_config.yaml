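# Demo pipeline configuration (desk scale).
# Annotations: [protocol] = value fixed by the study protocol the package
# implements; [chosen] = package default where the protocol is silent.
out_root: runs/demo            # [chosen]
n_classes: 8                   # [protocol] eight nut classes
n_per_class: 50                # [chosen] 500 at full scale
image_size: 32                 # [chosen] desk scale; 64/256 configurable
test_fraction: 0.2             # [protocol] 20% hold-out before augmentation
train_fraction: 0.8            # [protocol] 80/20 train/val after augmentation
gan_per_class: 0               # [chosen] GAN top-up size is unspecified
gan_epochs: 2                  # [chosen] 300 at full scale
gray_mode: paper               # [protocol] two-stage grayscale weighting
rendering: ckpf                # [chosen] best-performing single channel
classifier:
  atrous_channels: 32          # [chosen] 64 at full scale
  use_pre_context: true        # [protocol] pre-context block
  use_post_context: true       # [protocol] post-context block
epochs: 8                      # [chosen] demo budget
batch_size: 64                 # [protocol] batch size 64
lr: 3.0e-3                     # [chosen] 1e-4 at full scale (Adam-style)
seed: 1                        # [chosen]
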