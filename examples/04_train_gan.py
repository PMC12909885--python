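"""Train a tiny per-class DCGAN and watch the adversarial losses.

One unconditional GAN per class keeps the labels attached to the
synthetic images.  This demo trains on 64 copies of one fixture image for
100 steps — enough to see the generator loss fall.
"""

import numpy as np

from nutnet.dcgan import GanSpec, train_dcgan
from nutnet.fixtures import render_fixture_image

img = render_fixture_image(0, 32, np.random.default_rng([0, 0, 0]))
x = (img.astype(np.float32) / 127.5 - 1.0).transpose(2, 0, 1)
x = np.repeat(x[None], 64, axis=0)

spec = GanSpec(image_size=32, base_channels=16, batch_size=64, epochs=1)
ckpt, hist = train_dcgan(None, "brazil_nut", spec, "runs/example_gan",
                         seed=0, max_steps=100, images=x)

print("step   loss_D   loss_G  (loss_G includes the feature-matching term)")
for i in (0, 24, 49, 74, 99):
    print(f"{i + 1:4d}  {hist['loss_d'][i]:7.3f}  {hist['loss_g'][i]:7.3f}")
print("A falling generator loss means the samples drift toward the real "
      "image statistics; a sample grid PNG was written next to the "
      "checkpoint.")
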