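"""Run the feature-filter bank on one synthetic image.

Grayscale (two-stage weighting), Sobel magnitude, Canny edges, Harris
corner keypoints, the corner-key-point-featured (CKPF) rendering and the
kernel-isolated rendering.
"""

import numpy as np

from nutnet.filter_bank import FilterConfig, apply_filters
from nutnet.fixtures import render_fixture_image

rgb = render_fixture_image(2, 64, np.random.default_rng([0, 2, 0]))  # hexagon
fo = apply_filters(rgb, FilterConfig())

print(f"gray   range [{fo.gray.min():.3f}, {fo.gray.max():.3f}] "
      "(paper-mode white maps to 0.449, not 1.0)")
print(f"sobel  max-normalized, {np.count_nonzero(fo.sobel > 0.5)} strong-edge px")
print(f"canny  {int(fo.canny.sum())} edge pixels")
print(f"harris {len(fo.keypoints)} keypoints (row, col, response):")
for r, c, resp in fo.keypoints.points[:6]:
    print(f"   ({r:2d}, {c:2d})  {resp:.4g}")
print(f"ckpf   mean {fo.ckpf.mean():.3f} vs gray mean {fo.gray.mean():.3f} "
      "(background attenuated to 0.3x, corner disks boosted)")
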