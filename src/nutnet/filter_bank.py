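"""Feature-filter bank: grayscale composite, Sobel, Canny, Harris corner
keypoints, the corner-key-point-featured (CKPF) rendering, and kernel
isolation.

Grayscale has two modes.  ``paper`` applies a two-stage weighting — each
8-bit channel is first scaled by the classic luminance weights
(0.2989, 0.5870, 0.1140)/255 and the results are then recombined with
weights (0.3, 0.59, 0.11) — which maps pure white to ~0.4485 rather than
1.0.  ``standard`` is single-stage ITU-601 luminance.  The two must never
be mixed within a run; everything downstream consumes [0, 1] intensities
either way.

The corner detector is Harris (response R = det(M) - k trace(M)^2 on the
Gaussian-windowed structure tensor), thresholded relative to the maximum
response with 3x3 non-maximum suppression.  The CKPF image attenuates the
whole frame by ``alpha`` and restores/boosts small disks around each
keypoint in proportion to its normalized response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature as skfeature

from .manifest import DatasetManifest, LabeledImage

PAPER_WEIGHTS_STAGE1 = (0.2989, 0.5870, 0.1140)
PAPER_WEIGHTS_STAGE2 = (0.3, 0.59, 0.11)

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T

KERNELS = {
    "identity": np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=float),
    "laplacian_highboost": np.array(
        [[-1, -1, -1], [-1, 9, -1], [-1, -1, -1]], dtype=float),
    "sharpen": np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float),
}


@dataclass(frozen=True)
class HarrisParams:
    window_sigma: float = 1.0   # Gaussian structure-tensor window
    aperture_sigma: float = 0.0 # pre-smoothing before derivatives (0 = none)
    k: float = 0.04             # Harris sensitivity
    rel_thresh: float = 0.01    # threshold relative to max response


@dataclass
class KeypointSet:
    points: list[tuple[int, int, float]]   # (row, col, response)
    params: HarrisParams

    def __len__(self):
        return len(self.points)

    def coords(self):
        return [(r, c) for r, c, _ in self.points]


@dataclass
class FilterOutput:
    gray: np.ndarray
    sobel: np.ndarray
    canny: np.ndarray
    ckpf: np.ndarray
    kernel_isolated: np.ndarray
    keypoints: KeypointSet


@dataclass(frozen=True)
class FilterConfig:
    gray_mode: str = "paper"
    canny_low_rel: float = 0.1
    canny_high_rel: float = 0.3
    harris: HarrisParams = field(default_factory=HarrisParams)
    ckpf_alpha: float = 0.3
    ckpf_radius: int = 3
    ckpf_boost: float = 0.5
    kernel_name: str = "laplacian_highboost"
    renderings: tuple[str, ...] = ("gray", "sobel", "canny", "ckpf", "kernel")


def to_grayscale(rgb: np.ndarray, mode: str = "paper") -> np.ndarray:
    """8-bit HxWx3 -> [0,1] float grayscale (see module docstring)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected HxWx3 input")
    chans = rgb.astype(np.float64) / 255.0
    if mode == "paper":
        w = [a * b for a, b in zip(PAPER_WEIGHTS_STAGE1, PAPER_WEIGHTS_STAGE2)]
    elif mode == "standard":
        w = PAPER_WEIGHTS_STAGE1
    else:
        raise ValueError(f"unknown grayscale mode {mode!r}")
    gray = chans @ np.asarray(w)
    return np.clip(gray, 0.0, 1.0)


def sobel_magnitude(gray: np.ndarray, return_scale: bool = False):
    """sqrt(Gx^2 + Gy^2) with 3x3 Sobel kernels (cross-correlation),
    reflect borders; rescaled to [0,1] by the recorded max magnitude."""
    gray = np.asarray(gray, dtype=float)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.correlate(gray, SOBEL_X, mode="reflect")
    gy = ndimage.correlate(gray, SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    scale = mag.max()
    out = mag / scale if scale > 0 else mag
    return (out, scale) if return_scale else out


def sobel_gradients(gray: np.ndarray):
    gray = np.asarray(gray, dtype=float)
    gx = ndimage.correlate(gray, SOBEL_X, mode="reflect")
    gy = ndimage.correlate(gray, SOBEL_Y, mode="reflect")
    return gx, gy


def canny_edges(gray: np.ndarray, low_rel: float = 0.1,
                high_rel: float = 0.3) -> np.ndarray:
    """Standard Canny (Gaussian sigma=1, NMS, hysteresis); thresholds are
    fractions of the maximum gradient magnitude."""
    if not 0 < low_rel < high_rel <= 1:
        raise ValueError("need 0 < low_rel < high_rel <= 1")
    gray = np.asarray(gray, dtype=float)
    smoothed = ndimage.gaussian_filter(gray, 1.0)
    gmax = np.hypot(ndimage.sobel(smoothed, 0), ndimage.sobel(smoothed, 1)).max()
    if gmax == 0:
        return np.zeros(gray.shape, dtype=bool)
    return skfeature.canny(gray, sigma=1.0, low_threshold=low_rel * gmax,
                           high_threshold=high_rel * gmax, use_quantiles=False)


def harris_response(gray: np.ndarray, params: HarrisParams = HarrisParams()
                    ) -> np.ndarray:
    gray = np.asarray(gray, dtype=float)
    if params.aperture_sigma > 0:
        gray = ndimage.gaussian_filter(gray, params.aperture_sigma)
    ix, iy = sobel_gradients(gray)
    sxx = ndimage.gaussian_filter(ix * ix, params.window_sigma)
    syy = ndimage.gaussian_filter(iy * iy, params.window_sigma)
    sxy = ndimage.gaussian_filter(ix * iy, params.window_sigma)
    det = sxx * syy - sxy * sxy
    trace = sxx + syy
    return det - params.k * trace * trace


def detect_corners(gray: np.ndarray,
                   params: HarrisParams = HarrisParams()) -> KeypointSet:
    """Harris keypoints: response >= rel_thresh * max(R), 3x3 non-max
    suppression, positive responses only."""
    r = harris_response(gray, params)
    rmax = r.max()
    if rmax <= 0:
        return KeypointSet([], params)
    thresh = params.rel_thresh * rmax
    local_max = r == ndimage.maximum_filter(r, size=3, mode="constant",
                                            cval=-np.inf)
    rows, cols = np.nonzero((r >= thresh) & local_max)
    pts = sorted(((int(i), int(j), float(r[i, j])) for i, j in zip(rows, cols)),
                 key=lambda p: -p[2])
    return KeypointSet(pts, params)


def render_ckpf(gray: np.ndarray, keypoints: KeypointSet,
                alpha: float = 0.3, radius: int = 3,
                boost: float = 0.5) -> np.ndarray:
    """Attenuate-and-boost rendering: frame scaled by alpha, disks of
    ``radius`` px around each keypoint restored to full intensity and
    boosted by the normalized response."""
    gray = np.asarray(gray, dtype=float)
    out = alpha * gray
    if not keypoints.points:
        return np.clip(out, 0.0, 1.0)
    max_resp = max(p[2] for p in keypoints.points)
    yy, xx = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    for (r, c, resp) in keypoints.points:
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2
        rho = resp / max_resp if max_resp > 0 else 0.0
        out = np.where(disk, gray * (1.0 + boost * rho), out)
    return np.clip(out, 0.0, 1.0)


def kernel_isolate(gray: np.ndarray,
                   kernel_name: str = "laplacian_highboost") -> np.ndarray:
    """3x3 kernel convolution (reflect borders) clamped to [0,1]."""
    if kernel_name not in KERNELS:
        raise ValueError(f"unknown kernel {kernel_name!r}")
    gray = np.asarray(gray, dtype=float)
    out = ndimage.correlate(gray, KERNELS[kernel_name], mode="reflect")
    return np.clip(out, 0.0, 1.0)


def apply_filters(rgb: np.ndarray, config: FilterConfig = FilterConfig()
                  ) -> FilterOutput:
    gray = to_grayscale(rgb, config.gray_mode)
    kps = detect_corners(gray, config.harris)
    return FilterOutput(
        gray=gray,
        sobel=sobel_magnitude(gray),
        canny=canny_edges(gray, config.canny_low_rel, config.canny_high_rel),
        ckpf=render_ckpf(gray, kps, config.ckpf_alpha, config.ckpf_radius,
                         config.ckpf_boost),
        kernel_isolated=kernel_isolate(gray, config.kernel_name),
        keypoints=kps,
    )


_RENDER_ATTR = {"gray": "gray", "sobel": "sobel", "canny": "canny",
                "ckpf": "ckpf", "kernel": "kernel_isolated"}


def run_filtration(manifest: DatasetManifest, config: FilterConfig,
                   out_dir: Path | str) -> DatasetManifest:
    """Write the configured renderings per image and append ``filtered``
    records.  Per-file I/O errors are reported and skipped, the run
    continues."""
    out_dir = Path(out_dir)
    out = manifest.copy()
    new_records = []
    for rec in manifest.records:
        if rec.provenance == "filtered":
            continue
        try:
            rgb = np.asarray(Image.open(rec.path).convert("RGB"))
            fo = apply_filters(rgb, config)
        except OSError as exc:
            print(f"filtration: skipping {rec.path}: {exc}")
            continue
        cls_dir = out_dir / rec.class_label
        cls_dir.mkdir(parents=True, exist_ok=True)
        for name in config.renderings:
            arr = getattr(fo, _RENDER_ATTR[name]).astype(float)
            img = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
            fid = f"{rec.id}__{name}"
            path = cls_dir / f"{fid}.png"
            Image.fromarray(img).save(path)
            new_records.append(LabeledImage(
                id=fid, path=str(path), class_label=rec.class_label,
                split=rec.split, provenance="filtered", source_id=rec.id))
    out.extend(new_records)
    return out


def keypoints_to_csv(kps: KeypointSet, path: Path | str) -> None:
    import pandas as pd
    pd.DataFrame(kps.points, columns=["row", "col", "response"]).to_csv(
        path, index=False)
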