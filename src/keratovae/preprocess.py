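"""Image cleanup chain for topography maps.

Four stages mirror how raw topographer exports are prepared for modelling:

1. ``segment_cornea`` — an HSV saturation/value mask isolates the saturated
   color-coded disc from the near-gray background and annotation clutter;
   the largest connected component's bounding square is cropped.
2. ``remove_regular_noise`` — a 3x3 median filter removes impulse noise and a
   spectral notch suppresses the dominant periodic acquisition artifact.
3. ``ordered_grayscale`` — an order-preserving grayscale conversion: each
   pixel is assigned its nearest color-scale bin and the intensity is the
   normalized bin index, so sorting by intensity equals sorting by dioptric
   power (a plain luminance conversion would scramble this ordering).
4. ``prepare_input`` — model-specific resize and range normalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure, transform

from .synthmap import ColorScale

__all__ = [
    "CorneaImage",
    "GrayMap",
    "HsvConfig",
    "DenoiseConfig",
    "NoCorneaFound",
    "SegmentationAmbiguous",
    "segment_cornea",
    "remove_regular_noise",
    "ordered_grayscale",
    "grayscale_to_color",
    "prepare_input",
]

GRAY_SIZE = (104, 104)


class NoCorneaFound(ValueError):
    """No pixel passed the HSV mask."""


class SegmentationAmbiguous(ValueError):
    """The candidate component touches all four image borders."""


@dataclasses.dataclass(frozen=True)
class HsvConfig:
    s_min: float = 0.25
    v_min: float = 0.20


@dataclasses.dataclass
class CorneaImage:
    image: np.ndarray  # square RGB crop
    side: int
    source_bbox: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)


@dataclasses.dataclass
class GrayMap:
    """Order-preserving grayscale map; intensity = bin_index / (n_bins - 1)."""

    values: np.ndarray  # H x W float in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("grayscale values must lie in [0, 1]")


def segment_cornea(image: np.ndarray, hsv_cfg: HsvConfig | None = None) -> CorneaImage:
    """Crop the color-coded corneal disc via an HSV saturation mask.

    Thresholds saturation >= ``s_min`` and value >= ``v_min``, keeps the
    largest connected component and returns its bounding square (padded to
    square, clamped to the image).
    """
    cfg = hsv_cfg or HsvConfig()
    if image.ndim != 3 or image.shape[2] != 3 or min(image.shape[:2]) < 64:
        raise ValueError("expected an RGB image of at least 64 x 64")
    hsv = skcolor.rgb2hsv(image)
    mask = (hsv[..., 1] >= cfg.s_min) & (hsv[..., 2] >= cfg.v_min)
    if not mask.any():
        raise NoCorneaFound("no pixel passes the HSV mask")
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    comp = labels == largest
    ys, xs = np.nonzero(comp)
    h, w = mask.shape
    if ys.min() == 0 and xs.min() == 0 and ys.max() == h - 1 and xs.max() == w - 1:
        raise SegmentationAmbiguous("component touches all four borders")
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    x0, y0, x1, y1 = _pad_to_square(x0, y0, x1, y1, w, h)
    crop = image[y0:y1, x0:x1]
    return CorneaImage(image=crop, side=crop.shape[0], source_bbox=(x0, y0, x1, y1))


def _pad_to_square(x0: int, y0: int, x1: int, y1: int, w: int, h: int):
    bw, bh = x1 - x0, y1 - y0
    side = max(bw, bh)
    if bw < side:
        grow = side - bw
        x0 = max(0, x0 - grow // 2)
        x1 = min(w, x0 + side)
        x0 = max(0, x1 - side)
    if bh < side:
        grow = side - bh
        y0 = max(0, y0 - grow // 2)
        y1 = min(h, y0 + side)
        y0 = max(0, y1 - side)
    return x0, y0, x1, y1


@dataclasses.dataclass(frozen=True)
class DenoiseConfig:
    median_size: int = 3
    # a pixel is repaired by its 3x3 median only when it deviates from it
    # by more than this (impulses and line pixels do; map content does not)
    impulse_threshold: float = 25.0
    # notch an axis peak only when it exceeds this multiple of the median
    # magnitude along its axis (avoids eroding clean images)
    peak_ratio: float = 6.0
    notch_halfwidth: int = 1
    # protect everything slower than ~1/12 of the axis length: map content
    # lives at low frequency, grid-line artifacts (period <~ 12 px) above it
    dc_guard_frac: float = 1.0 / 12.0


def remove_regular_noise(image: np.ndarray, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Repair impulse pixels by a conditional median, then notch dominant
    periodic frequencies.

    The conditional median replaces a pixel with its 3x3 median only when it
    deviates from it by more than ``impulse_threshold`` — this removes
    salt-and-pepper impulses and most grid-line pixels while leaving intact
    content untouched (and is therefore nearly idempotent).  Axis-aligned
    grid lines concentrate their remaining spectral energy on the two
    frequency axes through DC, so the notch searches only there: per
    channel, any axis coefficient exceeding ``peak_ratio`` times the median
    magnitude of its axis (outside a DC guard band) is attenuated to that
    median, together with its conjugate.  Image content, whose energy is
    spread across the plane, is left untouched.
    """
    cfg = cfg or DenoiseConfig()
    img = np.asarray(image)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        chan = img[..., c].astype(float)
        # iterate the repair to its fixed point: a repaired pixel shifts its
        # neighbours' medians, so single-pass repair is not idempotent
        for _ in range(4):
            med = ndimage.median_filter(chan, size=cfg.median_size)
            bad = np.abs(chan - med) > cfg.impulse_threshold
            if not bad.any():
                break
            chan = np.where(bad, med, chan)
        out[..., c] = np.clip(_notch_channel(chan, cfg), 0, 255).astype(img.dtype)
    return out


def _notch_channel(chan: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    f = np.fft.fft2(chan)
    nh = cfg.notch_halfwidth
    for axis in (0, 1):
        n = f.shape[axis]
        g = max(3, int(round(n * cfg.dc_guard_frac)))
        line = np.abs(f[:, 0] if axis == 0 else f[0, :])
        baseline = np.median(line[g:n - g]) + 1e-12
        peaks = np.nonzero(line > cfg.peak_ratio * baseline)[0]
        for k in peaks:
            if k < g or k > n - g:  # DC guard (wrap-around aware)
                continue
            for kk in range(k - nh, k + nh + 1):
                kk %= n
                if axis == 0:
                    f[kk, 0] *= baseline / (abs(f[kk, 0]) + 1e-12)
                else:
                    f[0, kk] *= baseline / (abs(f[0, kk]) + 1e-12)
    return np.real(np.fft.ifft2(f))


def ordered_grayscale(image: np.ndarray, scale: ColorScale,
                      size: tuple[int, int] | None = GRAY_SIZE) -> GrayMap:
    """Convert an RGB map to grayscale while preserving the dioptric order.

    Each pixel is mapped to its nearest scale color (Euclidean in RGB) and
    then to the intensity ``bin_index / (n_bins - 1)``; the result is resized
    (area-averaging) to ``size``.  Background pixels follow the same
    nearest-color rule.
    """
    if scale.n_bins < 2:
        raise ValueError("scale must have at least 2 bins")
    rgb = np.asarray(image, dtype=float)
    colors = scale.colors.astype(float)  # (n_bins, 3)
    # nearest color without materializing an HxWxN distance cube per axis:
    # argmin over ||p||^2 - 2 p.c + ||c||^2
    flat = rgb.reshape(-1, 3)
    d = flat @ colors.T
    d = (colors ** 2).sum(axis=1)[None, :] - 2.0 * d
    bins = np.argmin(d, axis=1).reshape(rgb.shape[:2])
    values = bins.astype(float) / (scale.n_bins - 1)
    if size is not None and values.shape != tuple(size):
        values = transform.resize(values, size, order=1, anti_aliasing=True,
                                  preserve_range=True)
        values = np.clip(values, 0.0, 1.0)
    return GrayMap(values=values)


def grayscale_to_color(gray: np.ndarray | GrayMap, scale: ColorScale) -> np.ndarray:
    """Inverse of :func:`ordered_grayscale`: intensity -> bin -> scale color."""
    v = gray.values if isinstance(gray, GrayMap) else np.asarray(gray, dtype=float)
    if v.ndim == 3 and v.shape[-1] == 1:
        v = v[..., 0]
    bins = np.clip(np.round(v * (scale.n_bins - 1)).astype(int), 0, scale.n_bins - 1)
    return scale.colors[bins]


def prepare_input(image: np.ndarray, target: str,
                  size_override: int | None = None) -> np.ndarray:
    """Resize and range-normalize an image for a specific model family.

    - ``vae``: 104 x 104 x 1 in [0, 1]
    - ``custom_cnn``: 50 x 50 x 3 in [0, 1]
    - ``transfer``: backbone side (default 224) x 3 in [-1, 1]
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    if np.issubdtype(np.asarray(image).dtype, np.integer) or img.max() > 1.0:
        img = img / 255.0
    if target == "vae":
        side = size_override or 104
        if img.shape[2] != 1:
            img = img.mean(axis=2, keepdims=True)
        out = _resize(img, side)
    elif target == "custom_cnn":
        side = size_override or 50
        out = _resize(_to_rgb(img), side)
    elif target == "transfer":
        side = size_override or 224
        out = _resize(_to_rgb(img), side) * 2.0 - 1.0
    else:
        raise ValueError(f"unknown target {target!r}")
    return out.astype(np.float32)


def _to_rgb(img: np.ndarray) -> np.ndarray:
    return np.repeat(img, 3, axis=2) if img.shape[2] == 1 else img


def _resize(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape[0] == side and img.shape[1] == side:
        return img
    return transform.resize(img, (side, side, img.shape[2]), order=1,
                            anti_aliasing=img.shape[0] > side, preserve_range=True)
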