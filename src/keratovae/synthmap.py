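"""Parametric synthesis of color-coded corneal topography maps.

Clinical axial topography maps summarise corneal curvature (in diopters, D)
as a color-coded disc.  Normal corneas with regular astigmatism show a
symmetric "bowtie" (a cos 2θ modulation around the mean keratometry AveK);
keratoconic corneas additionally show a localized steepening ("cone"),
classically inferior, sometimes central, or an asymmetric bowtie with a
skewed radial axis (AB/SRAX).  This module generates such maps from a small
parametric model so that segmentation, grayscale conversion, generative
augmentation and classification can all be exercised and tested without
clinical images.

The curvature field is

    K(r, θ) = AveK + (Cyl/2)·cos 2(θ − axis) + A·exp(−d²/(2w²))

where ``A`` is the cone amplitude, ``d`` the distance to the cone center and
``w`` the cone width (both in fractions of the corneal radius).  AB/SRAX maps
use two cone lobes whose radial axes differ by a skew angle.

Coordinates follow image convention: pixel (0, 0) top-left, x rightward,
y downward, so "inferior" means larger y.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColorScale",
    "MapParams",
    "TopoMap",
    "NoiseConfig",
    "CanvasConfig",
    "default_color_scale",
    "sample_cohort",
    "curvature_field",
    "render_map",
    "add_acquisition_noise",
    "cohort_manifest",
]

NORMAL_PATTERN = "regular_astigmatism"
KCN_PATTERNS = ("inferior_cone", "central_cone", "ab_srax")
DEFAULT_KCN_MIX = {"inferior_cone": 0.6, "central_cone": 0.2, "ab_srax": 0.2}

# Table-style per-class index distributions (AveK / Cyl in diopters):
# keratoconus AveK 48.68 +/- 3.96, Cyl 4.64 +/- 2.53;
# normal AveK 44.15 +/- 1.57, Cyl 1.61 +/- 1.48.
CLASS_MOMENTS = {
    "kcn": {"ave_k": (48.68, 3.96), "cyl": (4.64, 2.53)},
    "normal": {"ave_k": (44.15, 1.57), "cyl": (1.61, 1.48)},
}
AVE_K_BOUNDS = (30.0, 70.0)


@dataclasses.dataclass(frozen=True)
class ColorScale:
    """Ordered dioptric color scale: stop *i* covers [threshold_i, threshold_{i+1})."""

    stops: tuple[tuple[float, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.stops]
        if len(thresholds) < 4:
            raise ValueError("color scale needs at least 4 stops")
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("power thresholds must be strictly increasing")
        colors = [c for _, c in self.stops]
        if len(set(colors)) != len(colors):
            raise ValueError("scale colors must be pairwise distinct")

    @property
    def n_bins(self) -> int:
        return len(self.stops)

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for t, _ in self.stops], dtype=float)

    @property
    def colors(self) -> np.ndarray:
        return np.array([c for _, c in self.stops], dtype=np.uint8)

    def bin_of(self, power: np.ndarray) -> np.ndarray:
        """Bin index per value; out-of-range powers clamp to the end bins."""
        idx = np.searchsorted(self.thresholds, np.asarray(power, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def default_color_scale(n_bins: int = 26, lo: float = 34.0, hi: float = 52.0) -> ColorScale:
    """Blue -> green -> yellow -> red progression mirroring clinical axial maps."""
    import colorsys

    thresholds = np.linspace(lo, hi, n_bins, endpoint=False)
    stops = []
    for i, t in enumerate(thresholds):
        # hue 2/3 (blue) down to 0 (red)
        h = (2.0 / 3.0) * (1.0 - i / (n_bins - 1))
        r, g, b = colorsys.hsv_to_rgb(h, 1.0, 1.0)
        stops.append((float(t), (round(r * 255), round(g * 255), round(b * 255))))
    return ColorScale(tuple(stops))


@dataclasses.dataclass(frozen=True)
class MapParams:
    """Ground-truth parameters of one simulated topography map."""

    pattern: str
    ave_k: float
    cyl: float
    axis: float
    cone_amplitude: float
    cone_center: tuple[float, float]
    cone_width: float
    label: str
    skew_angle: float = 0.0

    def __post_init__(self) -> None:
        if not (AVE_K_BOUNDS[0] <= self.ave_k <= AVE_K_BOUNDS[1]):
            raise ValueError(f"ave_k {self.ave_k} outside {AVE_K_BOUNDS}")
        if self.cyl < 0:
            raise ValueError("cyl must be >= 0")
        if self.cone_width <= 0:
            raise ValueError("cone_width must be > 0")
        if self.label == "normal":
            if self.pattern != NORMAL_PATTERN or self.cone_amplitude != 0:
                raise ValueError("normal maps are regular astigmatism with zero cone")
        elif self.label == "kcn":
            if self.pattern not in KCN_PATTERNS or self.cone_amplitude <= 0:
                raise ValueError("kcn maps need a cone pattern and positive amplitude")
        else:
            raise ValueError(f"unknown label {self.label!r}")


@dataclasses.dataclass
class TopoMap:
    """A rendered topography map with its generating field and provenance."""

    params: MapParams
    field: np.ndarray  # H x W float, NaN outside mask
    mask: np.ndarray  # H x W bool, inscribed circle
    image: np.ndarray  # H x W x 3 uint8
    origin: str = "original"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(n_normal: int, n_kcn: int, seed: int,
                  kcn_mix: dict[str, float] | None = None) -> list[MapParams]:
    """Draw per-map parameters for a cohort of ``n_normal`` + ``n_kcn`` eyes.

    AveK and Cyl are drawn from per-class Gaussians with the study-population
    moments above, truncated to the admissible parameter ranges.  Keratoconus
    pattern types follow ``kcn_mix`` (default 0.6 inferior / 0.2 central /
    0.2 AB/SRAX).  Deterministic given ``seed``.
    """
    if n_normal < 0 or n_kcn < 0:
        raise ValueError("cohort counts must be >= 0")
    kcn_mix = dict(DEFAULT_KCN_MIX if kcn_mix is None else kcn_mix)
    if abs(sum(kcn_mix.values()) - 1.0) > 1e-9 or set(kcn_mix) - set(KCN_PATTERNS):
        raise ValueError("kcn_mix must be a distribution over the kcn patterns")
    rng = np.random.default_rng(seed)
    out: list[MapParams] = []

    m = CLASS_MOMENTS["normal"]
    ave_k = _truncated_normal(rng, *m["ave_k"], *AVE_K_BOUNDS, n_normal)
    cyl = _truncated_normal(rng, *m["cyl"], 0.0, np.inf, n_normal)
    axis = rng.uniform(0.0, math.pi, n_normal)
    for i in range(n_normal):
        out.append(MapParams(
            pattern=NORMAL_PATTERN, ave_k=float(ave_k[i]), cyl=float(cyl[i]),
            axis=float(axis[i]), cone_amplitude=0.0, cone_center=(0.0, 0.0),
            cone_width=0.25, label="normal"))

    m = CLASS_MOMENTS["kcn"]
    ave_k = _truncated_normal(rng, *m["ave_k"], *AVE_K_BOUNDS, n_kcn)
    cyl = _truncated_normal(rng, *m["cyl"], 0.0, np.inf, n_kcn)
    axis = rng.uniform(0.0, math.pi, n_kcn)
    patterns = rng.choice(list(kcn_mix), p=list(kcn_mix.values()), size=n_kcn)
    amp = _truncated_normal(rng, 5.0, 2.0, 1.0, 15.0, n_kcn)
    width = rng.uniform(0.15, 0.30, n_kcn)
    for i in range(n_kcn):
        pat = str(patterns[i])
        skew = 0.0
        if pat == "inferior_cone":
            center = (float(rng.normal(0.0, 0.10)), float(rng.uniform(0.25, 0.55)))
        elif pat == "central_cone":
            center = (float(rng.normal(0.0, 0.07)), float(rng.normal(0.0, 0.07)))
        else:  # ab_srax: inferior-dominant lobe with a skewed opposite lobe
            center = (float(rng.normal(0.0, 0.10)), float(rng.uniform(0.25, 0.50)))
            skew = float(rng.uniform(math.radians(10), math.radians(35)))
        out.append(MapParams(
            pattern=pat, ave_k=float(ave_k[i]), cyl=float(cyl[i]), axis=float(axis[i]),
            cone_amplitude=float(amp[i]), cone_center=center,
            cone_width=float(width[i]), label="kcn", skew_angle=skew))
    return out


def curvature_field(params: MapParams, grid: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the dioptric curvature field on an ``(H, W)`` grid.

    Returns ``(field, mask)`` where ``mask`` is the inscribed circle and
    ``field`` is NaN outside it.
    """
    h, w = grid
    if h < 16 or w < 16:
        raise ValueError("grid must be at least 16 x 16")
    radius = min(h, w) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    # normalized coordinates in fractions of the corneal radius; y downward
    xn = (xx - cx) / radius
    yn = (yy - cy) / radius
    r = np.hypot(xn, yn)
    theta = np.arctan2(yn, xn)
    mask = r <= 1.0

    field = params.ave_k + (params.cyl / 2.0) * np.cos(2.0 * (theta - params.axis))
    if params.cone_amplitude > 0:
        field = field + _cone_term(params, xn, yn)
    field = np.where(mask, field, np.nan)
    return field, mask


def _cone_term(params: MapParams, xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
    cx0, cy0 = params.cone_center
    w2 = 2.0 * params.cone_width ** 2
    d2 = (xn - cx0) ** 2 + (yn - cy0) ** 2
    term = params.cone_amplitude * np.exp(-d2 / w2)
    if params.pattern == "ab_srax":
        # second lobe opposite the first, its radial axis skewed by skew_angle
        rho = math.hypot(cx0, cy0)
        phi = math.atan2(cy0, cx0) + math.pi + params.skew_angle
        cx1, cy1 = rho * math.cos(phi), rho * math.sin(phi)
        d2b = (xn - cx1) ** 2 + (yn - cy1) ** 2
        term = term + 0.6 * params.cone_amplitude * np.exp(-d2b / w2)
    return term


@dataclasses.dataclass(frozen=True)
class CanvasConfig:
    """Rendering canvas: disc of ``radius_frac * min(H, W)`` centered on ``size``."""

    size: tuple[int, int] = (300, 300)
    radius_frac: float = 0.35
    background: tuple[int, int, int] = (190, 190, 190)
    annotations: bool = True
    n_annotations: int = 6
    annotation_seed: int = 0


@dataclasses.dataclass
class RenderedMap:
    """Rendered image plus the geometry needed by downstream oracles."""

    image: np.ndarray  # H x W x 3 uint8
    disc_mask: np.ndarray  # bool, pixels colored from the field
    annotation_mask: np.ndarray  # bool, clutter pixels
    bbox: tuple[int, int, int, int]  # half-open disc bounding box (x0, y0, x1, y1)
    n_clamped: int  # pixels whose power fell outside the scale range


def render_map(field: np.ndarray, mask: np.ndarray, scale: ColorScale,
               canvas: CanvasConfig | None = None) -> RenderedMap:
    """Render a curvature field as a clinical-style color-coded disc.

    The field's inscribed disc is pasted centered on the canvas at
    ``radius_frac * min(size)``; each in-mask pixel is colored by its power
    bin.  Optional annotation clutter (near-gray blocks emulating words and
    numbers) is drawn outside a 1.1x radius ring so ground-truth crops remain
    well defined.  Powers outside the scale range clamp to the end bins and
    are counted in ``n_clamped``.
    """
    canvas = canvas or CanvasConfig()
    hc, wc = canvas.size
    radius = canvas.radius_frac * min(hc, wc)
    side = int(round(2 * radius))
    if field.shape[0] != side or field.shape[1] != side:
        field, mask = _resample_field(field, mask, side)
    img = np.empty((hc, wc, 3), dtype=np.uint8)
    img[:] = canvas.background

    finite = mask & np.isfinite(field)
    if not np.array_equal(finite, mask):
        raise ValueError("field must be finite inside the mask")
    bins = scale.bin_of(np.where(mask, field, scale.thresholds[0]))
    thresholds = scale.thresholds
    n_clamped = int(np.sum(mask & ((field < thresholds[0]) | (field >= thresholds[-1] + (thresholds[-1] - thresholds[-2])))))
    colors = scale.colors[bins]

    y0 = (hc - side) // 2
    x0 = (wc - side) // 2
    disc_mask = np.zeros((hc, wc), dtype=bool)
    disc_mask[y0:y0 + side, x0:x0 + side] = mask
    img[y0:y0 + side, x0:x0 + side][mask] = colors[mask]

    annotation_mask = np.zeros((hc, wc), dtype=bool)
    if canvas.annotations:
        annotation_mask = _draw_annotations(img, canvas, radius)

    bbox = (x0, y0, x0 + side, y0 + side)
    return RenderedMap(image=img, disc_mask=disc_mask,
                       annotation_mask=annotation_mask, bbox=bbox,
                       n_clamped=n_clamped)


def _resample_field(field: np.ndarray, mask: np.ndarray, side: int):
    """Nearest-neighbour resample of the field grid to the disc side length."""
    h, w = field.shape
    ys = np.clip((np.arange(side) + 0.5) * h / side, 0, h - 1).astype(int)
    xs = np.clip((np.arange(side) + 0.5) * w / side, 0, w - 1).astype(int)
    f = field[np.ix_(ys, xs)]
    # re-derive the inscribed mask at the new resolution to keep it circular
    cy = cx = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    m = np.hypot(yy - cy, xx - cx) <= side / 2.0
    f = np.where(m, np.where(np.isfinite(f), f, np.nanmean(f)), np.nan)
    return f, m


def _draw_annotations(img: np.ndarray, canvas: CanvasConfig, radius: float) -> np.ndarray:
    """Near-gray text-like blocks outside a 1.1x-radius square keep-out.

    The keep-out uses the Chebyshev (square) distance so that the disc's
    bounding-square crop — the ground-truth segmentation target — can never
    contain annotation pixels."""
    hc, wc = img.shape[:2]
    cy, cx = (hc - 1) / 2.0, (wc - 1) / 2.0
    rng = np.random.default_rng(canvas.annotation_seed)
    mask = np.zeros((hc, wc), dtype=bool)
    keep_out = 1.1 * radius
    for _ in range(canvas.n_annotations):
        for _attempt in range(50):
            bh = int(rng.integers(4, 9))
            bw = int(rng.integers(12, 32))
            y = int(rng.integers(0, hc - bh))
            x = int(rng.integers(0, wc - bw))
            corners = np.array([[y, x], [y, x + bw], [y + bh, x], [y + bh, x + bw]], float)
            d = np.maximum(np.abs(corners[:, 0] - cy), np.abs(corners[:, 1] - cx))
            if np.all(d > keep_out):
                break
        else:
            continue
        shade = int(rng.integers(0, 2)) * 235 + 10  # near-black or near-white
        block = np.full((bh, bw), shade, dtype=np.uint8)
        # pepper with gaps so blocks look like glyph runs rather than bars
        gaps = rng.random((bh, bw)) < 0.35
        block[gaps] = img[y:y + bh, x:x + bw, 0][gaps]
        img[y:y + bh, x:x + bw] = block[..., None]
        mask[y:y + bh, x:x + bw] = ~gaps
    return mask


@dataclasses.dataclass(frozen=True)
class NoiseConfig:
    """Structured acquisition noise: periodic grid lines plus impulse noise."""

    row_period: int = 9
    col_period: int = 9
    amplitude: int = 40
    impulse_density: float = 0.01


def add_acquisition_noise(image: np.ndarray, cfg: NoiseConfig | None = None,
                          seed: int = 0) -> np.ndarray:
    """Contaminate a rendered map with regular (periodic) and impulse noise."""
    cfg = cfg or NoiseConfig()
    out = image.astype(np.int16).copy()
    h, w = out.shape[:2]
    if cfg.amplitude:
        if cfg.row_period:
            out[::cfg.row_period, :, :] -= cfg.amplitude
        if cfg.col_period:
            out[:, ::cfg.col_period, :] -= cfg.amplitude
    out = np.clip(out, 0, 255).astype(np.uint8)
    if cfg.impulse_density > 0:
        rng = np.random.default_rng(seed)
        hits = rng.random((h, w)) < cfg.impulse_density
        salt = rng.random((h, w)) < 0.5
        out[hits & salt] = 255
        out[hits & ~salt] = 0
    return out


def cohort_manifest(cohort: Sequence[MapParams], files: Sequence[str] | None = None,
                    origins: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate a cohort as the manifest written next to rendered PNGs."""
    rows = []
    for i, p in enumerate(cohort):
        rows.append({
            "id": i,
            "label": p.label,
            "pattern": p.pattern,
            "ave_k": p.ave_k,
            "cyl": p.cyl,
            "axis": p.axis,
            "cone_amplitude": p.cone_amplitude,
            "origin": origins[i] if origins is not None else "original",
            "file": files[i] if files is not None else "",
        })
    return pd.DataFrame(rows)
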