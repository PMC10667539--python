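"""Clinical diagnostic evaluation: confusion matrices, prevalence-adjusted
metrics, ROC/AUC with the sensitivity~=specificity operating point, Grad-CAM
saliency, and original-vs-synthesized comparison tables.

PPV and NPV depend on disease prevalence; when a prevalence ``p`` is
supplied they are computed by Bayes' rule from sensitivity and specificity,

    PPV = sens*p / (sens*p + (1-spec)*(1-p))
    NPV = spec*(1-p) / (spec*(1-p) + (1-sens)*p),

which reduces exactly to the raw-count ratios when ``p`` equals the sample
positive fraction.  The screening literature commonly reports these at an
assumed clinic prevalence (e.g. 44%) rather than the test-set mix.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import transform

from . import nn
from .synthmap import ColorScale, default_color_scale

__all__ = [
    "ConfusionMatrix", "MetricReport", "RocCurve", "GradCamMap",
    "UndefinedRoc", "confusion", "diagnostic_metrics", "roc_curve_auc",
    "optimal_cutoff", "gradcam_heatmap", "overlay_heatmap",
    "compare_experiments", "report_from_scores",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")


class UndefinedRoc(ValueError):
    """ROC needs both classes present."""


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclasses.dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence_used: float | None = None
    auc: float = math.nan
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """2x2 counts with 1 = keratoconus (positive class)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def diagnostic_metrics(cm: ConfusionMatrix, prevalence: float | None = None) -> MetricReport:
    """Accuracy, sensitivity, specificity and (optionally prevalence-
    adjusted) predictive values.

    Metrics with an empty margin (e.g. sensitivity when tp + fn = 0) are
    returned as NaN and listed in ``MetricReport.undefined``.
    """
    if cm.total <= 0:
        raise ValueError("confusion matrix must contain at least one sample")
    if prevalence is not None and not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    acc = (cm.tp + cm.tn) / cm.total
    if prevalence is None:
        ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
        npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    else:
        p = prevalence
        if math.isnan(sens) or math.isnan(spec):
            undefined.extend(["ppv", "npv"])
            ppv = npv = math.nan
        else:
            ppv = ratio(sens * p, sens * p + (1 - spec) * (1 - p), "ppv")
            npv = ratio(spec * (1 - p), spec * (1 - p) + (1 - sens) * p, "npv")
    return MetricReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        ppv=ppv, npv=npv, prevalence_used=prevalence,
                        undefined=tuple(undefined))


@dataclasses.dataclass
class RocCurve:
    points: list[tuple[float, float, float]]  # (threshold, fpr, tpr)
    auc: float
    optimal_threshold: float


def roc_curve_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Threshold-swept ROC with trapezoidal AUC.

    Thresholds are the unique scores plus a +inf sentinel; a sample is
    called positive when ``score >= threshold``.  The trapezoidal AUC over
    (fpr, tpr) equals the pairwise concordance probability with ties
    counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRoc("both classes must be present")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pts = []
    for t in thresholds:
        pred = s >= t
        tpr = float(np.sum(pred & (y == 1)) / n_pos)
        fpr = float(np.sum(pred & (y == 0)) / n_neg)
        pts.append((float(t), fpr, tpr))
    fprs = np.array([p[1] for p in pts])
    tprs = np.array([p[2] for p in pts])
    order = np.argsort(fprs, kind="stable")
    auc = float(np.trapezoid(tprs[order], fprs[order]))
    curve = RocCurve(points=pts, auc=auc, optimal_threshold=math.nan)
    curve.optimal_threshold = optimal_cutoff(curve)
    return curve


def optimal_cutoff(curve: RocCurve) -> float:
    """Operating point closest to sensitivity = specificity.

    Minimizes |sens - spec|; ties break toward larger sens + spec, then
    smaller threshold.  Infinite sentinel thresholds are clamped out of
    contention only by the tie-break on threshold value.
    """
    if not curve.points:
        raise ValueError("empty ROC curve")
    best = None
    for t, fpr, tpr in curve.points:
        sens, spec = tpr, 1.0 - fpr
        key = (abs(sens - spec), -(sens + spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


@dataclasses.dataclass
class GradCamMap:
    heat: np.ndarray  # H x W in [0, 1]
    target_layer: str
    all_zero: bool = False


def _find_last_conv(model: nn.Sequential) -> str:
    names = [l.name for l in model.layers if isinstance(l, nn.Conv2D)]
    if not names:
        raise ValueError("model has no convolutional layer")
    return names[-1]


def gradcam_heatmap(model: nn.Sequential, image: np.ndarray,
                    target_layer: str | None = None) -> GradCamMap:
    """Gradient-weighted class activation map for the positive-class score.

    Channel weights are the spatial means of d(score)/d(activation) at the
    target layer (default: last conv layer); the heatmap is the rectified
    weighted activation sum, min-max normalized and upsampled to the input's
    spatial shape.
    """
    target_layer = target_layer or _find_last_conv(model)
    x = np.asarray(image, dtype=np.float32)[None, ...]
    idx = next((i for i, l in enumerate(model.layers) if l.name == target_layer), None)
    if idx is None:
        raise ValueError(f"no layer named {target_layer!r}")
    # forward, keeping the target activation
    h = x
    activations = None
    for i, layer in enumerate(model.layers):
        h = layer.forward(h)
        if i == idx:
            activations = h
    # backward from the positive-class score down to the target layer
    dy = np.ones_like(h)
    for layer in reversed(model.layers[idx + 1:]):
        dy = layer.backward(dy)
    grads = dy  # d score / d activations, (1, h, w, c)
    weights = grads.mean(axis=(1, 2))  # (1, c)
    cam = np.maximum((activations * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    if cam.max() <= 0:
        heat = np.zeros(x.shape[1:3])
        return GradCamMap(heat=heat, target_layer=target_layer, all_zero=True)
    cam = (cam - cam.min()) / (cam.max() - cam.min())
    heat = transform.resize(cam, x.shape[1:3], order=1, preserve_range=True)
    heat = np.clip(heat, 0.0, 1.0)
    return GradCamMap(heat=heat, target_layer=target_layer)


def overlay_heatmap(image: np.ndarray, heat: GradCamMap | np.ndarray,
                    alpha: float = 0.5, scale: ColorScale | None = None) -> np.ndarray:
    """Blend ``(1 - alpha) * image + alpha * colorized(heat)``.

    The heatmap is colorized through the same dioptric color-scale machinery
    used for map rendering (low = blue, high = red).
    """
    h = heat.heat if isinstance(heat, GradCamMap) else np.asarray(heat, dtype=float)
    img = np.asarray(image, dtype=float)
    if img.shape[:2] != h.shape:
        raise ValueError("image and heatmap spatial shapes must match")
    scale = scale or default_color_scale()
    lo, hi = scale.thresholds[0], scale.thresholds[-1]
    colorized = scale.colors[scale.bin_of(lo + h * (hi - lo))].astype(float)
    out = (1.0 - alpha) * img + alpha * colorized
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def compare_experiments(results: dict[str, dict[str, MetricReport]]) -> pd.DataFrame:
    """Original-vs-synthesized comparison table.

    ``results[model][condition]`` with conditions "original" and
    "synthesized".  Emits one row per (model, condition) with the six
    metrics, plus per-model flags marking metrics that improved under the
    synthesized condition; missing conditions yield NaN rows flagged in
    ``missing``.
    """
    if not any(len(conds) >= 1 for conds in results.values()):
        raise ValueError("at least one model with results required")
    rows = []
    for model, conds in results.items():
        for cond in ("original", "synthesized"):
            rep = conds.get(cond)
            row = {"model": model, "condition": cond, "missing": rep is None}
            if rep is None:
                row |= {k: math.nan for k in METRIC_NAMES}
            else:
                row |= rep.as_dict()
            rows.append(row)
        orig, syn = conds.get("original"), conds.get("synthesized")
        for name in METRIC_NAMES:
            improved = (orig is not None and syn is not None
                        and not math.isnan(getattr(orig, name))
                        and not math.isnan(getattr(syn, name))
                        and getattr(syn, name) > getattr(orig, name))
            rows[-1][f"improved_{name}"] = improved
    return pd.DataFrame(rows)


def report_from_scores(scores: Sequence[float], labels: Sequence[int],
                       threshold: float = 0.5,
                       prevalence: float | None = None) -> MetricReport:
    """Convenience: confusion at ``threshold`` + metrics + AUC in one call."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cm = confusion(y, (s >= threshold).astype(int))
    rep = diagnostic_metrics(cm, prevalence=prevalence)
    try:
        rep.auc = roc_curve_auc(s, y).auc
    except UndefinedRoc:
        rep.undefined = rep.undefined + ("auc",)
    return rep
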