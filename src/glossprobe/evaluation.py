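"""Predictor-vs-response comparisons and headline analyses.

Correlations at probe pixels, per-pixel-group prediction means, decision
rate curves under a swept threshold, the rotated-highlight RMSE test, and
the random-noise RMSE baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimuli import EPS_SPECULAR, rotate_specular


@dataclass
class CorrelationReport:
    r: float
    r2: float
    rmse: float


def correlate(predictor: np.ndarray, target: np.ndarray) -> CorrelationReport:
    x = np.asarray(predictor, dtype=np.float64).ravel()
    y = np.asarray(target, dtype=np.float64).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must be aligned with length >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in predictor vector")
    if y.std() == 0:
        raise ValueError("zero variance in target vector")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationReport(r=r, r2=r * r, rmse=rmse(x, y))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# Pixel-group means
# ---------------------------------------------------------------------------

@dataclass
class CategoryMeansReport:
    specular_mean: float | None
    bright_texture_mean: float | None
    other_mean: float | None
    pixel_counts: dict


def pixel_groups(specular: np.ndarray, image: np.ndarray,
                 texture: np.ndarray, brightness_threshold: float,
                 eps: float = EPS_SPECULAR):
    """Partition pixels into specular / bright texture / other masks.

    Bright texture: textured pixels whose composed intensity exceeds the
    global brightness threshold, excluding specular overlap.
    """
    spec_mask = specular > eps
    bright = (image > brightness_threshold) & (np.abs(texture - 1.0) > 1e-9)
    bright_tex = bright & ~spec_mask
    other = ~spec_mask & ~bright_tex
    return spec_mask, bright_tex, other


def category_means(predictions, records, brightness_threshold: float,
                   eps: float = EPS_SPECULAR) -> CategoryMeansReport:
    """Mean prediction per pixel group, pooled over an image set."""
    sums = {"specular": 0.0, "bright_texture": 0.0, "other": 0.0}
    counts = {"specular": 0, "bright_texture": 0, "other": 0}
    for pred, rec in zip(predictions, records):
        masks = pixel_groups(rec.components.specular, rec.image,
                             rec.texture_map, brightness_threshold, eps)
        for name, mask in zip(("specular", "bright_texture", "other"), masks):
            sums[name] += float(pred[mask].sum())
            counts[name] += int(mask.sum())
        total = sum(int(m.sum()) for m in masks)
        if total != pred.size:
            raise AssertionError("pixel groups do not partition the image")
    def _mean(name):
        return sums[name] / counts[name] if counts[name] else None
    return CategoryMeansReport(
        specular_mean=_mean("specular"),
        bright_texture_mean=_mean("bright_texture"),
        other_mean=_mean("other"),
        pixel_counts=counts)


# ---------------------------------------------------------------------------
# Decision-rate curves
# ---------------------------------------------------------------------------

@dataclass
class DecisionRateCurves:
    thresholds: np.ndarray
    tpr: np.ndarray | None
    fnr: np.ndarray | None
    fpr: np.ndarray | None
    tnr: np.ndarray | None


def decision_rate_curves(predictor: np.ndarray, gt_labels: np.ndarray,
                         thresholds: np.ndarray | None = None) -> DecisionRateCurves:
    """TPR/FNR over highlight probes and FPR/TNR over non-highlight probes
    as the decision threshold sweeps the predictor's value range.

    A probe counts as a positive decision when predictor > threshold; at
    threshold 0 every nonzero prediction passes.
    """
    x = np.asarray(predictor, dtype=np.float64).ravel()
    y = np.asarray(gt_labels).ravel().astype(bool)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0, 1.0], np.unique(x)]))
    pos, neg = y, ~y
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    tpr = fnr = fpr = tnr = None
    decisions = x[None, :] > thresholds[:, None]
    if n_pos:
        tpr = decisions[:, pos].mean(axis=1)
        fnr = 1.0 - tpr
    if n_neg:
        fpr = decisions[:, neg].mean(axis=1)
        tnr = 1.0 - fpr
    return DecisionRateCurves(thresholds=thresholds, tpr=tpr, fnr=fnr,
                              fpr=fpr, tnr=tnr)


# ---------------------------------------------------------------------------
# Rotated-highlight test
# ---------------------------------------------------------------------------

def rotation_rmse(predict_fn, plain_records, angles=(0, 90, 180, 270)):
    """Mean/SD per-image RMSE between predictions on recomposed
    rotated-specular stimuli and the rotated specular map itself."""
    for rec in plain_records:
        if rec.condition != "plain":
            raise ValueError("rotation_rmse requires untextured (plain) stimuli")
    out = {}
    for angle in angles:
        vals = []
        for rec in plain_records:
            rot = rotate_specular(rec, angle)
            pred = predict_fn(rot.image)
            vals.append(rmse(pred, rot.components.specular))
        vals = np.array(vals)
        out[angle] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out


def noise_rmse_baseline(n_pairs: int = 1000, size: int = 256, seed: int = 0):
    """RMSE between pairs of independent uniform-[0,1] noise images.

    Analytic limit: sqrt(E[(X - Y)^2]) = sqrt(1/6) ~ 0.408.
    """
    rng = np.random.default_rng(seed)
    vals = np.empty(n_pairs)
    for i in range(n_pairs):
        a = rng.random((size, size))
        b = rng.random((size, size))
        vals[i] = rmse(a, b)
    return float(vals.mean()), float(vals.std(ddof=1))
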