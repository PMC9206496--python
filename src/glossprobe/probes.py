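"""Pixel categorization and probe selection.

Pixels are sorted into four categories by agreement between the binarized
ground-truth specular map and the binarized threshold prediction:

    a: both signal a highlight          b: threshold only
    c: ground truth only                d: neither

One probe per required category is picked per image by maximizing a
category-specific continuous score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import EPS_SPECULAR, Catalog
from .threshold import ThresholdModel

CATEGORIES = ("a", "b", "c", "d")


def categorize_pixels(gt: np.ndarray, tm: np.ndarray,
                      eps: float = EPS_SPECULAR) -> np.ndarray:
    """Per-pixel category labels as a char array ('a'..'d')."""
    gt = np.asarray(gt)
    tm = np.asarray(tm)
    if gt.shape != tm.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs tm {tm.shape}")
    g = gt > eps
    t = tm > 0
    out = np.empty(gt.shape, dtype="U1")
    out[g & t] = "a"
    out[~g & t] = "b"
    out[g & ~t] = "c"
    out[~g & ~t] = "d"
    return out


def category_counts(labels: np.ndarray) -> dict[str, int]:
    return {c: int(np.sum(labels == c)) for c in CATEGORIES}


@dataclass(frozen=True)
class Probe:
    image_id: int
    row: int
    col: int
    category: str
    selection_score: float


@dataclass
class ProbeSet:
    probes: list[Probe]
    design: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)

    def image_ids(self) -> list[int]:
        return sorted({p.image_id for p in self.probes})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.image_id, p.row, p.col, p.category, p.selection_score)
             for p in self.probes],
            columns=["image_id", "row", "col", "category", "selection_score"])

    def save(self, csv_path, design_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if design_path is not None:
            with open(design_path, "w") as fh:
                json.dump(self.design, fh, indent=2)

    @classmethod
    def load(cls, csv_path, design_path=None) -> "ProbeSet":
        df = pd.read_csv(csv_path)
        probes = [Probe(int(r.image_id), int(r.row), int(r.col),
                        str(r.category), float(r.selection_score))
                  for r in df.itertuples()]
        design = {}
        if design_path is not None:
            with open(design_path) as fh:
                design = json.load(fh)
        return cls(probes=probes, design=design)


def selection_scores(image: np.ndarray, gt: np.ndarray, tm: np.ndarray,
                     model_threshold: float) -> dict[str, np.ndarray]:
    """Continuous per-category objectives (maximized during selection).

    a: strong joint agreement, min(gt, tm); b: threshold confidence; c:
    ground-truth strength; d: sub-threshold intensity margin (the pixel
    most confidently below the threshold, i.e. the darkest candidate).
    """
    return {
        "a": np.minimum(gt, tm),
        "b": tm,
        "c": gt,
        "d": model_threshold - np.asarray(image, dtype=np.float64),
    }


def _pick(labels: np.ndarray, score: np.ndarray, category: str):
    mask = labels == category
    if not mask.any():
        return None
    masked = np.where(mask, score, -np.inf)
    flat = int(np.argmax(masked))          # row-major tie-break: lowest (r, c)
    r, c = np.unravel_index(flat, labels.shape)
    return int(r), int(c), float(score[r, c])


def probes_for_image(image_id: int, image: np.ndarray, gt: np.ndarray,
                     model: ThresholdModel,
                     categories=CATEGORIES,
                     eps: float = EPS_SPECULAR):
    """One probe per requested category, or None if a category is absent."""
    tm = model.predict(image)
    labels = categorize_pixels(gt, tm, eps=eps)
    scores = selection_scores(image, gt, tm, model.threshold)
    out = []
    for cat in categories:
        hit = _pick(labels, scores[cat], cat)
        if hit is None:
            return None
        r, c, s = hit
        out.append(Probe(image_id=image_id, row=r, col=c, category=cat,
                         selection_score=s))
    return out


def _balanced_assignment(cells: dict, n_needed: int, rng) -> list[int]:
    """Draw image indices round-robin over (condition, scale) cells."""
    order = sorted(cells)
    rng.shuffle(order)
    for key in order:
        rng.shuffle(cells[key])
    chosen: list[int] = []
    depth = 0
    while len(chosen) < n_needed:
        progressed = False
        for key in order:
            pool = cells[key]
            if depth < len(pool) and len(chosen) < n_needed:
                chosen.append(pool[depth])
                progressed = True
        if not progressed:
            raise RuntimeError(
                f"not enough eligible images: needed {n_needed}, "
                f"found {len(chosen)} (cells: { {k: len(v) for k, v in cells.items()} })")
        depth += 1
    return chosen


def select_probes(catalog: Catalog, model: ThresholdModel,
                  n_four: int = 120, n_two: int = 120, seed: int = 0,
                  eps: float = EPS_SPECULAR) -> ProbeSet:
    """Select probe pixels: four categories on ``n_four`` images, the two
    disagreement categories (b, c) on ``n_two`` further images.

    Image assignment is seeded-random and balanced jointly over texture
    condition and surface scale level; images missing a required category
    are skipped and replaced.
    """
    rng = np.random.default_rng(seed)

    eligible_four: dict = {}
    eligible_two: dict = {}
    cached: dict[int, list] = {}
    for idx, rec in enumerate(catalog):
        key = (rec.condition, rec.scene.scale_level)
        four = probes_for_image(idx, rec.image, rec.components.specular,
                                model, CATEGORIES, eps)
        if four is not None:
            eligible_four.setdefault(key, []).append(idx)
            cached[idx] = four
            continue
        two = probes_for_image(idx, rec.image, rec.components.specular,
                               model, ("b", "c"), eps)
        if two is not None:
            eligible_two.setdefault(key, []).append(idx)
            cached[idx] = two

    chosen_four = _balanced_assignment(
        {k: list(v) for k, v in eligible_four.items()}, n_four, rng)
    used = set(chosen_four)
    pool_two: dict = {}
    for key, idxs in list(eligible_four.items()) + list(eligible_two.items()):
        rest = [i for i in idxs if i not in used]
        if rest:
            pool_two.setdefault(key, []).extend(rest)
    chosen_two = _balanced_assignment(pool_two, n_two, rng)

    probes: list[Probe] = []
    for idx in chosen_four:
        probes.extend(cached[idx])
    for idx in chosen_two:
        probes.extend(p for p in cached[idx] if p.category in "bc")
    design = {
        "n_four": n_four, "n_two": n_two, "seed": seed,
        "four_images": sorted(chosen_four), "two_images": sorted(chosen_two),
    }
    return ProbeSet(probes=probes, design=design)


def probe_values(probe_set: ProbeSet, maps_by_image: dict[int, np.ndarray]) -> np.ndarray:
    """Gather one predictor's values at every probe pixel, in probe order."""
    return np.array([maps_by_image[p.image_id][p.row, p.col]
                     for p in probe_set.probes], dtype=np.float64)
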