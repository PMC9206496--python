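"""Representational similarity analysis and lesion analysis.

A bank of 34 hand-engineered predictors in 7 categories is computed per
stimulus; first-order RDMs (pairwise Euclidean distances between images
in a representation) are compared between network units and predictors
via upper-triangle correlation/regression; units embed in 2-D through
metric MDS of the second-order (1 - r) RDM.  Lesioning zeroes all
weights of one filter and measures loss and probe-correlation deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .stimuli import CONDITIONS, EPS_SPECULAR, StimulusRecord
from .network import MultiScaleNet, evaluate_loss
from .pruning import pearson_fitness

PREDICTOR_CATEGORIES = {
    "input_image": ["image"],
    "summary_statistics": ["mean", "sd", "skewness", "kurtosis"],
    "edge_detection": ["gradient_x", "gradient_y", "local_contrast",
                       "local_normalized"],
    "gradients_anisotropy": ["orientation_x", "orientation_y", "anisotropy"],
    "geometry": ["camera_distance", "angle_to_camera", "light_distance",
                 "angle_to_light", "convexity", "pointiness", "normal_x",
                 "normal_y", "normal_z", "occluding_edges",
                 "occluding_distance"],
    "intrinsic": ["texture", "shading", "specular", "specular_direct",
                  "specular_indirect", "specular_coverage",
                  "texture_coverage"],
    "scene_information": ["surface_scale", "texture_type",
                          "texture_condition", "scene"],
}

PREDICTOR_NAMES = [n for names in PREDICTOR_CATEGORIES.values() for n in names]
assert len(PREDICTOR_NAMES) == 34

_TEXTURE_TYPES = ("plain", "voronoi", "marble", "checker", "false_highlight")


def _local_stats(image: np.ndarray, size: int = 5):
    mean = ndimage.uniform_filter(image, size)
    sq = ndimage.uniform_filter(image * image, size)
    sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    return mean, sd


def _one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v


def predictor_vectors(record: StimulusRecord, sigma: float | None = None,
                      n_scenes: int | None = None,
                      eps: float = EPS_SPECULAR) -> dict[str, np.ndarray]:
    """All 34 predictor representations of one stimulus, as flat vectors.

    Scalar predictors are length-1 vectors; categorical scene predictors
    are one-hot (``n_scenes`` sets the scene one-hot length; omit it for
    a length-1 scene-id code).
    """
    img = np.asarray(record.image, dtype=np.float64)
    comps = record.components
    if not comps.buffers:
        raise ValueError("record is missing geometry buffers; predictors "
                         "camera/light/normals/curvature unavailable")
    if sigma is None:
        sigma = 4.0 * img.shape[0] / 128.0
    out: dict[str, np.ndarray] = {}

    out["image"] = img.ravel()
    out["mean"] = np.array([img.mean()])
    out["sd"] = np.array([img.std()])
    flat = img.ravel()
    out["skewness"] = np.array([stats.skew(flat)])
    out["kurtosis"] = np.array([stats.kurtosis(flat)])

    gy, gx = np.gradient(img)
    out["gradient_x"] = gx.ravel()
    out["gradient_y"] = gy.ravel()
    lmean, lsd = _local_stats(img)
    out["local_contrast"] = lsd.ravel()
    out["local_normalized"] = ((img - lmean) / (lsd + 1e-3)).ravel()

    smooth = ndimage.gaussian_filter(img, sigma)
    sgy, sgx = np.gradient(smooth)
    mag = np.sqrt(sgx * sgx + sgy * sgy) + 1e-12
    out["orientation_x"] = (sgx / mag).ravel()
    out["orientation_y"] = (sgy / mag).ravel()
    # structure-tensor anisotropy of the smoothed image
    jxx = ndimage.gaussian_filter(sgx * sgx, sigma)
    jyy = ndimage.gaussian_filter(sgy * sgy, sigma)
    jxy = ndimage.gaussian_filter(sgx * sgy, sigma)
    tr = jxx + jyy
    det = jxx * jyy - jxy * jxy
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    l1 = tr / 2.0 + disc
    l2 = tr / 2.0 - disc
    out["anisotropy"] = ((l1 - l2) / (l1 + l2 + 1e-12)).ravel()

    buf = comps.buffers
    out["camera_distance"] = buf["camera_distance"].ravel()
    out["angle_to_camera"] = buf["angle_to_camera"].ravel()
    out["light_distance"] = buf["light_distance"].ravel()
    out["angle_to_light"] = buf["angle_to_light"].ravel()
    curv = buf["curvature"]
    out["convexity"] = np.sign(curv).ravel()
    out["pointiness"] = np.abs(curv).ravel()
    out["normal_x"] = buf["normal_x"].ravel()
    out["normal_y"] = buf["normal_y"].ravel()
    out["normal_z"] = buf["normal_z"].ravel()
    dgy, dgx = np.gradient(comps.depth)
    dmag = np.sqrt(dgx * dgx + dgy * dgy)
    occ = dmag > np.quantile(dmag, 0.99)
    out["occluding_edges"] = occ.astype(np.float64).ravel()
    out["occluding_distance"] = ndimage.distance_transform_edt(~occ).ravel()

    out["texture"] = np.asarray(record.texture_map, dtype=np.float64).ravel()
    out["shading"] = comps.shading.ravel()
    out["specular"] = comps.specular.ravel()
    out["specular_direct"] = comps.specular.ravel()      # direct-only renderer
    out["specular_indirect"] = np.zeros(img.size)
    out["specular_coverage"] = np.array([np.mean(comps.specular > eps)])
    out["texture_coverage"] = np.array(
        [np.mean(np.abs(record.texture_map - 1.0) > eps)])

    out["surface_scale"] = np.array([float(record.scene.scale_level)])
    out["texture_type"] = _one_hot(
        _TEXTURE_TYPES.index(record.texture_family), len(_TEXTURE_TYPES))
    out["texture_condition"] = _one_hot(
        CONDITIONS.index(record.condition), len(CONDITIONS))
    if n_scenes is None:
        out["scene"] = np.array([float(record.scene.scene_id)])
    else:
        out["scene"] = _one_hot(record.scene.scene_id % n_scenes, n_scenes)
    assert len(out) == 34
    return out


@dataclass
class PredictorBank:
    """Per-predictor (n_images, dim) representations over an image set."""

    representations: dict[str, np.ndarray]
    categories: dict[str, list] = field(default_factory=lambda: dict(PREDICTOR_CATEGORIES))

    @classmethod
    def from_records(cls, records, sigma: float | None = None) -> "PredictorBank":
        n_scenes = len({r.scene.scene_id for r in records})
        per_image = [predictor_vectors(r, sigma=sigma, n_scenes=n_scenes)
                     for r in records]
        reps = {name: np.stack([d[name] for d in per_image])
                for name in PREDICTOR_NAMES}
        return cls(representations=reps)

    def rdms(self) -> dict[str, np.ndarray]:
        return {name: first_order_rdm(rep)
                for name, rep in self.representations.items()}


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------

def first_order_rdm(representations: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between per-image representation vectors."""
    rep = np.asarray(representations, dtype=np.float64)
    if rep.ndim != 2 or rep.shape[0] < 3:
        raise ValueError("need a (n_images >= 3, dim) representation matrix")
    if not np.all(np.isfinite(rep)):
        raise ValueError("non-finite values in representations")
    return squareform(pdist(rep, metric="euclidean"))


def upper_triangle(rdm: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(rdm.shape[0], k=1)
    return rdm[iu]


def unit_rdms(net: MultiScaleNet, images) -> tuple[dict[str, np.ndarray], list[str]]:
    """First-order RDM per non-dead filter; returns (rdms, dead_filter_names).

    A filter is dead when its response map is constant across the whole
    image set (zero output variance).
    """
    responses: dict[str, list[np.ndarray]] = {}
    for im in images:
        x = im[np.newaxis, np.newaxis].astype(np.float32)
        t1 = net.tier1_outputs(x)
        z, cache = net._forward_from_tier1(t1, None, keep=True, x=x)
        acts = {}
        S = net.config.n_scales
        for s in range(S):
            acts[f"tier1/scale{s}"] = t1[s]
            acts[f"tier2/scale{s}"] = cache["t2"][s]
            acts[f"tier3/scale{s}"] = cache["t3"][s]
        acts["tier4"] = cache["t4"]
        acts["output"] = 1.0 / (1.0 + np.exp(-z))
        for name, arr in acts.items():
            for f in range(arr.shape[1]):
                responses.setdefault(f"{name}/f{f}", []).append(
                    arr[0, f].ravel())
    rdms, dead = {}, []
    for name, vecs in responses.items():
        rep = np.stack(vecs)
        if np.allclose(rep.std(axis=0), 0.0):
            dead.append(name)
        else:
            rdms[name] = first_order_rdm(rep)
    return rdms, dead


def category_similarity(unit_rdm: np.ndarray,
                        predictor_rdms: dict[str, np.ndarray],
                        names: list[str]) -> float:
    """OLS variance explained (R^2) of the unit RDM's upper triangle by the
    named predictors' upper triangles plus an intercept."""
    y = upper_triangle(unit_rdm)
    X = np.column_stack([upper_triangle(predictor_rdms[n]) for n in names]
                        + [np.ones(y.size)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / ss_tot)


def single_predictor_similarity(unit_rdm: np.ndarray,
                                predictor_rdm: np.ndarray) -> float:
    """Squared Pearson correlation of upper triangles."""
    a = upper_triangle(unit_rdm)
    b = upper_triangle(predictor_rdm)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1]) ** 2


def similarity_table(rdms: dict[str, np.ndarray],
                     bank_rdms: dict[str, np.ndarray]):
    """Per-unit per-category OLS R^2 and best single-predictor category."""
    cat_r2 = {}
    best_cat = {}
    for unit, rdm in rdms.items():
        per_cat = {}
        for cat, names in PREDICTOR_CATEGORIES.items():
            usable = [n for n in names if bank_rdms[n].std() > 0]
            per_cat[cat] = category_similarity(rdm, bank_rdms, usable) \
                if usable else 0.0
        cat_r2[unit] = per_cat
        best_name, best_val = None, -1.0
        for name, prdm in bank_rdms.items():
            v = single_predictor_similarity(rdm, prdm)
            if v > best_val:
                best_name, best_val = name, v
        best_cat[unit] = next(c for c, ns in PREDICTOR_CATEGORIES.items()
                              if best_name in ns)
    return cat_r2, best_cat


def second_order_rdm(rdms: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    names = list(rdms)
    if len(names) < 3:
        raise ValueError("need at least 3 unit RDMs")
    tri = np.stack([upper_triangle(rdms[n]) for n in names])
    corr = np.corrcoef(tri)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return names, np.clip(d, 0.0, None)


def second_order_embedding(rdms: dict[str, np.ndarray],
                           bank_rdms: dict[str, np.ndarray],
                           seed: int = 0):
    """2-D metric MDS of the second-order RDM + per-unit category labels."""
    names, d = second_order_rdm(rdms)
    mds = MDS(n_components=2, metric="precomputed", random_state=seed,
              init="random", normalized_stress=False)
    coords = mds.fit_transform(d)
    _, best_cat = similarity_table(rdms, bank_rdms)
    labels = [best_cat[n] for n in names]
    return names, coords, labels, float(mds.stress_)


# ---------------------------------------------------------------------------
# Lesion analysis
# ---------------------------------------------------------------------------

@dataclass
class LesionReport:
    units: list
    loss: np.ndarray
    probe_r: np.ndarray
    loss_delta: np.ndarray
    probe_r_delta: np.ndarray
    intact_loss: float
    intact_probe_r: float


def lesion_sweep(net: MultiScaleNet, eval_images, eval_labels,
                 predictor, pixels, mean_responses, mask=None) -> LesionReport:
    """Zero each filter's weights in turn; measure loss and probe r.

    ``predictor`` is a ProbePredictor built on the probe images (its
    tier-1 cache is rebuilt when a tier-1 filter is lesioned).
    """
    from .network import ProbePredictor

    def probe_r():
        preds = predictor.predict_pixels(pixels, mask=mask)
        r, _ = pearson_fitness(preds, mean_responses)
        return r

    intact_loss = evaluate_loss(net, eval_images, eval_labels, mask=mask)
    intact_r = probe_r()
    units, losses, rs = [], [], []
    for unit_name, conv, f in list(net.filters()):
        w_save = conv.W[f].copy()
        b_save = conv.b[f].copy()
        conv.W[f] = 0.0
        conv.b[f] = 0.0
        refresh_t1 = unit_name.startswith("tier1")
        if refresh_t1:
            pred = ProbePredictor(net, predictor.images)
        else:
            pred = predictor
        losses.append(evaluate_loss(net, eval_images, eval_labels, mask=mask))
        preds = pred.predict_pixels(pixels, mask=mask)
        r, _ = pearson_fitness(preds, mean_responses)
        rs.append(r)
        units.append(unit_name)
        conv.W[f] = w_save
        conv.b[f] = b_save
    losses = np.array(losses)
    rs = np.array(rs)
    return LesionReport(
        units=units, loss=losses, probe_r=rs,
        loss_delta=losses - intact_loss, probe_r_delta=rs - intact_r,
        intact_loss=intact_loss, intact_probe_r=intact_r)


def lesion_vs_similarity(report: LesionReport,
                         cat_r2: dict[str, dict[str, float]]):
    """R^2 between each lesion score and each category-similarity vector.

    Units missing from the similarity table (dead filters) are skipped;
    zero-variance similarity vectors are reported as None.
    """
    units = [u for u in report.units if u in cat_r2]
    idx = [report.units.index(u) for u in units]
    out: dict[str, dict[str, float | None]] = {}
    for score_name, vec in (("loss_delta", report.loss_delta),
                            ("probe_r_delta", report.probe_r_delta)):
        out[score_name] = {}
        sv = vec[idx]
        for cat in PREDICTOR_CATEGORIES:
            cs = np.array([cat_r2[u][cat] for u in units])
            if cs.std() == 0 or sv.std() == 0:
                out[score_name][cat] = None
            else:
                out[score_name][cat] = float(np.corrcoef(sv, cs)[0, 1]) ** 2
    return out
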