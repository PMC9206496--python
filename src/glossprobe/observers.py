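"""Synthetic observers and response-consistency statistics.

Real binary responses can be loaded from CSV (columns observer_id,
image_id, row, col, category, response).  The simulator generates
idiosyncratic per-observer behavior: each observer's probability of
calling a probe a highlight follows a logistic mixture of normalized
ground-truth specularity and threshold-relative intensity, with a
per-observer bias, multiplicative weight jitter, and a lapse rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .probes import ProbeSet, probe_values
from .threshold import ThresholdModel

RESPONSE_COLUMNS = ["observer_id", "image_id", "row", "col", "category", "response"]


@dataclass
class ObserverParams:
    """Generative parameters for the synthetic observer population.

    Each observer responds "highlight" with probability
    ``lapse/2 + (1-lapse) * sigmoid(w_gt*j_o*g + w_int*j_o*z + w_ctx*j_o*c
    + b_o)`` where ``g`` is visibility-gated normalized ground-truth
    specularity (humans miss highlights sitting on dark shading), ``z`` is
    soft threshold-relative intensity, ``c`` is local contrast pop-out
    (bright pixels standing out from their neighborhood read as
    highlights), ``b_o ~ N(bias_mean, bias_sd)`` and ``j_o`` is a
    multiplicative weight jitter.  Defaults are calibrated so the
    mean-response pattern over probe categories is a > b ~ c > d and
    neither ground truth nor the threshold model alone explains responses.
    """

    w_gt: float = 1.2
    w_int: float = 2.6
    w_ctx: float = 1.5
    bias_mean: float = -2.6
    bias_sd: float = 0.7
    weight_jitter_sd: float = 0.25
    lapse: float = 0.05
    n_observers: int = 15
    seed: int = 0
    gt_scale: float = 0.5          # g saturates at gt >= gt_scale
    vis_midpoint: float = 0.88     # visibility gate on pixel intensity
    vis_slope: float = 12.0        # 0 disables the gate
    z_slope: float = 8.0
    z_offset: float = 0.12         # shifts the soft cut below the threshold
    ctx_window: int = 7            # local pop-out neighborhood (pixels)
    ctx_scale: float = 3.0         # pop-out z-scores saturating at this value

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def local_popout(image: np.ndarray, window: int = 7,
                 scale: float = 3.0) -> np.ndarray:
    """Local contrast pop-out: neighborhood z-score clipped to [0, 1]."""
    from scipy import ndimage

    img = np.asarray(image, dtype=np.float64)
    m = ndimage.uniform_filter(img, window)
    sq = ndimage.uniform_filter(img * img, window)
    sd = np.sqrt(np.maximum(sq - m * m, 0.0))
    return np.clip((img - m) / (sd + 0.05) / scale, 0.0, 1.0)


def probe_features(probe_set: ProbeSet, catalog, model: ThresholdModel,
                   params: ObserverParams | None = None):
    """(g, z, c): gated normalized specularity, threshold-relative
    intensity, and local contrast pop-out at the probe pixels."""
    if params is None:
        params = ObserverParams()
    ids = probe_set.image_ids()
    gt = probe_values(probe_set, {i: catalog[i].components.specular
                                  for i in ids})
    x = probe_values(probe_set, {i: catalog[i].image for i in ids})
    c = probe_values(probe_set, {i: local_popout(catalog[i].image,
                                                 params.ctx_window,
                                                 params.ctx_scale)
                                 for i in ids})
    g = np.minimum(1.0, gt / params.gt_scale) if params.gt_scale > 0 else gt
    if params.vis_slope > 0:
        g = g * _sigmoid(params.vis_slope * (x - params.vis_midpoint))
    z = _sigmoid(params.z_slope * (x - (model.threshold - params.z_offset)))
    return g, z, c


def simulate_observers(probe_set: ProbeSet, catalog, model: ThresholdModel,
                       params: ObserverParams) -> pd.DataFrame:
    """Seeded Bernoulli responses for every (observer, probe) pair."""
    for p in probe_set.probes:
        if p.image_id >= len(catalog):
            raise KeyError(f"probe references image {p.image_id} not in catalog")
    g_tilde, z, ctx = probe_features(probe_set, catalog, model, params)
    rng = np.random.default_rng(params.seed)
    rows = []
    for o in range(params.n_observers):
        bias = rng.normal(params.bias_mean, params.bias_sd)
        jitter = max(0.05, rng.normal(1.0, params.weight_jitter_sd))
        p1 = params.lapse / 2.0 + (1.0 - params.lapse) * _sigmoid(
            params.w_gt * jitter * g_tilde + params.w_int * jitter * z
            + params.w_ctx * jitter * ctx + bias)
        resp = (rng.random(len(probe_set)) < p1).astype(int)
        for probe, r in zip(probe_set.probes, resp):
            rows.append((o, probe.image_id, probe.row, probe.col,
                         probe.category, int(r)))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def load_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response CSV missing columns: {sorted(missing)}")
    return df


def response_matrix(table: pd.DataFrame, probe_set: ProbeSet) -> np.ndarray:
    """(n_observers, n_probes) 0/1 matrix in probe order."""
    key = {(p.image_id, p.row, p.col): i for i, p in enumerate(probe_set.probes)}
    observers = sorted(table["observer_id"].unique())
    out = np.full((len(observers), len(probe_set)), -1, dtype=int)
    omap = {o: i for i, o in enumerate(observers)}
    for row in table.itertuples():
        j = key.get((row.image_id, row.row, row.col))
        if j is not None:
            out[omap[row.observer_id], j] = row.response
    if (out < 0).any():
        raise ValueError("response table does not cover every probe")
    return out


def mean_responses(table: pd.DataFrame, probe_set: ProbeSet) -> np.ndarray:
    return response_matrix(table, probe_set).mean(axis=0)


def split_half_observer_correlation(table: pd.DataFrame, probe_set: ProbeSet,
                                    n_iter: int = 10_000, seed: int = 0):
    """Split observers in half repeatedly; correlate half-mean responses.

    Returns (correlations, n_excluded) where excluded iterations had a
    zero-variance half mean.
    """
    mat = response_matrix(table, probe_set)
    n_obs = mat.shape[0]
    if n_obs < 4:
        raise ValueError("need at least 4 observers for split-half analysis")
    rng = np.random.default_rng(seed)
    half = n_obs // 2
    rs, excluded = [], 0
    for _ in range(n_iter):
        perm = rng.permutation(n_obs)
        m1 = mat[perm[:half]].mean(axis=0)
        m2 = mat[perm[half:]].mean(axis=0)
        if m1.std() == 0 or m2.std() == 0:
            excluded += 1
            continue
        rs.append(float(np.corrcoef(m1, m2)[0, 1]))
    return np.array(rs), excluded


@dataclass
class ConsistencyReport:
    intra_rate: float
    inter_rate: float
    intra_by_observer: np.ndarray
    inter_by_observer: np.ndarray
    t_statistic: float
    p_value: float
    dof: int
    cohens_d: float
    n_iter: int
    dropped_cells: int


def _comparability_cells(probe_set: ProbeSet, catalog) -> dict:
    """Group probe indices by (category, texture family, surface scale)."""
    cells: dict = {}
    for i, p in enumerate(probe_set.probes):
        rec = catalog[p.image_id]
        key = (p.category, rec.texture_family, rec.scene.scale_level)
        cells.setdefault(key, []).append(i)
    return cells


def rater_consistency(table: pd.DataFrame, probe_set: ProbeSet, catalog,
                      n_iter: int = 1000, seed: int = 0) -> ConsistencyReport:
    """Intra- vs inter-rater agreement over comparable-pixel pairings.

    Each iteration splits every comparability cell in half at random and
    pairs probes across the halves.  Intra-rater agreement is an
    observer's self-agreement across paired probes; inter-rater agreement
    compares an observer's first-half responses to every other observer's
    second-half responses.  A paired t-test and Cohen's d summarize the
    per-observer mean difference.
    """
    mat = response_matrix(table, probe_set)
    n_obs = mat.shape[0]
    cells = _comparability_cells(probe_set, catalog)
    usable = {k: v for k, v in cells.items() if len(v) >= 2}
    dropped = len(cells) - len(usable)
    if not usable:
        raise ValueError("no comparability cell holds >= 2 probes")
    rng = np.random.default_rng(seed)

    intra = np.zeros((n_iter, n_obs))
    inter = np.zeros((n_iter, n_obs))
    for it in range(n_iter):
        first, second = [], []
        for idxs in usable.values():
            perm = rng.permutation(len(idxs))
            half = len(idxs) // 2
            for a, b in zip(perm[:half], perm[half:2 * half]):
                first.append(idxs[a])
                second.append(idxs[b])
        f = np.array(first)
        s = np.array(second)
        r1 = mat[:, f]          # (n_obs, n_pairs)
        r2 = mat[:, s]
        intra[it] = (r1 == r2).mean(axis=1)
        agree = (r1[:, None, :] == r2[None, :, :]).mean(axis=2)  # (o, o')
        off = ~np.eye(n_obs, dtype=bool)
        inter[it] = np.array([agree[o, off[o]].mean() for o in range(n_obs)])

    intra_o = intra.mean(axis=0)
    inter_o = inter.mean(axis=0)
    diff = intra_o - inter_o
    sd = diff.std(ddof=1)
    if sd == 0:
        tstat, pval, d = np.nan, np.nan, np.nan
    else:
        tstat, pval = stats.ttest_rel(intra_o, inter_o)
        d = diff.mean() / sd
    return ConsistencyReport(
        intra_rate=float(intra_o.mean()), inter_rate=float(inter_o.mean()),
        intra_by_observer=intra_o, inter_by_observer=inter_o,
        t_statistic=float(tstat), p_value=float(pval), dof=n_obs - 1,
        cohens_d=float(d), n_iter=n_iter, dropped_cells=dropped)
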