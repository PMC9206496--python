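"""Multi-scale tiered convolutional highlight detector (pure NumPy).

Architecture: seven parallel processing scales (input resampled to 1/1
... 1/64 size in powers of two) across three tiers of 3x3 convolutional
layers with eight filters each.  Between tiers, every scale's output is
resampled to every other scale and concatenated, so each layer in the
next tier sees all seven scales (56 input channels).  A fourth,
full-scale eight-filter tier and a single-filter output layer produce a
per-pixel prediction squashed into (0, 1).

The 2 x 7 x 7 = 98 inter-tier connections (tier 1->2 and 2->3) can be
switched off by a binary mask without touching the trained weights:
masked source blocks contribute zeros to the destination concatenation.

Forward and backward passes are hand-written (no autodiff dependency);
downscaling is area averaging, upscaling is bilinear, both expressed as
separable linear maps so gradients are exact transposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_SCALES = 7
N_FILTERS = 8
MASKABLE_GAPS = 2
MASK_LENGTH = MASKABLE_GAPS * N_SCALES * N_SCALES  # 98


class MaskError(ValueError):
    pass


def mask_index(gap: int, src: int, dst: int) -> int:
    """Flat index of the (tier gap, source scale, destination scale) bit."""
    return gap * N_SCALES * N_SCALES + src * N_SCALES + dst


def full_mask() -> np.ndarray:
    return np.ones(MASK_LENGTH, dtype=np.uint8)


def _check_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != (MASK_LENGTH,):
        raise MaskError(f"connection mask must have length {MASK_LENGTH}, "
                        f"got shape {mask.shape}")
    return mask.astype(np.float32)


# ---------------------------------------------------------------------------
# Resampling (separable linear maps)
# ---------------------------------------------------------------------------

_UP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _up_matrix(n_in: int, factor: int) -> np.ndarray:
    """Bilinear upscale matrix (n_in*factor, n_in), align_corners=False."""
    key = (n_in, factor)
    if key not in _UP_CACHE:
        n_out = n_in * factor
        src = (np.arange(n_out) + 0.5) / factor - 0.5
        i0 = np.floor(src).astype(int)
        frac = src - i0
        i0c = np.clip(i0, 0, n_in - 1)
        i1c = np.clip(i0 + 1, 0, n_in - 1)
        U = np.zeros((n_out, n_in), dtype=np.float32)
        U[np.arange(n_out), i0c] += (1.0 - frac).astype(np.float32)
        U[np.arange(n_out), i1c] += frac.astype(np.float32)
        _UP_CACHE[key] = U
    return _UP_CACHE[key]


def downscale(x: np.ndarray, factor: int) -> np.ndarray:
    """Area-average pooling by an integer factor over the last two axes."""
    if factor == 1:
        return x
    *lead, h, w = x.shape
    y = x.reshape(*lead, h // factor, factor, w // factor, factor)
    return y.mean(axis=(-1, -3))


def downscale_backward(g: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return g
    g = np.repeat(np.repeat(g, factor, axis=-2), factor, axis=-1)
    return g / (factor * factor)


def upscale(x: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear upscale by an integer factor over the last two axes."""
    if factor == 1:
        return x
    U = _up_matrix(x.shape[-1], factor)
    y = np.einsum("oi,...ij->...oj", U, x)
    return np.einsum("pj,...oj->...op", U, y)


def upscale_backward(g: np.ndarray, factor: int, n_in: int) -> np.ndarray:
    if factor == 1:
        return g
    U = _up_matrix(n_in, factor)
    t = np.einsum("oi,...op->...ip", U, g)
    return np.einsum("pj,...ip->...ij", U, t)


def resample(x: np.ndarray, src_scale: int, dst_scale: int) -> np.ndarray:
    if dst_scale >= src_scale:
        return downscale(x, 2 ** (dst_scale - src_scale))
    return upscale(x, 2 ** (src_scale - dst_scale))


def resample_backward(g: np.ndarray, src_scale: int, dst_scale: int,
                      src_size: int) -> np.ndarray:
    if dst_scale >= src_scale:
        return downscale_backward(g, 2 ** (dst_scale - src_scale))
    return upscale_backward(g, 2 ** (src_scale - dst_scale), src_size)


# ---------------------------------------------------------------------------
# 3x3 convolution ("same" zero padding)
# ---------------------------------------------------------------------------

class Conv3x3:
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_channels * 9))
        self.W = rng.normal(0.0, std, size=(out_channels, in_channels, 3, 3)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x_pad: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = np.broadcast_to(self.b.reshape(1, -1, 1, 1), (n, self.W.shape[0], h, w)).copy()
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di:di + h, dj:dj + w]
                y += np.tensordot(xs, self.W[:, :, di, dj], axes=([1], [1])
                                  ).transpose(0, 3, 1, 2)
        if keep:
            self._x_pad = xp
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._x_pad
        n, o, h, w = g.shape
        gx = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di:di + h, dj:dj + w]
                self.gW[:, :, di, dj] += np.tensordot(
                    g, xs, axes=([0, 2, 3], [0, 2, 3]))
                gx[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    g, self.W[:, :, di, dj], axes=([1], [0])).transpose(0, 3, 1, 2)
        self.gb += g.sum(axis=(0, 2, 3))
        self._x_pad = None
        return gx[:, :, 1:-1, 1:-1]

    def zero_grad(self) -> None:
        self.gW[:] = 0
        self.gb[:] = 0


def _relu(x):
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    image_size: int = 256
    n_scales: int = N_SCALES
    filters_per_layer: int = N_FILTERS
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 50

    def __post_init__(self) -> None:
        if self.image_size % (2 ** (self.n_scales - 1)) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by "
                f"{2 ** (self.n_scales - 1)}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("image_size", "n_scales", "filters_per_layer", "seed",
                 "learning_rate", "batch_size", "epochs")}


class MultiScaleNet:
    """Four tiers of parallel 3x3 conv layers over a 7-scale pyramid."""

    def __init__(self, config: NetConfig):
        self.config = config
        S, F = config.n_scales, config.filters_per_layer
        root = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
        seeds = root.spawn(3 * S + 2)
        it = iter(seeds)
        self.tier1 = [Conv3x3(1, F, np.random.default_rng(next(it))) for _ in range(S)]
        self.tier2 = [Conv3x3(S * F, F, np.random.default_rng(next(it))) for _ in range(S)]
        self.tier3 = [Conv3x3(S * F, F, np.random.default_rng(next(it))) for _ in range(S)]
        self.tier4 = Conv3x3(S * F, F, np.random.default_rng(next(it)))
        self.out = Conv3x3(F, 1, np.random.default_rng(next(it)))
        # start the output near the logit of the sparse positive rate so
        # early epochs need not learn the base rate
        self.out.b[:] = -3.0

    # -- bookkeeping --------------------------------------------------------

    def layers(self):
        S = self.config.n_scales
        for s in range(S):
            yield f"tier1/scale{s}", self.tier1[s]
        for s in range(S):
            yield f"tier2/scale{s}", self.tier2[s]
        for s in range(S):
            yield f"tier3/scale{s}", self.tier3[s]
        yield "tier4", self.tier4
        yield "output", self.out

    def filters(self):
        """Every convolutional filter as (unit_name, conv, filter_index)."""
        for name, conv in self.layers():
            for f in range(conv.W.shape[0]):
                yield f"{name}/f{f}", conv, f

    def count_filters(self) -> int:
        return sum(1 for _ in self.filters())

    def count_parameters(self) -> int:
        return sum(conv.n_params for _, conv in self.layers())

    def parameters(self):
        for _, conv in self.layers():
            yield conv

    # -- forward ------------------------------------------------------------

    def tier1_outputs(self, x: np.ndarray, keep: bool = False) -> list[np.ndarray]:
        """Rectified tier-1 outputs per scale; genome/mask independent."""
        S = self.config.n_scales
        outs = []
        for s in range(S):
            pyr = downscale(x, 2 ** s)
            outs.append(_relu(self.tier1[s].forward(pyr, keep=keep)))
        return outs

    def _gap(self, prev: list[np.ndarray], convs, mask, gap: int,
             keep: bool = False):
        """One masked inter-tier gap: resample-all, concat, conv, relu."""
        S = self.config.n_scales
        F = self.config.filters_per_layer
        outs, concats = [], []
        for d in range(S):
            blocks = []
            for s in range(S):
                blk = resample(prev[s], s, d)
                if mask is not None:
                    bit = mask[mask_index(gap, s, d)]
                    if bit == 0.0:
                        blk = np.zeros_like(blk)
                    elif bit != 1.0:
                        blk = blk * bit
                blocks.append(blk)
            cin = np.concatenate(blocks, axis=1)
            outs.append(_relu(convs[d].forward(cin, keep=keep)))
            if keep:
                concats.append(cin)
        return outs, concats

    def forward(self, x: np.ndarray, mask=None, keep: bool = False):
        """Return (logits, cache).  ``x`` is (N, 1, H, W) in [0, 1]."""
        if mask is not None:
            mask = _check_mask(mask)
        t1 = self.tier1_outputs(x, keep=keep)
        return self._forward_from_tier1(t1, mask, keep, x=x)

    def _forward_from_tier1(self, t1, mask, keep=False, x=None):
        S = self.config.n_scales
        t2, c2 = self._gap(t1, self.tier2, mask, gap=0, keep=keep)
        t3, c3 = self._gap(t2, self.tier3, mask, gap=1, keep=keep)
        blocks4 = [resample(t3[s], s, 0) for s in range(S)]
        c4 = np.concatenate(blocks4, axis=1)
        t4 = _relu(self.tier4.forward(c4, keep=keep))
        z = self.out.forward(t4, keep=keep)
        cache = {"x": x, "t1": t1, "t2": t2, "t3": t3, "t4": t4,
                 "c2": c2, "c3": c3, "c4": c4, "mask": mask} if keep else None
        return z, cache

    def predict(self, image: np.ndarray, mask=None) -> np.ndarray:
        """Sigmoid prediction map for a single 2-D image (or (N,1,H,W))."""
        single = image.ndim == 2
        x = image[np.newaxis, np.newaxis].astype(np.float32) if single \
            else image.astype(np.float32)
        z, _ = self.forward(x, mask=mask)
        p = 1.0 / (1.0 + np.exp(-z))
        return p[0, 0] if single else p

    def predict_from_tier1(self, t1, mask=None) -> np.ndarray:
        if mask is not None:
            mask = _check_mask(mask)
        z, _ = self._forward_from_tier1(t1, mask)
        return 1.0 / (1.0 + np.exp(-z))

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, dz: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        S = self.config.n_scales
        F = self.config.filters_per_layer
        mask = cache["mask"]
        g = self.out.backward(dz)
        g = g * (cache["t4"] > 0)
        g = self.tier4.backward(g)
        # split tier-4 input gradient back to tier-3 scales
        gt3 = []
        for s in range(S):
            blk = g[:, s * F:(s + 1) * F]
            gt3.append(resample_backward(blk, s, 0, cache["t3"][s].shape[-1]))
        gt2 = self._gap_backward(gt3, cache["t3"], cache["t2"], self.tier3,
                                 mask, gap=1)
        gt1 = self._gap_backward(gt2, cache["t2"], cache["t1"], self.tier2,
                                 mask, gap=0)
        for s in range(S):
            g = gt1[s] * (cache["t1"][s] > 0)
            self.tier1[s].backward(g)

    def _gap_backward(self, gout, tier_out, prev_out, convs, mask, gap):
        S = self.config.n_scales
        F = self.config.filters_per_layer
        gprev = [np.zeros_like(p) for p in prev_out]
        for d in range(S):
            g = gout[d] * (tier_out[d] > 0)
            gc = convs[d].backward(g)
            for s in range(S):
                bit = 1.0 if mask is None else float(mask[mask_index(gap, s, d)])
                if bit == 0.0:
                    continue
                blk = gc[:, s * F:(s + 1) * F]
                gprev[s] += bit * resample_backward(
                    blk, s, d, prev_out[s].shape[-1])
        return gprev

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, conv in self.layers():
            out[f"{name}/W"] = conv.W
            out[f"{name}/b"] = conv.b
        return out

    def save(self, path) -> None:
        arrays = {k.replace("/", "__"): v for k, v in self.state_arrays().items()}
        np.savez(path, __config__=json.dumps(self.config.to_dict()), **arrays)

    @classmethod
    def load(cls, path) -> "MultiScaleNet":
        data = np.load(path, allow_pickle=False)
        config = NetConfig(**json.loads(str(data["__config__"])))
        net = cls(config)
        for name, conv in net.layers():
            conv.W = data[f"{name}/W".replace("/", "__")].copy()
            conv.b = data[f"{name}/b".replace("/", "__")].copy()
        return net


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


class Adam:
    def __init__(self, net: MultiScaleNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.parameters()]
        self.v = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.parameters()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for conv, (mW, mb), (vW, vb) in zip(self.net.parameters(), self.m, self.v):
            for p, g, m, v in ((conv.W, conv.gW, mW, vW), (conv.b, conv.gb, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for conv in self.net.parameters():
            conv.zero_grad()


@dataclass
class TrainingLog:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            for e, tr, vl in zip(self.epochs, self.train_loss, self.val_loss):
                fh.write(f"{e},{tr},{vl}\n")


def evaluate_loss(net: MultiScaleNet, images, labels, mask=None,
                  batch_size: int = 16) -> float:
    total, count = 0.0, 0
    for i in range(0, len(images), batch_size):
        x = np.stack([im for im in images[i:i + batch_size]])[:, None].astype(np.float32)
        y = np.stack([lb for lb in labels[i:i + batch_size]])[:, None].astype(np.float32)
        z, _ = net.forward(x, mask=mask)
        total += bce_with_logits(z, np.clip(y, 0.0, 1.0)) * x.shape[0]
        count += x.shape[0]
    return total / count


def train_network(net: MultiScaleNet, images, labels,
                  val_images=None, val_labels=None,
                  epochs: int | None = None, batch_size: int | None = None,
                  learning_rate: float | None = None, seed: int = 0,
                  lr_decay_epoch: int | None = None, lr_decay: float = 0.5,
                  ema_decay: float | None = None,
                  verbose: bool = False) -> TrainingLog:
    """Adam + per-pixel BCE against specular maps (labels clipped to [0,1]).

    ``lr_decay_epoch`` multiplies the learning rate by ``lr_decay`` from
    that epoch on.  ``ema_decay`` maintains a Polyak average of the
    weights, copied into the network after the last epoch (smooths the
    tail of short schedules).
    """
    cfg = net.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    opt = Adam(net, lr=lr)
    rng = np.random.default_rng(seed)
    n = len(images)
    log = TrainingLog()
    shadow = None
    if ema_decay is not None:
        shadow = [(c.W.copy(), c.b.copy()) for c in net.parameters()]
    for epoch in range(epochs):
        if lr_decay_epoch is not None and epoch == lr_decay_epoch:
            opt.lr *= lr_decay
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            x = np.stack([images[j] for j in idx])[:, None].astype(np.float32)
            y = np.clip(np.stack([labels[j] for j in idx])[:, None], 0.0, 1.0
                        ).astype(np.float32)
            z, cache = net.forward(x, keep=True)
            loss = bce_with_logits(z, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {i // batch_size}")
            p = 1.0 / (1.0 + np.exp(-z))
            dz = (p - y) / z.size
            opt.zero_grad()
            net.backward(cache, dz.astype(np.float32))
            opt.step()
            if shadow is not None:
                for conv, (sW, sb) in zip(net.parameters(), shadow):
                    sW *= ema_decay
                    sW += (1.0 - ema_decay) * conv.W
                    sb *= ema_decay
                    sb += (1.0 - ema_decay) * conv.b
            epoch_loss += loss * len(idx)
            seen += len(idx)
        vl = np.nan
        if val_images is not None:
            vl = evaluate_loss(net, val_images, val_labels, batch_size=batch_size)
        log.epochs.append(epoch)
        log.train_loss.append(epoch_loss / seen)
        log.val_loss.append(vl)
        if verbose:
            print(f"epoch {epoch}: train {epoch_loss / seen:.4f} val {vl:.4f}")
    if shadow is not None:
        for conv, (sW, sb) in zip(net.parameters(), shadow):
            conv.W = sW
            conv.b = sb
    return log


# ---------------------------------------------------------------------------
# Cached probe prediction (for the pruning search)
# ---------------------------------------------------------------------------

class ProbePredictor:
    """Caches tier-1 outputs per image; evaluates masked predictions.

    Tier-1 activity does not depend on the connection mask, so it is
    computed once per image; per-genome evaluation reruns only tiers 2-4.
    """

    def __init__(self, net: MultiScaleNet, images):
        self.net = net
        self.images = list(images)
        self._t1 = []
        for im in self.images:
            x = im[np.newaxis, np.newaxis].astype(np.float32)
            self._t1.append(net.tier1_outputs(x))

    def predict_maps(self, mask=None, image_indices=None) -> dict[int, np.ndarray]:
        if image_indices is None:
            image_indices = range(len(self.images))
        return {i: self.net.predict_from_tier1(self._t1[i], mask=mask)[0, 0]
                for i in image_indices}

    def predict_pixels(self, pixels, mask=None) -> np.ndarray:
        """pixels: sequence of (image_index, row, col).  Only the images
        referenced by ``pixels`` are forwarded."""
        needed = sorted({i for i, _, _ in pixels})
        maps = self.predict_maps(mask=mask, image_indices=needed)
        return np.array([maps[i][r, c] for i, r, c in pixels])
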