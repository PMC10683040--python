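"""The heart-labelling network: 3D U-Net with masked multi-class Dice loss.

The network takes two input channels — the HU-windowed CT and the binary
heart mask — and emits six per-voxel class probabilities (outside-heart,
LM, LAD, LCX, RCA, other).  Training supervision is partial: the Dice loss
is evaluated over labelled voxels only, and its gradient is exactly zero
with respect to the probabilities at unlabelled voxels, so the network is
free to extrapolate perfusion territories there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ..io_volumes import CTVolume, HeartMask, RegionLabelMap
from ..labelgen import SupervisionVolume, UNLABELLED
from .layers import (Adam, Conv3d, InstanceNorm3d, MaxPool3d, Param, ReLU,
                     Sequential, Upsample3d)

N_CLASSES = 6
DICE_EPS = 1e-6


@dataclass
class NetConfig:
    """Reference tiny configuration; sized for CPU training in minutes."""

    depth: int = 2
    base_channels: int = 8
    patch_size: tuple[int, int, int] = (16, 48, 48)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 4
    steps_per_epoch: int = 30
    seed: int = 0
    hu_window: tuple[float, float] = (-200.0, 1500.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma_range: tuple[float, float] = (0.0, 15.0)
    max_shift: int = 2
    #: network working grid, as integer downsample factors per axis; the
    #: default halves the in-plane resolution (~1.4 mm at 0.7 mm voxels),
    #: still far finer than the >= 10 mm territory scale being segmented
    working_downsample: tuple[int, int, int] = (1, 2, 2)
    dtype: str = field(default="float32", repr=False)

    def __post_init__(self):
        if isinstance(self.patch_size, int):
            self.patch_size = (self.patch_size,) * 3
        self.patch_size = tuple(int(p) for p in self.patch_size)
        self.working_downsample = tuple(int(f) for f in self.working_downsample)
        if any(f < 1 for f in self.working_downsample):
            raise ValueError("working_downsample factors must be >= 1")
        div = 2 ** self.depth
        if any(p % div for p in self.patch_size):
            raise ValueError(f"patch_size {self.patch_size} not divisible by 2^depth={div}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must be (lo, hi) with lo < hi")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def normalize_input(ct: CTVolume | np.ndarray, hu_window: tuple[float, float]) -> np.ndarray:
    """Clip HU to the window and map it affinely to [0, 1]."""
    lo, hi = hu_window
    if lo >= hi:
        raise ValueError("hu_window must satisfy lo < hi")
    voxels = ct.voxels if isinstance(ct, CTVolume) else np.asarray(ct)
    return ((np.clip(voxels, lo, hi) - lo) / (hi - lo)).astype(np.float32)


class UNet3D:
    """Encoder-decoder with skip connections, softmax over six classes."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dt = config.np_dtype
        c = config.base_channels
        d = config.depth

        def block(cin, cout):
            return Sequential(Conv3d(cin, cout, 3, rng, dt), InstanceNorm3d(cout, dt), ReLU(),
                              Conv3d(cout, cout, 3, rng, dt), InstanceNorm3d(cout, dt), ReLU())

        self.enc = []
        cin = 2
        for lvl in range(d):
            cout = c * 2 ** lvl
            self.enc.append(block(cin, cout))
            cin = cout
        self.pools = [MaxPool3d() for _ in range(d)]
        self.bottleneck = block(cin, c * 2 ** d)

        self.ups, self.reduces, self.posts = [], [], []
        cur = c * 2 ** d
        for lvl in reversed(range(d)):
            cout = c * 2 ** lvl
            self.ups.append(Upsample3d())
            self.reduces.append(Sequential(Conv3d(cur, cout, 3, rng, dt),
                                           InstanceNorm3d(cout, dt), ReLU()))
            self.posts.append(block(2 * cout, cout))
            cur = cout
        self.final = Conv3d(cur, N_CLASSES, 1, rng, dt)
        # start near-uniform class probabilities: a hot final layer makes
        # the Dice loss collapse onto the dominant background class
        self.final.W.value *= 0.1
        self._skip_channels = None

    def params(self) -> list[Param]:
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        for u, r, p in zip(self.ups, self.reduces, self.posts):
            out += r.params() + p.params()
        out += self.final.params()
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (6, B, D, H, W) for an input batch (2, B, D, H, W)."""
        skips = []
        for blockk, pool in zip(self.enc, self.pools):
            x = blockk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, red, post, skip in zip(self.ups, self.reduces, self.posts, reversed(skips)):
            x = red.forward(up.forward(x))
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = post.forward(x)
        return self.final.forward(x)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.final.backward(glogits)
        gskips = []
        for up, red, post, nskip in zip(reversed(self.ups), reversed(self.reduces),
                                        reversed(self.posts), reversed(self._skip_channels)):
            g = post.backward(g)
            gskips.append(g[:nskip])
            g = up.backward(red.backward(g[nskip:]))
        gskips.reverse()  # now ordered from deepest encoder level outwards
        g = self.bottleneck.backward(g)
        for blockk, pool, gskip in zip(reversed(self.enc), reversed(self.pools), gskips):
            g = pool.backward(g) + gskip
            g = blockk.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def build_network(config: NetConfig) -> UNet3D:
    """Construct the 3D U-Net with seeded parameter initialization."""
    return UNet3D(config)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# masked Dice loss
# ---------------------------------------------------------------------------

def masked_dice_loss(probs: np.ndarray, sup: SupervisionVolume | np.ndarray,
                     return_grad: bool = False):
    """Soft multi-class Dice loss over supervised voxels only.

    For each class c present among supervised voxels,
    ``D_c = 2 sum(p_c y_c) / (sum_sup p_c + sum y_c + eps)`` and the loss
    is ``1 - mean_c D_c``.  Probabilities at unsupervised voxels do not
    enter the loss, and the returned gradient is exactly zero there.

    `probs` is ``(6, ...)`` over any trailing shape that matches `labels`
    — a single volume or a whole batch (in which case the Dice overlap is
    pooled over the batch).
    """
    labels = sup.labels if isinstance(sup, SupervisionVolume) else np.asarray(sup)
    if probs.shape[1:] != labels.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {labels.shape}")
    mask = labels != UNLABELLED
    n_sup = int(mask.sum())
    if n_sup == 0:
        raise ValueError("no supervised voxels")
    classes = np.unique(labels[mask])
    grad = np.zeros_like(probs) if return_grad else None
    k = len(classes)
    dice_sum = 0.0
    for c in classes:
        y = labels == c
        p = probs[c]
        s_py = float(p[y].sum())
        s_p = float(p[mask].sum())
        s_y = float(y.sum())
        denom = s_p + s_y + DICE_EPS
        d_c = 2.0 * s_py / denom
        dice_sum += d_c
        if return_grad:
            # d(loss)/dp_c = -(2*y - D_c)/denom / k at supervised voxels
            g = np.zeros_like(p)
            g[mask] = -(2.0 * y[mask] - d_c) / denom / k
            grad[c] = g
    loss = 1.0 - dice_sum / k
    if return_grad:
        return loss, grad
    return loss


def softmax_backward(probs: np.ndarray, gprobs: np.ndarray) -> np.ndarray:
    """Chain dL/dprobs through the per-voxel softmax to dL/dlogits."""
    inner = (gprobs * probs).sum(axis=0, keepdims=True)
    return probs * (gprobs - inner)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, labels: np.ndarray, config: NetConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random isotropic rescale, shift, and HU noise on a training pair.

    `image` is channel-first (C, D, H, W); channel 0 is the normalized CT
    (linear interpolation, noise added), remaining channels (e.g. the
    heart mask) use nearest-neighbour like the labels.  The label patch is
    transformed identically with nearest-neighbour and -1 fill, so voxels
    pulled in from outside stay unsupervised.  The draw is fully
    determined by `rng`.
    """
    scale = float(rng.uniform(*config.scale_range))
    sigma = float(rng.uniform(*config.noise_sigma_range))
    shift = rng.integers(-config.max_shift, config.max_shift + 1, size=3) \
        if config.max_shift > 0 else np.zeros(3, dtype=int)

    out_img, out_lab = image, labels
    if scale != 1.0 or np.any(shift != 0):
        center = (np.asarray(labels.shape) - 1) / 2.0
        matrix = np.eye(3) / scale
        offset = center - (center + shift) / scale
        chans = [
            ndimage.affine_transform(image[ch], matrix, offset=offset,
                                     order=1 if ch == 0 else 0, mode="constant",
                                     cval=0.0, output=image.dtype)
            for ch in range(image.shape[0])
        ]
        out_img = np.stack(chans)
        out_lab = ndimage.affine_transform(labels, matrix, offset=offset, order=0,
                                           mode="constant", cval=UNLABELLED,
                                           output=labels.dtype)
    if sigma > 0:
        lo, hi = config.hu_window
        out_img = out_img.copy()
        out_img[0] = out_img[0] + rng.normal(0.0, sigma / (hi - lo), size=out_img[0].shape
                                             ).astype(out_img.dtype)
    return out_img, out_lab


# ---------------------------------------------------------------------------
# working-grid resampling
# ---------------------------------------------------------------------------

def _pad_to_multiple(arr: np.ndarray, factors, cval=None) -> np.ndarray:
    dims = arr.shape[-3:]
    pad = [(0, (-d) % f) for d, f in zip(dims, factors)]
    if not any(p[1] for p in pad):
        return arr
    full = [(0, 0)] * (arr.ndim - 3) + pad
    if cval is None:
        return np.pad(arr, full, mode="edge")
    return np.pad(arr, full, mode="constant", constant_values=cval)


def _pool_image(x: np.ndarray, factors) -> np.ndarray:
    """Mean-pool channel-first image stack by integer factors per axis."""
    fz, fy, fx = factors
    if (fz, fy, fx) == (1, 1, 1):
        return x
    x = _pad_to_multiple(x, factors)
    c, d, h, w = x.shape
    return x.reshape(c, d // fz, fz, h // fy, fy, w // fx, fx).mean(axis=(2, 4, 6))


def _stride_labels(lab: np.ndarray, factors, cval) -> np.ndarray:
    fz, fy, fx = factors
    if (fz, fy, fx) == (1, 1, 1):
        return lab
    lab = _pad_to_multiple(lab, factors, cval=cval)
    return lab[::fz, ::fy, ::fx]


def _upsample_to(arr: np.ndarray, factors, dims) -> np.ndarray:
    fz, fy, fx = factors
    out = arr.repeat(fz, axis=-3).repeat(fy, axis=-2).repeat(fx, axis=-1)
    return out[..., :dims[0], :dims[1], :dims[2]]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare(item, config: NetConfig):
    ct, heart, sup = item
    x = np.stack([
        normalize_input(ct, config.hu_window),
        heart.voxels.astype(np.float32),
    ]).astype(config.np_dtype)
    x = _pool_image(x, config.working_downsample).astype(config.np_dtype)
    labels = _stride_labels(sup.labels, config.working_downsample, UNLABELLED)
    # patch centres are drawn class-balanced over the in-heart supervised
    # classes, so scarce territories (LM especially) anchor patches as
    # often as abundant ones and do not collapse out of the softmax
    by_class = {int(c): np.argwhere(labels == c)
                for c in np.unique(labels) if c >= 1}
    anysup = np.argwhere(labels != UNLABELLED)
    if anysup.size == 0:
        raise ValueError("training item with no supervised voxels")
    return x, labels, by_class, anysup


def _sample_patch(x, labels, by_class, anysup, config, rng):
    p = np.asarray(config.patch_size)
    dims = np.asarray(labels.shape)
    u = rng.random()
    if by_class and u < 0.5:
        cls = sorted(by_class)[rng.integers(len(by_class))]
        pool = by_class[cls]
    elif by_class and u < 0.8:
        pool = by_class[max(by_class, key=lambda c: len(by_class[c]))]
    else:
        pool = anysup
    center = pool[rng.integers(len(pool))]
    jitter = rng.integers(-4, 5, size=3)
    start = np.clip(center - p // 2 + jitter, 0, np.maximum(dims - p, 0))
    sl = tuple(slice(s, s + q) for s, q in zip(start, p))
    return x[(slice(None),) + sl], labels[sl]


def train(dataset, config: NetConfig, net: UNet3D | None = None):
    """Masked-Dice training over random supervised patches.

    Parameters
    ----------
    dataset : list of (CTVolume, HeartMask, SupervisionVolume)
    config : NetConfig
    net : UNet3D, optional
        Continue training an existing network instead of a fresh one.

    Returns
    -------
    net : UNet3D
    log : list of dict
        Per-epoch mean training loss.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    net = net or build_network(config)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1CE]))
    prepared = [_prepare(item, config) for item in dataset]
    log = []
    warmup = max(1, config.epochs // 10)
    for epoch in range(config.epochs):
        # warmup against early collapse, then step decay for the final third
        if epoch < warmup:
            opt.lr = 0.2 * config.learning_rate
        elif epoch >= (2 * config.epochs) // 3:
            opt.lr = 0.3 * config.learning_rate
        else:
            opt.lr = config.learning_rate
        losses = []
        for _ in range(config.steps_per_epoch):
            opt.zero_grad()
            xs, labs = [], []
            for _ in range(config.batch_size):
                x, labels, by_class, anysup = prepared[rng.integers(len(prepared))]
                px, plab = _sample_patch(x, labels, by_class, anysup, config, rng)
                px, plab = augment(px, plab, config, rng)
                if not np.any(plab != UNLABELLED):  # augmentation pushed labels out
                    plab = plab.copy()
                    plab[0, 0, 0] = 0
                xs.append(px)
                labs.append(plab)
            bx = np.stack(xs, axis=1).astype(config.np_dtype)  # (2, B, ...)
            blab = np.stack(labs)                              # (B, ...)
            probs = softmax(net.forward(bx))
            loss, gprobs = masked_dice_loss(probs, blab, return_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
            net.backward(softmax_backward(probs, gprobs).astype(config.np_dtype))
            opt.clip_grad_norm(5.0)
            opt.step()
            losses.append(loss)
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return net, log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _window_starts(dim: int, patch: int) -> list[int]:
    if dim <= patch:
        return [0]
    step = max(patch // 2, 1)
    starts = list(range(0, dim - patch + 1, step))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def predict(ct: CTVolume, heart: HeartMask | np.ndarray, net: UNet3D,
            config: NetConfig | None = None) -> tuple[RegionLabelMap, np.ndarray]:
    """Sliding-window inference with 50% overlap and probability averaging.

    Voxels outside the heart mask are forced to class 0 in the label map.
    """
    config = config or net.config
    heart_arr = heart.voxels if isinstance(heart, HeartMask) else np.asarray(heart)
    if heart_arr.shape != ct.voxels.shape:
        raise ValueError("CT and heart mask shapes differ")
    native_dims = ct.voxels.shape
    x = np.stack([normalize_input(ct, config.hu_window),
                  heart_arr.astype(np.float32)]).astype(config.np_dtype)
    x = _pool_image(x, config.working_downsample).astype(config.np_dtype)
    dims = np.asarray(x.shape[1:])
    p = np.asarray(config.patch_size)
    padded = np.maximum(dims, p)
    if np.any(padded != dims):
        pad = [(0, int(q - d)) for d, q in zip(dims, padded)]
        x = np.pad(x, [(0, 0)] + pad)
    probs = np.zeros((N_CLASSES, *padded), dtype=np.float64)
    counts = np.zeros(padded, dtype=np.float64)
    windows = [
        (slice(z0, z0 + p[0]), slice(y0, y0 + p[1]), slice(x0, x0 + p[2]))
        for z0 in _window_starts(padded[0], p[0])
        for y0 in _window_starts(padded[1], p[1])
        for x0 in _window_starts(padded[2], p[2])
    ]
    chunk = 8
    for i in range(0, len(windows), chunk):
        group = windows[i:i + chunk]
        bx = np.stack([x[(slice(None),) + sl] for sl in group], axis=1)
        bp = softmax(net.forward(bx))
        for j, sl in enumerate(group):
            probs[(slice(None),) + sl] += bp[:, j]
            counts[sl] += 1
    probs /= counts
    probs = probs[:, :dims[0], :dims[1], :dims[2]]
    probs = _upsample_to(probs, config.working_downsample, native_dims)
    codes = probs.argmax(axis=0).astype(np.int16)
    codes[heart_arr == 0] = 0
    return RegionLabelMap(codes, ct.spacing), probs


# ---------------------------------------------------------------------------
# weights persistence
# ---------------------------------------------------------------------------

def save_weights(net: UNet3D, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(net.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_weights(path: str | Path) -> UNet3D:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
        net = build_network(NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in cfg.items()}))
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
    return net
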