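"""Landmark-regression CNN: 13 facial points from a 40x40 RGB crop.

The architecture follows the small tweaked-CNN lineage for facial landmark
localization: a shared trunk of four 3x3 convolutional stages (16-32-64-128
channels, tanh, 2x2 max-pool after each) followed by one specialised head
per landmark — two fully connected layers (512 -> 64 -> 2) with a sigmoid
output — so every landmark owns its own regressor on top of shared
features.  The output is 13 (x, y) pairs normalised to [0, 1] by the crop
frame.  Training is plain stochastic gradient descent with batch size 1,
mean-squared-error loss on the normalised coordinates, and the Adam update
rule; per-presentation augmentation applies either a horizontal mirror
(with the bilateral landmark index swap) or a saturation jitter.

The network and its backpropagation are implemented directly on numpy —
the model is small enough (~80k parameters, a few million multiply-adds per
step) that CPU training of a full cohort takes minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.color import hsv2rgb, rgb2hsv

from .io import (
    BILATERAL_PAIRS,
    N_LANDMARKS,
    NET_INPUT_SIZE,
    FaceImage,
    LandmarkSet,
    read_image,
    resize_to_input,
)
from .synthetic import load_manifest
from . import io as oio

#: Epoch presets: program version -> training epochs.
VERSION_EPOCHS = {1: 200, 2: 1000}

_CONV_CHANNELS = (16, 32, 64, 128)
_HEAD_HIDDEN = 64
_FLAT_DIM = 128 * 2 * 2  # trunk output: 128 channels at 2x2

#: Landmark index permutation applied under a horizontal mirror.
FLIP_PERMUTATION = np.arange(N_LANDMARKS)
for _r, _l in BILATERAL_PAIRS:
    FLIP_PERMUTATION[_r], FLIP_PERMUTATION[_l] = _l, _r


class DataError(RuntimeError):
    """Empty or unusable training/evaluation split."""


@dataclass
class TrainingConfig:
    epochs: int = 200
    batch_size: int = 1              # fixed by design; larger batches rejected
    learning_rate: float = 1e-3      # Adam base step size
    lr_min_factor: float = 0.05      # cosine decay floor (fraction of base)
    weight_decay: float = 1e-2       # decoupled L2 shrinkage (x current lr)
    augment: bool = True
    flip_prob: float = 0.5           # P(mirror); otherwise saturation jitter
    saturation_range: tuple[float, float] = (0.6, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")

    @classmethod
    def for_version(cls, version: int, **kw) -> "TrainingConfig":
        if version not in VERSION_EPOCHS:
            raise ValueError(f"unknown program version {version}; use 1 or 2")
        return cls(epochs=VERSION_EPOCHS[version], **kw)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["epoch", "train_loss"] + (["val_loss"] if self.val_loss else [])
            w.writerow(header)
            for i, tl in enumerate(self.train_loss, start=1):
                row = [i, f"{tl:.8g}"]
                if self.val_loss:
                    row.append(f"{self.val_loss[i - 1]:.8g}")
                w.writerow(row)
        return path


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(np.float32)


@dataclass
class ModelHandle:
    """Trained-parameter container plus architecture descriptor."""

    params: dict[str, np.ndarray]
    architecture: dict = field(default_factory=dict)

    def describe(self) -> dict:
        return dict(self.architecture)


def build_model(config: TrainingConfig | None = None, seed: int | None = None) -> ModelHandle:
    """Initialise an untrained model (Glorot-uniform, seeded)."""
    config = config or TrainingConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    c_in = 3
    for i, c_out in enumerate(_CONV_CHANNELS, start=1):
        fan_in = c_in * 9
        params[f"W{i}"] = _glorot(rng, (c_out, fan_in), fan_in, c_out)
        params[f"b{i}"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    params["HW1"] = _glorot(
        rng, (N_LANDMARKS, _FLAT_DIM, _HEAD_HIDDEN), _FLAT_DIM, _HEAD_HIDDEN
    )
    params["Hb1"] = np.zeros((N_LANDMARKS, _HEAD_HIDDEN), dtype=np.float32)
    params["HW2"] = _glorot(
        rng, (N_LANDMARKS, _HEAD_HIDDEN, 2), _HEAD_HIDDEN, 2
    )
    params["Hb2"] = np.zeros((N_LANDMARKS, 2), dtype=np.float32)
    arch = {
        "input": [3, NET_INPUT_SIZE, NET_INPUT_SIZE],
        "conv_channels": list(_CONV_CHANNELS),
        "kernel": 3,
        "pool": 2,
        "activation": "tanh",
        "heads": N_LANDMARKS,
        "head_layers": [_FLAT_DIM, _HEAD_HIDDEN, 2],
        "output": "sigmoid, 13 (x,y) pairs in [0,1]^2",
    }
    return ModelHandle(params=params, architecture=arch)


# ---------------------------------------------------------------------------
# forward / backward primitives

def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (H*W, C*9) patch matrix for a 3x3 same-padded conv."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)


def _col2im(dcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    d = dcols.reshape(h, w, c, 3, 3)
    dxp = np.zeros((c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w] += d[:, :, :, i, j].transpose(2, 0, 1)
    return dxp[:, 1 : h + 1, 1 : w + 1]


def _pool2(a: np.ndarray):
    """2x2 max-pool with stride 2 (odd trailing row/col dropped)."""
    c, h, w = a.shape
    h2, w2 = h // 2, w // 2
    v = a[:, : 2 * h2, : 2 * w2].reshape(c, h2, 2, w2, 2)
    v = v.transpose(0, 1, 3, 2, 4).reshape(c, h2, w2, 4)
    idx = v.argmax(axis=3)
    out = np.take_along_axis(v, idx[..., None], axis=3)[..., 0]
    return out, idx, (h, w)


def _unpool2(dout: np.ndarray, idx: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    c, h2, w2 = dout.shape
    h, w = shape
    dv = np.zeros((c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dv, idx[..., None], dout[..., None], axis=3)
    dv = dv.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, 2 * h2, 2 * w2)
    da = np.zeros((c, h, w), dtype=dout.dtype)
    da[:, : 2 * h2, : 2 * w2] = dv
    return da


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _forward(params: dict[str, np.ndarray], x: np.ndarray, want_cache: bool = False):
    """x: (3, S, S) float in [0, 1] -> (13, 2) in [0, 1]; optional cache."""
    if x.shape != (3, NET_INPUT_SIZE, NET_INPUT_SIZE):
        raise ValueError(
            f"network input must be (3, {NET_INPUT_SIZE}, {NET_INPUT_SIZE}), got {x.shape}"
        )
    cache: dict = {"x": x}
    a = x
    for i in range(1, 5):
        cols = _im2col(a)
        c, h, w = a.shape
        y = cols @ params[f"W{i}"].T + params[f"b{i}"]   # (h*w, c_out)
        act = np.tanh(y)
        amap = act.T.reshape(-1, h, w)
        pooled, idx, shape = _pool2(amap)
        if want_cache:
            cache[f"cols{i}"] = cols
            cache[f"act{i}"] = amap
            cache[f"idx{i}"] = idx
            cache[f"shape{i}"] = shape
            cache[f"in_shape{i}"] = (c, h, w)
        a = pooled
    flat = a.reshape(-1)
    h1 = np.einsum("i,lio->lo", flat, params["HW1"]) + params["Hb1"]
    hact = np.tanh(h1)
    o = np.einsum("lo,loj->lj", hact, params["HW2"]) + params["Hb2"]
    out = _sigmoid(o)
    if want_cache:
        cache["flat"] = flat
        cache["hact"] = hact
        cache["out"] = out
        cache["pooled4_shape"] = a.shape
        return out, cache
    return out


def _backward(params: dict[str, np.ndarray], cache: dict,
              target: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """MSE loss and gradients for one example."""
    out = cache["out"]
    diff = out - target
    loss = float(np.mean(diff**2))
    grads: dict[str, np.ndarray] = {}

    dout = 2.0 * diff / diff.size
    do = dout * out * (1.0 - out)                       # sigmoid'
    hact = cache["hact"]
    grads["HW2"] = np.einsum("lo,lj->loj", hact, do)
    grads["Hb2"] = do
    dh = np.einsum("loj,lj->lo", params["HW2"], do)
    dh1 = dh * (1.0 - hact**2)
    flat = cache["flat"]
    grads["HW1"] = np.einsum("i,lo->lio", flat, dh1)
    grads["Hb1"] = dh1
    dflat = np.einsum("lio,lo->i", params["HW1"], dh1)

    da = dflat.reshape(cache["pooled4_shape"])
    for i in range(4, 0, -1):
        dact = _unpool2(da, cache[f"idx{i}"], cache[f"shape{i}"])
        amap = cache[f"act{i}"]
        dy = dact * (1.0 - amap**2)                     # tanh'
        c_out = dy.shape[0]
        dymat = dy.reshape(c_out, -1).T                 # (h*w, c_out)
        cols = cache[f"cols{i}"]
        grads[f"W{i}"] = dymat.T @ cols
        grads[f"b{i}"] = dymat.sum(axis=0)
        if i > 1:
            dcols = dymat @ params[f"W{i}"]
            c, h, w = cache[f"in_shape{i}"]
            da = _col2im(dcols, c, h, w)
    return loss, grads


class _Adam:
    """Adam with optional decoupled weight decay on the weight matrices."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        # bias-corrected step size folds both corrections into one scalar
        alpha = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for k, g in grads.items():
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            params[k] -= alpha * m / (np.sqrt(v) + self.eps)
            if self.wd and k[0] in "WH" and k[1] != "b":  # weights, not biases
                params[k] -= self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# augmentation

def augment(
    image: FaceImage,
    landmarks: LandmarkSet,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
    saturation_range: tuple[float, float] = (0.6, 1.4),
    force: str | None = None,
) -> tuple[FaceImage, LandmarkSet]:
    """One augmentation draw: horizontal mirror OR saturation jitter.

    A mirror maps every x to (width-1) - x and swaps the bilateral landmark
    indices so anatomical sides stay consistent.  ``force`` ("flip" |
    "saturation") bypasses the random choice, for testing.
    """
    do_flip = force == "flip" or (force is None and rng.random() < flip_prob)
    if do_flip:
        pixels = image.pixels[:, ::-1].copy()
        pts = landmarks.points[FLIP_PERMUTATION].copy()
        pts[:, 0] = (image.width - 1) - pts[:, 0]
        return FaceImage(pixels, id=image.id), LandmarkSet(pts, landmarks.frame)
    factor = rng.uniform(*saturation_range)
    hsv = rgb2hsv(image.pixels)
    hsv[..., 1] = np.clip(hsv[..., 1] * factor, 0.0, 1.0)
    pixels = np.clip(hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
    return FaceImage(pixels, id=image.id), LandmarkSet(
        landmarks.points.copy(), landmarks.frame
    )


# ---------------------------------------------------------------------------
# training / inference

def _load_split(manifest: dict, split: str):
    """Resized 40x40 training pairs (uint8 image, landmark px at 40 scale)."""
    root = Path(manifest["_root"])
    ann = {r.image_id: r for r in oio.read_annotations(root / manifest["annotations"])}
    pairs = []
    for entry in manifest["images"]:
        if entry["split"] != split:
            continue
        img = read_image(root / entry["image"])
        rec = ann[entry["id"]]
        small, lms = resize_to_input(img, rec.landmarks)
        pairs.append((entry["id"], small, lms))
    return pairs


def train(
    model: ModelHandle,
    manifest: dict | str | Path,
    config: TrainingConfig,
    val_split: str | None = None,
) -> tuple[ModelHandle, TrainingHistory]:
    """Train in place: epochs x n single-example Adam steps.

    Each epoch presents every training image once in a shuffled order, with
    an independent augmentation draw per presentation.  Fully seeded: the
    same seed and data give a bit-identical model (run single-threaded for
    strict reproducibility).
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    pairs = _load_split(manifest, "train")
    if not pairs:
        raise DataError("training split is empty")
    val_pairs = _load_split(manifest, val_split) if val_split else []

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate,
                weight_decay=config.weight_decay)
    history = TrainingHistory()
    s = float(NET_INPUT_SIZE)

    # cosine learning-rate decay over epochs: batch-size-1 updates leave a
    # high stochastic noise floor at a constant step size
    base_lr, floor = config.learning_rate, config.lr_min_factor
    for _epoch in range(config.epochs):
        frac = _epoch / max(config.epochs - 1, 1)
        opt.lr = base_lr * (floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * frac)))
        order = rng.permutation(len(pairs))
        losses = np.empty(len(pairs))
        for k, j in enumerate(order):
            _sid, img, lms = pairs[j]
            if config.augment:
                img, lms = augment(
                    img, lms, rng, config.flip_prob, config.saturation_range
                )
            x = img.pixels.astype(np.float32).transpose(2, 0, 1) / np.float32(255.0)
            target = (lms.points / s).astype(np.float32)
            _out, cache = _forward(model.params, x, want_cache=True)
            loss, grads = _backward(model.params, cache, target)
            opt.step(model.params, grads)
            losses[k] = loss
        history.train_loss.append(float(losses.mean()))
        if val_pairs:
            vloss = []
            for _sid, img, lms in val_pairs:
                x = img.pixels.astype(np.float32).transpose(2, 0, 1) / np.float32(255.0)
                out = _forward(model.params, x)
                vloss.append(float(np.mean((out - lms.points / s) ** 2)))
            history.val_loss.append(float(np.mean(vloss)))
    return model, history


def predict(
    model: ModelHandle, image: FaceImage, crop_frame: tuple[int, int] | int | None = None
) -> LandmarkSet:
    """Predict the 13 landmarks of a face-centred crop.

    The image is resized to the 40x40 network input; the normalised output
    pairs are rescaled to ``crop_frame`` (default: the image's own frame).
    """
    if crop_frame is None:
        crop_frame = (image.width, image.height)
    elif isinstance(crop_frame, int):
        crop_frame = (crop_frame, crop_frame)
    small = resize_to_input(image)
    x = small.pixels.astype(np.float32).transpose(2, 0, 1) / np.float32(255.0)
    out = _forward(model.params, x)
    pts = out * np.array(crop_frame, dtype=np.float64)
    return LandmarkSet(pts, crop_frame)


def evaluate(
    model: ModelHandle, manifest: dict | str | Path, split: str = "test"
) -> dict:
    """Landmark error normalised by the true intercanthal distance.

    Returns per-landmark mean normalised errors (keyed by landmark name),
    the grand mean over landmarks and images, and the subject count.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    root = Path(manifest["_root"])
    ann = {r.image_id: r for r in oio.read_annotations(root / manifest["annotations"])}
    entries = [e for e in manifest["images"] if e["split"] == split]
    if not entries:
        raise DataError(f"split {split!r} is empty")
    errs = np.zeros((len(entries), N_LANDMARKS))
    for i, entry in enumerate(entries):
        img = read_image(root / entry["image"])
        truth = ann[entry["id"]].landmarks
        pred = predict(model, img, truth.frame)
        icd = float(np.linalg.norm(truth.points[9] - truth.points[10]))
        errs[i] = np.linalg.norm(pred.points - truth.points, axis=1) / icd
    per_landmark = errs.mean(axis=0)
    return {
        "per_landmark": {
            name: float(v) for name, v in zip(oio.LANDMARK_NAMES, per_landmark)
        },
        "mean_normalized_error": float(errs.mean()),
        "n_images": len(entries),
    }


# ---------------------------------------------------------------------------
# checkpoints

_CHECKPOINT_VERSION = 1


def save_model(model: ModelHandle, path: str | Path) -> Path:
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        __version__=np.array(_CHECKPOINT_VERSION),
        __architecture__=np.frombuffer(
            json.dumps(model.architecture).encode(), dtype=np.uint8
        ),
        **model.params,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> ModelHandle:
    import json

    with np.load(path) as data:
        version = int(data["__version__"])
        if version != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        arch = json.loads(bytes(data["__architecture__"]).decode())
        params = {
            k: data[k] for k in data.files if not k.startswith("__")
        }
    return ModelHandle(params=params, architecture=arch)
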