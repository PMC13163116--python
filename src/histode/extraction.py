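"""Transfer-learning style deep-feature extraction.

A frozen convolutional backbone maps a 224×224×3 image to a 576-channel
feature map h; global average pooling (GAP) collapses h to a 576-vector z;
a trainable two-layer head expands and re-compresses the representation:

    z1 = ReLU(BN(W1 z + b1)),  W1 ∈ R^{1536×576},  dropout p = 0.3
    z2 = ReLU(BN(W2 z1 + b2)), W2 ∈ R^{1024×1536}, dropout p = 0.3
    ŷ  = Softmax(W3 z2 + b3),  W3 ∈ R^{C×1024}

Only the head is trained (10 epochs, Adam, cross-entropy); the backbone
parameters never change, which a checksum verifies.  After training, the
1024-dimensional penultimate representation z2 (evaluation mode, dropout
off) is exported as the feature vector for downstream selection and
classification.

The backbone ships with seeded He-initialized random weights so the full
pipeline runs self-contained; ImageNet-pretrained weights are not bundled
(a saved extractor checkpoint can be loaded instead).  Everything is plain
NumPy: forward, backward (including batch-norm gradients) and Adam are
implemented here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DecodeError, InvalidConfigError, InvalidDatasetError
from .io import FeatureMatrix

__all__ = [
    "ExtractionConfig",
    "Extractor",
    "preprocess_image",
    "global_average_pool",
    "forward_head",
    "train_head",
    "extract_features",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ExtractionConfig:
    """Geometry and training schedule of the extractor."""

    input_side: int = 224
    channels: int = 3
    backbone_out_channels: int = 576
    hidden_dim: int = 1536
    feature_dim: int = 1024
    n_classes: int = 2
    dropout_p: float = 0.3
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    freeze_backbone: bool = True
    pretrained: bool = False
    normalization_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalization_std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0

    def validate(self) -> None:
        if not self.feature_dim < self.hidden_dim:
            raise InvalidConfigError("feature_dim must be < hidden_dim")
        if not 0.0 <= self.dropout_p < 1.0:
            raise InvalidConfigError("dropout_p must be in [0, 1)")
        if self.input_side < 32:
            raise InvalidConfigError("input_side must be >= 32")
        if self.pretrained:
            raise InvalidConfigError(
                "pretrained backbone weights are not bundled; "
                "set pretrained=False or load a saved extractor checkpoint"
            )
        if not self.freeze_backbone:
            raise InvalidConfigError(
                "backbone fine-tuning is not supported; freeze_backbone must stay True"
            )

    def to_dict(self) -> dict:
        return {
            "input_side": self.input_side,
            "channels": self.channels,
            "backbone_out_channels": self.backbone_out_channels,
            "hidden_dim": self.hidden_dim,
            "feature_dim": self.feature_dim,
            "n_classes": self.n_classes,
            "dropout_p": self.dropout_p,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_image(
    image: str | Path | Image.Image | np.ndarray,
    config: ExtractionConfig,
) -> np.ndarray:
    """Decode, resize to ``input_side``² (bilinear) and standardize each
    channel with the configured mean/std.  Grayscale inputs are promoted to
    3 channels.  Returns a (3, S, S) float64 array; deterministic."""
    if isinstance(image, (str, Path)):
        path = Path(image)
        try:
            with Image.open(path) as im:
                im = im.convert("RGB")
                return _preprocess_pil(im, config)
        except (UnidentifiedImageError, OSError) as exc:
            raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    if isinstance(image, np.ndarray):
        arr = image
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0, 1) * 255).astype(np.uint8)
        image = Image.fromarray(arr, mode="RGB")
    return _preprocess_pil(image.convert("RGB"), config)


def _preprocess_pil(im: Image.Image, config: ExtractionConfig) -> np.ndarray:
    if im.size[0] < 1 or im.size[1] < 1:
        raise DecodeError("image has no pixels")
    s = config.input_side
    if im.size != (s, s):
        im = im.resize((s, s), Image.BILINEAR)
    arr = np.asarray(im, dtype=np.float64) / 255.0  # (S, S, 3)
    mean = np.asarray(config.normalization_mean)
    std = np.asarray(config.normalization_std)
    arr = (arr - mean) / std
    return arr.transpose(2, 0, 1)


# ---------------------------------------------------------------------------
# Frozen convolutional backbone
# ---------------------------------------------------------------------------

class ConvBackbone:
    """Three strided conv+ReLU stages, ~32× spatial downsampling, ending in
    ``out_channels`` feature maps.  Weights are He-initialized from the seed
    and never updated."""

    def __init__(self, out_channels: int = 576, channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        plan = [
            (channels, 64, 7, 4, 3),
            (64, 192, 5, 4, 2),
            (192, out_channels, 3, 2, 1),
        ]
        self.layers = []
        for cin, cout, k, stride, pad in plan:
            fan_in = cin * k * k
            W = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
            b = np.zeros(cout)
            self.layers.append({"W": W, "b": b, "stride": stride, "pad": pad})
        self.out_channels = out_channels

    def checksum(self) -> str:
        h = hashlib.sha256()
        for layer in self.layers:
            h.update(np.ascontiguousarray(layer["W"]).tobytes())
            h.update(np.ascontiguousarray(layer["b"]).tobytes())
        return h.hexdigest()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C, H, W) -> feature maps (N, out_channels, H', W')."""
        for layer in self.layers:
            x = _conv2d(x, layer["W"], layer["b"], layer["stride"], layer["pad"])
            np.maximum(x, 0.0, out=x)
        return x


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    o, _, kh, kw = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = cols @ W.reshape(o, -1).T + b
    return out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)


def global_average_pool(h: np.ndarray) -> np.ndarray:
    """GAP: z[c] = mean over spatial positions of h[c,·,·].

    Accepts (C, H', W') or batched (N, C, H', W')."""
    h = np.asarray(h)
    if h.ndim not in (3, 4) or h.shape[-1] < 1 or h.shape[-2] < 1:
        raise InvalidDatasetError(f"expected (C,H,W) or (N,C,H,W) with H,W >= 1, got {h.shape}")
    return h.mean(axis=(-2, -1))


# ---------------------------------------------------------------------------
# Trainable head
# ---------------------------------------------------------------------------

class Head:
    """Two Linear→BatchNorm→ReLU→Dropout blocks and a softmax output."""

    def __init__(self, config: ExtractionConfig, rng: np.random.Generator):
        din, dh, df, c = (
            config.backbone_out_channels,
            config.hidden_dim,
            config.feature_dim,
            config.n_classes,
        )
        self.config = config
        he = lambda fan_in, shape: rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.params = {
            "W1": he(din, (dh, din)), "b1": np.zeros(dh),
            "g1": np.ones(dh), "be1": np.zeros(dh),
            "W2": he(dh, (df, dh)), "b2": np.zeros(df),
            "g2": np.ones(df), "be2": np.zeros(df),
            "W3": rng.standard_normal((c, df)) / np.sqrt(df), "b3": np.zeros(c),
        }
        self.running = {
            "mu1": np.zeros(dh), "var1": np.ones(dh),
            "mu2": np.zeros(df), "var2": np.ones(df),
        }

    # -- batch norm -----------------------------------------------------
    def _bn_forward(self, a, idx, train):
        g = self.params[f"g{idx}"]
        be = self.params[f"be{idx}"]
        if train:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            self.running[f"mu{idx}"] = (
                (1 - _BN_MOMENTUM) * self.running[f"mu{idx}"] + _BN_MOMENTUM * mu
            )
            self.running[f"var{idx}"] = (
                (1 - _BN_MOMENTUM) * self.running[f"var{idx}"] + _BN_MOMENTUM * var
            )
        else:
            mu = self.running[f"mu{idx}"]
            var = self.running[f"var{idx}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (a - mu) * inv_std
        return g * xhat + be, (xhat, inv_std, g)

    @staticmethod
    def _bn_backward(dout, cache):
        xhat, inv_std, g = cache
        bsz = dout.shape[0]
        dg = (dout * xhat).sum(axis=0)
        dbe = dout.sum(axis=0)
        dxhat = dout * g
        da = (inv_std / bsz) * (
            bsz * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return da, dg, dbe

    # -- forward --------------------------------------------------------
    def forward(self, z, train=False, rng=None):
        """Returns (z2, yhat, cache).  z2 is the post-ReLU penultimate
        representation (dropout is applied after it on the training path
        only)."""
        p = self.params
        cfg = self.config
        if z.ndim != 2 or z.shape[1] != cfg.backbone_out_channels:
            raise InvalidConfigError(
                f"expected (B, {cfg.backbone_out_channels}) input, got {z.shape}"
            )
        cache = {"z": z}
        a1 = z @ p["W1"].T + p["b1"]
        bn1, cache["bn1"] = self._bn_forward(a1, 1, train)
        r1 = np.maximum(bn1, 0.0)
        cache["r1_pos"] = bn1 > 0
        if train and cfg.dropout_p > 0:
            m1 = (rng.random(r1.shape) >= cfg.dropout_p) / (1 - cfg.dropout_p)
            r1d = r1 * m1
            cache["m1"] = m1
        else:
            r1d = r1
        cache["r1d"] = r1d
        a2 = r1d @ p["W2"].T + p["b2"]
        bn2, cache["bn2"] = self._bn_forward(a2, 2, train)
        z2 = np.maximum(bn2, 0.0)
        cache["r2_pos"] = bn2 > 0
        if train and cfg.dropout_p > 0:
            m2 = (rng.random(z2.shape) >= cfg.dropout_p) / (1 - cfg.dropout_p)
            z2d = z2 * m2
            cache["m2"] = m2
        else:
            z2d = z2
        cache["z2d"] = z2d
        logits = z2d @ p["W3"].T + p["b3"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        yhat = e / e.sum(axis=1, keepdims=True)
        return z2, yhat, cache

    # -- backward -------------------------------------------------------
    def backward(self, yhat, y_onehot, cache):
        """Cross-entropy gradient through the whole head."""
        p = self.params
        bsz = yhat.shape[0]
        grads = {}
        dlogits = (yhat - y_onehot) / bsz
        grads["W3"] = dlogits.T @ cache["z2d"]
        grads["b3"] = dlogits.sum(axis=0)
        dz2d = dlogits @ p["W3"]
        if "m2" in cache:
            dz2d = dz2d * cache["m2"]
        dbn2 = dz2d * cache["r2_pos"]
        da2, grads["g2"], grads["be2"] = self._bn_backward(dbn2, cache["bn2"])
        grads["W2"] = da2.T @ cache["r1d"]
        grads["b2"] = da2.sum(axis=0)
        dr1d = da2 @ p["W2"]
        if "m1" in cache:
            dr1d = dr1d * cache["m1"]
        dbn1 = dr1d * cache["r1_pos"]
        da1, grads["g1"], grads["be1"] = self._bn_backward(dbn1, cache["bn1"])
        grads["W1"] = da1.T @ cache["z"]
        grads["b1"] = da1.sum(axis=0)
        return grads


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def forward_head(
    z: np.ndarray, head: Head, mode: str = "eval", rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run a batch of pooled vectors through the head.

    mode="eval" (deterministic: dropout off, running BN statistics) or
    "train" (batch statistics + dropout; requires ``rng``).
    Returns (z2, ŷ); every ŷ row is a probability vector.
    """
    if mode not in ("train", "eval"):
        raise InvalidConfigError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train"
    if train and rng is None:
        raise InvalidConfigError("train mode needs an rng for dropout")
    z2, yhat, _ = head.forward(np.asarray(z, dtype=np.float64), train=train, rng=rng)
    return z2, yhat


# ---------------------------------------------------------------------------
# Dataset scanning
# ---------------------------------------------------------------------------

def scan_image_tree(root: str | Path) -> tuple[list[tuple[Path, str]], list[str]]:
    """List (path, label) pairs from a class-per-subdirectory tree.

    Class-to-index mapping is alphabetical over subdirectory names; files are
    sorted within each class, so row order is deterministic.
    """
    root = Path(root)
    if not root.is_dir():
        raise InvalidDatasetError(f"{root} is not a directory")
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    pairs: list[tuple[Path, str]] = []
    for cls in classes:
        files = sorted(
            p for p in (root / cls).iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
        )
        pairs.extend((p, cls) for p in files)
    if not pairs:
        raise InvalidDatasetError(f"no images found under {root}")
    return pairs, classes


# ---------------------------------------------------------------------------
# Training and extraction
# ---------------------------------------------------------------------------

@dataclass
class Extractor:
    """Frozen backbone + (possibly trained) head + bookkeeping."""

    backbone: ConvBackbone
    head: Head
    config: ExtractionConfig
    classes: list[str]
    loss_history: list[float] = field(default_factory=list)
    initial_loss: float | None = None
    manifest: list[dict] = field(default_factory=list)

    def backbone_checksum(self) -> str:
        return self.backbone.checksum()

    def pooled(self, images: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Backbone + GAP over a (N, 3, S, S) stack, chunked for memory."""
        outs = []
        for i in range(0, images.shape[0], chunk):
            h = self.backbone.forward(images[i : i + chunk])
            outs.append(global_average_pool(h))
        return np.concatenate(outs, axis=0)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(
            {
                "format_version": 1,
                "config": self.config,
                "backbone_layers": self.backbone.layers,
                "head_params": self.head.params,
                "head_running": self.head.running,
                "classes": self.classes,
                "loss_history": self.loss_history,
                "initial_loss": self.initial_loss,
            },
            path,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Extractor":
        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise InvalidConfigError(f"unsupported checkpoint version in {path}")
        config = blob["config"]
        backbone = ConvBackbone(
            config.backbone_out_channels, config.channels, config.seed
        )
        backbone.layers = blob["backbone_layers"]
        head = Head(config, np.random.default_rng(config.seed))
        head.params = blob["head_params"]
        head.running = blob["head_running"]
        return cls(
            backbone,
            head,
            config,
            blob["classes"],
            blob["loss_history"],
            blob["initial_loss"],
        )


def _cross_entropy(yhat: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(yhat[np.arange(len(y)), y] + 1e-12)))


def train_head(images: str | Path, config: ExtractionConfig) -> Extractor:
    """Train only the head on a labelled image tree for exactly
    ``config.epochs`` passes; the backbone is frozen throughout (checksums
    verified before/after).  Returns the trained extractor with its loss
    trajectory and image manifest."""
    config.validate()
    pairs, classes = scan_image_tree(images)
    if len(classes) < 2:
        raise InvalidDatasetError(
            f"need at least 2 classes, found {len(classes)}: {classes}"
        )
    config.n_classes = len(classes)
    cls_index = {c: k for k, c in enumerate(classes)}

    X = np.stack([preprocess_image(p, config) for p, _ in pairs])
    y = np.array([cls_index[c] for _, c in pairs])
    manifest = [
        {"row": i, "path": str(p), "label": c} for i, (p, c) in enumerate(pairs)
    ]

    backbone = ConvBackbone(config.backbone_out_channels, config.channels, config.seed)
    before = backbone.checksum()
    rng = np.random.default_rng(config.seed)
    head = Head(config, rng)
    extractor = Extractor(backbone, head, config, classes, manifest=manifest)

    Z = extractor.pooled(X)
    onehot = np.eye(len(classes))[y]

    _, yhat0, _ = head.forward(Z, train=False)
    extractor.initial_loss = _cross_entropy(yhat0, y)

    opt = Adam(head.params, config.learning_rate)
    n = Z.shape[0]
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            _, yhat, cache = head.forward(Z[idx], train=True, rng=rng)
            epoch_losses.append(_cross_entropy(yhat, y[idx]) * len(idx))
            grads = head.backward(yhat, onehot[idx], cache)
            opt.step(head.params, grads)
        extractor.loss_history.append(float(np.sum(epoch_losses) / n))

    after = backbone.checksum()
    if before != after:  # pragma: no cover - freezing is structural
        raise RuntimeError("backbone parameters changed during head training")
    return extractor


def extract_features(
    images: str | Path, extractor: Extractor
) -> tuple[FeatureMatrix, list[dict]]:
    """Export the 1024-dimensional z2 representation for every image.

    Evaluation mode (dropout off, running BN statistics), so repeated calls
    are identical.  Returns the feature matrix and a row-aligned manifest.
    """
    pairs, _classes = scan_image_tree(images)
    config = extractor.config
    X = np.stack([preprocess_image(p, config) for p, _ in pairs])
    Z = extractor.pooled(X)
    z2, _ = forward_head(Z, extractor.head, mode="eval")
    labels = np.array([c for _, c in pairs], dtype=object)
    manifest = [
        {"row": i, "path": str(p), "label": c} for i, (p, c) in enumerate(pairs)
    ]
    return FeatureMatrix(z2, labels), manifest
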