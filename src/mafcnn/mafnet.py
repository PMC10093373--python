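"""MAFNet: the CoT-attention CNN feature extractor.

Architecture: a 1x1 convolution stem, four stages of residual bottleneck
modules distributed [2,2,2,2], a global-average pool and a fully-connected
head.  Inside each bottleneck the 3x3 convolution is replaced by a
Contextual Transformer (CoT) attention block that fuses a static grouped-3x3
context with a dynamic, attention-weighted aggregation of the local values
(a plain 3x3 convolution is available for ablation).  Counting the stem and
the FC head as modules, the default configuration has
1 + 3 * (2+2+2+2) + 1 = 26 convolution modules.

Training minimises softmax cross-entropy under a step learning-rate
schedule, lr = lr0 * 0.1^floor(epoch/30), with SGD momentum 0.9; the
penultimate fully-connected activations serve as the extracted features for
the downstream classifier.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concat
from ._nn import SGD, BatchNorm2d, Conv2d, Dropout, Linear, Module, ReLU

__all__ = ["MAFNetConfig", "TrainSettings", "softmax", "cross_entropy_loss",
           "lr_schedule", "CoTBlock", "MAFNet", "build_mafnet",
           "train_mafnet", "extract_features", "save_checkpoint",
           "load_checkpoint"]


# ---------------------------------------------------------------------------
# the scalar building blocks of the training objective


def softmax(z: np.ndarray) -> np.ndarray:
    """Probability vector exp(z_i) / sum exp(z), computed shift-stably."""
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(onehot_labels: np.ndarray,
                       probabilities: np.ndarray) -> float:
    """Batch-mean cross-entropy -sum_i l_i log p_i.

    Probabilities are floored at 1e-12 before the log so saturated wrong
    predictions yield a large finite loss instead of infinity.
    """
    l = np.atleast_2d(np.asarray(onehot_labels, dtype=np.float64))
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    if l.shape != p.shape:
        raise ValueError("labels and probabilities must have equal shape")
    return float(np.mean(-np.sum(l * np.log(np.maximum(p, 1e-12)), axis=1)))


def lr_schedule(lr0: float, epoch: int) -> float:
    """Step decay: lr0 * 0.1^floor(epoch / 30)."""
    if lr0 <= 0:
        raise ValueError("lr0 must be > 0")
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * 0.1 ** (epoch // 30)


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass(frozen=True)
class MAFNetConfig:
    stage_module_counts: tuple[int, int, int, int] = (2, 2, 2, 2)
    stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    input_size: int = 32
    n_classes: int = 2
    feature_dim: int = 64
    use_cot: bool = True

    def __post_init__(self):
        if len(self.stage_module_counts) != 4 or len(self.stage_channels) != 4:
            raise ValueError("four stages are required")
        if any(c < 1 for c in self.stage_module_counts):
            raise ValueError("stage module counts must be >= 1")
        if any(c < 4 for c in self.stage_channels):
            raise ValueError("stage channels must be >= 4")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.input_size < 16 or self.input_size % 8:
            raise ValueError("input_size must be >= 16 and divisible by 8")

    @property
    def conv_module_count(self) -> int:
        """Stem + three convolutions per bottleneck module + FC head."""
        return 1 + 3 * sum(self.stage_module_counts) + 1


@dataclasses.dataclass(frozen=True)
class TrainSettings:
    lr0: float = 0.01
    batch_size: int = 5
    epochs: int = 50
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# modules


class CoTBlock(Module):
    """Contextual Transformer attention over a k x k neighbourhood.

    Static path: grouped k x k convolution of the input (the contextual
    keys).  Dynamic path: a two-layer 1x1 convolution on [keys, query]
    produces one attention logit per neighbourhood position, softmax over
    the k^2 positions weights the unfolded value embedding.  Output is the
    sum of both paths, same shape as the input.
    """

    def __init__(self, channels: int, kernel: int = 3, *,
                 rng: np.random.Generator):
        super().__init__()
        if kernel < 3 or kernel % 2 == 0:
            raise ValueError("kernel must be an odd integer >= 3")
        if channels < 1:
            raise ValueError("channels must be >= 1")
        groups = 4 if channels % 4 == 0 else 1
        mid = max(channels // 2, 4)
        self.kernel = kernel
        self.key_embed = Conv2d(channels, channels, kernel, padding=kernel // 2,
                                groups=groups, bias=False, rng=rng)
        self.key_bn = BatchNorm2d(channels)
        self.value_embed = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.value_bn = BatchNorm2d(channels)
        self.att_reduce = Conv2d(2 * channels, mid, 1, rng=rng)
        self.att_bn = BatchNorm2d(mid)
        self.att_expand = Conv2d(mid, kernel * kernel, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        keys = self.key_bn(self.key_embed(x)).relu()
        att = self.att_expand(self.att_bn(self.att_reduce(
            concat([keys, x], axis=1))).relu())       # (N, k*k, H, W)
        att = ad.softmax(att, axis=1)
        n, _, h, w = att.shape
        att = att.reshape(n, 1, k * k, h, w)
        values = self.value_bn(self.value_embed(x)).unfold(k)  # (N,C,k*k,H,W)
        dynamic = (values * att).sum(axis=2)
        return keys + dynamic


class Bottleneck(Module):
    """1x1 reduce -> CoT (or plain 3x3) -> 1x1 expand, with residual."""

    def __init__(self, in_ch: int, out_ch: int, *, use_cot: bool,
                 downsample: bool, rng: np.random.Generator):
        super().__init__()
        mid = max(out_ch // 2, 4)
        self.downsample = downsample
        self.reduce = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        if use_cot:
            self.spatial = CoTBlock(mid, 3, rng=rng)
        else:
            self.spatial = Conv2d(mid, mid, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.expand = Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.project = (Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
                        if in_ch != out_ch else None)

    def forward(self, x: Tensor) -> Tensor:
        if self.downsample:
            x = x.avg_pool2()
        y = self.bn1(self.reduce(x)).relu()
        y = self.bn2(self.spatial(y)).relu()
        y = self.bn3(self.expand(y))
        shortcut = self.project(x) if self.project is not None else x
        return (y + shortcut).relu()


class MAFNet(Module):
    def __init__(self, config: MAFNetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.stage_channels
        self.stem = Conv2d(3, ch[0], 1, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(ch[0])
        blocks: list[Module] = []
        in_ch = ch[0]
        for s, (count, out_ch) in enumerate(zip(config.stage_module_counts, ch)):
            for m in range(count):
                blocks.append(Bottleneck(in_ch, out_ch, use_cot=config.use_cot,
                                         downsample=(s > 0 and m == 0), rng=rng))
                in_ch = out_ch
        self.blocks = blocks
        for i, b in enumerate(blocks):
            setattr(self, f"block{i}", b)
        self.fc1 = Linear(ch[3], config.feature_dim, rng=rng)
        self.drop = Dropout(0.5)
        # near-zero head init -> the untrained network predicts ~uniformly
        self.fc2 = Linear(config.feature_dim, config.n_classes, rng=rng,
                          init_std=0.01)

    # -- introspection ---------------------------------------------------
    @property
    def conv_module_count(self) -> int:
        return self.config.conv_module_count

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ---------------------------------------------------------
    def _trunk(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}px input, got {x.shape[2]}")
        y = self.stem_bn(self.stem(x)).relu()
        for b in self.blocks:
            y = b(y)
        return y.mean(axis=(2, 3))            # global average pool

    def features(self, x: Tensor) -> Tensor:
        """Penultimate activations (the extracted feature vector)."""
        return self.fc1(self._trunk(x)).relu()

    def forward(self, x: Tensor) -> Tensor:
        """Class-probability rows."""
        f = self.drop(self.features(x))
        return ad.softmax(self.fc2(f), axis=1)


def build_mafnet(config: MAFNetConfig, seed: int = 0) -> MAFNet:
    return MAFNet(config, seed=seed)


# ---------------------------------------------------------------------------
# training and extraction


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError("images must be (N, H, W, 3)")
    return images.transpose(0, 3, 1, 2)


def train_mafnet(network: MAFNet, images: np.ndarray, labels: np.ndarray,
                 settings: TrainSettings) -> np.ndarray:
    """Minimise cross-entropy with SGD momentum 0.9 under the step
    learning-rate schedule.  Returns the per-epoch mean training loss.
    Deterministic for a fixed seed."""
    x = _to_nchw(images)
    labels = np.asarray(labels, dtype=int)
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    if labels.min() < 0 or labels.max() >= network.config.n_classes:
        raise ValueError("labels out of range")
    rng = np.random.default_rng(settings.seed)
    for m in network.modules():
        if isinstance(m, Dropout):
            m.p = settings.dropout
            m.rng = rng
    network.train()
    opt = SGD(network.parameters(), lr=settings.lr0, momentum=0.9)
    onehot = np.eye(network.config.n_classes)[labels]
    n = x.shape[0]
    history = np.empty(settings.epochs)
    for epoch in range(settings.epochs):
        opt.lr = lr_schedule(settings.lr0, epoch)
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            probs = network(Tensor(x[idx]))
            loss = -(Tensor(onehot[idx])
                     * probs.clamp_min(1e-12).log()).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(idx))
        history[epoch] = float(np.average(losses, weights=weights))
    network.eval()
    return history


def extract_features(network: MAFNet, images: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Penultimate-layer features, one row per input image."""
    x = _to_nchw(images)
    network.eval()
    rows = [network.features(Tensor(x[i:i + batch_size])).data
            for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(rows, axis=0)


def predict_proba(network: MAFNet, images: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    x = _to_nchw(images)
    network.eval()
    rows = [network(Tensor(x[i:i + batch_size])).data
            for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# persistence


def save_checkpoint(network: MAFNet, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **network.state_dict())
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(network.config), indent=2))


def load_checkpoint(path: str | pathlib.Path) -> MAFNet:
    path = pathlib.Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    for key in ("stage_module_counts", "stage_channels"):
        cfg[key] = tuple(cfg[key])
    network = MAFNet(MAFNetConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as data:
        network.load_state_dict(dict(data.items()))
    network.eval()
    return network
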