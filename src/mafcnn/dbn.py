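"""Deep belief network classifier built from stacked RBMs.

A restricted Boltzmann machine is a bipartite energy model over binary
visible units v in {0,1}^n and hidden units h in {0,1}^m:

    E(v, h) = -a.v - b.h - v^T W h,    p(v, h) = exp(-E) / Z.

Both conditionals factorise into logistic units, which gives the Gibbs
sampler used by contrastive divergence (CD-k).  The DBN is trained greedily:
RBM 1 on the (min-max rescaled) input features, RBM 2 on RBM 1's hidden
probabilities, and so on; a multinomial logistic output layer is then
attached and the whole stack is fine-tuned with backpropagated
cross-entropy.  Continuous features are treated as visible activation
probabilities (Bernoulli convention).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from ._autodiff import Tensor, softmax
from ._nn import SGD

__all__ = ["RBMParams", "DBNConfig", "DBNClassifier", "rbm_energy",
           "partition_function", "exact_log_likelihood", "conditional_hidden",
           "conditional_visible", "train_rbm_cd", "stack_dbn", "dbn_predict"]

_ENUM_LIMIT = 20


@dataclasses.dataclass
class RBMParams:
    """Weights W (visible x hidden) and biases a (visible), b (hidden)."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W.shape != (self.a.size, self.b.size):
            raise ValueError("W must be (len(a), len(b))")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.a))
                and np.all(np.isfinite(self.b))):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.a.size

    @property
    def n_hidden(self) -> int:
        return self.b.size


@dataclasses.dataclass(frozen=True)
class DBNConfig:
    layer_sizes: tuple[int, ...] | None = None   # None -> sized from data
    cd_steps: int = 1
    rbm_lr: float = 0.5
    rbm_epochs: int = 30
    finetune_lr: float = 0.5
    finetune_epochs: int = 60
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.layer_sizes is not None and (
                len(self.layer_sizes) < 1 or any(s < 1 for s in self.layer_sizes)):
            raise ValueError("layer_sizes must be >= 1 positive widths")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        for name in ("rbm_lr", "finetune_lr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all((x == 0.0) | (x == 1.0)):
        raise ValueError(f"{name} must be binary (0/1)")
    return x


def rbm_energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Joint configuration energy of one (v, h) state."""
    v = _check_binary(v, "v")
    h = _check_binary(h, "h")
    return float(-params.a @ v - params.b @ h - v @ params.W @ h)


def _all_states(n: int) -> np.ndarray:
    """All 2^n binary vectors, row i = binary digits of i (LSB first)."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.float64)


def partition_function(params: RBMParams) -> float:
    """Exact Z by enumerating all 2^(n+m) joint states."""
    n, m = params.n_visible, params.n_hidden
    if n + m > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to n + m <= {_ENUM_LIMIT}")
    V = _all_states(n)                      # (2^n, n)
    H = _all_states(m)                      # (2^m, m)
    # -E over the joint grid
    neg_e = (V @ params.a)[:, None] + (H @ params.b)[None, :] + V @ params.W @ H.T
    return float(np.exp(neg_e).sum())


def exact_log_likelihood(data: np.ndarray, params: RBMParams) -> float:
    """Mean log p(v) over data rows, marginalising h analytically and
    normalising with the enumerated Z (enumerable models only)."""
    data = np.asarray(data, dtype=np.float64)
    z = partition_function(params)
    free = data @ params.a + np.sum(
        np.log1p(np.exp(data @ params.W + params.b)), axis=1)
    return float(np.mean(free) - np.log(z))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def conditional_hidden(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(b_j + sum_i w_ij v_i); accepts binary states
    or mean-field activations in [0, 1]."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != params.n_visible:
        raise ValueError("visible dimension mismatch")
    return _sigmoid(v @ params.W + params.b)


def conditional_visible(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(a_i + sum_j w_ij h_j)."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("hidden dimension mismatch")
    return _sigmoid(h @ params.W.T + params.a)


def train_rbm_cd(data: np.ndarray, n_hidden: int, config: DBNConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[RBMParams, np.ndarray]:
    """Contrastive-divergence training (CD-k, minibatch, no momentum).

    Positive statistics use the data and p(h|v0); negative statistics come
    from k Gibbs steps with mean-field visible reconstructions.  Returns the
    trained parameters and one mean squared one-step reconstruction error
    per epoch.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D array")
    if np.any(data < 0) or np.any(data > 1):
        raise ValueError("data rows must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_samples, n_visible = data.shape
    params = RBMParams(W=rng.normal(0.0, 0.01, (n_visible, n_hidden)),
                       a=np.zeros(n_visible), b=np.zeros(n_hidden))
    history = np.empty(config.rbm_epochs)
    for epoch in range(config.rbm_epochs):
        order = rng.permutation(n_samples)
        errors = []
        for start in range(0, n_samples, config.batch_size):
            v0 = data[order[start:start + config.batch_size]]
            ph0 = conditional_hidden(v0, params)
            h = (rng.random(ph0.shape) < ph0).astype(np.float64)
            for step in range(config.cd_steps):
                vk = conditional_visible(h, params)
                phk = conditional_hidden(vk, params)
                if step < config.cd_steps - 1:
                    h = (rng.random(phk.shape) < phk).astype(np.float64)
            m = v0.shape[0]
            params.W += config.rbm_lr * (v0.T @ ph0 - vk.T @ phk) / m
            params.a += config.rbm_lr * np.mean(v0 - vk, axis=0)
            params.b += config.rbm_lr * np.mean(ph0 - phk, axis=0)
            errors.append(float(np.mean((v0 - vk) ** 2)))
        history[epoch] = float(np.mean(errors))
    return params, history


def _default_layer_sizes(n_features: int) -> tuple[int, ...]:
    cap = max(8, 4 * n_features)
    return tuple(min(w, cap) for w in (256, 128, 64))


class DBNClassifier:
    """Greedy RBM stack (three hidden layers by default) with a multinomial
    logistic output, fine-tuned end to end."""

    def __init__(self, config: DBNConfig | None = None):
        self.config = config or DBNConfig()
        self.rbms: list[RBMParams] = []
        self.out_W: np.ndarray | None = None
        self.out_b: np.ndarray | None = None
        self._feat_min: np.ndarray | None = None
        self._feat_range: np.ndarray | None = None
        self.n_classes: int | None = None

    # -- scaling -------------------------------------------------------
    def _rescale(self, features: np.ndarray, fit: bool) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if fit:
            self._feat_min = features.min(axis=0)
            rng = features.max(axis=0) - self._feat_min
            self._feat_range = np.where(rng > 0, rng, 1.0)
        return np.clip((features - self._feat_min) / self._feat_range, 0.0, 1.0)

    # -- training ------------------------------------------------------
    def fit(self, features: np.ndarray, labels: np.ndarray) -> "DBNClassifier":
        features = np.asarray(features, dtype=np.float64)
        labels = np.asarray(labels, dtype=int)
        if features.shape[0] != labels.shape[0]:
            raise ValueError("feature/label count mismatch")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        x = self._rescale(features, fit=True)
        self.n_classes = int(labels.max()) + 1
        sizes = (cfg.layer_sizes if cfg.layer_sizes is not None
                 else _default_layer_sizes(features.shape[1]))

        # greedy layer-wise pre-training
        self.rbms = []
        rep = x
        for width in sizes:
            params, _ = train_rbm_cd(rep, width, cfg, rng)
            self.rbms.append(params)
            rep = conditional_hidden(rep, params)

        # supervised fine-tuning through the logistic stack
        Ws = [Tensor(p.W.copy(), requires_grad=True) for p in self.rbms]
        bs = [Tensor(p.b.copy(), requires_grad=True) for p in self.rbms]
        out_w = Tensor(rng.normal(0.0, 0.01, (sizes[-1], self.n_classes)),
                       requires_grad=True)
        out_b = Tensor(np.zeros(self.n_classes), requires_grad=True)
        trainables = Ws + bs + [out_w, out_b]
        opt = SGD(trainables, lr=cfg.finetune_lr, momentum=0.9)
        onehot = np.eye(self.n_classes)[labels]
        n = x.shape[0]
        for _ in range(cfg.finetune_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                t = Tensor(x[idx])
                for W, b in zip(Ws, bs):
                    t = (t @ W + b).sigmoid()
                probs = softmax(t @ out_w + out_b, axis=1)
                loss = -(Tensor(onehot[idx])
                         * probs.clamp_min(1e-12).log()).sum() * (1.0 / len(idx))
                opt.zero_grad()
                loss.backward()
                opt.step()
        for p, W, b in zip(self.rbms, Ws, bs):
            p.W, p.b = W.data, b.data
        self.out_W, self.out_b = out_w.data, out_b.data
        return self

    # -- inference -----------------------------------------------------
    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if self.out_W is None:
            raise RuntimeError("classifier is not trained")
        x = self._rescale(features, fit=False)
        if x.shape[1] != self.rbms[0].n_visible:
            raise ValueError("feature dimension mismatch")
        for p in self.rbms:
            x = conditional_hidden(x, p)
        logits = x @ self.out_W + self.out_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        arrays = {"out_W": self.out_W, "out_b": self.out_b,
                  "feat_min": self._feat_min, "feat_range": self._feat_range}
        for i, p in enumerate(self.rbms):
            arrays |= {f"W{i}": p.W, f"a{i}": p.a, f"b{i}": p.b}
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {"n_layers": len(self.rbms), "n_classes": self.n_classes,
                "config": dataclasses.asdict(self.config)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "DBNClassifier":
        path = pathlib.Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = meta["config"]
        if cfg_dict.get("layer_sizes") is not None:
            cfg_dict["layer_sizes"] = tuple(cfg_dict["layer_sizes"])
        model = cls(DBNConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz")) as data:
            model.rbms = [RBMParams(W=data[f"W{i}"], a=data[f"a{i}"],
                                    b=data[f"b{i}"])
                          for i in range(meta["n_layers"])]
            model.out_W = data["out_W"]
            model.out_b = data["out_b"]
            model._feat_min = data["feat_min"]
            model._feat_range = data["feat_range"]
        model.n_classes = meta["n_classes"]
        return model


def stack_dbn(features: np.ndarray, labels: np.ndarray,
              config: DBNConfig | None = None) -> DBNClassifier:
    """Train a DBN classifier on a feature matrix (functional wrapper)."""
    return DBNClassifier(config).fit(features, labels)


def dbn_predict(model: DBNClassifier, features: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    probs = model.predict_proba(features)
    return np.argmax(probs, axis=1), probs
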