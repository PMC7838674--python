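"""Classification backbone: residual CNN with DMS layers.

Layer order: stem convolution + ReLU -> 2x2 max-pool -> residual stages,
each stage followed by one dynamic multi-scale layer -> global max-pool ->
fully connected softmax head over the two classes (left / right).  The
penultimate pooling is max rather than the conventional average pooling so
the head sees the most salient activation of each feature channel.

Residual blocks come in the two standard flavours: *basic* (two same-size
convolutions) and *bottleneck* (1x1 reduce, spatial convolution, 1x1
expand).  ReLU follows every convolution and the skip addition.  The exact
depth and widths are configurable through :class:`NetworkSpec`; the default
is a small three-stage network sized for few-hundred-trial EEG datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng

from . import autodiff as ad
from .autodiff import Tensor
from .dms import DMSConfig, DMSLayer

BLOCK_KINDS = ("basic", "bottleneck")


@dataclass(frozen=True)
class NetworkSpec:
    """Backbone layout: stem, residual stages, DMS placement, head."""

    stem: tuple[int, int, int] = (3, 16, 2)  # (kernel, filters, pool size)
    stages: tuple[tuple[int, int, int], ...] = ((2, 16, 1), (2, 32, 2), (2, 64, 2))
    block_kind: str = "basic"
    dms: DMSConfig = field(default_factory=DMSConfig)
    head_pool: str = "max"
    n_classes: int = 2

    def __post_init__(self):
        if self.n_classes != 2:
            raise ValueError("this classifier is strictly two-class")
        if self.block_kind not in BLOCK_KINDS:
            raise ValueError(f"block_kind must be one of {BLOCK_KINDS}")
        if self.head_pool not in ("max", "avg"):
            raise ValueError("head_pool must be 'max' or 'avg'")
        if self.stem[2] not in (1, 2):
            raise ValueError("stem pool size must be 1 (no pool) or 2")
        for n_blocks, filters, stride in self.stages:
            if filters < self.dms.n_splits:
                raise ValueError(
                    f"stage width {filters} smaller than dms.n_splits="
                    f"{self.dms.n_splits}")
            if n_blocks < 1 or stride < 1:
                raise ValueError("stages need n_blocks >= 1 and stride >= 1")

    def to_dict(self) -> dict:
        if self.dms.kernel_rule is not None:
            raise ValueError("custom kernel rules are not serialisable")
        return {"stem": list(self.stem),
                "stages": [list(s) for s in self.stages],
                "block_kind": self.block_kind,
                "dms": {"n_splits": self.dms.n_splits,
                        "enabled_branches": list(self.dms.enabled_branches)},
                "head_pool": self.head_pool,
                "n_classes": self.n_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(stem=tuple(d["stem"]),
                   stages=tuple(tuple(s) for s in d["stages"]),
                   block_kind=d["block_kind"],
                   dms=DMSConfig(n_splits=d["dms"]["n_splits"],
                                 enabled_branches=tuple(d["dms"]["enabled_branches"])),
                   head_pool=d["head_pool"],
                   n_classes=d["n_classes"])


def _he_kernel(rng: Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


class Conv2D:
    """Same-padded convolution layer with trainable kernel and bias."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 rng: Generator | None = None):
        init = (_he_kernel(rng, (kernel, kernel, cin, cout)) if rng is not None
                else np.zeros((kernel, kernel, cin, cout)))
        self.kernel = Tensor(init, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.params = [self.kernel, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.kernel, self.bias, stride=self.stride)


def _residual_forward_t(x: Tensor, weights: dict, kind: str,
                        stride: int = 1) -> Tensor:
    """Shared residual-block forward: y = ReLU(F(x) + shortcut(x))."""
    def conv(t, wb, s=1):
        return ad.conv2d(t, ad.as_tensor(wb["kernel"]),
                         ad.as_tensor(wb["bias"]), stride=s)

    if kind == "basic":
        f = conv(ad.relu(conv(x, weights["conv1"], stride)), weights["conv2"])
    elif kind == "bottleneck":
        f = ad.relu(conv(x, weights["reduce"], stride))
        f = ad.relu(conv(f, weights["conv"]))
        f = conv(f, weights["expand"])
    else:
        raise ValueError(f"unknown block kind {kind!r}")
    if "proj" in weights and weights["proj"] is not None:
        shortcut = conv(x, weights["proj"], stride)
    else:
        if stride != 1 or f.data.shape != x.data.shape:
            raise ValueError(
                f"shape change {x.data.shape} -> {f.data.shape} requires a "
                f"projection shortcut")
        shortcut = x
    return ad.relu(ad.add(f, shortcut))


def residual_block(x: np.ndarray, weights: dict, kind: str = "basic") -> np.ndarray:
    """Functional residual block on a single (H, W, C) map.

    ``weights`` follows the same schema as :class:`ResidualBlock` but with
    plain arrays: basic blocks need ``conv1``/``conv2`` entries, bottleneck
    blocks ``reduce``/``conv``/``expand``; an optional ``proj`` entry
    supplies the projection shortcut for width changes.
    """
    x = np.asarray(x, dtype=np.float64)
    out = _residual_forward_t(Tensor(x[None]), weights, kind)
    return out.data[0]


class ResidualBlock:
    def __init__(self, cin: int, cout: int, kind: str, stride: int,
                 rng: Generator, kernel: int = 3):
        self.kind = kind
        self.stride = stride
        self.params: list[Tensor] = []

        def make(cin_, cout_, k):
            kt = Tensor(_he_kernel(rng, (k, k, cin_, cout_)), requires_grad=True)
            bt = Tensor(np.zeros(cout_), requires_grad=True)
            self.params += [kt, bt]
            return {"kernel": kt, "bias": bt}

        if kind == "basic":
            self.weights = {"conv1": make(cin, cout, kernel),
                            "conv2": make(cout, cout, kernel)}
        else:
            mid = max(cout // 4, 1)
            self.weights = {"reduce": make(cin, mid, 1),
                            "conv": make(mid, mid, kernel),
                            "expand": make(mid, cout, 1)}
        if stride != 1 or cin != cout:
            self.weights["proj"] = make(cin, cout, 1)

    def __call__(self, x: Tensor) -> Tensor:
        return _residual_forward_t(x, self.weights, self.kind, self.stride)


class _Relu:
    params: list = []

    def __call__(self, x):
        return ad.relu(x)


class _MaxPool:
    params: list = []

    def __call__(self, x):
        return ad.max_pool2d(x)


class _GlobalPool:
    params: list = []

    def __init__(self, kind: str):
        self.kind = kind

    def __call__(self, x):
        return ad.global_max_pool(x) if self.kind == "max" else ad.global_avg_pool(x)


class Dense:
    def __init__(self, din: int, dout: int, rng: Generator | None):
        init = (rng.standard_normal((din, dout)) * np.sqrt(1.0 / din)
                if rng is not None else np.zeros((din, dout)))
        self.w = Tensor(init, requires_grad=True)
        self.b = Tensor(np.zeros(dout), requires_grad=True)
        self.params = [self.w, self.b]

    def __call__(self, x):
        return ad.dense(x, self.w, self.b)


@dataclass
class ModelState:
    """A built network: spec, ordered layers, flat parameter list."""

    spec: NetworkSpec
    input_shape: tuple[int, int, int]
    seed: int
    layers: list  # (name, layer, output_shape)

    @property
    def params(self) -> list[Tensor]:
        out = []
        for _, layer, _ in self.layers:
            out += layer.params
        return out

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def logits(self, batch: np.ndarray) -> Tensor:
        """Forward pass up to the pre-softmax logits (keeps the tape)."""
        x = Tensor(np.asarray(batch, dtype=np.float64))
        if x.data.ndim != 4 or x.data.shape[1:] != self.input_shape:
            raise ValueError(f"expected batch of shape (n, *{self.input_shape}), "
                             f"got {x.data.shape}")
        for _, layer, _ in self.layers:
            x = layer(x)
        return x

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities, (n, 2), rows summing to 1."""
        return ad.softmax(self.logits(batch).data)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(batch), axis=1)

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != np.asarray(w).shape:
                raise ValueError(f"weight shape {np.asarray(w).shape} != "
                                 f"parameter shape {p.data.shape}")
            p.data = np.asarray(w, dtype=np.float64).copy()

    def describe(self) -> str:
        rows = [f"{'layer':<28}{'output shape':<20}{'params':>8}"]
        for name, layer, shape in self.layers:
            n = sum(p.data.size for p in layer.params)
            rows.append(f"{name:<28}{str(shape):<20}{n:>8}")
        rows.append(f"{'total':<28}{'':<20}{self.param_count():>8}")
        return "\n".join(rows)


def build_network(spec: NetworkSpec,
                  input_shape: tuple[int, int, int] = (15, 21, 2),
                  seed: int = 0) -> ModelState:
    """Assemble the network for a given feature-tensor shape.

    Initialisation is variance-scaled and fully determined by ``seed``.
    Returns an inspectable :class:`ModelState` whose layer list records the
    propagated output shape of every layer.
    """
    rng = default_rng(seed)
    h, w, c = input_shape
    layers = []

    def ceil_div(a, s):
        return -(-a // s)

    k, filters, pool = spec.stem
    layers.append((f"stem_conv{k}x{k}", Conv2D(c, filters, k, 1, rng),
                   (h, w, filters)))
    layers.append(("stem_relu", _Relu(), (h, w, filters)))
    c = filters
    if pool > 1:
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("input too small for the stem pool")
        layers.append(("stem_maxpool", _MaxPool(), (h, w, c)))

    for si, (n_blocks, filters, stride) in enumerate(spec.stages, start=1):
        for bi in range(n_blocks):
            s = stride if bi == 0 else 1
            block = ResidualBlock(c, filters, spec.block_kind, s, rng)
            h, w = ceil_div(h, s), ceil_div(w, s)
            c = filters
            layers.append((f"stage{si}_block{bi + 1}", block, (h, w, c)))
        dms_layer = DMSLayer(c, h, w, spec.dms, rng)
        layers.append((f"stage{si}_dms", dms_layer, (h, w, c)))

    layers.append((f"global_{spec.head_pool}pool", _GlobalPool(spec.head_pool),
                   (c,)))
    layers.append(("fc", Dense(c, spec.n_classes, rng), (spec.n_classes,)))
    return ModelState(spec=spec, input_shape=tuple(input_shape), seed=seed,
                      layers=layers)


def save_checkpoint(model: ModelState, path) -> None:
    """Persist weights + spec + input shape + seed to one NPZ file."""
    meta = json.dumps({"spec": model.spec.to_dict(),
                       "input_shape": list(model.input_shape),
                       "seed": model.seed})
    arrays = {f"param_{i:04d}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        weights = [f[k] for k in sorted(f.files) if k.startswith("param_")]
    model = build_network(NetworkSpec.from_dict(meta["spec"]),
                          tuple(meta["input_shape"]), meta["seed"])
    model.set_weights(weights)
    return model
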