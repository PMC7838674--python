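"""Dynamic multi-scale (DMS) feature learning layer.

The layer splits a feature map along channels into ``n_splits`` sub-maps,
runs each through a multi-scale module — up to three parallel same-padded
2-D convolutions whose kernel sizes are tied to the sub-map's spatial
dimension d (targets d, d/2, d/4), concatenated and fused by a 1x1
convolution — chains information across sub-maps by adding the previous
module's output to the next module's input (Res2Net-style hierarchy), and
finally mixes the concatenated outputs with a channel shuffle so that later
layers see cross-split combinations.  Output shape always equals input
shape.

Two surfaces are provided: a functional NumPy API over single (H, W, C)
maps with an explicit, serialisable weight schema (used by tests and
oracles), and :class:`DMSLayer`, the trainable batched layer used by the
backbone.  Both run the same underlying tensor code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.random import Generator, default_rng

from . import autodiff as ad
from .autodiff import Tensor

BRANCH_NAMES = ("Conv1", "Conv2", "Conv3")


def default_kernel_rule(d: int) -> tuple[int, int, int]:
    """Map a spatial dimension d to the three branch kernel sizes.

    Targets d, d/2 and d/4 are mapped to usable odd kernel sizes:
    k_j = largest odd integer <= min(d, round(d / 2^(j-1))), floored at 1,
    so that same-padding stays symmetric and the largest branch is
    realisable on a d-wide map.
    """
    if d < 1:
        raise ValueError("spatial dimension must be >= 1")
    sizes = []
    for j in range(3):
        k = min(d, int(round(d / 2 ** j)))
        if k % 2 == 0:
            k -= 1
        sizes.append(max(k, 1))
    return tuple(sizes)


def dynamic_kernel_sizes(d: int, rule: Callable | None = None) -> tuple[int, int, int]:
    """Kernel sizes (k1, k2, k3) for the three branches at dimension d."""
    return (rule or default_kernel_rule)(d)


@dataclass(frozen=True)
class DMSConfig:
    """Split count, enabled branches and kernel-size rule for a DMS layer."""

    n_splits: int = 4
    enabled_branches: tuple[str, ...] = BRANCH_NAMES
    kernel_rule: Callable | None = None

    def __post_init__(self):
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        branches = tuple(self.enabled_branches)
        if not branches:
            raise ValueError("at least one branch must be enabled")
        for b in branches:
            if b not in BRANCH_NAMES:
                raise ValueError(f"unknown branch {b!r}; valid: {BRANCH_NAMES}")
        object.__setattr__(self, "enabled_branches", branches)


def split_channel_counts(C: int, n: int) -> list[int]:
    """Channel counts per sub-map: n-1 equal parts of floor(C/n), remainder last."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > C:
        raise ValueError(f"cannot split {C} channels into {n} sub-maps")
    base = C // n
    return [base] * (n - 1) + [C - base * (n - 1)]


def channel_split(F: np.ndarray, n: int) -> list[np.ndarray]:
    """Partition the trailing channel axis into n contiguous sub-maps."""
    F = np.asarray(F)
    counts = split_channel_counts(F.shape[-1], n)
    bounds = np.cumsum([0] + counts)
    return [F[..., lo:hi] for lo, hi in zip(bounds[:-1], bounds[1:])]


def shuffle_permutation(C: int, groups: int) -> np.ndarray:
    """Group-transpose permutation: view C channels as (groups x C/groups),
    read out the transpose."""
    if C % groups != 0:
        raise ValueError(f"{C} channels not divisible into {groups} groups")
    return np.arange(C).reshape(groups, C // groups).T.ravel()


def channel_shuffle(F: np.ndarray, groups: int) -> np.ndarray:
    """Apply the group-transpose channel permutation (contents unchanged)."""
    F = np.asarray(F)
    return F[..., shuffle_permutation(F.shape[-1], groups)]


# ---------------------------------------------------------------------------
# weights


def _he_init(rng: Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


def init_module_weights(c_s: int, kernel_sizes: tuple[int, int, int],
                        branches: tuple[str, ...],
                        rng: Generator | None = None) -> dict:
    """Weights for one multi-scale module M_i.

    Schema: ``{"branches": {name: {"kernel": (k,k,c_s,c_s), "bias": (c_s,)}},
    "fuse": {"kernel": (1,1,len(branches)*c_s,c_s), "bias": (c_s,)}}``.
    With ``rng=None`` all weights are zero.
    """
    def draw(shape):
        return _he_init(rng, shape) if rng is not None else np.zeros(shape)

    out = {"branches": {}}
    for name in branches:
        k = kernel_sizes[BRANCH_NAMES.index(name)]
        out["branches"][name] = {"kernel": draw((k, k, c_s, c_s)),
                                 "bias": np.zeros(c_s)}
    out["fuse"] = {"kernel": draw((1, 1, len(branches) * c_s, c_s)),
                   "bias": np.zeros(c_s)}
    return out


def init_layer_weights(C: int, d: int, cfg: DMSConfig,
                       rng: Generator | None = None) -> list[dict]:
    """Weights for a full DMS layer on a C-channel map of spatial dim d."""
    sizes = dynamic_kernel_sizes(d, cfg.kernel_rule)
    return [init_module_weights(c_s, sizes, cfg.enabled_branches, rng)
            for c_s in split_channel_counts(C, cfg.n_splits)]


# ---------------------------------------------------------------------------
# forward passes (shared tensor core)


def _module_forward_t(s: Tensor, weights: dict,
                      branches: tuple[str, ...]) -> Tensor:
    c_s = s.data.shape[-1]
    outs = []
    for name in branches:
        try:
            wb = weights["branches"][name]
        except KeyError as exc:
            raise ValueError(f"missing weights for branch {name}") from exc
        if wb["kernel"].shape[2] != c_s or wb["kernel"].shape[3] != c_s:
            raise ValueError(
                f"branch {name}: kernel {wb['kernel'].shape} does not map "
                f"{c_s} -> {c_s} channels")
        outs.append(ad.relu(ad.conv2d(s, ad.as_tensor(wb["kernel"]),
                                      ad.as_tensor(wb["bias"]))))
    cat = outs[0] if len(outs) == 1 else ad.concat_channels(outs)
    fuse = weights["fuse"]
    if fuse["kernel"].shape[2] != cat.data.shape[-1]:
        raise ValueError(
            f"fuse kernel expects {fuse['kernel'].shape[2]} channels, "
            f"got {cat.data.shape[-1]}")
    return ad.relu(ad.conv2d(cat, ad.as_tensor(fuse["kernel"]),
                             ad.as_tensor(fuse["bias"])))


def _layer_forward_t(F: Tensor, cfg: DMSConfig, weights: list[dict]) -> Tensor:
    C = F.data.shape[-1]
    counts = split_channel_counts(C, cfg.n_splits)
    bounds = np.cumsum([0] + counts)
    zs: list[Tensor] = []
    z_prev: Tensor | None = None
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        s = ad.slice_channels(F, int(lo), int(hi))
        if z_prev is not None and z_prev.data.shape[-1] == s.data.shape[-1]:
            s = ad.add(s, z_prev)
        z_prev = _module_forward_t(s, weights[i], cfg.enabled_branches)
        zs.append(z_prev)
    cat = zs[0] if len(zs) == 1 else ad.concat_channels(zs)
    groups = cfg.n_splits if C % cfg.n_splits == 0 else 1
    return ad.permute_channels(cat, shuffle_permutation(C, groups))


# ---------------------------------------------------------------------------
# functional NumPy API (single map, tape-free)


def dms_module(s: np.ndarray, cfg: DMSConfig, weights: dict) -> np.ndarray:
    """One multi-scale module on a single (H, W, C) map -> same shape."""
    s = np.asarray(s, dtype=np.float64)
    out = _module_forward_t(Tensor(s[None]), weights, cfg.enabled_branches)
    return out.data[0]


def dms_layer(F: np.ndarray, cfg: DMSConfig, weights: list[dict]) -> np.ndarray:
    """Full DMS layer on a single (H, W, C) map -> same shape."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError("expected an (H, W, C) feature map")
    out = _layer_forward_t(Tensor(F[None]), cfg, weights)
    return out.data[0]


# ---------------------------------------------------------------------------
# trainable layer


class DMSLayer:
    """Batched trainable DMS layer for the backbone (NHWC tensors)."""

    def __init__(self, C: int, H: int, W: int, cfg: DMSConfig,
                 rng: Generator | None = None):
        if cfg.n_splits > C:
            raise ValueError(f"n_splits={cfg.n_splits} exceeds {C} channels")
        self.cfg = cfg
        self.kernel_sizes = dynamic_kernel_sizes(min(H, W), cfg.kernel_rule)
        raw = init_layer_weights(C, min(H, W), cfg, rng or default_rng(0))
        # re-wrap arrays as trainable parameter tensors, preserving schema
        self.weights = []
        self.params: list[Tensor] = []
        for module in raw:
            wrapped = {"branches": {}, "fuse": None}
            for name, wb in module["branches"].items():
                kt = Tensor(wb["kernel"], requires_grad=True)
                bt = Tensor(wb["bias"], requires_grad=True)
                wrapped["branches"][name] = {"kernel": kt, "bias": bt}
                self.params += [kt, bt]
            kt = Tensor(module["fuse"]["kernel"], requires_grad=True)
            bt = Tensor(module["fuse"]["bias"], requires_grad=True)
            wrapped["fuse"] = {"kernel": kt, "bias": bt}
            self.params += [kt, bt]
            self.weights.append(wrapped)

    def __call__(self, x: Tensor) -> Tensor:
        return _layer_forward_t(x, self.cfg, self.weights)
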