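"""Self-contained oracle and invariant checks, runnable without pytest.

Each function recomputes one verifiable quantity from scratch — comparing
the production code against brute-force oracles or closed forms — and
returns it as a number, so the same routines back the ``dms-eeg selftest``
command and the repository's acceptance reporting.
"""

from __future__ import annotations

import numpy as np
from numpy.random import default_rng

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import NetworkSpec, build_network, residual_block
from .dms import (DMSConfig, channel_shuffle, channel_split, dms_layer,
                  init_layer_weights, init_module_weights, dms_module,
                  dynamic_kernel_sizes, shuffle_permutation,
                  split_channel_counts)
from .reference import conv2d_direct
from .stft import (STFTConfig, WindowSpec, WINDOW_NAMES, dft_oracle,
                   rotation_factor, stft, window_coefficients)
from .training import TrainConfig, lr_trace


def stft_oracle_max_error(n_signals: int = 50, seed: int = 0) -> float:
    """Max |production STFT frame - direct-DFT of the windowed segment|.

    Draws random signals (lengths <= 256), window names, window lengths and
    hops; every frame of the fast transform must agree with the O(N^2)
    summation oracle.
    """
    rng = default_rng(seed)
    worst = 0.0
    for _ in range(n_signals):
        name = WINDOW_NAMES[rng.integers(len(WINDOW_NAMES))]
        wlen = int(rng.integers(4, 33))
        hop = int(rng.integers(1, wlen + 1))
        n = int(rng.integers(wlen, 257))
        cfg = STFTConfig(window=WindowSpec(name, wlen), hop=hop, n_fft=wlen,
                         band=(0.0, 1.0))
        x = rng.standard_normal(n)
        fast = stft(x, cfg)
        w = window_coefficients(cfg.window)
        for m in range(fast.shape[1]):
            seg = x[m * hop : m * hop + wlen] * w
            worst = max(worst, float(np.abs(fast[:, m] - dft_oracle(seg)).max()))
    return worst


def rotation_identity_max_error(sizes=(4, 8, 16, 64)) -> float:
    """Half-period antisymmetry W_N^{k+N/2} = -W_N^k and full-period
    periodicity W_N^{k+N} = W_N^k, all k < N."""
    worst = 0.0
    for N in sizes:
        k = np.arange(N)
        worst = max(worst, float(np.abs(
            rotation_factor(N, k + N // 2) + rotation_factor(N, k)).max()))
        worst = max(worst, float(np.abs(
            rotation_factor(N, k + N) - rotation_factor(N, k)).max()))
    return worst


def _closed_form_window(name: str, N: int) -> np.ndarray:
    """Textbook closed forms, written independently of the production path."""
    n = np.arange(N, dtype=np.float64)
    if name == "boxcar":
        return np.ones(N)
    if name == "hann":
        return 0.5 - 0.5 * np.cos(2 * np.pi * n / (N - 1))
    if name == "hamming":
        return 0.54 - 0.46 * np.cos(2 * np.pi * n / (N - 1))
    if name == "bartlett":
        half = (N - 1) / 2.0
        return 1.0 - np.abs(n - half) / half
    if name == "triang":
        half = (N - 1) / 2.0
        denom = (N + 1) / 2.0 if N % 2 == 1 else N / 2.0
        return 1.0 - np.abs(n - half) / denom
    raise ValueError(name)


def window_closed_form_max_error(lengths=range(3, 66)) -> float:
    """Pointwise deviation of all five windows from their closed forms,
    and from their own mirror image (symmetry)."""
    worst = 0.0
    for name in WINDOW_NAMES:
        for N in lengths:
            w = window_coefficients(WindowSpec(name, N))
            worst = max(worst, float(np.abs(w - _closed_form_window(name, N)).max()))
            worst = max(worst, float(np.abs(w - w[::-1]).max()))
    return worst


def dms_invariant_violations(seed: int = 0) -> int:
    """Count violations of the DMS layer algebra over a shape grid.

    Checks, for (H, W, C, n_splits) with C >= n: output shape == input
    shape; split/concat round-trip exactness; shuffle bijectivity with
    multiset preservation; zero weights -> zero output.
    """
    rng = default_rng(seed)
    violations = 0
    grid = [(h, w, c, n) for h in (2, 5, 8) for w in (3, 8) for c in (4, 6, 10)
            for n in (1, 2, 3, 4) if c >= n]
    for h, w, c, n in grid:
        F = rng.standard_normal((h, w, c))
        cfg = DMSConfig(n_splits=n)
        parts = channel_split(F, n)
        if [p.shape[-1] for p in parts] != split_channel_counts(c, n):
            violations += 1
        if not np.array_equal(np.concatenate(parts, axis=-1), F):
            violations += 1
        groups = n if c % n == 0 else 1
        shuffled = channel_shuffle(F, groups)
        perm = shuffle_permutation(c, groups)
        if sorted(map(int, perm)) != list(range(c)):
            violations += 1
        inv = np.empty_like(perm)
        inv[perm] = np.arange(c)
        if not np.array_equal(shuffled[..., inv], F):
            violations += 1
        zero_w = init_layer_weights(c, min(h, w), cfg, rng=None)
        out_zero = dms_layer(F, cfg, zero_w)
        if out_zero.shape != F.shape or np.abs(out_zero).max() != 0.0:
            violations += 1
        rand_w = init_layer_weights(c, min(h, w), cfg, rng=rng)
        out = dms_layer(F, cfg, rand_w)
        if out.shape != F.shape:
            violations += 1
    return violations


def conv_oracle_max_error(seed: int = 0) -> float:
    """Max deviation of every convolution path from the nested-loop oracle.

    Covers: plain branch convolutions at several kernel sizes and strides,
    the DMS module (single 1x1 branch vs oracle composition), and both
    residual block kinds on small inputs (<= 8x8x8).
    """
    rng = default_rng(seed)
    worst = 0.0
    # raw convolution layers
    for (h, w, cin, cout, k, s) in [(8, 8, 8, 4, 3, 1), (5, 7, 2, 3, 5, 1),
                                    (8, 6, 3, 3, 1, 1), (8, 8, 4, 4, 3, 2)]:
        x = rng.standard_normal((h, w, cin))
        wk = rng.standard_normal((k, k, cin, cout))
        b = rng.standard_normal(cout)
        fast = ad.conv2d(Tensor(x[None]), Tensor(wk), Tensor(b), stride=s).data[0]
        worst = max(worst, float(np.abs(fast - conv2d_direct(x, wk, b, s)).max()))
    # single-branch 1x1 DMS module vs direct composition
    x = rng.standard_normal((6, 6, 4))
    cfg = DMSConfig(n_splits=1, enabled_branches=("Conv3",))
    wts = init_module_weights(4, dynamic_kernel_sizes(6), ("Conv3",), rng)
    got = dms_module(x, cfg, wts)
    mid = np.maximum(conv2d_direct(x, wts["branches"]["Conv3"]["kernel"],
                                   wts["branches"]["Conv3"]["bias"]), 0.0)
    ref = np.maximum(conv2d_direct(mid, wts["fuse"]["kernel"],
                                   wts["fuse"]["bias"]), 0.0)
    worst = max(worst, float(np.abs(got - ref).max()))
    # residual blocks vs oracle composition
    x = rng.standard_normal((4, 4, 2))
    wb = {"conv1": {"kernel": rng.standard_normal((3, 3, 2, 2)),
                    "bias": rng.standard_normal(2)},
          "conv2": {"kernel": rng.standard_normal((3, 3, 2, 2)),
                    "bias": rng.standard_normal(2)}}
    got = residual_block(x, wb, kind="basic")
    mid = np.maximum(conv2d_direct(x, wb["conv1"]["kernel"],
                                   wb["conv1"]["bias"]), 0.0)
    ref = np.maximum(conv2d_direct(mid, wb["conv2"]["kernel"],
                                   wb["conv2"]["bias"]) + x, 0.0)
    worst = max(worst, float(np.abs(got - ref).max()))
    wbt = {"reduce": {"kernel": rng.standard_normal((1, 1, 2, 1)),
                      "bias": rng.standard_normal(1)},
           "conv": {"kernel": rng.standard_normal((3, 3, 1, 1)),
                    "bias": rng.standard_normal(1)},
           "expand": {"kernel": rng.standard_normal((1, 1, 1, 2)),
                      "bias": rng.standard_normal(2)}}
    got = residual_block(x, wbt, kind="bottleneck")
    f = np.maximum(conv2d_direct(x, wbt["reduce"]["kernel"],
                                 wbt["reduce"]["bias"]), 0.0)
    f = np.maximum(conv2d_direct(f, wbt["conv"]["kernel"],
                                 wbt["conv"]["bias"]), 0.0)
    f = conv2d_direct(f, wbt["expand"]["kernel"], wbt["expand"]["bias"])
    worst = max(worst, float(np.abs(got - np.maximum(f + x, 0.0)).max()))
    return worst


def softmax_row_sum_max_deviation(seed: int = 0) -> float:
    """Max |sum(row) - 1| of forward-pass probabilities, random weights."""
    rng = default_rng(seed)
    model = build_network(NetworkSpec(), input_shape=(15, 21, 2), seed=seed)
    probs = model.forward(rng.standard_normal((6, 15, 21, 2)))
    return float(np.abs(probs.sum(axis=1) - 1.0).max())


def zero_weight_residual_identity_error(seed: int = 0) -> float:
    """Residual block with zero weights and identity shortcut must act as
    identity on nonnegative inputs (y = ReLU(0 + x) = x)."""
    rng = default_rng(seed)
    x = np.abs(rng.standard_normal((5, 6, 3)))
    zeros = {"conv1": {"kernel": np.zeros((3, 3, 3, 3)), "bias": np.zeros(3)},
             "conv2": {"kernel": np.zeros((3, 3, 3, 3)), "bias": np.zeros(3)}}
    return float(np.abs(residual_block(x, zeros, kind="basic") - x).max())


#: the documented toy network for the parameter-count check
TOY_SPEC = NetworkSpec(stem=(3, 8, 2), stages=((1, 8, 1),),
                       dms=DMSConfig(n_splits=2))


def toy_param_count() -> tuple[int, int]:
    """(built count, hand-computed closed form) for the documented toy spec.

    Toy layout on 15x21x2 input: 3x3 stem conv to 8 filters, 2x2 pool,
    one basic residual block at width 8, one DMS layer (2 splits of 4
    channels, spatial dim 7 -> kernels (7, 3, 1)), global max-pool, FC.
    """
    model = build_network(TOY_SPEC, input_shape=(15, 21, 2), seed=0)
    stem = 3 * 3 * 2 * 8 + 8
    block = 2 * (3 * 3 * 8 * 8 + 8)
    per_module = ((7 * 7 * 4 * 4 + 4) + (3 * 3 * 4 * 4 + 4)
                  + (1 * 1 * 4 * 4 + 4) + (1 * 1 * 12 * 4 + 4))
    fc = 8 * 2 + 2
    expected = stem + block + 2 * per_module + fc
    return model.param_count(), expected


def lr_schedule_values() -> tuple[float, float]:
    """(LR after 10 stale epochs, LR after 20 stale epochs) from 3e-4.

    A scripted never-improving validation history must drive the rate to
    1.5e-4 after the first patience window and clamp at the 1e-4 floor
    (never 7.5e-5) after the second.
    """
    cfg = TrainConfig()
    stale = [0.5] + [0.4] * 30  # one improvement, then permanently stale
    trace = lr_trace(stale, cfg)
    return trace[10], trace[20]


CHECKS = {
    "stft_oracle_max_error": (stft_oracle_max_error, lambda v: v < 1e-9),
    "rotation_identity_max_error": (rotation_identity_max_error,
                                    lambda v: v < 1e-12),
    "window_closed_form_max_error": (window_closed_form_max_error,
                                     lambda v: v < 1e-12),
    "dms_invariant_violations": (dms_invariant_violations, lambda v: v == 0),
    "conv_oracle_max_error": (conv_oracle_max_error, lambda v: v < 1e-6),
    "softmax_row_sum_max_deviation": (softmax_row_sum_max_deviation,
                                      lambda v: v < 1e-6),
    "zero_weight_residual_identity_error": (
        zero_weight_residual_identity_error, lambda v: v == 0.0),
    "toy_param_count": (toy_param_count, lambda v: v[0] == v[1]),
    "lr_schedule_values": (lr_schedule_values,
                           lambda v: v == (1.5e-4, 1e-4)),
}


def run_all(verbose: bool = False) -> list[str]:
    """Run every check; return the names of any that failed."""
    failures = []
    for name, (fn, ok) in CHECKS.items():
        value = fn()
        passed = ok(value)
        if verbose:
            print(f"{'PASS' if passed else 'FAIL'}  {name} = {value}")
        if not passed:
            failures.append(name)
    return failures
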