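"""Accuracy metric and ablation grid runners.

Accuracy is computed from a standard binary confusion matrix with *left* as
the positive class: Accuracy = (TP + TN) / (TP + TN + FP + FN), reported as
a two-decimal percentage in tables.

Four grid runners re-run the full encode -> train -> evaluate pipeline over
one varying axis while holding the others at the reference configuration
(hann window, C3/C4 channels, 3-6 s segment, all three convolution
branches, 4 channel splits):

* ``windows``   — 5 STFT windows x {C3/C4, C3/Cz/C4}  (10 cells)
* ``intervals`` — 3 s segments sliding from 3-6 s to 5-8 s  (5 cells)
* ``branches``  — every nonempty subset of the three DMS convolutions (7)
* ``splits``    — 1 to 6 channel splits  (6 cells)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import NetworkSpec, build_network
from .dms import DMSConfig
from .io import DatasetBundle, segment_trials, select_channels
from .stft import STFTConfig, WindowSpec, WINDOW_NAMES, encode_features, feature_array
from .synthetic import LABELS
from .training import TrainConfig, train_model, split_train_val

#: reference configuration each grid holds fixed on its non-varying axes
BASE_WINDOW = "hann"
BASE_CHANNELS = ("C3", "C4")
BASE_INTERVAL = (3.0, 6.0)
BASE_BRANCHES = ("Conv1", "Conv2", "Conv3")
BASE_SPLITS = 4

GRID_AXES = ("windows", "intervals", "branches", "splits")

INTERVALS = ((3.0, 6.0), (3.5, 6.5), (4.0, 7.0), (4.5, 7.5), (5.0, 8.0))
BRANCH_SUBSETS = (("Conv1",), ("Conv2",), ("Conv3",),
                  ("Conv1", "Conv2"), ("Conv1", "Conv3"), ("Conv2", "Conv3"),
                  ("Conv1", "Conv2", "Conv3"))
CHANNEL_SETS = (("C3", "C4"), ("C3", "Cz", "C4"))
SPLIT_NUMBERS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; left is the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _as_label(x) -> str:
    if isinstance(x, str):
        if x not in LABELS:
            raise ValueError(f"label {x!r} not in {LABELS}")
        return x
    return LABELS[int(x)]


def confusion(predictions, truth) -> ConfusionCounts:
    """Confusion counts from parallel label sequences (strings or 0/1)."""
    predictions = [_as_label(p) for p in predictions]
    truth = [_as_label(t) for t in truth]
    if len(predictions) != len(truth):
        raise ValueError(f"{len(predictions)} predictions for "
                         f"{len(truth)} truth labels")
    if not truth:
        raise ValueError("empty label sequences")
    tp = sum(p == "left" and t == "left" for p, t in zip(predictions, truth))
    tn = sum(p == "right" and t == "right" for p, t in zip(predictions, truth))
    fp = sum(p == "left" and t == "right" for p, t in zip(predictions, truth))
    fn = sum(p == "right" and t == "left" for p, t in zip(predictions, truth))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total, as a fraction in [0, 1]."""
    if counts.total == 0:
        raise ValueError("no evaluated trials")
    return (counts.TP + counts.TN) / counts.total


def accuracy_percent(counts: ConfusionCounts) -> float:
    """Accuracy as a percentage rounded to two decimals (table format)."""
    return round(100.0 * accuracy(counts), 2)


@dataclass
class RunResult:
    """Outcome of one grid cell: config, counts, accuracy, history."""

    config: dict
    counts: ConfusionCounts | None
    accuracy: float | None
    history: object | None
    seed: int
    error: str | None = None

    @property
    def accuracy_pct(self) -> float | None:
        return None if self.accuracy is None else round(100.0 * self.accuracy, 2)


def run_cell(bundle: DatasetBundle, *, window: str = BASE_WINDOW,
             channels=BASE_CHANNELS, interval=BASE_INTERVAL,
             branches=BASE_BRANCHES, n_splits: int = BASE_SPLITS,
             train_cfg: TrainConfig | None = None,
             spec: NetworkSpec | None = None,
             stft_cfg: STFTConfig | None = None, seed: int = 0) -> RunResult:
    """One full encode -> train -> evaluate run; accuracy on the held-out set."""
    cfg_desc = {"window": window, "channels": tuple(channels),
                "interval": tuple(interval), "branches": tuple(branches),
                "n_splits": int(n_splits)}
    train_cfg = dataclasses.replace(train_cfg or TrainConfig(), seed=seed)
    base_stft = stft_cfg or STFTConfig()
    stft_cfg = dataclasses.replace(
        base_stft, window=WindowSpec(window, base_stft.window.length))
    spec = spec or NetworkSpec()
    spec = dataclasses.replace(
        spec, dms=DMSConfig(n_splits=n_splits, enabled_branches=tuple(branches),
                            kernel_rule=spec.dms.kernel_rule))

    labeled = bundle.labeled
    prepared = segment_trials(select_channels(labeled, channels), *interval)
    features = encode_features(prepared, stft_cfg)
    X = feature_array(features)
    y = labeled.labels()
    model = build_network(spec, input_shape=X.shape[1:], seed=seed)
    train_idx, val_idx = split_train_val(y, train_cfg.val_fraction,
                                         train_cfg.seed)
    model, history = train_model(model, X, y, train_cfg,
                                 split=(train_idx, val_idx))
    preds = model.predict(X[val_idx])
    counts = confusion(preds, y[val_idx])
    return RunResult(config=cfg_desc, counts=counts, accuracy=accuracy(counts),
                     history=history, seed=seed)


def grid_cells(axis: str) -> list[dict]:
    """Enumerate the cell configurations of one ablation axis, in table order."""
    if axis == "windows":
        return [{"window": w, "channels": ch}
                for ch in CHANNEL_SETS for w in WINDOW_NAMES]
    if axis == "intervals":
        return [{"interval": iv} for iv in INTERVALS]
    if axis == "branches":
        return [{"branches": br} for br in BRANCH_SUBSETS]
    if axis == "splits":
        return [{"n_splits": n} for n in SPLIT_NUMBERS]
    raise ValueError(f"unknown grid axis {axis!r}; choose from {GRID_AXES}")


def cell_seed(base_seed: int, index: int) -> int:
    """Independent deterministic seed for one grid cell."""
    return int(np.random.SeedSequence((base_seed, index)).generate_state(1)[0]
               % (2 ** 31))


def run_grid(bundle: DatasetBundle, axis: str, base_seed: int = 0,
             train_cfg: TrainConfig | None = None,
             spec: NetworkSpec | None = None,
             stft_cfg: STFTConfig | None = None) -> list[RunResult]:
    """Run every cell of one ablation axis; failed cells are recorded, not dropped."""
    results = []
    for i, overrides in enumerate(grid_cells(axis)):
        seed = cell_seed(base_seed, i)
        try:
            results.append(run_cell(bundle, train_cfg=train_cfg, spec=spec,
                                    stft_cfg=stft_cfg, seed=seed, **overrides))
        except Exception as exc:  # a failed cell must still appear in the table
            desc = {"window": BASE_WINDOW, "channels": BASE_CHANNELS,
                    "interval": BASE_INTERVAL, "branches": BASE_BRANCHES,
                    "n_splits": BASE_SPLITS}
            desc.update(overrides)
            results.append(RunResult(config=desc, counts=None, accuracy=None,
                                     history=None, seed=seed, error=str(exc)))
    return results


def results_table(results: list[RunResult]) -> pd.DataFrame:
    """Flatten RunResults into a tidy table (one row per grid cell)."""
    rows = []
    for r in results:
        row = {"window": r.config["window"],
               "channels": "/".join(r.config["channels"]),
               "interval": "-".join(str(v) for v in r.config["interval"]),
               "branches": "+".join(r.config["branches"]),
               "n_splits": r.config["n_splits"],
               "seed": r.seed,
               "TP": r.counts.TP if r.counts else None,
               "TN": r.counts.TN if r.counts else None,
               "FP": r.counts.FP if r.counts else None,
               "FN": r.counts.FN if r.counts else None,
               "accuracy_pct": r.accuracy_pct,
               "error": r.error}
        rows.append(row)
    return pd.DataFrame(rows)
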