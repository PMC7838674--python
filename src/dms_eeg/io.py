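"""Dataset containers and file IO for trial collections.

Real cued motor-imagery recordings of this kind are distributed as
MATLAB containers whose internal array names and axis order vary between
mirrors, so :func:`load_bci2_dataset` takes an explicit ``layout``
description instead of hard-coding a schema.  Synthetic datasets round-trip
through NPZ.  Loading never rescales or filters samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io

from .synthetic import LABELS, Trial

#: project-wide label encoding, fixed: left -> 0, right -> 1
LABEL_TO_INDEX = {"left": 0, "right": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}

#: axis-order codes: t = trials, c = channels, s = samples
_AXIS_CODES = ("tcs", "tsc", "cts", "cst", "stc", "sct")


@dataclass
class DatasetBundle:
    """A homogeneous list of trials sharing fs, channel order and length."""

    trials: list[Trial]
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self):
        self.channel_names = tuple(self.channel_names)
        for tr in self.trials:
            if tr.fs != self.fs or tuple(tr.channel_names) != self.channel_names:
                raise ValueError("trial metadata inconsistent with bundle")
        lengths = {tr.n_samples for tr in self.trials}
        if len(lengths) > 1:
            raise ValueError(f"trials have unequal sample counts: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labeled(self) -> "DatasetBundle":
        """Sub-bundle containing only trials with a class label."""
        return DatasetBundle([t for t in self.trials if t.label is not None],
                             self.fs, self.channel_names)

    def data_array(self) -> np.ndarray:
        """Stack trials into an (n_trials, n_channels, n_samples) array."""
        return np.stack([t.data for t in self.trials])

    def labels(self) -> np.ndarray:
        """Integer labels (left=0, right=1); -1 for unlabeled trials."""
        return np.array([LABEL_TO_INDEX.get(t.label, -1) for t in self.trials])


def bundle_from_trials(trials: list[Trial]) -> DatasetBundle:
    if not trials:
        raise ValueError("no trials")
    return DatasetBundle(list(trials), trials[0].fs, tuple(trials[0].channel_names))


def save_dataset(trials: list[Trial], path) -> None:
    """Write trials to NPZ: data (n,c,s), labels (n, strings), fs, channels."""
    bundle = bundle_from_trials(trials)
    labels = np.array([t.label if t.label is not None else "" for t in trials])
    np.savez(path, data=bundle.data_array(), labels=labels,
             fs=np.float64(bundle.fs),
             channel_names=np.array(bundle.channel_names))


def load_dataset(path) -> DatasetBundle:
    """Read an NPZ written by :func:`save_dataset`, bit-exactly."""
    with np.load(path, allow_pickle=False) as f:
        data = f["data"]
        labels = [str(x) for x in f["labels"]]
        fs = float(f["fs"])
        channel_names = tuple(str(c) for c in f["channel_names"])
    trials = [Trial(data=data[i], channel_names=channel_names, fs=fs,
                    label=labels[i] or None, trial_id=i)
              for i in range(data.shape[0])]
    return DatasetBundle(trials, fs, channel_names)


def load_bci2_dataset(path, layout: dict) -> DatasetBundle:
    """Load a MATLAB-style trial container with a declared layout.

    Parameters
    ----------
    path : a ``.mat`` (or ``.npz``) file holding a 3-D trial array and a
        label vector.
    layout : dict with keys
        ``data_key``  — name of the trial array,
        ``label_key`` — name of the label vector,
        ``axes``      — axis-order code over {t, c, s} (e.g. ``"sct"`` for
        (samples, channels, trials)),
        ``fs``        — sampling rate in Hz (default 128),
        ``channel_names`` — ordered names (default C3, Cz, C4),
        ``label_map`` — mapping from stored label values to left/right
        (default {1: left, 2: right}).

    Trials whose label is missing (NaN — the competition's undisclosed test
    cues) are returned with ``label=None`` so callers can exclude them from
    training.
    """
    path = Path(path)
    required = {"data_key", "label_key", "axes"}
    missing = required - set(layout)
    if missing:
        raise ValueError(f"layout missing keys: {sorted(missing)}")
    axes = layout["axes"]
    if axes not in _AXIS_CODES:
        raise ValueError(f"axes must be one of {_AXIS_CODES}, got {axes!r}")

    if path.suffix == ".npz":
        container = dict(np.load(path, allow_pickle=False))
    else:
        container = scipy.io.loadmat(path)
    for key in (layout["data_key"], layout["label_key"]):
        if key not in container:
            present = [k for k in container if not k.startswith("__")]
            raise ValueError(f"array {key!r} not found in {path.name}; "
                             f"file contains {present}")

    raw = np.asarray(container[layout["data_key"]], dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError(f"array {layout['data_key']!r} must be 3-D, "
                         f"got shape {raw.shape}")
    # reorder declared axes to (trials, channels, samples)
    perm = [axes.index(a) for a in "tcs"]
    data = np.transpose(raw, perm)
    if not np.isfinite(data).all():
        raise ValueError(f"array {layout['data_key']!r} contains non-finite samples")

    raw_labels = np.asarray(container[layout["label_key"]], dtype=np.float64).ravel()
    if raw_labels.size != data.shape[0]:
        raise ValueError(
            f"label vector length {raw_labels.size} does not match "
            f"{data.shape[0]} trials (check the declared axis order)")
    label_map = {float(k): v for k, v in
                 layout.get("label_map", {1: "left", 2: "right"}).items()}
    for v in label_map.values():
        if v not in LABELS:
            raise ValueError(f"label_map values must be in {LABELS}")

    fs = float(layout.get("fs", 128.0))
    channel_names = tuple(layout.get("channel_names", ("C3", "Cz", "C4")))
    if len(channel_names) != data.shape[1]:
        raise ValueError(f"{len(channel_names)} channel names for "
                         f"{data.shape[1]} channels")
    trials = []
    for i in range(data.shape[0]):
        if np.isnan(raw_labels[i]):
            label = None
        else:
            value = float(raw_labels[i])
            if value not in label_map:
                raise ValueError(f"trial {i}: label value {value} not in label_map")
            label = label_map[value]
        trials.append(Trial(data=data[i], channel_names=channel_names,
                            fs=fs, label=label, trial_id=i))
    return DatasetBundle(trials, fs, channel_names)


def select_channels(bundle: DatasetBundle, names) -> DatasetBundle:
    """Restrict every trial to the named channels, in the given order."""
    names = tuple(names)
    if not names:
        raise ValueError("channel selection must be nonempty")
    for nm in names:
        if nm not in bundle.channel_names:
            raise ValueError(f"unknown channel {nm!r}; "
                             f"valid names: {list(bundle.channel_names)}")
    idx = [bundle.channel_names.index(nm) for nm in names]
    trials = [Trial(data=t.data[idx], channel_names=names, fs=t.fs,
                    label=t.label, trial_id=t.trial_id) for t in bundle.trials]
    return DatasetBundle(trials, bundle.fs, names)


def segment_trials(bundle: DatasetBundle, t0: float, t1: float) -> DatasetBundle:
    """Cut every trial to the half-open sample window [round(t0*fs), round(t1*fs))."""
    if not bundle.trials:
        raise ValueError("empty bundle")
    n = bundle.trials[0].n_samples
    duration = n / bundle.fs
    if not (0.0 <= t0 < t1 <= duration + 1e-9):
        raise ValueError(f"window [{t0}, {t1}] outside trial of {duration} s")
    i0 = int(round(t0 * bundle.fs))
    i1 = int(round(t1 * bundle.fs))
    if i1 > n:
        raise ValueError(f"window end sample {i1} exceeds trial length {n}")
    trials = [Trial(data=t.data[:, i0:i1], channel_names=t.channel_names,
                    fs=t.fs, label=t.label, trial_id=t.trial_id)
              for t in bundle.trials]
    return DatasetBundle(trials, bundle.fs, bundle.channel_names)
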