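"""Windowing and GDM ground-truth labelling.

Kinematics are cut into 3 s windows (75 samples at 25 Hz) with 70%
overlap.  The fractional hop 75 * 0.3 = 22.5 is floored to 22 samples
(overlap 70.7%): denser windows lose no data.  A window is labelled GDM
when at least one third of its samples are GDM, which in turn holds for
bimanual samples and for unimanual samples on the active side.

Normalization is per channel with statistics pooled over all training
windows, fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WINDOW_S = 3.0
OVERLAP = 0.7
GDM_WINDOW_FRACTION = 1.0 / 3.0

_CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "vel_x", "vel_y", "vel_z")


@dataclass
class WindowSet:
    """Windows for one wrist: an (n_windows, win_len, 6) array plus metadata.

    Channels 0-2 are filtered acceleration, 3-5 band-passed velocity.
    ``start`` holds each window's first sample index in the source stream.
    """

    subject_id: str
    side: str
    fs: float
    data: np.ndarray  # (n_windows, win_len, 6)
    start: np.ndarray  # (n_windows,) int
    gdm_label: np.ndarray  # (n_windows,) bool
    task_context: np.ndarray  # (n_windows,) str: dominant task_type
    hop: int
    n_samples: int  # length of the source stream

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Normalizer:
    """Per-channel standardization fitted on a training split."""

    mean: np.ndarray  # (6,)
    std: np.ndarray  # (6,)


def gdm_ground_truth(task_type: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Per-sample GDM mask from task labels and the wrist's active role.

    GDM iff the sample is bimanual, or unimanual on the active side.
    Passive-side unimanual (recorded as task-free by the labelling
    convention), passive and task-free samples are non-GDM.
    """
    task_type = np.asarray(task_type)
    active = np.asarray(active, dtype=bool)
    known = {"unimanual", "bimanual", "passive", "task_free"}
    unknown = set(np.unique(task_type)) - known
    if unknown:
        raise ValueError(f"unknown task types: {sorted(unknown)}")
    return (task_type == "bimanual") | ((task_type == "unimanual") & active)


def window_starts(n_samples: int, win_len: int, hop: int) -> np.ndarray:
    """Start indices 0, hop, 2*hop, ... while a full window fits."""
    if n_samples < win_len:
        return np.zeros(0, dtype=int)
    return np.arange(0, n_samples - win_len + 1, hop)


def compute_hop(win_len: int, overlap: float = OVERLAP) -> int:
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    hop = int(np.floor(win_len * (1 - overlap)))
    if hop < 1:
        raise ValueError("overlap too high: zero hop")
    return hop


def make_windows(
    subject_id: str,
    side: str,
    acc: np.ndarray,
    vel: np.ndarray,
    gdm_mask: np.ndarray,
    task_type: np.ndarray,
    fs: float = 25.0,
    win_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> WindowSet:
    """Slice one wrist's kinematics into labelled 6-channel windows.

    A stream shorter than one window yields an empty WindowSet.  The GDM
    label applies the >= 1/3 sample-fraction rule; ``task_context`` is the
    most frequent task type within the window (ties broken by first
    occurrence order of :func:`numpy.unique`).
    """
    # fractional window lengths (e.g. 2.5 s at 25 Hz) floor to whole samples
    win_len = int(np.floor(win_s * fs + 1e-9))
    if win_len < 2:
        raise ValueError("window too short")
    hop = compute_hop(win_len, overlap)
    data6 = np.concatenate([np.asarray(acc, float), np.asarray(vel, float)], axis=1)
    if data6.shape[1] != 6:
        raise ValueError("acc and vel must each have 3 channels")
    n = data6.shape[0]
    starts = window_starts(n, win_len, hop)
    windows = np.stack([data6[s:s + win_len] for s in starts]) if len(starts) else \
        np.zeros((0, win_len, 6))
    gdm_mask = np.asarray(gdm_mask, dtype=bool)
    task_type = np.asarray(task_type)
    labels = np.zeros(len(starts), dtype=bool)
    context = np.empty(len(starts), dtype=object)
    for i, s in enumerate(starts):
        frac = gdm_mask[s:s + win_len].mean()
        labels[i] = frac >= GDM_WINDOW_FRACTION - 1e-12
        kinds, counts = np.unique(task_type[s:s + win_len], return_counts=True)
        context[i] = kinds[np.argmax(counts)]
    return WindowSet(
        subject_id=subject_id, side=side, fs=fs, data=windows,
        start=starts, gdm_label=labels, task_context=context,
        hop=hop, n_samples=n,
    )


def fit_normalizer(train_windows: np.ndarray) -> Normalizer:
    """Per-channel mean/SD pooled over all samples of all training windows.

    Population (ddof=0) statistics, so re-applying to the training set
    itself gives exactly mean 0 and SD 1 per channel.
    """
    x = np.asarray(train_windows, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_windows, win_len, channels)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training windows")
    flat = x.reshape(-1, x.shape[2])
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    zero = np.flatnonzero(std == 0)
    if len(zero):
        names = [_CHANNEL_NAMES[i] if i < 6 else str(i) for i in zero]
        raise ValueError(f"zero-variance channel(s): {', '.join(names)}")
    return Normalizer(mean=mean, std=std)


def apply_normalizer(norm: Normalizer, windows: np.ndarray) -> np.ndarray:
    return (np.asarray(windows, dtype=float) - norm.mean) / norm.std
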