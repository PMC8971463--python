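"""Overlapping sliding-window segmentation and window labelling.

Windows of a fixed sample length are advanced by a constant step
(default 5 samples, so consecutive windows overlap by ``w - 5``).  Each
window is assigned the activity covering its final sample; windows that
straddle a bout boundary are flagged as transition windows, and windows
ending in an unannotated stretch get the background sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from wristhar.synthetic import BACKGROUND, IMUStream, LabelInterval

logger = logging.getLogger(__name__)

#: Default analysis window sizes in samples (0.3-2.9 s at 50 Hz).
DEFAULT_WINDOW_SIZES = (15, 32, 60, 81, 100, 149)

#: Default shift between consecutive windows, in samples.
DEFAULT_STEP = 5


@dataclass(frozen=True)
class WindowInstance:
    """One fixed-length segment of a subject's stream."""

    subject_id: str
    start_index: int
    window_size: int
    label: str = BACKGROUND
    spans_transition: bool = False

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    @property
    def end_index(self) -> int:
        """Exclusive end sample index."""
        return self.start_index + self.window_size


def window_count(n_samples: int, window_size: int, step: int) -> int:
    """Number of windows of ``window_size`` advanced by ``step`` over ``n_samples``."""
    if window_size > n_samples:
        return 0
    return (n_samples - window_size) // step + 1


def segment(
    stream: IMUStream, window_size: int, step: int = DEFAULT_STEP
) -> list[WindowInstance]:
    """Cut ``stream`` into unlabelled windows starting at 0, step, 2*step, ...

    A window size exceeding the stream length yields an empty list (with
    a warning) rather than an error, so short recordings degrade
    gracefully.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    t = stream.n_samples
    if window_size > t:
        logger.warning(
            "window_size %d exceeds stream length %d for subject %s; no windows",
            window_size,
            t,
            stream.subject_id,
        )
        return []
    starts = range(0, t - window_size + 1, step)
    return [
        WindowInstance(stream.subject_id, s, window_size) for s in starts
    ]


def _subject_intervals(
    subject_id: str, labels: Sequence[LabelInterval]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ivs = sorted(
        (iv for iv in labels if iv.subject_id == subject_id),
        key=lambda iv: iv.start_index,
    )
    starts = np.array([iv.start_index for iv in ivs], dtype=int)
    ends = np.array([iv.end_index for iv in ivs], dtype=int)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"overlapping label intervals for subject {subject_id}")
    return starts, ends, [iv.activity for iv in ivs]


def _interval_at(
    starts: np.ndarray, ends: np.ndarray, index: int
) -> int | None:
    """Index of the interval containing sample ``index``, or None."""
    i = int(np.searchsorted(starts, index, side="right")) - 1
    if i >= 0 and index < ends[i]:
        return i
    return None


def label_window(
    window: WindowInstance, labels: Sequence[LabelInterval]
) -> WindowInstance:
    """Resolve a window's activity label.

    The label is the activity covering the window's final sample (the
    background sentinel if that sample is unannotated).  The window is
    flagged as spanning a transition unless a single bout — or
    uninterrupted background — covers it entirely.
    """
    starts, ends, acts = _subject_intervals(window.subject_id, labels)
    return _label_one(window, starts, ends, acts)


def _label_one(
    window: WindowInstance,
    starts: np.ndarray,
    ends: np.ndarray,
    acts: list[str],
) -> WindowInstance:
    last = window.end_index - 1
    i_end = _interval_at(starts, ends, last)
    if i_end is None:
        label = BACKGROUND
        # homogeneous background iff no interval intersects the window
        j = int(np.searchsorted(ends, window.start_index, side="right"))
        spans = j < len(starts) and starts[j] < window.end_index
    else:
        label = acts[i_end]
        spans = not (
            starts[i_end] <= window.start_index and window.end_index <= ends[i_end]
        )
    return replace(window, label=label, spans_transition=bool(spans))


def label_windows(
    windows: Sequence[WindowInstance], labels: Sequence[LabelInterval]
) -> list[WindowInstance]:
    """Vector form of :func:`label_window` (per-subject interval reuse)."""
    cache: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    out = []
    for w in windows:
        if w.subject_id not in cache:
            cache[w.subject_id] = _subject_intervals(w.subject_id, labels)
        out.append(_label_one(w, *cache[w.subject_id]))
    return out


def drop_background(windows: Sequence[WindowInstance]) -> list[WindowInstance]:
    """Remove background-labelled windows (they carry no activity class)."""
    return [w for w in windows if w.label != BACKGROUND]


def window_seconds(window_size: int, sampling_rate: float) -> float:
    """Window duration in seconds at the given sampling rate."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    return window_size / sampling_rate
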