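"""Per-window time- and frequency-domain features.

Each window yields, per signal, six time-domain statistics (mean,
median, variance, skewness, kurtosis, range) and ``3 + n_bands``
frequency-domain statistics (peak frequency, peak power, per-band
power, spectral entropy) computed from the periodogram of the
mean-removed signal.  Signals are the six raw channels plus the
accelerometer Euclidean-norm magnitude, so the default configuration
(one band) produces 7 x 10 = 70 features in a fixed order.

Conventions for degenerate input are chosen to keep every vector
finite: constant signals get skewness = kurtosis = 0 and zero spectral
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from wristhar.segmentation import WindowInstance
from wristhar.synthetic import IMUStream

#: Default frequency band (Hz) covering gross-motor cadence.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.5, 5.0),)

TIME_STAT_NAMES = ("mean", "median", "variance", "skewness", "kurtosis", "range")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values for one window."""

    window: WindowInstance
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")


def time_features(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(mean, median, variance, skewness, kurtosis, range) of a sample vector.

    Moments are population-style (ddof=0); skewness and kurtosis are the
    standardized 3rd and 4th central moments (kurtosis of a normal is 3)
    and are defined as 0 for constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mean = float(np.mean(x))
    median = float(np.median(x))
    var = float(np.var(x))
    rng = float(np.ptp(x))
    if var == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(spst.skew(x, bias=True))
        kurt = float(spst.kurtosis(x, fisher=False, bias=True))
    return mean, median, var, skew, kurt, rng


def periodogram(
    x: np.ndarray, sampling_rate: float, axis: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed signal, spectrum scaling.

    With this scaling the periodogram bins sum exactly (Parseval) to the
    population variance of the signal.
    """
    return sps.periodogram(
        x,
        fs=sampling_rate,
        window="boxcar",
        detrend="constant",
        scaling="spectrum",
        axis=axis,
    )


def freq_features(
    x: np.ndarray,
    sampling_rate: float,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> tuple[float, float, tuple[float, ...], float]:
    """(peak_frequency, peak_power, band_powers, spectral_entropy).

    Peak statistics exclude the DC bin; spectral entropy is the Shannon
    entropy (bits) of the DC-excluded periodogram normalized to a
    probability mass.  A signal that is zero after mean removal returns
    all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    nyq = sampling_rate / 2.0
    for lo, hi in bands:
        if not (0 < lo < hi <= nyq):
            raise ValueError(f"band ({lo}, {hi}) outside (0, {nyq}]")
    f, p = periodogram(x, sampling_rate)
    return _freq_stats_1d(f, p, bands)


def _freq_stats_1d(
    f: np.ndarray, p: np.ndarray, bands: Sequence[tuple[float, float]]
) -> tuple[float, float, tuple[float, ...], float]:
    p_ac = p[1:]  # DC excluded
    f_ac = f[1:]
    total = float(p_ac.sum())
    if total <= 0.0:
        return 0.0, 0.0, tuple(0.0 for _ in bands), 0.0
    k = int(np.argmax(p_ac))
    peak_f = float(f_ac[k])
    peak_p = float(p_ac[k])
    band_powers = tuple(
        float(p_ac[(f_ac >= lo) & (f_ac <= hi)].sum()) for lo, hi in bands
    )
    q = p_ac / total
    nz = q[q > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return peak_f, peak_p, band_powers, entropy


def signal_names(channels: Sequence[str]) -> tuple[str, ...]:
    """Feature signals: raw channels plus the accelerometer magnitude."""
    return tuple(channels) + ("acc_mag",)


def feature_names(
    channels: Sequence[str],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> tuple[str, ...]:
    stats = list(TIME_STAT_NAMES) + ["peak_frequency", "peak_power"]
    stats += [f"band_power_{lo:g}_{hi:g}" for lo, hi in bands]
    stats.append("spectral_entropy")
    return tuple(
        f"{sig}__{stat}" for sig in signal_names(channels) for stat in stats
    )


def _signal_matrix(samples: np.ndarray) -> np.ndarray:
    """Append the accelerometer Euclidean norm as an extra column."""
    acc_mag = np.linalg.norm(samples[:, :3], axis=1, keepdims=True)
    return np.hstack([samples, acc_mag])


def extract(
    window_samples: np.ndarray,
    sampling_rate: float,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    window: WindowInstance | None = None,
    channels: Sequence[str] | None = None,
) -> FeatureVector:
    """Full feature vector for one window's sample matrix (T x 6 channels)."""
    window_samples = np.asarray(window_samples, dtype=float)
    if not np.all(np.isfinite(window_samples)):
        where = f" (subject {window.subject_id}, start {window.start_index})" if window else ""
        raise ValueError(f"non-finite samples in window{where}")
    if channels is None:
        channels = [f"ch{i}" for i in range(window_samples.shape[1])]
    sig = _signal_matrix(window_samples)
    values: list[float] = []
    for col in sig.T:
        values.extend(time_features(col))
        pf, pp, bp, se = freq_features(col, sampling_rate, bands)
        values.extend((pf, pp, *bp, se))
    ref = window if window is not None else WindowInstance("?", 0, sig.shape[0])
    return FeatureVector(
        window=ref,
        values=np.asarray(values),
        names=feature_names(channels, bands),
    )


def extract_matrix(
    stream: IMUStream,
    windows: Sequence[WindowInstance],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> np.ndarray:
    """Vectorized feature extraction for many same-size windows of one stream.

    Returns an (n_windows, n_features) array in :func:`feature_names`
    order.  Equivalent to calling :func:`extract` per window but batched
    along the window axis for speed.
    """
    if not windows:
        return np.zeros((0, len(feature_names(stream.channels))))
    sizes = {w.window_size for w in windows}
    if len(sizes) != 1:
        raise ValueError("extract_matrix requires a single window size")
    w = sizes.pop()
    sig = _signal_matrix(stream.samples[:, :6])
    starts = np.array([win.start_index for win in windows])
    if np.any(starts + w > stream.n_samples):
        raise ValueError("window extends past end of stream")
    # (n_windows, w, n_signals)
    view = np.lib.stride_tricks.sliding_window_view(sig, w, axis=0)
    cube = view[starts].transpose(0, 2, 1)
    if not np.all(np.isfinite(cube)):
        raise ValueError(f"non-finite samples in stream {stream.subject_id}")

    n_win, _, n_sig = cube.shape
    mean = cube.mean(axis=1)
    median = np.median(cube, axis=1)
    var = cube.var(axis=1)
    centered = cube - mean[:, None, :]
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(var > 0, (centered**3).mean(axis=1) / sd**3, 0.0)
        kurt = np.where(var > 0, (centered**4).mean(axis=1) / var**2, 0.0)
    rng = cube.max(axis=1) - cube.min(axis=1)

    f, p = periodogram(cube, stream.sampling_rate, axis=1)
    p_ac = p[:, 1:, :]
    f_ac = f[1:]
    total = p_ac.sum(axis=1)
    k = p_ac.argmax(axis=1)
    peak_f = np.where(total > 0, f_ac[k], 0.0)
    peak_p = np.where(total > 0, np.take_along_axis(p_ac, k[:, None, :], 1)[:, 0, :], 0.0)
    band_ps = []
    for lo, hi in bands:
        mask = (f_ac >= lo) & (f_ac <= hi)
        band_ps.append(np.where(total > 0, p_ac[:, mask, :].sum(axis=1), 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total[:, None, :] > 0, p_ac / total[:, None, :], 0.0)
        logq = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
    entropy = -(q * logq).sum(axis=1)

    stats = [mean, median, var, skew, kurt, rng, peak_f, peak_p, *band_ps, entropy]
    # signal-major layout: all statistics of signal 0, then signal 1, ...
    stacked = np.stack(stats, axis=2)  # (n_win, n_sig, n_stats)
    return stacked.reshape(n_win, n_sig * len(stats))
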