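"""Band-power feature extraction for seizure detection.

Each 2 s window of each channel is summarized by 16 features: fifteen mean
spectral powers over overlapping bands spanning 1-20 Hz (1 Hz wide bands
stepped by 0.5 Hz through the delta/theta range, then 8-14 and 14-20 Hz for
alpha and beta) and the peak frequency.  Per-channel blocks are
concatenated channel-major into one vector, so a 22-channel scalp montage
yields 352 features and the 4-channel ear montage 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .preprocess import AnnotatedEpoch

__all__ = [
    "FEATURE_BANDS",
    "FeatureConfig",
    "FeatureMatrix",
    "window_signal",
    "band_powers",
    "peak_frequency",
    "build_feature_matrix",
]

#: The fifteen (lo, hi) Hz band definitions, in feature order.
FEATURE_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 2.0), (1.5, 2.5), (2.0, 3.0), (2.5, 3.5), (3.0, 4.0),
    (3.5, 4.5), (4.0, 5.0), (4.5, 5.5), (5.0, 6.0), (5.5, 6.5),
    (6.0, 7.0), (6.5, 7.5), (7.0, 8.0), (8.0, 14.0), (14.0, 20.0),
)


@dataclass(frozen=True)
class FeatureConfig:
    window_s: float = 2.0
    bands: tuple[tuple[float, float], ...] = FEATURE_BANDS
    peak_search_range_hz: tuple[float, float] = (1.0, 20.0)
    window_step_s: float | None = None  # None -> non-overlapping

    @property
    def step_s(self) -> float:
        return self.window_step_s if self.window_step_s is not None else self.window_s


@dataclass
class FeatureMatrix:
    """Per-window feature vectors: (n_windows, 16 * n_channels).

    Layout is channel-major: for each channel, the 15 band powers in band
    order followed by the peak frequency.
    """

    vectors: np.ndarray
    window_times_s: np.ndarray    # window start times, seconds
    labels: np.ndarray            # "seizure" | "non_seizure" per window
    channel_block_names: list[str]

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def width(self) -> int:
        return self.vectors.shape[1]

    def feature_names(self) -> list[str]:
        names = []
        for ch in self.channel_block_names:
            names += [f"{ch}.bp_{lo:g}-{hi:g}" for lo, hi in FEATURE_BANDS]
            names.append(f"{ch}.peakf")
        return names


def window_signal(epoch: AnnotatedEpoch, cfg: FeatureConfig | None = None):
    """Cut an epoch into half-open windows labeled by their midpoints.

    Returns ``(starts_s, windows, labels)`` where ``windows`` is an array
    of shape (n_windows, n_channels, window_samples) and a window is
    labeled "seizure" when its midpoint lies inside any annotation.
    """
    cfg = cfg or FeatureConfig()
    sig = epoch.signal
    fs = sig.fs_hz
    wlen = int(round(cfg.window_s * fs))
    step = int(round(cfg.step_s * fs))
    if wlen <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    starts = np.arange(0, sig.n_samples - wlen + 1, step)
    windows = np.stack([sig.data[:, s : s + wlen] for s in starts]) if len(starts) else \
        np.empty((0, sig.data.shape[0], wlen))
    starts_s = starts / fs
    mid = starts_s + cfg.window_s / 2
    labels = np.array(
        [
            "seizure"
            if any(a.onset_s <= m < a.end_s for a in epoch.annotations)
            else "non_seizure"
            for m in mid
        ]
    )
    return starts_s, windows, labels


def _periodogram(x: np.ndarray, fs_hz: float):
    """Single Hann-tapered periodogram along the last axis."""
    return scipy.signal.periodogram(
        x, fs=fs_hz, window="hann", detrend="constant", axis=-1
    )


def _band_masks(freqs: np.ndarray, bands) -> np.ndarray:
    """(n_bands, n_bins) membership by bin-center inclusion, closed interval."""
    return np.stack([(freqs >= lo) & (freqs <= hi) for lo, hi in bands])


def band_powers(
    window: np.ndarray, fs_hz: float, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Fifteen mean PSD values, one per band, in the printed band order."""
    cfg = cfg or FeatureConfig()
    freqs, psd = _periodogram(np.asarray(window, dtype=float), fs_hz)
    masks = _band_masks(freqs, cfg.bands)
    return masks @ psd / masks.sum(axis=1)


def peak_frequency(
    window: np.ndarray, fs_hz: float, cfg: FeatureConfig | None = None
) -> float:
    """Frequency of the maximum PSD bin inside the search range (1-20 Hz).

    An all-zero (degenerate) window reports 0 Hz.
    """
    cfg = cfg or FeatureConfig()
    freqs, psd = _periodogram(np.asarray(window, dtype=float), fs_hz)
    lo, hi = cfg.peak_search_range_hz
    in_range = (freqs >= lo) & (freqs <= hi)
    sub = psd[in_range]
    if sub.size == 0 or np.all(sub == 0):
        return 0.0
    return float(freqs[in_range][np.argmax(sub)])


def build_feature_matrix(
    epoch: AnnotatedEpoch,
    montage_channels: list[str] | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Concatenate the 16 per-channel features over every window of an epoch."""
    cfg = cfg or FeatureConfig()
    sig = epoch.signal
    names = montage_channels if montage_channels is not None else list(sig.channel_names)
    idx = [sig.channel_names.index(n) for n in names]

    starts_s, windows, labels = window_signal(epoch, cfg)
    n_w = len(starts_s)
    n_ch = len(idx)
    if n_w == 0:
        return FeatureMatrix(
            np.empty((0, 16 * n_ch)), starts_s, labels, list(names)
        )
    sel = windows[:, idx, :]  # (w, ch, samples)
    freqs, psd = _periodogram(sel.reshape(n_w * n_ch, -1), sig.fs_hz)
    masks = _band_masks(freqs, cfg.bands)
    bp = (psd @ masks.T) / masks.sum(axis=1)  # (w*ch, 15)

    lo, hi = cfg.peak_search_range_hz
    in_range = (freqs >= lo) & (freqs <= hi)
    sub = psd[:, in_range]
    peak = np.where(
        np.all(sub == 0, axis=1), 0.0, freqs[in_range][np.argmax(sub, axis=1)]
    )
    per_channel = np.concatenate([bp, peak[:, None]], axis=1)  # (w*ch, 16)
    vectors = per_channel.reshape(n_w, n_ch * 16)
    return FeatureMatrix(vectors, starts_s, labels, list(names))
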