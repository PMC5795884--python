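"""Preprocessing: band-pass filtering, BSS-CCA muscle-artifact removal, epoching.

The artifact-removal step is blind source separation by canonical
correlation analysis (BSS-CCA): the multichannel signal is decomposed into
sources that are maximally autocorrelated, by computing the canonical
correlations between the signal and a delayed copy of itself.  Ongoing EEG
rhythms have near-unit lag-one autocorrelation while broadband muscle
activity does not, so sources whose canonical correlation falls below a
threshold are zeroed before reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .montage import MultichannelSignal, Recording, SeizureAnnotation

__all__ = [
    "AnnotatedEpoch",
    "BsccaConfig",
    "bandpass",
    "bsscca_denoise",
    "extract_seizure_epochs",
    "sample_nonseizure_epochs",
]


@dataclass
class AnnotatedEpoch:
    """Fixed-length excerpt with epoch-relative seizure annotations."""

    signal: MultichannelSignal
    annotations: list[SeizureAnnotation]
    epoch_class: str  # "seizure" | "non_seizure"
    patient_id: int = 0
    source_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_class not in ("seizure", "non_seizure"):
            raise ValueError(f"unknown epoch class {self.epoch_class!r}")
        if self.epoch_class == "seizure" and not self.annotations:
            raise ValueError("seizure epoch without annotations")
        if self.epoch_class == "non_seizure" and self.annotations:
            raise ValueError("non-seizure epoch carries annotations")

    @property
    def duration_s(self) -> float:
        return self.signal.duration_s


@dataclass
class BsccaConfig:
    window_s: float = 10.0
    delay_samples: int = 1
    autocorr_threshold: float = 0.30  # sources below are treated as muscle

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 <= self.autocorr_threshold < 1):
            raise ValueError("autocorr_threshold must lie in [0, 1)")


def bandpass(
    sig: MultichannelSignal, low_hz: float = 0.5, high_hz: float = 35.0
) -> MultichannelSignal:
    """Zero-phase 4th-order Butterworth band-pass (default 0.5-35 Hz)."""
    nyq = sig.fs_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs {sig.fs_hz} Hz"
        )
    sos = scipy.signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=sig.fs_hz, output="sos"
    )
    out = scipy.signal.sosfiltfilt(sos, sig.data, axis=1)
    return MultichannelSignal(sig.fs_hz, list(sig.channel_names), out, sig.start_time)


def _cca_window(x: np.ndarray, delay: int, rtol: float = 1e-9):
    """Canonical correlations between a window and its delayed copy.

    Works in the numerically non-null principal subspace so that low-rank
    mixtures (fewer sources than channels) are handled exactly.  Returns
    ``(unmixing, mixing, corrs)`` with sources ``S = unmixing @ centered``
    ordered by decreasing canonical correlation, or ``None`` when the window
    is degenerate (fewer than two non-null dimensions).
    """
    xc = x - x.mean(axis=1, keepdims=True)
    x1 = xc[:, :-delay]
    x2 = xc[:, delay:]
    n = x1.shape[1]
    c11 = x1 @ x1.T / n
    c22 = x2 @ x2.T / n
    c12 = x1 @ x2.T / n

    def whiten(c):
        vals, vecs = scipy.linalg.eigh(c)
        keep = vals > max(vals.max(), 0) * rtol
        if not np.any(keep):
            return None
        return vecs[:, keep] * (1.0 / np.sqrt(vals[keep]))  # (ch, r)

    w1 = whiten(c11)
    w2 = whiten(c22)
    if w1 is None or w2 is None or min(w1.shape[1], w2.shape[1]) < 2:
        return None
    m = w1.T @ c12 @ w2
    u, s, _ = scipy.linalg.svd(m, full_matrices=False)
    corrs = np.clip(s, 0.0, 1.0)
    unmixing = u.T @ w1.T            # (r, ch): sources of the first copy
    mixing = np.linalg.pinv(unmixing)  # (ch, r)
    return unmixing, mixing, corrs


def bsscca_denoise(
    sig: MultichannelSignal, cfg: BsccaConfig | None = None
) -> MultichannelSignal:
    """Remove low-autocorrelation (muscle-like) sources window by window.

    Per non-overlapping window: decompose into CCA sources against the
    delayed copy, zero the sources whose canonical correlation falls below
    ``cfg.autocorr_threshold``, and reconstruct.  Degenerate windows are
    passed through unchanged with a warning.
    """
    cfg = cfg or BsccaConfig()
    if sig.data.shape[0] < 2:
        raise ValueError("BSS-CCA requires at least two channels")
    win = int(round(cfg.window_s * sig.fs_hz))
    win = min(win, sig.n_samples)
    if win <= cfg.delay_samples + 2:
        raise ValueError("window too short for the configured delay")
    out = sig.data.copy()
    for i0 in range(0, sig.n_samples, win):
        seg = sig.data[:, i0 : i0 + win]
        if seg.shape[1] <= cfg.delay_samples + 2:
            continue  # trailing sliver: keep unchanged
        res = _cca_window(seg, cfg.delay_samples)
        if res is None:
            warnings.warn(
                f"BSS-CCA: degenerate window at {i0 / sig.fs_hz:.1f} s kept unchanged",
                stacklevel=2,
            )
            continue
        unmixing, mixing, corrs = res
        keep = corrs >= cfg.autocorr_threshold
        mean = seg.mean(axis=1, keepdims=True)
        sources = unmixing @ (seg - mean)
        sources[~keep] = 0.0
        out[:, i0 : i0 + win] = mixing @ sources + mean
    return MultichannelSignal(sig.fs_hz, list(sig.channel_names), out, sig.start_time)


def _to_signal(rec_or_sig) -> MultichannelSignal:
    if isinstance(rec_or_sig, MultichannelSignal):
        return rec_or_sig
    if isinstance(rec_or_sig, Recording):
        return MultichannelSignal(
            rec_or_sig.fs_hz,
            list(rec_or_sig.electrode_labels),
            rec_or_sig.data,
            rec_or_sig.start_time,
        )
    raise TypeError(f"expected Recording or MultichannelSignal, got {type(rec_or_sig)}")


def extract_seizure_epochs(
    rec,
    annotations: list[SeizureAnnotation],
    epoch_len_s: float = 3600.0,
    anchor: float = 0.5,
    patient_id: int = 0,
) -> list[AnnotatedEpoch]:
    """One fixed-length epoch around each seizure (onset at ``anchor`` fraction).

    Epochs are clipped at the recording edges (truncated, with a warning)
    rather than padded; annotations are re-expressed epoch-relative, and any
    other seizure falling inside the window is carried along.
    """
    sig = _to_signal(rec)
    epochs = []
    for ann in annotations:
        t0 = ann.onset_s - anchor * epoch_len_s
        t1 = t0 + epoch_len_s
        c0, c1 = max(t0, 0.0), min(t1, sig.duration_s)
        if (c0, c1) != (t0, t1):
            warnings.warn(
                f"seizure epoch at onset {ann.onset_s:.0f} s clipped to "
                f"[{c0:.0f}, {c1:.0f}) s",
                stacklevel=2,
            )
        window = sig.slice_seconds(c0, c1)
        # the anchor seizure first, then any other seizure inside the window
        others = [a for a in annotations if a is not ann]
        rel = [
            SeizureAnnotation(
                max(a.onset_s - c0, 0.0), min(a.end_s - c0, c1 - c0), a.label
            )
            for a in [ann] + others
            if a.onset_s < c1 and a.end_s > c0
        ]
        epochs.append(
            AnnotatedEpoch(window, rel, "seizure", patient_id, source_offset_s=c0)
        )
    return epochs


def sample_nonseizure_epochs(
    rec,
    annotations: list[SeizureAnnotation],
    n: int = 5,
    epoch_len_s: float = 3600.0,
    guard_s: float = 1800.0,
    seed: int = 0,
    patient_id: int = 0,
) -> list[AnnotatedEpoch]:
    """Sample ``n`` disjoint seizure-free epochs, each >= ``guard_s`` from
    every annotation; uniform over admissible starts, deterministic per seed.

    Returns as many epochs as fit (with a warning) when the recording has
    too little seizure-free time.
    """
    sig = _to_signal(rec)
    rng = np.random.default_rng(seed)
    # forbidden zones: annotation +/- guard
    forbidden = [
        (a.onset_s - guard_s - epoch_len_s, a.end_s + guard_s) for a in annotations
    ]

    def admissible(t0: float, taken: list[tuple[float, float]]) -> bool:
        if t0 < 0 or t0 + epoch_len_s > sig.duration_s:
            return False
        for lo, hi in forbidden:
            if lo < t0 < hi:
                return False
        for lo, hi in taken:
            if t0 < hi and t0 + epoch_len_s > lo:
                return False
        return True

    taken: list[tuple[float, float]] = []
    epochs: list[AnnotatedEpoch] = []
    # draw on a fine grid of candidate starts, shuffled once
    step = max(epoch_len_s / 8.0, 1.0)
    candidates = np.arange(0.0, max(sig.duration_s - epoch_len_s, 0.0) + 1e-9, step)
    rng.shuffle(candidates)
    for t0 in candidates:
        if len(epochs) >= n:
            break
        if admissible(float(t0), taken):
            window = sig.slice_seconds(float(t0), float(t0) + epoch_len_s)
            epochs.append(
                AnnotatedEpoch(window, [], "non_seizure", patient_id,
                               source_offset_s=float(t0))
            )
            taken.append((float(t0), float(t0) + epoch_len_s))
    if len(epochs) < n:
        warnings.warn(
            f"only {len(epochs)} of {n} requested non-seizure epochs fit",
            stacklevel=2,
        )
    epochs.sort(key=lambda e: e.source_offset_s)
    return epochs
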