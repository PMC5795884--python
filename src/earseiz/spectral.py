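"""Ictal spectra and coherence-based channel similarity.

The similarity of a behind-the-ear channel to each scalp channel during
seizures is measured by the magnitude-squared coherence

    Cxy(f) = |Gxy(f)|^2 / (Gxx(f) Gyy(f)),

with the cross/auto spectral densities estimated by Welch averaging
(2 s Hann segments, 50% overlap), then averaged over 2-20 Hz and over
seizures.  The scalp channel with the highest such value is the "best
matchup" for that ear channel.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "SpectralParams",
    "SpectrumEstimate",
    "CoherenceResult",
    "MatchupTable",
    "estimate_psd",
    "coherence",
    "best_matchup",
    "aggregate_matchup_table",
    "load_matchup_reference",
    "round_half_up",
]


@dataclass(frozen=True)
class SpectralParams:
    segment_s: float = 2.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "constant"

    def nperseg(self, fs_hz: float) -> int:
        return int(round(self.segment_s * fs_hz))

    def noverlap(self, fs_hz: float) -> int:
        return int(round(self.overlap * self.nperseg(fs_hz)))

    def n_segments(self, n_samples: int, fs_hz: float) -> int:
        nper, nov = self.nperseg(fs_hz), self.noverlap(fs_hz)
        if n_samples < nper:
            return 0
        return 1 + (n_samples - nper) // (nper - nov)


@dataclass
class SpectrumEstimate:
    freqs_hz: np.ndarray
    psd: np.ndarray  # µV²/Hz
    params: SpectralParams


@dataclass
class CoherenceResult:
    freqs_hz: np.ndarray
    cxy: np.ndarray
    band_mean: float
    pair: tuple[str, str] = ("", "")
    band_hz: tuple[float, float] = (2.0, 20.0)


@dataclass
class MatchupTable:
    rows: pd.DataFrame            # pid, ear_channel, scalp_channel, coherence
    column_summary: pd.DataFrame  # ear_channel, mean, sd, n, sd_defined


def estimate_psd(
    x: np.ndarray, fs_hz: float, params: SpectralParams | None = None
) -> SpectrumEstimate:
    """Welch PSD of a single-channel segment (µV²/Hz)."""
    params = params or SpectralParams()
    x = np.asarray(x, dtype=float)
    nper = params.nperseg(fs_hz)
    if len(x) < 2 * nper:
        raise ValueError(
            f"segment of {len(x)} samples shorter than two {nper}-sample windows"
        )
    freqs, psd = scipy.signal.welch(
        x, fs=fs_hz, window=params.window, nperseg=nper,
        noverlap=params.noverlap(fs_hz), detrend=params.detrend,
    )
    return SpectrumEstimate(freqs, psd, params)


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs_hz: float,
    params: SpectralParams | None = None,
    band_hz: tuple[float, float] = (2.0, 20.0),
    pair: tuple[str, str] = ("", ""),
) -> CoherenceResult:
    """Magnitude-squared coherence on the Welch grid plus its 2-20 Hz mean.

    A single averaging segment makes the estimate identically one, so fewer
    than two segments is an error; fewer than eight draws a bias warning.
    """
    params = params or SpectralParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coherence inputs must have equal length")
    n_seg = params.n_segments(len(x), fs_hz)
    if n_seg < 2:
        raise ValueError(
            f"coherence needs >= 2 averaging segments, got {n_seg}: a "
            "single-segment estimate is identically 1"
        )
    if n_seg < 8:
        warnings.warn(
            f"only {n_seg} averaging segments; coherence bias ~1/segments is large",
            stacklevel=2,
        )
    freqs, cxy = scipy.signal.coherence(
        x, y, fs=fs_hz, window=params.window, nperseg=params.nperseg(fs_hz),
        noverlap=params.noverlap(fs_hz), detrend=params.detrend,
    )
    cxy = np.clip(cxy, 0.0, 1.0)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return CoherenceResult(freqs, cxy, float(np.mean(cxy[in_band])), pair, band_hz)


def best_matchup(
    ear_channel: np.ndarray,
    scalp_channels: dict[str, np.ndarray],
    ictal_windows_s: list[tuple[float, float]],
    fs_hz: float,
    params: SpectralParams | None = None,
    band_hz: tuple[float, float] = (2.0, 20.0),
) -> tuple[str, float]:
    """Scalp channel with highest seizure-averaged band-mean coherence.

    Band-mean coherence is computed per ictal window and averaged across
    windows for each scalp channel; ties break to the first channel in the
    supplied (montage) order.
    """
    if not ictal_windows_s:
        raise ValueError("need at least one ictal window")
    if not scalp_channels:
        raise ValueError("need at least one scalp channel")
    ear = np.asarray(ear_channel, dtype=float)
    means: dict[str, float] = {}
    for name, scalp in scalp_channels.items():
        vals = []
        for t0, t1 in ictal_windows_s:
            i0, i1 = int(np.floor(t0 * fs_hz)), int(np.floor(t1 * fs_hz))
            res = coherence(
                ear[i0:i1], np.asarray(scalp, dtype=float)[i0:i1],
                fs_hz, params, band_hz, pair=("ear", name),
            )
            vals.append(res.band_mean)
        means[name] = float(np.mean(vals))
    best = max(means, key=lambda k: means[k])  # dict order breaks ties
    return best, means[best]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in the report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_matchup_table(rows: pd.DataFrame) -> MatchupTable:
    """Per-ear-channel mean and sample SD (n-1) of best-matchup coherences.

    ``rows`` needs columns pid, ear_channel, scalp_channel, coherence.
    Reported values are rounded half-up to two decimals; a single-patient
    column gets SD 0 with ``sd_defined=False``.
    """
    required = {"pid", "ear_channel", "scalp_channel", "coherence"}
    if not required.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    summaries = []
    for ear, grp in rows.groupby("ear_channel", sort=False):
        vals = grp["coherence"].to_numpy(dtype=float)
        sd_defined = len(vals) > 1
        summaries.append(
            {
                "ear_channel": ear,
                "mean": round_half_up(float(np.mean(vals))),
                "sd": round_half_up(float(np.std(vals, ddof=1))) if sd_defined else 0.0,
                "n": len(vals),
                "sd_defined": sd_defined,
            }
        )
    return MatchupTable(rows.reset_index(drop=True), pd.DataFrame(summaries))


def load_matchup_reference() -> pd.DataFrame:
    """Published per-patient best-matchup coherences (12-patient cohort)."""
    res = importlib.resources.files("earseiz.data").joinpath("matchup_reference.csv")
    with res.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    df = pd.DataFrame(rows)
    df["pid"] = df["pid"].astype(int)
    df["coherence"] = df["coherence"].astype(float)
    return df
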